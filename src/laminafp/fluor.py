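"""Quantification of axon-label fluorescence line profiles.

A line profile runs parallel to the laminar axis: position (um from the
distal edge) versus 8-bit gray value for one label channel.  The package
quantifies where each channel's axon density peaks, the gap between the
two channels' peaks, and the overlap area shared by the two channels
after each has been normalized to unit peak.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FluorescenceProfile

__all__ = [
    "normalize_fluorescence",
    "peak_fluorescence_location",
    "peak_separation",
    "axon_overlap_area",
]


def normalize_fluorescence(
    profile: FluorescenceProfile, baseline_policy: str = "min_subtract"
) -> FluorescenceProfile:
    """Scale a profile to unit peak, optionally subtracting its minimum first.

    ``min_subtract`` removes the background floor before scaling (so the
    profile spans [0, 1]); ``none`` scales the raw values.  Idempotent:
    renormalizing an already-normalized profile leaves it unchanged.
    """
    if baseline_policy not in ("none", "min_subtract"):
        raise ValueError("baseline_policy must be 'none' or 'min_subtract'")
    gv = profile.gray_values.astype(float)
    if gv.size == 0:
        raise ValueError("profile is empty")
    if np.ptp(gv) == 0:
        raise ValueError("cannot normalize a constant profile")
    if baseline_policy == "min_subtract":
        gv = gv - gv.min()
    gv = gv / gv.max()
    return FluorescenceProfile(
        positions_um=profile.positions_um,
        gray_values=gv,
        channel=profile.channel,
        normalized=True,
        specimen_id=profile.specimen_id,
        condition=profile.condition,
    )


def peak_fluorescence_location(profile: FluorescenceProfile) -> float:
    """Position (um from the distal edge) of peak pixel intensity.

    Ties are broken toward the distal edge.
    """
    if profile.gray_values.size == 0:
        raise ValueError("profile is empty")
    return float(profile.positions_um[int(np.argmax(profile.gray_values))])


def _check_common_grid(a: FluorescenceProfile, b: FluorescenceProfile) -> None:
    if a.positions_um.size != b.positions_um.size or not np.allclose(
        a.positions_um, b.positions_um
    ):
        raise ValueError("profiles are on different position grids")


def peak_separation(profile_a: FluorescenceProfile, profile_b: FluorescenceProfile) -> float:
    """Distance (um) between the two channels' peak-fluorescence positions."""
    _check_common_grid(profile_a, profile_b)
    return abs(peak_fluorescence_location(profile_a) - peak_fluorescence_location(profile_b))


def axon_overlap_area(
    profile_a: FluorescenceProfile, profile_b: FluorescenceProfile
) -> float:
    """Area shared by two unit-peak profiles, in normalized gray value * um.

    Sum over positions of the pointwise minimum, times the grid spacing.
    Both inputs must already be normalized to peak 1.0 (channels are
    normalized independently so label intensity differences between dyes
    do not bias the overlap).
    """
    if not (profile_a.normalized and profile_b.normalized):
        raise ValueError("axon_overlap_area requires profiles normalized to unit peak")
    _check_common_grid(profile_a, profile_b)
    return float(
        np.minimum(profile_a.gray_values, profile_b.gray_values).sum() * profile_a.dx_um
    )
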