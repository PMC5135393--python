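"""Peak field-potential quantification and spatial profiles.

The monosynaptic response is taken as the peak deflection within 4 ms of
the stimulus.  Deflections are measured as absolute deviation from the
pre-stimulus baseline (mean of all samples before the stimulus), so
negative-going evoked potentials are handled naturally and the measure is
invariant to a constant offset on the trace.  Per-tectum profiles are
normalized so the largest amplitude along the axis is exactly 1.0, which
lets profiles be averaged across tecta and compared between modalities.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FPRecording, SpatialProfile

__all__ = [
    "peak_amplitude",
    "build_spatial_profile",
    "peak_location",
    "average_profiles",
    "overlap_index",
]


def peak_amplitude(
    trace: np.ndarray,
    time_ms: np.ndarray,
    stim_time_ms: float,
    window_ms: float = 4.0,
    return_sign: bool = False,
) -> float | tuple[float, int]:
    """Peak absolute deflection from baseline within the monosynaptic window.

    The window is half-open, (stim_time, stim_time + window_ms], which
    excludes any stimulus-artifact sample at t = stim_time.  Baseline is
    the mean of all pre-stimulus samples.

    With ``return_sign`` the sign of the extremal deflection (+1, -1, or 0
    for a flat window) is returned alongside the amplitude.
    """
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    if trace.shape != time_ms.shape:
        raise ValueError("trace and time_ms must have the same shape")
    pre = time_ms < stim_time_ms
    if not pre.any():
        raise ValueError("no pre-stimulus samples available for the baseline")
    if stim_time_ms + window_ms > time_ms[-1] + 1e-9:
        raise ValueError(
            f"window (stim + {window_ms:g} ms) extends beyond the trace end "
            f"({time_ms[-1]:g} ms)"
        )
    baseline = trace[pre].mean()
    in_window = (time_ms > stim_time_ms) & (time_ms <= stim_time_ms + window_ms + 1e-9)
    dev = trace[in_window] - baseline
    idx = int(np.argmax(np.abs(dev)))
    amp = float(abs(dev[idx]))
    if return_sign:
        return amp, int(np.sign(dev[idx]))
    return amp


def build_spatial_profile(
    recording: FPRecording,
    normalize: bool = True,
    window_ms: float = 4.0,
) -> SpatialProfile:
    """Spatial profile of monosynaptic peak amplitudes along the laminar axis.

    One :func:`peak_amplitude` per laminar position; with ``normalize``
    the profile is divided by its per-tectum maximum so it peaks at 1.0.
    """
    amps = np.array(
        [
            peak_amplitude(
                recording.potentials[:, j],
                recording.time_ms,
                recording.stim_time_ms,
                window_ms,
            )
            for j in range(recording.n_positions)
        ]
    )
    if normalize:
        amax = amps.max()
        if amax <= 0:
            raise ValueError("cannot normalize an all-zero amplitude profile")
        amps = amps / amax
    return SpatialProfile(
        positions_um=recording.positions_um,
        amplitudes=amps,
        normalized=normalize,
        n_contributing=1,
        modality=recording.modality,
        condition=recording.condition,
        tectum_id=recording.tectum_id,
    )


def peak_location(profile: SpatialProfile) -> float:
    """Laminar position (um from the distal edge) of the profile maximum.

    Ties are broken toward the distal edge (smallest position).
    """
    if profile.amplitudes.size == 0:
        raise ValueError("profile is empty")
    return float(profile.positions_um[int(np.argmax(profile.amplitudes))])


def _common_length(profiles: list[SpatialProfile]) -> int:
    dx = profiles[0].dx_um
    for p in profiles:
        if not np.isclose(p.dx_um, dx):
            raise ValueError("profiles have mismatched grid spacing")
        if abs(p.positions_um[0]) > 1e-9:
            raise ValueError("profiles must be aligned at the distal edge (0 um)")
    return min(p.positions_um.size for p in profiles)


def average_profiles(profiles: list[SpatialProfile]) -> SpatialProfile:
    """Pointwise mean of normalized per-tectum profiles.

    Profiles are aligned at the distal edge and truncated to the shortest
    extent (the fixed 10-um grid makes truncation exact, no interpolation).
    The result is *not* re-normalized: its maximum is the mean of the
    contributing normalized amplitudes, generally below 1.0.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    states = {p.normalized for p in profiles}
    if states != {True}:
        raise ValueError("average_profiles requires all profiles normalized")
    m = _common_length(profiles)
    stack = np.vstack([p.amplitudes[:m] for p in profiles])
    return SpatialProfile(
        positions_um=profiles[0].positions_um[:m],
        amplitudes=stack.mean(axis=0),
        normalized=False,
        n_contributing=sum(p.n_contributing for p in profiles),
        modality=profiles[0].modality if len({p.modality for p in profiles}) == 1 else None,
        condition=profiles[0].condition if len({p.condition for p in profiles}) == 1 else None,
    )


def overlap_index(
    profile_a: SpatialProfile,
    profile_b: SpatialProfile,
    weight_by_dx: bool = False,
) -> float:
    """Shared area of two normalized spatial profiles.

    Sums, over the laminar positions common to both profiles (aligned at
    the distal edge), the pointwise minimum of the two amplitude curves —
    the portion of the response profile common to both inputs.  Symmetric
    in its arguments; bounded by the smaller profile sum.  By default a
    plain sum over grid points; ``weight_by_dx`` multiplies by the grid
    spacing to give an area in amplitude*um.
    """
    for p in (profile_a, profile_b):
        if not p.normalized:
            raise ValueError("overlap_index requires normalized profiles")
    m = _common_length([profile_a, profile_b])
    if m < 1:
        raise ValueError("profiles share no common positions")
    overlap = np.minimum(profile_a.amplitudes[:m], profile_b.amplitudes[:m]).sum()
    if weight_by_dx:
        overlap *= profile_a.dx_um
    return float(overlap)
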