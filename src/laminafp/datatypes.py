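"""Core containers for laminar field-potential analysis.

All positions are measured in micrometres from the *distal edge* of the
tectal neuropil (the outermost point of the laminar axis), which is the
origin of every spatial measurement in this package.  Recordings are
time x position matrices sampled on a uniform 10-um laminar grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Modality = Literal["RGC", "HB"]

#: Conditions understood by the synthetic generator and the pipeline.
CONDITIONS = ("control", "dcr", "mk801_early", "mk801_late")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def check_uniform_grid(positions_um: np.ndarray, *, origin_zero: bool = True) -> float:
    """Validate a laminar position grid and return its spacing dx (um).

    Positions must be strictly increasing with constant spacing; by default
    they must start at 0 (the distal edge).
    """
    pos = _as_1d(positions_um, "positions_um")
    if pos.size < 2:
        raise ValueError("need at least two laminar positions")
    diffs = np.diff(pos)
    if np.any(diffs <= 0):
        raise ValueError("positions_um must be strictly increasing")
    if not np.allclose(diffs, diffs[0], rtol=0, atol=1e-9):
        bad = pos[np.argmax(~np.isclose(diffs, diffs[0], rtol=0, atol=1e-9)) + 1]
        raise ValueError(
            f"non-uniform laminar grid: spacing breaks at position {bad:g} um"
        )
    if origin_zero and abs(pos[0]) > 1e-9:
        raise ValueError(f"laminar grid must start at the distal edge (0 um), got {pos[0]:g}")
    return float(diffs[0])


@dataclass
class FPRecording:
    """Evoked field potentials for one tectum and one stimulated modality.

    ``potentials`` is a [time_sample x position] matrix in recording units;
    ``positions_um`` is the uniform laminar grid (um from the distal edge).
    """

    potentials: np.ndarray
    time_ms: np.ndarray
    positions_um: np.ndarray
    stim_time_ms: float
    modality: str = "HB"
    tectum_id: str = "t0"
    condition: str = "control"

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.time_ms = _as_1d(self.time_ms, "time_ms")
        self.positions_um = _as_1d(self.positions_um, "positions_um")
        if self.potentials.shape != (self.time_ms.size, self.positions_um.size):
            raise ValueError(
                f"potentials shape {self.potentials.shape} does not match "
                f"(n_time={self.time_ms.size}, n_pos={self.positions_um.size})"
            )
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")
        if not (self.time_ms[0] <= self.stim_time_ms <= self.time_ms[-1]):
            raise ValueError(
                f"stim_time_ms={self.stim_time_ms:g} lies outside the recorded "
                f"interval [{self.time_ms[0]:g}, {self.time_ms[-1]:g}] ms"
            )
        self.dx_um = check_uniform_grid(self.positions_um)

    @property
    def n_positions(self) -> int:
        return self.positions_um.size


@dataclass
class SpatialProfile:
    """Per-position peak response amplitudes along the laminar axis."""

    positions_um: np.ndarray
    amplitudes: np.ndarray
    normalized: bool = False
    n_contributing: int = 1
    modality: str | None = None
    condition: str | None = None
    tectum_id: str | None = None

    def __post_init__(self) -> None:
        self.positions_um = _as_1d(self.positions_um, "positions_um")
        self.amplitudes = _as_1d(self.amplitudes, "amplitudes")
        if self.positions_um.size != self.amplitudes.size:
            raise ValueError("positions_um and amplitudes must have equal length")
        self.dx_um = check_uniform_grid(self.positions_um)
        if self.normalized:
            amax = self.amplitudes.max(initial=-np.inf)
            if not np.isclose(amax, 1.0):
                raise ValueError(f"normalized profile must peak at 1.0, max is {amax:g}")
            if self.amplitudes.min() < -1e-12:
                raise ValueError("normalized amplitudes must lie in [0, 1]")


@dataclass
class CSDMap:
    """Discrete second spatial derivative of an FP recording.

    Values are in potential units per um^2 (extracellular conductivity is
    omitted, so magnitudes are arbitrary but comparable within a study).
    Interior positions only: the first and last ``n`` grid points of the
    recording have no flanking trace at distance n*dx and are excluded.
    """

    values: np.ndarray
    time_ms: np.ndarray
    positions_um: np.ndarray
    n: int
    dx_um: float
    stim_time_ms: float
    sink_polarity: str = "positive_second_derivative"
    modality: str | None = None
    tectum_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_ms = _as_1d(self.time_ms, "time_ms")
        self.positions_um = _as_1d(self.positions_um, "positions_um")
        if self.values.shape != (self.time_ms.size, self.positions_um.size):
            raise ValueError("CSD values shape does not match time/position axes")
        if self.sink_polarity not in (
            "positive_second_derivative",
            "negative_second_derivative",
        ):
            raise ValueError(f"unknown sink_polarity {self.sink_polarity!r}")
        check_uniform_grid(self.positions_um, origin_zero=False)

    @property
    def differentiation_grid_um(self) -> float:
        """Spatial span of the three-point stencil, n * dx (um)."""
        return self.n * self.dx_um

    def sink_values(self) -> np.ndarray:
        """CSD values oriented so that sinks are positive."""
        if self.sink_polarity == "positive_second_derivative":
            return self.values
        return -self.values


@dataclass
class SinkSource:
    """A localized CSD extremum (current sink or source)."""

    location_um: float
    time_ms: float
    magnitude: float
    kind: str = "primary"  # primary | secondary
    polarity: str = "sink"


@dataclass
class FluorescenceProfile:
    """Axon-label line profile: position vs. 8-bit gray value (or normalized)."""

    positions_um: np.ndarray
    gray_values: np.ndarray
    channel: str = "HB"
    normalized: bool = False
    specimen_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.positions_um = _as_1d(self.positions_um, "positions_um")
        self.gray_values = np.asarray(self.gray_values, dtype=float)
        if self.gray_values.ndim != 1 or self.gray_values.size != self.positions_um.size:
            raise ValueError("gray_values must be 1-D and match positions_um")
        self.dx_um = check_uniform_grid(self.positions_um, origin_zero=False)
        if not self.normalized:
            gv = self.gray_values
            if np.any(gv < 0) or np.any(gv > 255):
                raise ValueError("raw gray values must lie in [0, 255]")
            if not np.allclose(gv, np.round(gv)):
                raise ValueError("raw gray values must be integers (8-bit)")


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic recording."""

    true_sink_center_um: float
    true_sink_onset_ms: float
    true_secondary_center_um: float
    condition: str = "control"
    modality: str = "HB"

    def __post_init__(self) -> None:
        # The recurrent (secondary) sink co-localizes with the primary by
        # construction; this is a structural property of the forward model.
        if not np.isclose(self.true_secondary_center_um, self.true_sink_center_um):
            raise ValueError("secondary sink must co-localize with the primary sink")


@dataclass
class GroupSummary:
    """Mean, SEM, n and a two-sided confidence interval for one group."""

    mean: float
    sem: float
    n: int
    ci_low: float
    ci_high: float
    ci_method: str = "normal_z"
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")


@dataclass
class TestResult:
    """Outcome of a normality-routed two-group comparison."""

    statistic: float
    p_value: float
    test_used: str  # unpaired_t | mann_whitney
    normality_p_a: float
    normality_p_b: float
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
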