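"""Synthetic forward model for laminar evoked field potentials.

The study's raw recordings are not public, so this module generates
recordings with known ground truth that reproduce their structure: a
spatially localized monosynaptic current sink (Gaussian along the laminar
axis) flanked by balancing return sources, followed by a recurrent
(polysynaptic) sink at the same laminar location, embedded in additive
Gaussian noise.

Construction
------------
The spatial profile of the evoked potential is built first, as a
unit-depth negative Gaussian well centred at ``sink_center_um`` and
hard-windowed to zero at and beyond 3 grid steps from either axis end
(the potential therefore has *exact* compact support on the grid).  The
ground-truth CSD is its discrete second difference: a localized positive
sink at the well centre flanked by balancing negative sources — the
flanks of the well, plus a boundary-concentrated return source when the
sink sits near the window edge (return currents truncated at the
neuropil boundary).  Because the well is exactly zero on the outer grid
points, both discrete moments of the ground-truth CSD vanish exactly,
the second-difference telescoping sum is zero to float precision, and
double cumulative integration of the ground-truth CSD reproduces the
potential exactly: the stencil round trip is exact by construction.
Under the package's default sign convention a sink is a *positive*
second derivative, so the evoked potential is a negative-going
deflection centred on the sink, as evoked field potentials are.

With ``source_balance`` disabled the ground-truth CSD is instead a bare
Gaussian sink with no return sources; the potential is then obtained by
double cumulative integration with its ends pinned to zero and has no
compact support (the balance invariant deliberately does not hold).

The temporal kernel is an alpha function ``((t-lat)/tau) * exp(1-(t-lat)/tau)``
whose peak (at lat + tau, default 1 + 1.5 = 2.5 ms after the stimulus)
falls inside the 4-ms monosynaptic window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import CONDITIONS, FluorescenceProfile, FPRecording, GroundTruth

__all__ = [
    "SyntheticConfig",
    "CONDITION_PRESETS",
    "generate_fp_recording",
    "generate_cohort",
    "generate_fluorescence_pair",
]


#: Per-condition mean sink centers (um from the distal edge) and spatial SDs
#: for each modality.  Means follow the study's group statistics: control
#: RGC distal (~50 um) and HB proximal (~100 um); enucleation (dcr) shifts
#: the HB sink distally (~69 um) and broadens it; early NMDAR blockade
#: (mk801_early) collapses the separation (RGC ~72, HB ~70 um, broadened);
#: late blockade (mk801_late) leaves control-like positions but adds a
#: low-amplitude diffuse HB component in the distal territory.
CONDITION_PRESETS: dict[str, dict[str, dict]] = {
    "control": {
        "RGC": dict(center_um=50.0, width_um=15.0),
        "HB": dict(center_um=100.0, width_um=15.0),
    },
    "dcr": {
        "RGC": dict(center_um=50.0, width_um=15.0),
        "HB": dict(center_um=69.0, width_um=20.0),
    },
    "mk801_early": {
        "RGC": dict(center_um=72.0, width_um=20.0),
        "HB": dict(center_um=70.0, width_um=20.0),
    },
    "mk801_late": {
        "RGC": dict(center_um=50.0, width_um=15.0),
        "HB": dict(
            center_um=100.0,
            width_um=15.0,
            diffuse=dict(center_um=60.0, width_um=30.0, amplitude_fraction=0.25),
        ),
    },
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic evoked recording.

    Defaults reproduce the acquisition geometry of the study: a ~150-um
    laminar axis sampled every 10 um, traces digitized at 10 kHz.
    """

    axis_length_um: float = 150.0
    dx_um: float = 10.0
    sample_rate_hz: float = 10_000.0
    trace_duration_ms: float = 50.0
    stim_time_ms: float = 10.0
    condition: str = "control"
    modality: str = "HB"
    sink_center_um: float = 100.0
    sink_width_um: float = 15.0
    sink_amplitude: float = 1.0
    source_balance: bool = True
    latency_ms: float = 1.0
    rise_tau_ms: float = 1.5
    recurrent_delay_ms: float = 8.0
    recurrent_tau_ms: float = 3.0
    recurrent_amplitude_fraction: float = 0.5
    diffuse_component: dict | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_steps = self.axis_length_um / self.dx_um
        if self.axis_length_um <= 0 or self.dx_um <= 0 or abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("axis_length_um must be a positive multiple of dx_um")
        if not (0.0 <= self.sink_center_um <= self.axis_length_um):
            raise ValueError("sink_center_um must lie on the laminar axis")
        if self.sink_width_um <= 0:
            raise ValueError("sink_width_um must be positive")
        if self.trace_duration_ms <= 0:
            raise ValueError("trace_duration_ms must be positive")
        if not (0.0 < self.stim_time_ms < self.trace_duration_ms):
            raise ValueError("stim_time_ms must fall inside the trace")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.modality not in ("RGC", "HB"):
            raise ValueError("modality must be 'RGC' or 'HB'")

    def positions_um(self) -> np.ndarray:
        n = int(round(self.axis_length_um / self.dx_um)) + 1
        return np.arange(n) * self.dx_um

    def time_ms(self) -> np.ndarray:
        dt_ms = 1000.0 / self.sample_rate_hz
        n = int(round(self.trace_duration_ms / dt_ms))
        return np.arange(n) * dt_ms

    @classmethod
    def for_condition(cls, condition: str, modality: str, **overrides) -> "SyntheticConfig":
        """Config preloaded with the condition/modality preset sink geometry."""
        preset = CONDITION_PRESETS[condition][modality]
        kw = dict(
            condition=condition,
            modality=modality,
            sink_center_um=preset["center_um"],
            sink_width_um=preset["width_um"],
            diffuse_component=preset.get("diffuse"),
        )
        kw.update(overrides)
        return cls(**kw)


def _alpha_kernel(t_ms: np.ndarray, onset_ms: float, tau_ms: float) -> np.ndarray:
    """Unit-peak alpha function starting at onset_ms, peaking tau_ms later."""
    u = (t_ms - onset_ms) / tau_ms
    return np.where(u > 0, u * np.exp(1.0 - u), 0.0)


def _potential_well(
    positions: np.ndarray, center: float, width: float
) -> np.ndarray:
    """Unit-depth negative Gaussian well, hard-windowed to compact support.

    The well is exactly zero at and beyond 3 grid steps from either axis
    end, so its discrete second difference (the ground-truth CSD) has both
    moments exactly zero: the sink at the well centre is balanced by the
    well's flanks and, for near-edge centres, by a return source
    concentrated at the window edge.
    """
    dx = positions[1] - positions[0]
    g = np.exp(-0.5 * ((positions - center) / width) ** 2)
    g[positions <= 3 * dx + 1e-9] = 0.0
    g[positions >= positions[-1] - 3 * dx - 1e-9] = 0.0
    return -g


def _unbalanced_potential(
    positions: np.ndarray, center: float, width: float
) -> np.ndarray:
    """Potential of a bare Gaussian sink with no return sources.

    Double cumulative integration of the sink profile, with the residual
    linear ramp removed so the potential is pinned to zero at both ends
    (a linear term has zero second difference, so the interior CSD is
    unchanged).  No compact support: balance deliberately does not hold.
    """
    dx = positions[1] - positions[0]
    sink = np.exp(-0.5 * ((positions - center) / width) ** 2)
    s = np.cumsum(sink)
    v = np.zeros_like(sink)
    v[1:] = np.cumsum(s[:-1]) * dx**2
    return v - v[-1] * (positions - positions[0]) / (positions[-1] - positions[0])


def _spatial_potential(config: "SyntheticConfig", positions: np.ndarray) -> np.ndarray:
    if config.source_balance:
        spatial = _potential_well(positions, config.sink_center_um, config.sink_width_um)
        if config.diffuse_component is not None:
            dc = config.diffuse_component
            spatial = spatial + dc["amplitude_fraction"] * _potential_well(
                positions, dc["center_um"], dc["width_um"]
            )
        return spatial
    spatial = _unbalanced_potential(positions, config.sink_center_um, config.sink_width_um)
    if config.diffuse_component is not None:
        dc = config.diffuse_component
        spatial = spatial + dc["amplitude_fraction"] * _unbalanced_potential(
            positions, dc["center_um"], dc["width_um"]
        )
    return spatial


def generate_fp_recording(config: SyntheticConfig) -> tuple[FPRecording, GroundTruth]:
    """Generate one synthetic evoked FP recording and its ground truth.

    Returns the [time x position] potential matrix wrapped as
    :class:`FPRecording` plus the generator-side :class:`GroundTruth`.
    Identical config (including seed) gives bit-identical output.
    """
    positions = config.positions_um()
    t = config.time_ms()

    spatial = _spatial_potential(config, positions)

    onset = config.stim_time_ms + config.latency_ms
    temporal = _alpha_kernel(t, onset, config.rise_tau_ms)
    if config.recurrent_amplitude_fraction > 0:
        temporal = temporal + config.recurrent_amplitude_fraction * _alpha_kernel(
            t, config.stim_time_ms + config.recurrent_delay_ms, config.recurrent_tau_ms
        )

    potentials = config.sink_amplitude * np.outer(temporal, spatial)

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        potentials = potentials + rng.normal(0.0, config.noise_sd, potentials.shape)

    rec = FPRecording(
        potentials=potentials,
        time_ms=t,
        positions_um=positions,
        stim_time_ms=config.stim_time_ms,
        modality=config.modality,
        condition=config.condition,
    )
    truth = GroundTruth(
        true_sink_center_um=config.sink_center_um,
        true_sink_onset_ms=onset,
        true_secondary_center_um=config.sink_center_um,
        condition=config.condition,
        modality=config.modality,
    )
    return rec, truth


def generate_cohort(
    config: SyntheticConfig,
    n_tecta: int,
    modalities: tuple[str, ...] | set[str] = ("RGC", "HB"),
    seed: int = 0,
    jitter_sd_um: float = 15.0,
    center_overrides: dict[str, float] | None = None,
) -> list[tuple[FPRecording, GroundTruth]]:
    """Generate a cohort of tecta with per-tectum jittered sink centers.

    Sink centers for each modality are drawn around the condition-preset
    means with SD ``jitter_sd_um`` and clipped to the interior of the
    compact-support window (4 grid steps from each end), where a sink
    remains localizable.
    Per-recording seeds are derived deterministically from ``seed``.
    ``center_overrides`` maps a modality to a mean center (um) replacing
    the condition preset, for cohorts with programmed sink positions.
    """
    if n_tecta < 1:
        raise ValueError("n_tecta must be at least 1")
    modalities = tuple(sorted(set(modalities)))
    if not modalities:
        raise ValueError("modalities must not be empty")
    for m in modalities:
        if m not in ("RGC", "HB"):
            raise ValueError(f"unknown modality {m!r}")

    rng = np.random.default_rng(seed)
    out: list[tuple[FPRecording, GroundTruth]] = []
    lo = 4 * config.dx_um
    hi = config.axis_length_um - 4 * config.dx_um
    for i in range(n_tecta):
        for modality in modalities:
            preset = CONDITION_PRESETS[config.condition][modality]
            center = preset["center_um"]
            if center_overrides and modality in center_overrides:
                center = center_overrides[modality]
            if jitter_sd_um > 0:
                center += rng.normal(0.0, jitter_sd_um)
            center = float(np.clip(center, lo, hi))
            child_seed = int(rng.integers(0, 2**31 - 1))
            cfg = replace(
                config,
                modality=modality,
                sink_center_um=center,
                sink_width_um=preset["width_um"],
                diffuse_component=preset.get("diffuse"),
                seed=child_seed,
            )
            rec, truth = generate_fp_recording(cfg)
            rec.tectum_id = f"{config.condition}_{i:03d}"
            out.append((rec, truth))
    return out


def generate_fluorescence_pair(
    centers_um: tuple[float, float],
    widths_um: tuple[float, float] = (12.0, 12.0),
    amplitudes: tuple[float, float] = (180.0, 180.0),
    baseline: float = 20.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    axis_length_um: float = 150.0,
    dx_um: float = 10.0,
    channels: tuple[str, str] = ("RGC", "HB"),
) -> tuple[FluorescenceProfile, FluorescenceProfile]:
    """Two-channel synthetic axon-label line profiles on a common grid.

    Each channel is a Gaussian bump plus baseline plus Gaussian noise,
    quantized to integer 8-bit gray values (clipped to [0, 255]).
    """
    for a in amplitudes:
        if a + baseline > 255:
            raise ValueError("amplitude + baseline must not exceed 255 gray values")
    if len(centers_um) != 2 or len(widths_um) != 2 or len(amplitudes) != 2:
        raise ValueError("centers_um, widths_um and amplitudes must each have two entries")
    positions = np.arange(int(round(axis_length_um / dx_um)) + 1) * dx_um
    rng = np.random.default_rng(seed)
    profiles = []
    for center, width, amp, channel in zip(centers_um, widths_um, amplitudes, channels):
        values = baseline + amp * np.exp(-0.5 * ((positions - center) / width) ** 2)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, values.shape)
        gray = np.clip(np.round(values), 0, 255)
        profiles.append(
            FluorescenceProfile(positions_um=positions, gray_values=gray, channel=channel)
        )
    return profiles[0], profiles[1]
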