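"""Current-source-density estimation from laminar field potentials.

The CSD is the discrete second spatial derivative of the potential,

    CSD(x, t) = [V(x + n*dx, t) + V(x - n*dx, t) - 2 V(x, t)] / (n*dx)^2

evaluated at every position with both flanking recordings available.
With the study's 10-um recording grid and n = 2 this reproduces the
20-um spatial differentiation grid.  Extracellular conductivity is
omitted, so values are in potential units per um^2 (arbitrary scale).

Sign convention: by default a current *sink* is a positive second
derivative — a spatially localized negative-going potential well has
positive curvature at its centre.  The ``sink_polarity`` flag on the map
records the convention and drives both detection and rendering, since
published image plots do not state theirs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datatypes import CSDMap, FPRecording, SinkSource

__all__ = ["compute_csd", "locate_major_sink", "render_image_plot"]


def compute_csd(
    recording: FPRecording,
    n: int = 2,
    sink_polarity: str = "positive_second_derivative",
    pad_edges: bool = False,
) -> CSDMap:
    """Three-point second-difference CSD of a laminar FP recording.

    Parameters
    ----------
    n : step count of the stencil; the differentiation grid is n * dx um.
    pad_edges : if set, replicate the outermost recorded traces n times on
        each side before differentiating, so the output covers the full
        axis (edge values are approximations); by default only interior
        positions are returned.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    p = recording.n_positions
    if p < 2 * n + 1:
        raise ValueError(
            f"CSD with n={n} needs at least {2 * n + 1} laminar positions, got {p}"
        )
    v = recording.potentials
    positions = recording.positions_um
    if pad_edges:
        v = np.concatenate(
            [np.repeat(v[:, :1], n, axis=1), v, np.repeat(v[:, -1:], n, axis=1)], axis=1
        )
        out_positions = positions
    else:
        out_positions = positions[n:-n]
    h2 = (n * recording.dx_um) ** 2
    values = (v[:, 2 * n :] + v[:, : -2 * n] - 2.0 * v[:, n:-n]) / h2
    return CSDMap(
        values=values,
        time_ms=recording.time_ms,
        positions_um=out_positions,
        n=n,
        dx_um=recording.dx_um,
        stim_time_ms=recording.stim_time_ms,
        sink_polarity=sink_polarity,
        modality=recording.modality,
        tectum_id=recording.tectum_id,
        condition=recording.condition,
    )


def _window_mask(
    time_ms: np.ndarray, window: str, stim_time_ms: float, mono_window_ms: float
) -> np.ndarray:
    mono_end = stim_time_ms + mono_window_ms + 1e-9
    if window == "monosynaptic":
        return (time_ms > stim_time_ms) & (time_ms <= mono_end)
    if window == "recurrent":
        return time_ms > mono_end
    if window == "full":
        return time_ms > stim_time_ms
    raise ValueError(f"unknown window {window!r}; use monosynaptic, recurrent or full")


def locate_major_sink(
    csd: CSDMap,
    window: str = "monosynaptic",
    stim_time_ms: float | None = None,
    mono_window_ms: float = 4.0,
) -> SinkSource:
    """Position and time of the largest sink in the selected time window.

    ``monosynaptic`` is the half-open window (stim, stim + mono_window_ms];
    ``recurrent`` is everything after it; ``full`` is everything after the
    stimulus.  Ties are broken toward the distal edge, then earlier time.
    """
    stim = csd.stim_time_ms if stim_time_ms is None else stim_time_ms
    mask = _window_mask(csd.time_ms, window, stim, mono_window_ms)
    if not mask.any():
        raise ValueError(f"time window {window!r} contains no samples")
    sinks = csd.sink_values()[mask, :]
    times = csd.time_ms[mask]
    peak = sinks.max()
    # among maximal entries: smallest position, then earliest time
    t_idx, x_idx = np.nonzero(sinks >= peak - 0.0)
    order = np.lexsort((times[t_idx], csd.positions_um[x_idx]))
    ti, xi = t_idx[order[0]], x_idx[order[0]]
    peak_time = float(times[ti])
    kind = "primary" if peak_time <= stim + mono_window_ms + 1e-9 else "secondary"
    return SinkSource(
        location_um=float(csd.positions_um[xi]),
        time_ms=peak_time,
        magnitude=float(sinks[ti, xi]),
        kind=kind,
        polarity="sink",
    )


def render_image_plot(csd: CSDMap, output_path: str | Path, dpi: int = 150) -> Path:
    """Render the CSD map as an image plot (time vs. laminar depth).

    Sinks are mapped to red and sources to blue on a diverging colormap
    with a symmetric scale about zero; the distal and proximal ends of the
    laminar axis are annotated.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    output_path = Path(output_path)
    if not output_path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {output_path.parent}")

    sinks = csd.sink_values()  # positive = sink regardless of stored convention
    vmax = np.abs(sinks).max()
    if vmax == 0:
        vmax = 1.0
    fig, ax = plt.subplots(figsize=(6, 4))
    mesh = ax.pcolormesh(
        csd.time_ms,
        csd.positions_um,
        sinks.T,
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        shading="nearest",
    )
    ax.invert_yaxis()  # distal edge at the top, as in laminar depth plots
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("laminar position (µm from distal edge)")
    ax.annotate("distal", xy=(0.01, 0.98), xycoords="axes fraction", va="top", fontsize=8)
    ax.annotate("proximal", xy=(0.01, 0.02), xycoords="axes fraction", va="bottom", fontsize=8)
    title = " ".join(filter(None, [csd.condition, csd.modality, csd.tectum_id]))
    ax.set_title(title or "CSD image plot")
    fig.colorbar(mesh, ax=ax, label="CSD (sink → red)")
    fig.tight_layout()
    fig.savefig(output_path, dpi=dpi)
    plt.close(fig)
    return output_path
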