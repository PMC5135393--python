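"""End-to-end study orchestration: simulate → profile → CSD → fluorescence → stats.

``run_study`` drives the whole analysis for a set of experimental
conditions, producing per-tectum measurement tables, condition-average
spatial profiles, overlap indices, fluorescence metrics, group summaries
with confidence intervals, two-group comparisons, rendered figures, and a
machine-readable JSON report containing every number behind the figures.
Everything is deterministic given the configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import csd as csd_mod
from . import fluor as fluor_mod
from . import fp_profile as fp_mod
from . import io as io_mod
from . import stats as stats_mod
from . import synth
from .datatypes import FPRecording, GroundTruth, SpatialProfile

__all__ = ["StudyConfig", "ReportBundle", "run_study"]

log = logging.getLogger("laminafp")

#: Modalities recorded per condition: enucleated (dcr) tecta have no
#: contralateral RGC input, so only HB-evoked responses are recorded there.
DEFAULT_MODALITIES = {
    "control": ["RGC", "HB"],
    "dcr": ["HB"],
    "mk801_early": ["RGC", "HB"],
    "mk801_late": ["RGC", "HB"],
}


@dataclass
class StudyConfig:
    """Configuration of a full simulated (or imported) study."""

    conditions: list[str] = field(default_factory=lambda: list(DEFAULT_MODALITIES))
    modalities: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MODALITIES.items()}
    )
    n_tecta: int = 10
    n_fluorescence_specimens: int = 5
    seed: int = 0
    noise_sd: float = 0.05
    jitter_sd_um: float = 15.0
    mono_window_ms: float = 4.0
    csd_n: int = 2
    sink_polarity: str = "positive_second_derivative"
    overlap_weight_by_dx: bool = False
    ci_method: str = "normal_z"
    alpha_normality: float = 0.05
    output_dir: str = "results/study"
    input_dir: str | None = None  # read recordings instead of simulating
    overwrite: bool = False
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.n_tecta < 1:
            raise ValueError("n_tecta must be at least 1")
        if self.mono_window_ms <= 0:
            raise ValueError("mono_window_ms must be positive")
        if self.csd_n < 1:
            raise ValueError("csd_n must be a positive integer")
        for c in self.conditions:
            if c not in synth.CONDITION_PRESETS:
                raise ValueError(f"unknown condition {c!r}")
            if not self.modalities.get(c):
                raise ValueError(f"no modalities configured for condition {c!r}")


@dataclass
class ReportBundle:
    """All tables, figures and the machine-readable report of one study run."""

    measurements: pd.DataFrame
    overlap_table: pd.DataFrame
    fluorescence_table: pd.DataFrame
    group_summaries: pd.DataFrame
    comparisons: pd.DataFrame
    average_profiles: dict[str, SpatialProfile]
    figures: list[Path]
    report_json: Path | None
    report: dict


def _simulate_recordings(config: StudyConfig) -> list[tuple[FPRecording, GroundTruth]]:
    recs: list[tuple[FPRecording, GroundTruth]] = []
    master = np.random.default_rng(config.seed)
    for condition in config.conditions:
        cond_seed = int(master.integers(0, 2**31 - 1))
        base = synth.SyntheticConfig(condition=condition, noise_sd=config.noise_sd)
        recs.extend(
            synth.generate_cohort(
                base,
                n_tecta=config.n_tecta,
                modalities=tuple(config.modalities[condition]),
                seed=cond_seed,
                jitter_sd_um=config.jitter_sd_um,
            )
        )
    return recs


def _load_recordings(config: StudyConfig) -> list[tuple[FPRecording, GroundTruth | None]]:
    in_dir = Path(config.input_dir)
    paths = sorted(in_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recording CSVs found in {in_dir}")
    return [io_mod.read_recording_csv(p) for p in paths]


def _measure(config: StudyConfig, recs) -> tuple[pd.DataFrame, dict]:
    rows = []
    profiles: dict[tuple[str, str], list[SpatialProfile]] = {}
    for rec, truth in recs:
        profile = fp_mod.build_spatial_profile(rec, window_ms=config.mono_window_ms)
        cmap = csd_mod.compute_csd(rec, n=config.csd_n, sink_polarity=config.sink_polarity)
        sink = csd_mod.locate_major_sink(
            cmap, window="monosynaptic", mono_window_ms=config.mono_window_ms
        )
        rows.append(
            {
                "tectum_id": rec.tectum_id,
                "condition": rec.condition,
                "modality": rec.modality,
                "fp_peak_um": fp_mod.peak_location(profile),
                "csd_sink_um": sink.location_um,
                "csd_sink_time_ms": sink.time_ms,
                "true_center_um": truth.true_sink_center_um if truth else np.nan,
            }
        )
        profiles.setdefault((rec.condition, rec.modality), []).append(profile)
    return pd.DataFrame(rows), profiles


def _overlap_table(config: StudyConfig, profiles) -> pd.DataFrame:
    """Per-tectum RGC/HB overlap index, for conditions with both modalities."""
    rows = []
    for condition in config.conditions:
        key_r, key_h = (condition, "RGC"), (condition, "HB")
        if key_r not in profiles or key_h not in profiles:
            continue
        by_id_r = {p.tectum_id: p for p in profiles[key_r]}
        by_id_h = {p.tectum_id: p for p in profiles[key_h]}
        for tid in sorted(set(by_id_r) & set(by_id_h)):
            rows.append(
                {
                    "tectum_id": tid,
                    "condition": condition,
                    "overlap_index": fp_mod.overlap_index(
                        by_id_r[tid], by_id_h[tid], weight_by_dx=config.overlap_weight_by_dx
                    ),
                }
            )
    return pd.DataFrame(rows)


def _fluorescence_table(config: StudyConfig) -> pd.DataFrame:
    """Simulated two-channel axon-label metrics per condition."""
    rows = []
    master = np.random.default_rng(config.seed + 1)
    for condition in config.conditions:
        preset = synth.CONDITION_PRESETS[condition]
        if len(config.modalities[condition]) < 2:
            continue
        for i in range(config.n_fluorescence_specimens):
            seed_i = int(master.integers(0, 2**31 - 1))
            jit = np.random.default_rng(seed_i)
            centers = (
                preset["RGC"]["center_um"] + jit.normal(0, config.jitter_sd_um / 2),
                preset["HB"]["center_um"] + jit.normal(0, config.jitter_sd_um / 2),
            )
            widths = (preset["RGC"]["width_um"], preset["HB"]["width_um"])
            a, b = synth.generate_fluorescence_pair(
                centers_um=centers, widths_um=widths, seed=seed_i
            )
            an = fluor_mod.normalize_fluorescence(a)
            bn = fluor_mod.normalize_fluorescence(b)
            rows.append(
                {
                    "specimen_id": f"{condition}_f{i:03d}",
                    "condition": condition,
                    "rgc_peak_um": fluor_mod.peak_fluorescence_location(an),
                    "hb_peak_um": fluor_mod.peak_fluorescence_location(bn),
                    "peak_separation_um": fluor_mod.peak_separation(an, bn),
                    "overlap_area": fluor_mod.axon_overlap_area(an, bn),
                }
            )
    return pd.DataFrame(rows)


def _summaries(config: StudyConfig, measurements, overlap, fluo) -> pd.DataFrame:
    rows = []

    def add(group: str, quantity: str, values) -> None:
        if len(values) == 0:
            return
        s = stats_mod.summarize_group(values, method=config.ci_method)
        rows.append(
            {
                "group": group,
                "quantity": quantity,
                "mean": s.mean,
                "sem": s.sem,
                "n": s.n,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "ci_method": s.ci_method,
            }
        )

    for (condition, modality), grp in measurements.groupby(["condition", "modality"]):
        add(f"{condition}/{modality}", "fp_peak_um", grp["fp_peak_um"].to_numpy())
        add(f"{condition}/{modality}", "csd_sink_um", grp["csd_sink_um"].to_numpy())
    for condition, grp in overlap.groupby("condition"):
        add(condition, "overlap_index", grp["overlap_index"].to_numpy())
    for condition, grp in (fluo.groupby("condition") if len(fluo) else []):
        add(condition, "fluor_peak_separation_um", grp["peak_separation_um"].to_numpy())
        add(condition, "fluor_overlap_area", grp["overlap_area"].to_numpy())
    return pd.DataFrame(rows)


def _comparisons(config: StudyConfig, measurements, overlap, fluo) -> pd.DataFrame:
    """The study's two-group contrasts, run on whatever groups are present."""
    rows = []

    def pick(cond, modality, col):
        sel = measurements[
            (measurements.condition == cond) & (measurements.modality == modality)
        ]
        return sel[col].to_numpy()

    def add(label, a, b) -> None:
        if len(a) < 3 or len(b) < 3:
            return
        r = stats_mod.compare_groups(a, b, alpha_normality=config.alpha_normality)
        rows.append(
            {
                "comparison": label,
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "n_a": r.n_a,
                "n_b": r.n_b,
                "test": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
        )

    conds = set(config.conditions)
    for col in ("fp_peak_um", "csd_sink_um"):
        if {"control", "dcr"} <= conds:
            add(f"HB {col}: control vs dcr", pick("control", "HB", col), pick("dcr", "HB", col))
        for c in conds & {"control", "mk801_early", "mk801_late"}:
            if {"RGC", "HB"} <= set(config.modalities[c]):
                add(f"{c} {col}: RGC vs HB", pick(c, "RGC", col), pick(c, "HB", col))
        if {"control", "mk801_early"} <= conds:
            add(
                f"RGC {col}: control vs mk801_early",
                pick("control", "RGC", col),
                pick("mk801_early", "RGC", col),
            )
    if len(overlap):
        for c in conds & {"mk801_early", "mk801_late"}:
            a = overlap[overlap.condition == "control"]["overlap_index"].to_numpy()
            b = overlap[overlap.condition == c]["overlap_index"].to_numpy()
            add(f"overlap_index: control vs {c}", a, b)
    if len(fluo):
        for c in conds & {"mk801_early", "mk801_late"}:
            a = fluo[fluo.condition == "control"]["peak_separation_um"].to_numpy()
            b = fluo[fluo.condition == c]["peak_separation_um"].to_numpy()
            add(f"fluor_peak_separation: control vs {c}", a, b)
    return pd.DataFrame(rows)


def _average_profiles(profiles) -> dict[str, SpatialProfile]:
    return {
        f"{cond}/{mod}": fp_mod.average_profiles(plist)
        for (cond, mod), plist in sorted(profiles.items())
    }


def _render_figures(config: StudyConfig, out, averages, recs) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figures: list[Path] = []
    # average spatial profiles, one panel per condition
    for condition in config.conditions:
        keys = [k for k in averages if k.startswith(f"{condition}/")]
        if not keys:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for k in keys:
            p = averages[k]
            ax.plot(p.positions_um, p.amplitudes, marker="o", label=k.split("/")[1])
        ax.set_xlabel("distance from distal edge (µm)")
        ax.set_ylabel("mean normalized peak FP")
        ax.set_title(f"{condition}: average spatial profiles")
        ax.legend()
        fig.tight_layout()
        path = out / f"profiles_{condition}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        figures.append(path)
    # one CSD image plot for the first recording of each condition
    seen = set()
    for rec, _ in recs:
        if rec.condition in seen:
            continue
        seen.add(rec.condition)
        cmap = csd_mod.compute_csd(rec, n=config.csd_n, sink_polarity=config.sink_polarity)
        path = out / f"csd_{rec.condition}_{rec.modality}_{rec.tectum_id}.png"
        csd_mod.render_image_plot(cmap, path)
        figures.append(path)
    return figures


def run_study(config: StudyConfig) -> ReportBundle:
    """Run the full analysis described by ``config``; see module docstring."""
    config.validate()
    out = Path(config.output_dir)
    report_path = out / "report.json"
    if report_path.exists() and not config.overwrite:
        raise FileExistsError(
            f"{report_path} already exists; refusing to overwrite a completed "
            "report (set overwrite to regenerate)"
        )
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    log.info("study start: conditions=%s seed=%d", config.conditions, config.seed)

    recs = _load_recordings(config) if config.input_dir else _simulate_recordings(config)
    measurements, profiles = _measure(config, recs)
    overlap = _overlap_table(config, profiles)
    fluo = _fluorescence_table(config) if config.input_dir is None else pd.DataFrame()
    summaries = _summaries(config, measurements, overlap, fluo)
    comparisons = _comparisons(config, measurements, overlap, fluo)
    averages = _average_profiles(profiles)

    io_mod.write_measurements_csv(measurements, out / "measurements.csv")
    if len(overlap):
        io_mod.write_measurements_csv(overlap, out / "overlap.csv")
    if len(fluo):
        io_mod.write_measurements_csv(fluo, out / "fluorescence.csv")
    io_mod.write_measurements_csv(summaries, out / "group_summaries.csv")
    io_mod.write_measurements_csv(comparisons, out / "comparisons.csv")

    figures = _render_figures(config, out, averages, recs) if config.make_figures else []

    report = {
        "config": dataclasses.asdict(config),
        "measurements": measurements.to_dict(orient="records"),
        "overlap": overlap.to_dict(orient="records"),
        "fluorescence": fluo.to_dict(orient="records"),
        "group_summaries": summaries.to_dict(orient="records"),
        "comparisons": comparisons.to_dict(orient="records"),
        "average_profiles": {
            k: {
                "positions_um": p.positions_um.tolist(),
                "amplitudes": p.amplitudes.tolist(),
                "n_contributing": p.n_contributing,
            }
            for k, p in averages.items()
        },
        "figures": [f.name for f in figures],
    }
    report_path.write_text(json.dumps(report, indent=1))
    log.info("study done in %.2f s; report at %s", time.perf_counter() - t0, report_path)

    return ReportBundle(
        measurements=measurements,
        overlap_table=overlap,
        fluorescence_table=fluo,
        group_summaries=summaries,
        comparisons=comparisons,
        average_profiles=averages,
        figures=figures,
        report_json=report_path,
        report=report,
    )
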