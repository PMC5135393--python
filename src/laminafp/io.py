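"""CSV / JSON file formats for recordings, profiles and measurement tables.

A recording is a wide CSV — first column ``time_ms``, remaining column
headers the laminar distances in um from the distal edge — accompanied by
a JSON sidecar of the same stem carrying modality, condition, tectum id,
stimulus time, grid spacing, seed and (for synthetic data) ground truth.
The same dialect serves synthetic and imported real data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FluorescenceProfile, FPRecording, GroundTruth, SpatialProfile

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_fluorescence_csv",
    "read_fluorescence_csv",
    "write_measurements_csv",
    "profiles_to_frame",
]

_SIDECAR_REQUIRED = ("modality", "condition", "tectum_id", "stim_time_ms", "dx_um")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording_csv(
    recording: FPRecording,
    path: str | Path,
    ground_truth: GroundTruth | None = None,
    seed: int | None = None,
) -> Path:
    """Write a recording as wide CSV plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        recording.potentials,
        columns=[f"{p:g}" for p in recording.positions_um],
    )
    df.insert(0, "time_ms", recording.time_ms)
    df.to_csv(path, index=False)
    meta = {
        "modality": recording.modality,
        "condition": recording.condition,
        "tectum_id": recording.tectum_id,
        "stim_time_ms": recording.stim_time_ms,
        "dx_um": recording.dx_um,
        "seed": seed,
        "ground_truth": dataclasses.asdict(ground_truth) if ground_truth else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording_csv(path: str | Path) -> tuple[FPRecording, GroundTruth | None]:
    """Read a wide-CSV recording and its JSON sidecar.

    Raises a descriptive error for missing sidecar fields, non-numeric
    position headers or a non-uniform laminar grid.  Lossless round trip:
    ``read(write(x))`` reproduces the matrix to full stored precision.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}: {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} lacks required fields: {missing}")

    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time_ms":
        raise ValueError(f"first column must be 'time_ms', got {df.columns[0]!r}")
    try:
        positions = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric position header in {path}: {exc}") from exc

    rec = FPRecording(
        potentials=df.iloc[:, 1:].to_numpy(dtype=float),
        time_ms=df["time_ms"].to_numpy(dtype=float),
        positions_um=positions,
        stim_time_ms=float(meta["stim_time_ms"]),
        modality=meta["modality"],
        tectum_id=meta["tectum_id"],
        condition=meta["condition"],
    )
    truth = GroundTruth(**meta["ground_truth"]) if meta.get("ground_truth") else None
    return rec, truth


def write_fluorescence_csv(
    profiles: list[FluorescenceProfile], path: str | Path
) -> Path:
    """Long-format CSV: position_um, channel, gray_value."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        for pos, gv in zip(p.positions_um, p.gray_values):
            rows.append({"position_um": pos, "channel": p.channel, "gray_value": gv})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_fluorescence_csv(path: str | Path) -> list[FluorescenceProfile]:
    df = pd.read_csv(path)
    required = {"position_um", "channel", "gray_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"fluorescence CSV must have columns {sorted(required)}")
    out = []
    for channel, grp in df.groupby("channel", sort=True):
        grp = grp.sort_values("position_um")
        gv = grp["gray_value"].to_numpy(dtype=float)
        out.append(
            FluorescenceProfile(
                positions_um=grp["position_um"].to_numpy(dtype=float),
                gray_values=gv,
                channel=str(channel),
                normalized=bool(gv.max() <= 1.0),
            )
        )
    return out


def write_measurements_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def profiles_to_frame(profiles: list[SpatialProfile]) -> pd.DataFrame:
    """Tidy frame of profile amplitudes (one row per tectum x position)."""
    rows = []
    for p in profiles:
        for pos, amp in zip(p.positions_um, p.amplitudes):
            rows.append(
                {
                    "tectum_id": p.tectum_id,
                    "condition": p.condition,
                    "modality": p.modality,
                    "position_um": pos,
                    "amplitude": amp,
                }
            )
    return pd.DataFrame(rows)
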