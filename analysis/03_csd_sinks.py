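#!/usr/bin/env python
"""Current-source-density maps and major-sink localization.

Computes the CSD of every simulated recording on the 20-um
differentiation grid (n = 2 steps of the 10-um recording grid), locates
the major monosynaptic sink and the recurrent sink, writes the sink
table under results/tables/, and renders one CSD image plot per
condition/modality under results/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd

from laminafp import compute_csd, locate_major_sink, render_image_plot
from laminafp.io import read_recording_csv, write_measurements_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    ap.add_argument("--figures", type=Path, default=Path("results/figures"))
    args = ap.parse_args()
    args.figures.mkdir(parents=True, exist_ok=True)

    rows, plotted = [], set()
    for csv in sorted(args.sim.glob("*/*.csv")):
        rec, truth = read_recording_csv(csv)
        cmap = compute_csd(rec, n=2)
        mono = locate_major_sink(cmap, window="monosynaptic")
        recur = locate_major_sink(cmap, window="recurrent")
        rows.append(
            dict(
                tectum_id=rec.tectum_id,
                condition=rec.condition,
                modality=rec.modality,
                csd_sink_um=mono.location_um,
                csd_sink_time_ms=mono.time_ms,
                recurrent_sink_um=recur.location_um,
                true_center_um=truth.true_sink_center_um if truth else None,
            )
        )
        key = (rec.condition, rec.modality)
        if key not in plotted:
            plotted.add(key)
            render_image_plot(
                cmap, args.figures / f"csd_{rec.condition}_{rec.modality}.png"
            )
    sinks = pd.DataFrame(rows)
    write_measurements_csv(sinks, args.out / "csd_sinks.csv")

    print(sinks.groupby(["condition", "modality"])["csd_sink_um"].agg(["mean", "sem", "count"]))
    colocal = (sinks.recurrent_sink_um == sinks.csd_sink_um).mean()
    print(f"\nrecurrent sink co-localizes with the primary in {colocal:.0%} of recordings")


if __name__ == "__main__":
    main()
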