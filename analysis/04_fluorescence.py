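#!/usr/bin/env python
"""Axon-label line-profile quantification.

Simulates two-channel (RGC/HB) fluorescence line profiles per condition
around the same laminar centers as the electrophysiology, normalizes
each channel to unit peak, and measures peak locations, the RGC-HB peak
separation (the gap between the two axon populations) and the overlap
area.  Writes the metrics table under results/tables/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from laminafp import (
    CONDITION_PRESETS,
    axon_overlap_area,
    generate_fluorescence_pair,
    normalize_fluorescence,
    peak_fluorescence_location,
    peak_separation,
)
from laminafp.io import write_measurements_csv


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-specimens", type=int, default=5)
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    rows = []
    for condition, preset in CONDITION_PRESETS.items():
        for i in range(args.n_specimens):
            seed_i = int(rng.integers(0, 2**31 - 1))
            jit = np.random.default_rng(seed_i)
            centers = (
                preset["RGC"]["center_um"] + jit.normal(0, 7.5),
                preset["HB"]["center_um"] + jit.normal(0, 7.5),
            )
            a, b = generate_fluorescence_pair(
                centers_um=centers,
                widths_um=(preset["RGC"]["width_um"], preset["HB"]["width_um"]),
                seed=seed_i,
            )
            an, bn = normalize_fluorescence(a), normalize_fluorescence(b)
            rows.append(
                dict(
                    specimen_id=f"{condition}_f{i:03d}",
                    condition=condition,
                    rgc_peak_um=peak_fluorescence_location(an),
                    hb_peak_um=peak_fluorescence_location(bn),
                    peak_separation_um=peak_separation(an, bn),
                    overlap_area=axon_overlap_area(an, bn),
                )
            )
    fluo = pd.DataFrame(rows)
    write_measurements_csv(fluo, args.out / "fluorescence.csv")
    print(
        fluo.groupby("condition")[["peak_separation_um", "overlap_area"]]
        .mean()
        .round(2)
    )
    print("\n(separation shrinks and overlap grows where the inputs desegregate)")


if __name__ == "__main__":
    main()
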