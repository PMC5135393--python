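#!/usr/bin/env python
"""Simulate the study's evoked-recording cohorts.

Generates seeded cohorts of synthetic tecta for the four experimental
conditions (control, enucleated/DCR, early and late NMDAR blockade) with
the modalities each condition actually has, and writes every recording
as wide CSV + JSON sidecar under results/sim/<condition>/.
"""

import argparse
from pathlib import Path

from laminafp import SyntheticConfig, generate_cohort
from laminafp.io import write_recording_csv
from laminafp.pipeline import DEFAULT_MODALITIES


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-tecta", type=int, default=10)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    total = 0
    for i, (condition, modalities) in enumerate(DEFAULT_MODALITIES.items()):
        cohort = generate_cohort(
            SyntheticConfig(condition=condition, noise_sd=0.05),
            n_tecta=args.n_tecta,
            modalities=tuple(modalities),
            seed=args.seed + i,
        )
        for rec, truth in cohort:
            path = args.out / condition / f"{rec.tectum_id}_{rec.modality}.csv"
            write_recording_csv(rec, path, ground_truth=truth, seed=args.seed + i)
        total += len(cohort)
        print(f"{condition}: {len(cohort)} recordings ({', '.join(modalities)})")
    print(f"wrote {total} recordings under {args.out}")


if __name__ == "__main__":
    main()
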