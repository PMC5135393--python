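# laminafp

Laminar field-potential profiling, current-source-density (CSD) mapping and
input-segregation statistics for the developing optic tectum.

## The problem

In the *Xenopus* tadpole optic tectum, two afferent inputs innervate the same
neuropil but segregate along its distal–proximal laminar axis: retinal
ganglion cell (RGC) axons target the distal lamina, hindbrain-relayed
mechanosensory (HB) axons the proximal lamina. The degree of segregation —
and its loss after monocular enucleation or chronic NMDA-receptor blockade —
can be quantified from evoked extracellular field potentials (FPs) recorded
every 10 µm along the laminar axis, and from fluorescence line profiles of
dye-labeled axons. This package implements that analysis end to end, for
anyone working with laminar evoked-potential depth profiles:

- **FP profiling** — the monosynaptic response at each position is the peak
  deflection from the pre-stimulus baseline within 4 ms of the stimulus;
  per-tectum profiles are normalized so the largest amplitude is 1.0,
  letting profiles be averaged across tecta and compared between inputs.
- **CSD mapping** — the discrete second spatial derivative

  ```
  CSD(x, t) = [V(x + n·Δx, t) + V(x − n·Δx, t) − 2·V(x, t)] / (n·Δx)²
  ```

  with Δx = 10 µm and n = 2 (a 20-µm differentiation grid), which localizes
  the major synaptic current sink; sinks are rendered red and sources blue
  in image plots.
- **Overlap index** — Σₓ min(a(x), b(x)) over two normalized profiles: the
  portion of the response common to both inputs, a scalar measure of
  segregation loss.
- **Fluorescence line profiles** — peak-intensity positions, the RGC–HB peak
  separation (the gap between the two axon bands) and the shared area of the
  unit-normalized profiles.
- **Group statistics** — mean ± SEM with 95% CIs (normal-z or Student-t),
  and two-group comparisons routed by a Shapiro–Wilk normality test to an
  unpaired two-tailed t-test or a two-sided Mann–Whitney U test.

Because the original recordings are not public, a seeded forward model
(`laminafp.synth`) generates recordings with known ground truth: a Gaussian
current sink with balancing return sources, an alpha-function time course
peaking 2.5 ms post-stimulus, a delayed recurrent sink at the same location,
condition presets (control, enucleated/DCR, early and late MK-801 blockade)
and additive Gaussian noise. All positions are measured in µm from the
distal edge of the neuropil.

## Worked example

```python
from laminafp import (SyntheticConfig, generate_fp_recording, build_spatial_profile,
                      peak_location, compute_csd, locate_major_sink, overlap_index,
                      summarize_group)

cfg = SyntheticConfig(condition="control", modality="HB", sink_center_um=100.0,
                      noise_sd=0.05, seed=7)
rec, truth = generate_fp_recording(cfg)
prof = build_spatial_profile(rec)          # normalized spatial FP profile
print("FP peak:", peak_location(prof), "um")

cmap = compute_csd(rec, n=2)               # 20-um differentiation grid
sink = locate_major_sink(cmap, window="monosynaptic")

rgc, _ = generate_fp_recording(SyntheticConfig(condition="control", modality="RGC",
                                               sink_center_um=50.0, noise_sd=0.05, seed=8))
print(overlap_index(build_spatial_profile(rgc), prof))

s = summarize_group([104, 97, 110, 93, 118, 101, 99, 108, 112, 98])
```

prints

```
FP peak: 100.0 um from distal edge (truth: 100.0 um)
major primary sink at 100 um, 2.5 ms post-stimulus
RGC-HB overlap index: 1.95
group: 104.0 +/- 2.48 um (n=10), 95% CI [99.15, 108.85]
```

The HB-evoked FP peaks 100 µm from the distal edge (proximal lamina) and the
CSD sink falls at the same position inside the 4-ms monosynaptic window; the
RGC profile peaks distally at 50 µm, so the two normalized profiles share
only a small overlap (1.95 summed amplitude units over the 10-µm grid).

## Analysis scripts

The study pipeline is laid out as numbered drivers over the library:

```sh
python analysis/01_simulate_cohorts.py --seed 1    # cohorts for all conditions
python analysis/02_fp_profiles.py                  # profiles, peaks, overlap
python analysis/03_csd_sinks.py                    # CSD maps and sink tables
python analysis/04_fluorescence.py --seed 1        # axon-label line profiles
python analysis/05_group_comparisons.py            # summaries and contrasts
```

Tables land under `results/tables/`, figures under `results/figures/`.
The same stages are available as a CLI (`laminafp simulate|profile|csd|fluor|
compare|report|all`), and `laminafp report` runs everything in one go from a
YAML config.

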