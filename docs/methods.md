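# Methods

## Coordinate frame and measurement model

All positions are distances in µm from the distal (lateral) edge of the
tectal neuropil, the one landmark that can be identified reproducibly across
preparations; the laminar axis runs distal → proximal on a uniform grid of
Δx = 10 µm (default axis length 150 µm, 16 positions). Traces are sampled at
10 kHz; the stimulus occurs at a configurable time (default 10 ms into a
50-ms sweep).

The monosynaptic response at a position is the **peak absolute deflection
from baseline** within the 4-ms window after the stimulus. Two choices here
are ours, because the measurement is usually described without them:

- Baseline is the mean of *all* pre-stimulus samples, and the deflection is
  measured as |V − baseline|. Evoked field potentials are typically
  negative-going; working with the absolute deviation makes the quantity
  sign-free while the sign of the extremum is kept as metadata.
- The window is half-open, (stim, stim + 4 ms], which excludes a stimulus
  artifact sitting exactly on the stimulus sample.

Per-tectum spatial profiles are normalized to a maximum of exactly 1.0.
Profiles from different tecta are averaged after aligning at the distal edge
and truncating to the common extent — on a fixed 10-µm grid this is exact,
so no interpolation is introduced. The averaged profile is *not*
re-normalized (its maximum is the mean of unit-peak profiles). Ties in any
argmax are broken toward the distal edge, then (for spatio-temporal maps)
toward earlier time; this makes every localization deterministic.

## Current-source density

The CSD is the three-point discrete second spatial derivative

    CSD(x, t) = [V(x + n·Δx, t) + V(x − n·Δx, t) − 2 V(x, t)] / (n·Δx)²

with n = 2 by default, reproducing a 20-µm spatial differentiation grid on
the 10-µm recording grid; both n and Δx are configurable. Extracellular
conductivity is omitted, so units are potential/µm² on an arbitrary scale —
positions and relative magnitudes, not absolute current densities, are the
scientific output. Only interior positions (those with both flanking
recordings) are returned by default; an optional replicate-padding mode
extends estimates to the axis ends at the cost of biased edge values.

**Sign convention.** Published image plots rarely state whether a sink is a
positive or negative second derivative. A spatially localized negative-going
potential well has positive curvature at its centre, so the package defaults
to sink = positive second derivative, but the convention is an explicit
`sink_polarity` flag on every map, honoured by both sink detection and the
red/blue rendering, rather than a hidden assumption.

Sink search windows: *monosynaptic* = (stim, stim + 4 ms],
*recurrent* = everything later, *full* = everything post-stimulus. The
recurrent window exists because evoked responses show a delayed polysynaptic
sink that re-activates the same laminar location as the primary sink.

## Synthetic forward model

The generator stands in for unreleased raw recordings; its defaults are the
study conditions, not free dials.

Spatial structure: the evoked potential's laminar profile is a unit-depth
negative Gaussian well at the configured sink centre (spatial SD 15 µm for
normal conditions, 20 µm for the "widened" enucleation/early-blockade
conditions), hard-windowed to zero at and beyond three grid steps from
either axis end. The ground-truth CSD is the discrete second difference of
this well: a positive sink at the centre flanked by the negative source
lobes of the well's shoulders, plus a boundary-concentrated return source
when the sink sits near the window edge (return currents truncated at the
neuropil boundary). We build the potential first, rather than integrating a
parametric sink-plus-sources CSD, for a numerical reason: on a 150-µm axis,
solving Gaussian flanker amplitudes for exact discrete moment balance is
ill-conditioned whenever a flanker is truncated by an axis end — which
happens precisely at the study's sink positions (40–60 µm and 90–110 µm).
The windowed-well construction gives, by construction and exactly,

- zero potential at and beyond both axis ends (compact support),
- both discrete moments of the CSD equal to zero (source–sink balance: the
  interior telescoping sum of second differences vanishes to float
  precision),
- an exact stencil round trip: double cumulative integration of the
  ground-truth CSD reproduces the potential identically.

With `source_balance` disabled the CSD is a bare Gaussian sink and the
potential (double integral, ends pinned to zero) has no compact support;
this exists to demonstrate what balance buys.

Temporal structure: a unit-peak alpha function (t/τ)·e^(1−t/τ) with 1 ms
latency and τ = 1.5 ms, peaking 2.5 ms post-stimulus — inside the 4-ms
monosynaptic window, which is the only published constraint. The recurrent
component is a second alpha kernel (τ = 3 ms) at the same laminar profile,
delayed 8 ms and scaled to 0.5 of the primary; the late-blockade HB preset
adds a 0.25-amplitude diffuse well (SD 30 µm, centred 60 µm) emulating a
low-intensity desegregated axon population.

Condition presets (mean sink centre µm; chosen from the study's group
statistics): control RGC 50 / HB 100; enucleated (DCR) HB 69, widened;
early blockade RGC 72 / HB 70, widened; late blockade control-like plus the
diffuse HB component. Cohorts jitter per-tectum centres with SD 15 µm,
clipped to [40, 110] µm — the window inside which a sink plus its
differentiation grid fits on the axis; sinks outside it are not localizable
at the 20-µm grid, as the widened-width analysis below also shows. Noise is
i.i.d. Gaussian per sample (default SD 5% of the sink amplitude); correlated
noise, stimulus artifacts and drift are deliberately not modelled.

**Width limit.** At spatial SD ≥ ~22 µm the well is so broad relative to the
70-µm localizable window that the boundary return source out-curves the
sink's centre for the n = 2 stencil, biasing localization by more than one
grid step. The "widened" presets therefore use 20 µm, the widest SD whose
noise-free localization error stays within one grid step everywhere in the
jitter range.

What passing synthetic tests does *not* show: the generator is a separable
(space × time) single-sink model on a short 1-D axis. Real recordings have
multiple overlapping sinks, volume conduction from outside the axis,
correlated noise, electrode drift and stimulus artifacts; recovery rates
here bound performance only under the stated model.

## Fluorescence line profiles

Profiles are position vs. 8-bit gray value (0–255) for one channel, taken
from a line drawn parallel to the laminar axis; extraction from images is
out of scope — profiles arrive as CSV. Channels are normalized
independently to unit peak (optionally after subtracting the profile
minimum, the default, since dye background differs between channels), then
the overlap area is Σ min(a, b)·Δx in normalized-intensity·µm. Peak
separation is the distance between the two channels' argmax positions. The
synthetic generator quantizes Gaussian bumps plus baseline and noise to
integer gray values clipped to [0, 255].

## Group statistics

Summaries are mean ± SEM (SD with n−1 denominator over √n). Two 95% CI
rules are first-class: normal-z (±1.96·SEM) and Student-t (±t(0.975, n−1)·SEM).
Published laminar-position intervals are internally inconsistent — some
groups match one rule, some the other — so the rule is an explicit per-call
choice; a single-observation group gets SEM 0 and a degenerate interval.

Comparisons: Shapiro–Wilk on each group at α = 0.05 (the standard small-n
normality test); both pass → classical equal-variance unpaired two-tailed
t-test (Welch optional); otherwise two-sided Mann–Whitney U, exact when the
pooled sample is ≤ 20 *and* untied (the exact distribution does not correct
for ties), else normal approximation with continuity correction. A constant
group is routed as non-normal (Shapiro–Wilk is undefined there). No
multiple-testing correction is applied, matching the reporting convention
the analysis mirrors. Groups need n ≥ 3 (the minimum for Shapiro–Wilk).

## Validation suite and problem sizes

`laminafp.validation` re-runs the analysis at fixed sizes: 100 seeded
recordings for the sink-recovery rate (≥ 95% within one grid step at 10%
noise), cohorts of 20 tecta for mean-recovery, 50 master seeds × 12
tecta/group for the control-vs-enucleated shift detection, and 2,000 null
pairs (n = 10) for type-I calibration; each recording is 500 samples × 16
positions, so the whole suite runs in seconds on one core.

One statistical note: with per-tectum jitter SD 15 µm and n = 12/group, the
exact noncentral-t power of a two-sided unpaired t-test to detect a 20-µm
shift is 0.877; measured end-to-end detection rates (~0.84–0.88, with grid
rounding and localization noise on top) sit at, not below, what those
conditions allow.

## Known limitations

- 1-D CSD only; no inverse methods (kCSD/iCSD), no volume-conductor model,
  no conductivity scaling.
- No artifact rejection or filtering of raw traces; the analysis assumes
  clean evoked sweeps.
- Localization resolution is one grid step (10 µm); sinks between grid
  points resolve to a neighbouring grid position, and sinks within ~30 µm of
  an axis end are not reliably localizable at the 20-µm differentiation
  grid.
- The overlap index defaults to a plain sum over grid points (matching the
  magnitude range of published indices on ~15-point profiles); a
  Δx-weighted variant is available when an area in amplitude·µm is wanted.
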