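"""Forward-model contracts: determinism, balance, ground-truth recovery."""

import numpy as np
import pytest

from laminafp import (
    CONDITION_PRESETS,
    SyntheticConfig,
    compute_csd,
    generate_cohort,
    generate_fluorescence_pair,
    generate_fp_recording,
    locate_major_sink,
)
from laminafp.fluor import normalize_fluorescence, peak_fluorescence_location
from laminafp.fp_profile import build_spatial_profile, peak_location


class TestGenerateRecording:
    def test_deterministic_under_fixed_seed(self):
        cfg = SyntheticConfig(noise_sd=0.1, seed=42)
        rec1, _ = generate_fp_recording(cfg)
        rec2, _ = generate_fp_recording(cfg)
        np.testing.assert_array_equal(rec1.potentials, rec2.potentials)

    def test_distinct_seeds_differ(self):
        a, _ = generate_fp_recording(SyntheticConfig(noise_sd=0.1, seed=1))
        b, _ = generate_fp_recording(SyntheticConfig(noise_sd=0.1, seed=2))
        assert not np.array_equal(a.potentials, b.potentials)

    def test_prestimulus_is_baseline_noise_only(self):
        rec, _ = generate_fp_recording(SyntheticConfig(noise_sd=0.0))
        pre = rec.time_ms < rec.stim_time_ms
        assert np.all(rec.potentials[pre, :] == 0.0)

    @pytest.mark.parametrize("center", [50.0, 80.0, 100.0])
    def test_csd_roundtrip_extremum_at_on_grid_center(self, center):
        """The stencil applied to the generated potential peaks exactly at
        the configured sink position, inside the monosynaptic window."""
        cfg = SyntheticConfig(sink_center_um=center, noise_sd=0.0)
        rec, truth = generate_fp_recording(cfg)
        sink = locate_major_sink(compute_csd(rec), window="monosynaptic")
        assert sink.location_um == center == truth.true_sink_center_um
        assert rec.stim_time_ms < sink.time_ms <= rec.stim_time_ms + 4.0

    def test_off_grid_center_recovered_to_nearest_grid_point(self):
        """A sink between grid points (85 um) localizes to within half a
        grid step (the recording grid cannot resolve finer)."""
        rec, truth = generate_fp_recording(
            SyntheticConfig(sink_center_um=85.0, noise_sd=0.0)
        )
        sink = locate_major_sink(compute_csd(rec))
        assert abs(sink.location_um - truth.true_sink_center_um) <= 5.0

    def test_recurrent_sink_colocalizes_with_primary(self):
        rec, truth = generate_fp_recording(SyntheticConfig(sink_center_um=100.0, noise_sd=0.0))
        cmap = compute_csd(rec)
        primary = locate_major_sink(cmap, window="monosynaptic")
        secondary = locate_major_sink(cmap, window="recurrent")
        assert secondary.location_um == primary.location_um
        assert secondary.kind == "secondary"
        assert primary.time_ms < secondary.time_ms

    def test_source_balance_gives_zero_interior_sum(self):
        """Compact-support potential: the telescoping sum of the discrete
        second difference over interior points vanishes at every time."""
        for center, width in [(50.0, 15.0), (69.0, 20.0), (100.0, 15.0)]:
            cfg = SyntheticConfig(sink_center_um=center, sink_width_um=width, noise_sd=0.0)
            rec, _ = generate_fp_recording(cfg)
            for n in (1, 2):
                cmap = compute_csd(rec, n=n)
                assert (
                    np.abs(cmap.values.sum(axis=1)).max()
                    < 1e-9 * np.abs(cmap.values).max()
                )

    def test_unbalanced_config_breaks_compact_support(self):
        cfg = SyntheticConfig(sink_center_um=100.0, source_balance=False, noise_sd=0.0)
        rec, _ = generate_fp_recording(cfg)
        cmap = compute_csd(rec, n=1)
        assert np.abs(cmap.values.sum(axis=1)).max() > 1e-3 * np.abs(cmap.values).max()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sink_width_um=-1.0),
            dict(trace_duration_ms=-5.0),
            dict(stim_time_ms=60.0),
            dict(sink_center_um=200.0),
            dict(noise_sd=-0.1),
            dict(axis_length_um=155.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestCohort:
    def test_zero_jitter_centers_equal_preset_mean(self):
        cohort = generate_cohort(
            SyntheticConfig(condition="control"), n_tecta=5, modalities=("HB",),
            seed=0, jitter_sd_um=0.0,
        )
        assert all(t.true_sink_center_um == 100.0 for _, t in cohort)

    def test_distinct_tecta_differ(self):
        cohort = generate_cohort(
            SyntheticConfig(noise_sd=0.05), n_tecta=2, modalities=("HB",), seed=0
        )
        assert not np.array_equal(cohort[0][0].potentials, cohort[1][0].potentials)

    def test_empty_modalities_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SyntheticConfig(), n_tecta=2, modalities=(), seed=0)

    def test_cohort_mean_peaks_recover_preset_means(self):
        """Monte-Carlo parameter recovery: with 15-um jitter and 5% noise,
        mean recovered FP peak locations land within one grid step of the
        configured condition means (control RGC 50 um, HB 100 um)."""
        fp_peaks = {"RGC": [], "HB": []}
        for seed in range(10):
            cohort = generate_cohort(
                SyntheticConfig(condition="control", noise_sd=0.05),
                n_tecta=2, modalities=("RGC", "HB"), seed=seed,
            )
            for rec, _ in cohort:
                fp_peaks[rec.modality].append(peak_location(build_spatial_profile(rec)))
        assert abs(np.mean(fp_peaks["RGC"]) - 50.0) <= 10.0
        assert abs(np.mean(fp_peaks["HB"]) - 100.0) <= 10.0

    def test_center_override_replaces_preset(self):
        cohort = generate_cohort(
            SyntheticConfig(condition="control"), n_tecta=3, modalities=("HB",),
            seed=0, jitter_sd_um=0.0, center_overrides={"HB": 84.0},
        )
        assert all(t.true_sink_center_um == 84.0 for _, t in cohort)


class TestLocalizationUnderNoise:
    def test_recovery_rate_and_monotone_degradation(self):
        """Sink recovery within one grid step in >= 95% of seeded runs at
        10% noise, and mean localization error non-decreasing in noise."""
        errors = {}
        for noise in (0.0, 0.05, 0.1, 0.3):
            errs = []
            for seed in range(40):
                cfg = SyntheticConfig(
                    sink_center_um=85.0, noise_sd=noise, seed=seed
                )
                rec, truth = generate_fp_recording(cfg)
                sink = locate_major_sink(compute_csd(rec))
                errs.append(abs(sink.location_um - truth.true_sink_center_um))
            errors[noise] = np.array(errs)
        assert np.mean(errors[0.1] <= 10.0) >= 0.95
        means = [errors[k].mean() for k in sorted(errors)]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestFluorescencePair:
    def test_noise_free_peak_at_nearest_grid_point(self):
        a, b = generate_fluorescence_pair(
            centers_um=(88.6, 65.8), noise_sd=0.0, seed=0
        )
        assert peak_fluorescence_location(a) == 90.0
        assert peak_fluorescence_location(b) == 70.0

    def test_zero_amplitude_gives_flat_baseline(self):
        a, b = generate_fluorescence_pair(
            centers_um=(50.0, 100.0), amplitudes=(0.0, 0.0), baseline=20.0,
            noise_sd=0.0, seed=0,
        )
        assert np.all(a.gray_values == 20.0) and np.all(b.gray_values == 20.0)
        with pytest.raises(ValueError):
            normalize_fluorescence(a)  # constant profile cannot be normalized

    def test_deterministic_and_8bit(self):
        a1, b1 = generate_fluorescence_pair(centers_um=(50.0, 100.0), seed=7)
        a2, _ = generate_fluorescence_pair(centers_um=(50.0, 100.0), seed=7)
        np.testing.assert_array_equal(a1.gray_values, a2.gray_values)
        for p in (a1, b1):
            assert np.all(p.gray_values == np.round(p.gray_values))
            assert p.gray_values.min() >= 0 and p.gray_values.max() <= 255

    def test_saturating_amplitude_rejected(self):
        with pytest.raises(ValueError):
            generate_fluorescence_pair(
                centers_um=(50.0, 100.0), amplitudes=(250.0, 100.0), baseline=20.0
            )


def test_condition_presets_cover_all_conditions():
    for cond, presets in CONDITION_PRESETS.items():
        assert {"RGC", "HB"} <= set(presets)
        for p in presets.values():
            assert 40.0 <= p["center_um"] <= 110.0
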