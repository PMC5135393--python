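"""Peak-amplitude quantification, profiles, averaging and overlap index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminafp import (
    FPRecording,
    SpatialProfile,
    SyntheticConfig,
    average_profiles,
    build_spatial_profile,
    generate_fp_recording,
    overlap_index,
    peak_amplitude,
    peak_location,
)


def _profile(amps, normalized=False, dx=10.0):
    return SpatialProfile(
        positions_um=np.arange(len(amps)) * dx,
        amplitudes=np.asarray(amps, dtype=float),
        normalized=normalized,
    )


class TestPeakAmplitude:
    time = np.arange(0, 20, 0.1)

    def test_flat_trace_gives_zero(self):
        assert peak_amplitude(np.zeros_like(self.time), self.time, 10.0) == 0.0

    def test_event_outside_4ms_window_ignored(self):
        """A large deflection 6 ms after the stimulus must not beat a
        smaller one inside the monosynaptic window."""
        trace = np.zeros_like(self.time)
        trace[np.isclose(self.time, 12.0)] = -0.8
        trace[np.isclose(self.time, 16.0)] = 1.2
        assert peak_amplitude(trace, self.time, 10.0) == pytest.approx(0.8)

    def test_matches_exhaustive_scan(self, rng):
        """Noisy trace: peak equals a brute-force scan of |V - baseline|
        over exactly the samples in (stim, stim + 4 ms]."""
        trace = rng.normal(0, 1, self.time.size)
        stim = 10.0
        baseline = trace[self.time < stim].mean()
        mask = (self.time > stim) & (self.time <= stim + 4.0 + 1e-9)
        expected = np.abs(trace[mask] - baseline).max()
        assert peak_amplitude(trace, self.time, stim) == pytest.approx(expected)

    def test_offset_invariance(self, rng):
        trace = rng.normal(0, 1, self.time.size)
        a = peak_amplitude(trace, self.time, 10.0)
        b = peak_amplitude(trace + 123.4, self.time, 10.0)
        assert a == pytest.approx(b)

    def test_sign_metadata(self):
        trace = np.zeros_like(self.time)
        trace[np.isclose(self.time, 12.0)] = -0.8
        amp, sign = peak_amplitude(trace, self.time, 10.0, return_sign=True)
        assert (amp, sign) == (pytest.approx(0.8), -1)

    def test_window_beyond_trace_end_rejected(self):
        with pytest.raises(ValueError, match="beyond the trace end"):
            peak_amplitude(np.zeros_like(self.time), self.time, 18.0)

    def test_no_prestimulus_samples_rejected(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            peak_amplitude(np.zeros_like(self.time), self.time, 0.0)


class TestSpatialProfile:
    def test_normalization_values(self):
        """Raw per-position amplitudes [0.2, 0.8, 0.4] normalize to
        [0.25, 1.0, 0.5]."""
        t = np.arange(0, 20, 0.1)
        pots = np.zeros((t.size, 3))
        for j, amp in enumerate([0.2, 0.8, 0.4]):
            pots[np.isclose(t, 12.0), j] = -amp
        rec = FPRecording(pots, t, np.array([0.0, 10.0, 20.0]), stim_time_ms=10.0)
        prof = build_spatial_profile(rec)
        np.testing.assert_allclose(prof.amplitudes, [0.25, 1.0, 0.5])
        assert prof.normalized and prof.amplitudes.max() == 1.0

    def test_all_zero_normalization_rejected(self):
        t = np.arange(0, 20, 0.1)
        rec = FPRecording(
            np.zeros((t.size, 3)), t, np.array([0.0, 10.0, 20.0]), stim_time_ms=10.0
        )
        with pytest.raises(ValueError, match="all-zero"):
            build_spatial_profile(rec)
        raw = build_spatial_profile(rec, normalize=False)
        assert np.all(raw.amplitudes == 0.0)

    def test_roundtrip_argmax_at_ground_truth(self, clean_rgc_recording):
        rec, truth = clean_rgc_recording
        prof = build_spatial_profile(rec)
        assert peak_location(prof) == truth.true_sink_center_um == 50.0


class TestPeakLocation:
    def test_simple_argmax(self):
        assert peak_location(_profile([0.25, 1.0, 0.5], normalized=True)) == 10.0

    def test_tie_broken_toward_distal_edge(self):
        assert peak_location(_profile([1.0, 1.0, 0.2], normalized=True)) == 0.0


class TestAverageProfiles:
    def test_identical_profiles_average_to_themselves(self):
        p = _profile([0.5, 1.0, 0.5], normalized=True)
        avg = average_profiles([p, p])
        np.testing.assert_allclose(avg.amplitudes, p.amplitudes)
        assert avg.n_contributing == 2 and not avg.normalized

    def test_pointwise_mean(self):
        a = _profile([1.0, 0.0], normalized=True)
        b = _profile([0.0, 1.0], normalized=True)
        np.testing.assert_allclose(average_profiles([a, b]).amplitudes, [0.5, 0.5])

    def test_unequal_lengths_truncated_at_distal_alignment(self):
        a = _profile([1.0, 0.5, 0.25, 0.1], normalized=True)
        b = _profile([0.5, 1.0], normalized=True)
        avg = average_profiles([a, b])
        np.testing.assert_allclose(avg.amplitudes, [0.75, 0.75])

    def test_mixed_normalization_rejected(self):
        a = _profile([1.0, 0.5], normalized=True)
        b = _profile([2.0, 1.0], normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            average_profiles([a, b])

    def test_average_of_cohort_peaks_near_generator_mean(self):
        from laminafp import generate_cohort

        cohort = generate_cohort(
            SyntheticConfig(condition="control", noise_sd=0.05),
            n_tecta=10, modalities=("HB",), seed=3,
        )
        avg = average_profiles([build_spatial_profile(r) for r, _ in cohort])
        assert abs(peak_location(avg) - 100.0) <= 10.0


class TestOverlapIndex:
    def test_self_overlap_equals_own_sum(self):
        p = _profile([0.5, 1.0, 0.5], normalized=True)
        assert overlap_index(p, p) == pytest.approx(2.0)

    def test_disjoint_supports_give_zero(self):
        a = _profile([1.0, 0.0, 0.0], normalized=True)
        b = _profile([0.0, 0.0, 1.0], normalized=True)
        assert overlap_index(a, b) == 0.0

    def test_min_sum_oracle(self):
        a = _profile([1.0, 0.4, 0.0], normalized=True)
        b = _profile([0.0, 0.6, 1.0], normalized=True)
        assert overlap_index(a, b) == pytest.approx(0.4)
        assert overlap_index(a, b, weight_by_dx=True) == pytest.approx(4.0)

    def test_unnormalized_inputs_rejected(self):
        a = _profile([2.0, 1.0], normalized=False)
        b = _profile([1.0, 0.5], normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            overlap_index(a, b)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.lists(st.floats(0, 1), min_size=2, max_size=12),
        b=st.lists(st.floats(0, 1), min_size=2, max_size=12),
    )
    def test_symmetry_and_bounds(self, a, b):
        a, b = list(a), list(b)
        a[0] = b[0] = 1.0  # force a well-defined normalized maximum
        pa, pb = _profile(a, normalized=True), _profile(b, normalized=True)
        ab, ba = overlap_index(pa, pb), overlap_index(pb, pa)
        assert ab == pytest.approx(ba)
        m = min(len(a), len(b))
        assert 0.0 <= ab <= min(sum(a[:m]), sum(b[:m])) + 1e-12

    def test_overlap_monotone_in_profile_separation(self):
        """Moving two synthetic unimodal profiles closer never decreases
        the overlap index (separations 0..100 um)."""
        positions = np.arange(0, 151, 10.0)

        def gauss_profile(center):
            g = np.exp(-0.5 * ((positions - center) / 15.0) ** 2)
            return SpatialProfile(positions, g / g.max(), normalized=True)

        fixed = gauss_profile(25.0)
        seps = np.arange(0.0, 101.0, 10.0)
        vals = [overlap_index(fixed, gauss_profile(25.0 + s)) for s in seps]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))
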