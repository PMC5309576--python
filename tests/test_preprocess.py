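"""Resampling, alignment filter, zero-phase filtering, lag estimation."""

import numpy as np
import pytest

import tidalcompare as tc
from tidalcompare.preprocess import FilterSpec, filter_magnitude_response


def sine_trace(freq, fs, duration=45.0, phase=0.0, amp=1.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    return tc.Trace(amp * np.sin(2 * np.pi * freq * t + phase), fs=fs)


class TestResample:
    def test_constant_preserved(self):
        tr = tc.Trace(np.full(200, 3.7), fs=30.0)
        out = tc.resample_shape_preserving(tr, 100.0)
        assert out.fs == 100.0
        np.testing.assert_allclose(out.values, 3.7)

    def test_monotone_input_stays_monotone(self):
        tr = tc.Trace(np.linspace(0, 1, 150) ** 2, fs=30.0)
        out = tc.resample_shape_preserving(tr, 100.0)
        assert np.all(np.diff(out.values) >= 0)

    def test_identity_on_own_rate(self):
        rng = np.random.default_rng(0)
        tr = tc.Trace(rng.normal(size=300), fs=30.0)
        out = tc.resample_shape_preserving(tr, 30.0)
        np.testing.assert_allclose(out.values, tr.values, atol=1e-12)

    def test_sinusoid_peaks_move_under_5ms(self):
        # respiratory-band sinusoid, 30 -> 100 Hz, grid extrema vs analytic
        tr = sine_trace(0.25, 30.0)
        out = tc.resample_shape_preserving(tr, 100.0)
        v, t = out.values, out.times
        idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
        analytic = 1.0 + 4.0 * np.arange(11)  # peaks of sin(2*pi*0.25*t)
        for ta in analytic:
            if 0.5 < ta < 44.5:
                assert np.min(np.abs(t[idx] - ta)) <= 0.005 + 1e-9

    def test_too_few_samples(self):
        with pytest.raises(tc.DataError):
            tc.resample_shape_preserving(tc.Trace(np.array([1.0, 2.0]), fs=30.0), 100.0)


class TestAlignmentFilter:
    def test_stopband_attenuation_meets_spec(self):
        spec = tc.design_alignment_filter(100.0)
        peak = filter_magnitude_response(
            spec, np.linspace(0.06, 9.9, 400)
        ).max()
        stop = np.concatenate(
            [np.linspace(0.001, 0.02, 100), np.linspace(15.0, 49.0, 200)]
        )
        atten_db = 20 * np.log10(filter_magnitude_response(spec, stop) / peak)
        assert np.max(atten_db) <= -50.0 + 1e-3  # equiripple floor, float slack

    def test_passband_ripple_within_half_db(self):
        spec = tc.design_alignment_filter(100.0)
        freqs = np.linspace(0.06, 9.9, 500)
        resp = filter_magnitude_response(spec, freqs)
        db = 20 * np.log10(resp / resp.max())
        assert db.min() >= -0.5 - 1e-6

    def test_low_fs_rejected(self):
        with pytest.raises(tc.ConfigError):
            tc.design_alignment_filter(15.0)

    def test_bad_spec_rejected(self):
        with pytest.raises(tc.ConfigError):
            FilterSpec(order=0)
        with pytest.raises(tc.ConfigError):
            FilterSpec(passband_edges_hz=(10.0, 0.05))


class TestZeroPhase:
    def test_in_band_sinusoid_peak_unmoved(self):
        tr = sine_trace(1.0, 100.0)
        spec = tc.design_alignment_filter(100.0)
        out = tc.bandpass_zero_phase(tr, spec)
        # compare the peak index within a single interior cycle (periodic
        # signals have many equal maxima, so a global argmax is ambiguous)
        mid = slice(2000, 2100)
        assert np.argmax(out.values[mid]) == np.argmax(tr.values[mid])

    def test_dc_removed(self):
        tr = tc.Trace(np.full(4500, 2.0), fs=100.0)
        spec = tc.design_alignment_filter(100.0)
        out = tc.bandpass_zero_phase(tr, spec)
        assert np.max(np.abs(out.values)) < 0.02 * 2.0

    def test_deep_stopband_two_pass_attenuation(self):
        # realized transfer function applied twice: >= 100 dB at 0.02 Hz
        spec = tc.design_alignment_filter(100.0)
        resp2 = filter_magnitude_response(spec, np.array([0.02]), passes=2)
        peak = filter_magnitude_response(spec, np.linspace(0.06, 9.9, 400)).max()
        assert 20 * np.log10(resp2[0] / peak**2) <= -100.0

    def test_double_filtering_equals_squared_response(self):
        # amplitude after two zero-phase passes ~ single-pass gain^4 on a sinusoid
        freq = 0.5
        tr = sine_trace(freq, 100.0, duration=120.0)
        spec = tc.design_alignment_filter(100.0)
        once = tc.bandpass_zero_phase(tr, spec)
        twice = tc.bandpass_zero_phase(once, spec)
        g2 = filter_magnitude_response(spec, np.array([freq]), passes=2)[0]
        mid = slice(2000, 10000)
        amp_once = np.max(np.abs(once.values[mid]))
        amp_twice = np.max(np.abs(twice.values[mid]))
        assert amp_twice / amp_once == pytest.approx(g2, rel=1e-3)

    def test_short_trace_rejected(self):
        spec = tc.design_alignment_filter(100.0)
        with pytest.raises(tc.DataError):
            tc.bandpass_zero_phase(tc.Trace(np.ones(8), fs=100.0), spec)


class TestEstimateLag:
    def test_identity_gives_zero_lag_unit_peak(self):
        tr = sine_trace(0.25, 100.0)
        res = tc.estimate_lag(tr, tr, max_lag=5.0)
        assert res.lag == 0.0
        assert res.peak_correlation == pytest.approx(1.0, abs=1e-9)
        assert not res.flagged

    def test_integer_delay_recovered_exactly(self, rng):
        # brute-force oracle: delay by 37 samples via roll of a long signal
        base = np.cumsum(rng.normal(size=6000))  # smooth-ish random walk
        a = tc.Trace(base[500:5000], fs=100.0)
        b = tc.Trace(base[500 - 37 : 5000 - 37], fs=100.0)  # b delayed
        res = tc.estimate_lag(a, b, max_lag=1.0)
        assert res.lag == pytest.approx(0.37, abs=1e-12)

    def test_independent_noise_flagged(self, rng):
        a = tc.Trace(rng.normal(size=3000), fs=100.0)
        b = tc.Trace(rng.normal(size=3000), fs=100.0)
        res = tc.estimate_lag(a, b, max_lag=2.0)
        assert res.flagged

    def test_gain_invariance(self):
        tr = sine_trace(0.25, 100.0)
        scaled = tr.with_values(17.0 * tr.values)
        res = tc.estimate_lag(tr, scaled, max_lag=2.0)
        assert res.lag == 0.0
        assert res.peak_correlation == pytest.approx(1.0, abs=1e-9)

    def test_excessive_max_lag_rejected(self):
        tr = sine_trace(0.25, 100.0, duration=4.0)
        with pytest.raises(tc.DataError):
            tc.estimate_lag(tr, tr, max_lag=10.0)

    def test_filter_then_estimate_recovers_injected_offset(self):
        # end-to-end: simulated recording with known inter-device offset
        cfg = tc.SimConfig(inter_device_offset=0.8, cv_timing=0.08, artifact_rate=0.0)
        rec = tc.simulate_recording(cfg, seed=2)
        slp = tc.resample_shape_preserving(rec.slp_displacement, 100.0)
        spec = tc.design_alignment_filter(100.0)
        vf = tc.bandpass_zero_phase(rec.pnt_volume, spec)
        sf = tc.bandpass_zero_phase(slp, spec)
        res = tc.estimate_lag(vf, sf, max_lag=5.0)
        assert abs(res.lag - 0.8) <= 0.01 + 1e-9  # within one PNT sample


class TestAlignAndTruncate:
    def test_zero_lag_equal_lengths_unchanged(self):
        tr = sine_trace(0.25, 100.0)
        a, b = tc.align_and_truncate(tr, tr, 0.0)
        np.testing.assert_array_equal(a.values, tr.values)
        np.testing.assert_array_equal(b.values, tr.values)

    def test_lag_shortens_by_lag_samples(self):
        tr = sine_trace(0.25, 100.0)  # 4500 samples
        a, b = tc.align_and_truncate(tr, tr, 0.8)
        assert len(a) == len(b) == len(tr) - 80

    def test_values_are_aligned(self, rng):
        base = rng.normal(size=5000)
        a = tc.Trace(base[:4000], fs=100.0)
        b = tc.Trace(np.concatenate([rng.normal(size=60), base[:4000]]), fs=100.0)
        out_a, out_b = tc.align_and_truncate(a, b, 0.6)
        np.testing.assert_array_equal(out_a.values, out_b.values)

    def test_no_overlap_rejected(self):
        tr = sine_trace(0.25, 100.0, duration=2.0)
        with pytest.raises(tc.DataError):
            tc.align_and_truncate(tr, tr, 10.0)
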