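"""Quality metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest

from whiskdecode import metrics as Q
from whiskdecode.recording import DataError, IntervalSet, Recording, WindowSpec


def brute_sliding(samples, fs, w, fn):
    """Naive per-window loop, independent of the vectorized implementation."""
    width = int(round(w.width_s * fs))
    hop = int(round((w.width_s - w.overlap_s) * fs))
    out = []
    start = 0
    while start + width <= len(samples):
        out.append(fn(samples[start : start + width]))
        start += hop
    return np.array(out)


class TestSlidingMetrics:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rms_vpp_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        fs = 4000.0
        rec = Recording(rng.standard_normal(int(1.7 * fs)), fs)
        w = WindowSpec(0.2, 0.1)
        got = Q.sliding_rms(rec, w).values
        want = brute_sliding(rec.samples, fs, w, lambda x: np.sqrt(np.mean(x**2)))
        np.testing.assert_allclose(got, want, rtol=1e-9)
        got = Q.sliding_vpp(rec, w).values
        want = brute_sliding(rec.samples, fs, w, lambda x: x.max() - x.min())
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_constant_signal(self):
        rec = Recording(np.full(4000, -3.0), 4000.0)
        w = WindowSpec(0.2, 0.1)
        assert np.allclose(Q.sliding_rms(rec, w).values, 3.0)
        assert np.allclose(Q.sliding_vpp(rec, w).values, 0.0)

    def test_sine_closed_forms(self):
        fs, A = 16000.0, 2.5
        t = np.arange(int(2 * fs)) / fs
        rec = Recording(A * np.sin(2 * np.pi * 100 * t), fs)
        w = WindowSpec(0.2, 0.1)
        assert np.allclose(Q.sliding_rms(rec, w).values, A / np.sqrt(2), rtol=0.02)
        assert np.allclose(Q.sliding_vpp(rec, w).values, 2 * A, rtol=0.02)

    def test_window_count_invariant(self):
        fs, T = 1000.0, 3.35
        rec = Recording(np.zeros(int(T * fs)) + 1.0, fs)
        w = WindowSpec(0.2, 0.1)
        expected = int(np.floor((T - w.width_s) / (w.width_s - w.overlap_s))) + 1
        assert len(Q.sliding_rms(rec, w)) == expected


class TestSNR:
    def test_closed_forms(self):
        assert Q.snr_db(1.0, 1.0) == pytest.approx(0.0)
        assert Q.snr_db(2.0, 1.0) == pytest.approx(10 * np.log10(2), abs=1e-12)
        assert Q.snr_db(2.0, 1.0, power=True) == pytest.approx(20 * np.log10(2), abs=1e-12)

    def test_monotone_in_signal(self):
        vals = [Q.snr_db(s, 1.0) for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(Exception):
            Q.snr_db(0.0, 1.0)
        with pytest.raises(Exception):
            Q.snr_db(1.0, -1.0)

    def test_trial_snr_identical_statistics(self, rng):
        fs = 4000.0
        rec = Recording(rng.standard_normal(int(40 * fs)), fs)
        move = IntervalSet([(0.0, 15.0)])
        rest = IntervalSet([(20.0, 40.0)])
        s = Q.trial_snr(rec, move, rest)
        assert abs(s.mean()) < 0.5  # same process in both states -> ~0 dB

    def test_trial_snr_requires_rest_floor(self, rng):
        fs = 4000.0
        rec = Recording(rng.standard_normal(int(12 * fs)), fs)
        with pytest.raises(DataError):
            Q.trial_snr(rec, IntervalSet([(0, 5)]), IntervalSet([(6, 11)]))


class TestInBandRatio:
    def test_pure_tones(self):
        fs = 16000.0
        t = np.arange(int(5 * fs)) / fs
        low = Recording(np.sin(2 * np.pi * 100 * t), fs)
        high = Recording(np.sin(2 * np.pi * 3000 * t), fs)
        assert Q.in_band_power_ratio(low).mean() > 0.97
        assert Q.in_band_power_ratio(high).mean() < 0.03

    def test_equal_power_mixture(self):
        fs = 16000.0
        t = np.arange(int(5 * fs)) / fs
        mix = Recording(np.sin(2 * np.pi * 100 * t) + np.sin(2 * np.pi * 3000 * t), fs)
        assert Q.in_band_power_ratio(mix).mean() == pytest.approx(0.5, abs=0.05)

    def test_bounded(self, rng):
        fs = 16000.0
        rec = Recording(rng.standard_normal(int(5 * fs)), fs)
        vals = Q.in_band_power_ratio(rec).values
        assert np.all(vals >= 0) and np.all(vals <= 1)


class TestPersistenceSpectrum:
    def test_column_sums_equal_segment_count(self, rng):
        rec = Recording(rng.standard_normal(16000), 16000.0)
        ps = Q.persistence_spectrum(rec)
        np.testing.assert_array_equal(ps.counts.sum(axis=0), ps.n_segments)

    def test_sine_concentrates(self):
        fs = 8000.0
        t = np.arange(int(4 * fs)) / fs
        ps = Q.persistence_spectrum(Recording(np.sin(2 * np.pi * 500 * t), fs))
        fbin = np.argmin(np.abs(ps.freq_bins_hz - 500.0))
        top_levels = ps.counts[:, fbin]
        # the 500 Hz bin occupies the top intensity levels in every segment
        assert top_levels[-ps.counts.shape[0] // 4 :].sum() == ps.n_segments

    def test_too_short_errors(self):
        with pytest.raises(DataError):
            Q.persistence_spectrum(Recording(np.zeros(100) + 1.0, 1000.0))


class TestEnvelopeCorrelation:
    def test_identical_envelopes(self, rng):
        fs = 125.0
        env = Recording(np.abs(rng.standard_normal(int(10 * fs))) + 0.1, fs)
        r = Q.envelope_correlation(env, env, WindowSpec(1.0, 0.5)).values
        assert np.allclose(r, 1.0)

    def test_negated_envelope(self, rng):
        fs = 125.0
        a = Recording(rng.standard_normal(int(10 * fs)), fs)
        b = Recording(-a.samples, fs)
        r = Q.envelope_correlation(a, b, WindowSpec(1.0, 0.5)).values
        assert np.allclose(r, -1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(99)
        fs = 125.0
        a = Recording(rng.standard_normal(int(60 * fs)), fs)
        b = Recording(rng.standard_normal(int(60 * fs)), fs)
        r = Q.envelope_correlation(a, b, WindowSpec(4.0, 2.0)).values
        assert np.nanmean(np.abs(r)) < 0.2

    def test_zero_variance_window_is_missing(self):
        fs = 125.0
        a = Recording(np.ones(int(4 * fs)), fs)
        b = Recording(np.arange(int(4 * fs), dtype=float), fs)
        r = Q.envelope_correlation(a, b, WindowSpec(1.0, 0.0)).values
        assert np.all(np.isnan(r))


class TestConcordance:
    def test_identity(self):
        y = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        assert Q.concordance_cc(y, y).rho_c == pytest.approx(1.0)

    def test_shifted_sequence_worked_case(self):
        # population variance of (0..4) is 2; shift of 1 gives 2*2/(2+2+1)
        y = np.arange(5.0)
        res = Q.concordance_cc(y, y + 1.0)
        assert res.rho_c == pytest.approx(0.8, abs=1e-12)
        assert res.rho == pytest.approx(1.0)

    def test_sign_flip(self):
        y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert Q.concordance_cc(y, -y).rho_c == pytest.approx(-1.0, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(5):
            y = rng.standard_normal(50)
            z = rng.standard_normal(50) + 0.3 * y
            a = Q.concordance_cc(y, z)
            b = Q.concordance_cc(z, y)
            assert a.rho_c == pytest.approx(b.rho_c, abs=1e-12)
            assert abs(a.rho_c) <= 1.0 + 1e-12
            assert abs(a.rho_c) <= abs(a.rho) + 1e-12

    def test_joint_affine_invariance(self, rng):
        y = rng.standard_normal(40)
        z = rng.standard_normal(40)
        base = Q.concordance_cc(y, z).rho_c
        scaled = Q.concordance_cc(3.5 * y + 2.0, 3.5 * z + 2.0).rho_c
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(DataError):
            Q.concordance_cc(np.ones(5), np.arange(5.0))
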