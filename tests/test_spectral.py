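"""Spectra, binning, complexity measures and bin-count selection.

Brute-force oracles: per-bin population variance by explicit loops, Shannon
evenness by direct -sum(p ln p)/ln B evaluation, and the law of total
variance for the nested-binning monotonicity of mean intra-bin variance.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scapekit.recording_io import AudioRecording
from scapekit import spectral as sp


def _brute_mean_intra_bin_variance(power, point_edges):
    """Oracle: plain-Python population variance per bin, then mean."""
    out = []
    for lo, hi in zip(point_edges[:-1], point_edges[1:]):
        chunk = power[lo:hi]
        m = sum(chunk) / len(chunk)
        out.append(sum((x - m) ** 2 for x in chunk) / len(chunk))
    return sum(out) / len(out)


class TestPowerSpectrum:
    def test_sine_peak_location(self):
        fs, f0 = 8000.0, 1000.0
        t = np.arange(8000) / fs
        rec = AudioRecording(samples=np.sin(2 * np.pi * f0 * t),
                             sample_rate=fs)
        raw = sp.power_spectrum(rec, method="fullfft")
        assert raw.freqs[np.argmax(raw.power)] == pytest.approx(f0, abs=1.0)

    def test_zero_signal_zero_power(self):
        rec = AudioRecording(samples=np.zeros(1024), sample_rate=8000)
        raw = sp.power_spectrum(rec, method="fullfft")
        assert np.all(raw.power == 0.0)

    def test_parseval_fullfft(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 4096)
        rec = AudioRecording(samples=x, sample_rate=8000)
        raw = sp.power_spectrum(rec, method="fullfft")
        df = raw.freqs[1] - raw.freqs[0]
        assert np.sum(raw.power) * df == pytest.approx(np.mean(x ** 2),
                                                       rel=1e-6)

    def test_parseval_welch_white_noise(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 80_000)
        rec = AudioRecording(samples=x, sample_rate=8000)
        raw = sp.power_spectrum(rec, method="welch")
        df = raw.freqs[1] - raw.freqs[0]
        assert np.sum(raw.power) * df == pytest.approx(np.var(x), rel=0.05)

    def test_welch_segment_too_long(self):
        rec = AudioRecording(samples=np.zeros(100), sample_rate=8000)
        with pytest.raises(ValueError, match="segment_length"):
            sp.power_spectrum(rec, method="welch", segment_length=1000)


class TestBinning:
    @pytest.mark.parametrize("n,B,expected_counts", [
        (8, 2, [4, 4]),
        (7, 2, [4, 3]),       # larger bins first
        (10, 3, [4, 3, 3]),
        (4096, 1024, [4] * 1024),
    ])
    def test_remainder_rule(self, n, B, expected_counts):
        scheme = sp.make_binning(n, nyquist=1000.0, B=B)
        assert list(np.diff(scheme.point_edges)) == expected_counts

    def test_bad_bin_count(self):
        with pytest.raises(ValueError):
            sp.make_binning(4, 1000.0, 5)

    def test_bin_means_hand_oracle(self):
        raw = sp.RawSpectrum(power=[1, 3, 2, 4], freqs=[0, 1, 2, 3])
        scheme = sp.make_binning(4, 3.0, 2)
        bs = sp.bin_spectrum(raw, scheme)
        assert list(bs.values) == [2.0, 3.0]

    def test_identity_binning(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 16)
        raw = sp.RawSpectrum(power=p, freqs=np.arange(16.0))
        bs = sp.bin_spectrum(raw, sp.make_binning(16, 15.0, 16))
        assert np.allclose(bs.values, p)

    def test_constant_spectrum(self):
        raw = sp.RawSpectrum(power=np.full(12, 3.5), freqs=np.arange(12.0))
        bs = sp.bin_spectrum(raw, sp.make_binning(12, 11.0, 5))
        assert np.allclose(bs.values, 3.5)

    @given(st.integers(2, 64).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(1, n),
                            st.lists(st.floats(0, 1e3), min_size=n,
                                     max_size=n))))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_binning_conserves_total_power(self, case):
        n, B, power = case
        raw = sp.RawSpectrum(power=power, freqs=np.arange(float(n)))
        scheme = sp.make_binning(n, float(n), B)
        bs = sp.bin_spectrum(raw, scheme)
        counts = np.diff(scheme.point_edges)
        assert np.sum(bs.values * counts) == pytest.approx(np.sum(power),
                                                           rel=1e-9, abs=1e-9)


class TestLogTransform:
    def test_powers_of_ten(self):
        raw = sp.RawSpectrum(power=[1, 10, 100], freqs=[0, 1, 2])
        bs = sp.bin_spectrum(raw, sp.make_binning(3, 2.0, 3))
        lg = sp.log_transform(bs)
        assert np.allclose(lg.values, [0, 1, 2])
        assert lg.scale == "log10"

    def test_floor(self):
        bs = sp.BinnedSpectrum(values=[0.0], scheme=sp.make_binning(1, 1.0, 1))
        assert sp.log_transform(bs, floor_eps=1e-12).values[0] == -12.0

    def test_double_transform_is_error(self):
        bs = sp.BinnedSpectrum(values=[1.0], scheme=sp.make_binning(1, 1.0, 1))
        with pytest.raises(ValueError, match="linear"):
            sp.log_transform(sp.log_transform(bs))

    def test_monotone_input_stays_monotone(self):
        bs = sp.BinnedSpectrum(values=[1., 2., 5., 9.],
                               scheme=sp.make_binning(4, 3.0, 4))
        out = sp.log_transform(bs).values
        assert np.all(np.diff(out) > 0)


class TestIntraBinVariance:
    def test_hand_oracle(self):
        raw = sp.RawSpectrum(power=[1, 3, 2, 4], freqs=np.arange(4.0))
        v = sp.mean_intra_bin_variance(raw, sp.make_binning(4, 3.0, 2))
        assert v == pytest.approx(1.0)  # mean(var[1,3], var[2,4]) population

    @pytest.mark.parametrize("B", [1, 3, 12])
    def test_constant_spectrum_zero(self, B):
        raw = sp.RawSpectrum(power=np.full(12, 2.0), freqs=np.arange(12.0))
        assert sp.mean_intra_bin_variance(raw, sp.make_binning(12, 11.0, B)) == 0

    def test_single_point_bins_zero(self):
        rng = np.random.default_rng(6)
        raw = sp.RawSpectrum(power=rng.uniform(0, 1, 9),
                             freqs=np.arange(9.0))
        assert sp.mean_intra_bin_variance(raw, sp.make_binning(9, 8.0, 9)) == 0

    @given(st.integers(2, 64).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(1, n),
                            st.lists(st.floats(0, 100), min_size=n,
                                     max_size=n))))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_matches_brute_force(self, case):
        n, B, power = case
        raw = sp.RawSpectrum(power=power, freqs=np.arange(float(n)))
        scheme = sp.make_binning(n, float(n), B)
        got = sp.mean_intra_bin_variance(raw, scheme)
        want = _brute_mean_intra_bin_variance(power, list(scheme.point_edges))
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


class TestEvenness:
    def test_uniform_is_one(self):
        bs = sp.BinnedSpectrum(values=np.full(8, 0.3),
                               scheme=sp.make_binning(8, 7.0, 8))
        assert sp.spectral_evenness(bs) == pytest.approx(1.0)

    def test_delta_is_zero(self):
        bs = sp.BinnedSpectrum(values=[0, 0, 5, 0],
                               scheme=sp.make_binning(4, 3.0, 4))
        assert sp.spectral_evenness(bs) == pytest.approx(0.0)

    def test_two_bin_value(self):
        bs = sp.BinnedSpectrum(values=[0.8, 0.2],
                               scheme=sp.make_binning(2, 1.0, 2))
        # -(0.8 ln 0.8 + 0.2 ln 0.2) / ln 2
        assert sp.spectral_evenness(bs) == pytest.approx(0.7219, abs=1e-4)

    def test_all_zero_is_error(self):
        bs = sp.BinnedSpectrum(values=[0.0, 0.0],
                               scheme=sp.make_binning(2, 1.0, 2))
        with pytest.raises(ValueError, match="all-zero"):
            sp.spectral_evenness(bs)

    def test_single_bin_defined_as_one(self):
        bs = sp.BinnedSpectrum(values=[2.0], scheme=sp.make_binning(1, 1.0, 1))
        assert sp.spectral_evenness(bs) == 1.0

    @given(st.lists(st.floats(1e-6, 1e3), min_size=2, max_size=32),
           st.floats(1e-3, 1e3))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_scale_invariance_and_range(self, vals, c):
        n = len(vals)
        scheme = sp.make_binning(n, float(n), n)
        e1 = sp.spectral_evenness(sp.BinnedSpectrum(values=vals, scheme=scheme))
        e2 = sp.spectral_evenness(
            sp.BinnedSpectrum(values=np.asarray(vals) * c, scheme=scheme))
        assert e1 == pytest.approx(e2, rel=1e-9, abs=1e-12)
        assert 0.0 <= e1 <= 1.0 + 1e-12


class TestBinSelection:
    def _random_sample(self, n_spectra=20, n_pts=4096, seed=7):
        rng = np.random.default_rng(seed)
        freqs = np.linspace(0, 22_050, n_pts)
        out = []
        for _ in range(n_spectra):
            base = np.exp(-freqs / 3000.0)
            out.append(sp.RawSpectrum(
                power=base * rng.uniform(0.5, 1.5, n_pts), freqs=freqs))
        return out

    def test_constant_sample_zero_variance_curve(self):
        freqs = np.arange(64.0)
        sample = [sp.RawSpectrum(power=np.full(64, 2.0), freqs=freqs)]
        curve = sp.bin_selection_curve(sample, [2, 4, 8, 16])
        assert np.all(curve.v_bar == 0.0)

    def test_vbar_non_increasing_for_nested_binnings(self):
        # nested bin counts on a divisible length: law of total variance
        sample = self._random_sample(n_spectra=10, n_pts=64)
        curve = sp.bin_selection_curve(sample, [1, 2, 4, 8, 16, 32, 64])
        assert np.all(np.diff(curve.v_bar) <= 1e-12)
        assert curve.v_bar[-1] == pytest.approx(0.0, abs=1e-15)

    def test_bin_count_exceeding_length_is_error(self):
        sample = self._random_sample(n_spectra=1, n_pts=32)
        with pytest.raises(ValueError, match="exceeds"):
            sp.bin_selection_curve(sample, [16, 64])

    def test_select_on_constructed_curve(self):
        curve = sp.BinSelectionCurve(
            bin_counts=[50, 100, 200, 400],
            v_bar=[4, 3, 2, 1], h_bar=[1, 2, 3, 4],
            rel_change_v=[1.0, 0.5, 0.05, 0.04],
            rel_change_h=[1.0, 0.5, 0.05, 0.04])
        assert sp.select_bin_count(curve, 0.1,
                                   round_to_power_of_two=False) == 200
        assert sp.select_bin_count(
            sp.BinSelectionCurve(
                bin_counts=[50, 100, 200, 400],
                v_bar=[4, 3, 2, 1], h_bar=[1, 2, 3, 4],
                rel_change_v=[1.0, 0.5, 0.05, 0.04],
                rel_change_h=[1.0, 0.5, 0.05, 0.04]),
            0.1, round_to_power_of_two=True) == 256

    def test_vacuous_threshold_returns_first_b(self):
        curve = sp.BinSelectionCurve(
            bin_counts=[50, 100, 200], v_bar=[3, 2, 1], h_bar=[1, 2, 3])
        assert sp.select_bin_count(curve, 1.0,
                                   round_to_power_of_two=False) == 50

    def test_never_saturates_returns_none(self):
        curve = sp.BinSelectionCurve(
            bin_counts=[50, 100, 200],
            v_bar=[3, 2, 1], h_bar=[1, 2, 3],
            rel_change_v=[np.nan, 1.0, 1.0],
            rel_change_h=[np.nan, 1.0, 1.0])
        assert sp.select_bin_count(curve, 0.1) is None

    def test_threshold_monotonicity(self):
        sample = self._random_sample(n_spectra=5, n_pts=512)
        curve = sp.bin_selection_curve(sample, [2, 4, 8, 16, 32, 64, 128])
        got = [sp.select_bin_count(curve, t, round_to_power_of_two=False)
               for t in (0.5, 0.2, 0.1, 0.05)]
        picked = [b for b in got if b is not None]
        assert picked == sorted(picked)  # lower threshold => B* not smaller


class TestCochran:
    def test_finite_population_study_configuration(self):
        # margin 1%, confidence 99%, N = 416,797 recordings
        exact, rounded = sp.cochran_sample_size(0.01, 0.99, 416_797)
        assert exact == 15_953
        assert rounded == 16_000

    def test_textbook_no_fpc(self):
        exact, _ = sp.cochran_sample_size(0.05, 0.95, None)
        assert exact == 385

    def test_large_population_limit(self):
        no_fpc, _ = sp.cochran_sample_size(0.03, 0.95, None)
        huge, _ = sp.cochran_sample_size(0.03, 0.95, 10 ** 12)
        assert abs(no_fpc - huge) <= 1
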