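import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from isoload.exceptions import (
    DataError,
    DegenerateInputError,
    ParameterError,
)
from isoload.signals import (
    UniformSignal,
    butter_lowpass,
    fit_monoexp,
    linear_slope,
    median_frequency,
    moving_average,
    rms_windowed,
    segment_repetitions,
    stft_psd,
)


def sig(values, fs=1.0):
    return UniformSignal(fs, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# moving average
# ---------------------------------------------------------------------------

class TestMovingAverage:
    def test_constant_unchanged(self):
        out = moving_average(sig(np.full(50, 7.0)), 5.0)
        assert np.allclose(out.values, 7.0)

    def test_three_sample_center(self):
        out = moving_average(sig([1.0, 2.0, 3.0]), 3.0)
        assert out.values[1] == pytest.approx(2.0)

    def test_step_matches_direct_convolution(self):
        x = np.zeros(60)
        x[30:] = 1.0
        w = 7
        out = moving_average(sig(x), float(w))
        # direct per-sample window means (independent loop oracle)
        expected = np.array([
            x[max(0, i - w // 2): i + w // 2 + 1].mean() for i in range(60)])
        assert np.allclose(out.values, expected)

    def test_window_longer_than_signal(self):
        with pytest.raises(DegenerateInputError):
            moving_average(sig([1.0, 2.0]), 10.0)


# ---------------------------------------------------------------------------
# Butterworth low-pass
# ---------------------------------------------------------------------------

class TestButterLowpass:
    def _gain(self, f, fs=1000.0, cutoff=10.0):
        t = np.arange(0, 30.0, 1.0 / fs)
        x = np.sin(2 * np.pi * f * t)
        y = butter_lowpass(sig(x, fs), cutoff).values
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        return np.sqrt(np.mean(y[mid] ** 2)) / np.sqrt(np.mean(x[mid] ** 2))

    def test_dc_gain_is_one(self):
        out = butter_lowpass(sig(np.full(500, 3.3), 100.0), 10.0)
        assert np.allclose(out.values, 3.3, atol=1e-9)

    def test_half_power_at_cutoff(self):
        # forward-backward second order: |H|^2 = 1/2 at the cutoff
        assert self._gain(10.0) == pytest.approx(0.5, rel=0.02)

    def test_passband_flat(self):
        assert self._gain(1.0) >= 0.99

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            butter_lowpass(sig(np.zeros(100), 100.0), 60.0)


# ---------------------------------------------------------------------------
# windowed RMS
# ---------------------------------------------------------------------------

class TestRMSWindowed:
    def test_constant(self):
        out = rms_windowed(sig(np.full(40, 4.0)), 5.0)
        assert np.allclose(out.values, 4.0)

    def test_sine_integer_periods(self):
        fs, f0, amp = 1000.0, 10.0, 2.5
        t = np.arange(0, 2.0, 1.0 / fs)
        x = amp * np.sin(2 * np.pi * f0 * t)
        out = rms_windowed(sig(x, fs), 0.5)  # 5 full periods
        mid = slice(500, 1500)
        assert np.allclose(out.values[mid], amp / np.sqrt(2), rtol=1e-3)

    def test_white_noise_sd(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3.0, 20000)
        out = rms_windowed(sig(x, 100.0), 100.0)
        assert out.values[10000] == pytest.approx(3.0, rel=0.05)


# ---------------------------------------------------------------------------
# STFT power spectra
# ---------------------------------------------------------------------------

class TestStftPsd:
    @pytest.mark.parametrize("n_extra", [0, 1, 100, 255, 256, 257])
    def test_window_count_formula(self, n_extra):
        fs = 2048.0
        nwin, nhop = 512, 256
        n = nwin + n_extra
        frame = stft_psd(sig(np.ones(n), fs))
        assert frame.n_windows == (n - nwin) // nhop + 1

    def test_pure_tone_peak_bin(self):
        fs = 2048.0
        t = np.arange(0, 1.0, 1 / fs)
        frame = stft_psd(sig(np.sin(2 * np.pi * 100.0 * t), fs))
        for row in frame.power:
            peak = frame.freqs[np.argmax(row)]
            nearest = frame.freqs[np.argmin(np.abs(frame.freqs - 100.0))]
            assert peak == nearest

    def test_zero_signal(self):
        frame = stft_psd(sig(np.zeros(1024), 2048.0))
        assert np.all(frame.power == 0)

    def test_two_tones_dominate(self):
        fs = 2048.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 150 * t)
        frame = stft_psd(sig(x, fs))
        mean_power = frame.power.mean(axis=0)
        top2 = frame.freqs[np.argsort(mean_power)[-2:]]
        assert set(np.round(top2 / 2) * 2) == {48.0, 148.0} or \
            all(min(abs(f - 50), abs(f - 150)) <= 4.0 for f in top2)

    def test_parseval_per_window(self):
        # each PSD row sums to the energy of its Hann-weighted segment
        rng = np.random.default_rng(1)
        fs = 2048.0
        x = rng.normal(0, 1, 4096)
        frame = stft_psd(sig(x, fs))
        nwin, nhop = 512, 256
        w = sps.get_window("hann", nwin, fftbins=True)
        for i in range(frame.n_windows):
            seg = x[i * nhop: i * nhop + nwin] * w
            assert frame.power[i].sum() == pytest.approx(np.sum(seg**2),
                                                         rel=1e-6)

    def test_too_short_signal(self):
        with pytest.raises(DegenerateInputError):
            stft_psd(sig(np.zeros(100), 2048.0))


# ---------------------------------------------------------------------------
# median frequency
# ---------------------------------------------------------------------------

def brute_force_mdf(freqs, power):
    """Scalar-loop quantile search with piecewise-uniform bins."""
    widths = np.empty_like(freqs)
    widths[1:-1] = (freqs[2:] - freqs[:-2]) / 2.0
    widths[0] = freqs[1] - freqs[0]
    widths[-1] = freqs[-1] - freqs[-2]
    half = power.sum() / 2.0
    acc = 0.0
    for j in range(len(freqs)):
        if acc + power[j] >= half:
            frac = (half - acc) / power[j] if power[j] > 0 else 0.5
            return freqs[j] - widths[j] / 2.0 + frac * widths[j]
        acc += power[j]
    raise AssertionError("unreachable")


class TestMedianFrequency:
    def test_flat_spectrum_half_band(self):
        freqs = np.arange(0.0, 101.0)
        assert median_frequency(freqs, np.ones_like(freqs)) == pytest.approx(50.0)

    def test_single_bin(self):
        freqs = np.arange(0.0, 101.0)
        p = np.zeros_like(freqs)
        p[37] = 5.0
        assert median_frequency(freqs, p) == pytest.approx(freqs[37])

    def test_triangular_spectrum_quantile(self):
        # density rising linearly on [0, 100]: median at 100/sqrt(2)
        freqs = np.arange(0.0, 100.5, 0.5)
        assert median_frequency(freqs, freqs.copy()) == pytest.approx(
            100.0 / np.sqrt(2), abs=0.5)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DataError):
            median_frequency(np.arange(10.0), np.zeros(10))

    def test_matches_brute_force_on_random_spectra(self):
        rng = np.random.default_rng(7)
        freqs = np.fft.rfftfreq(512, 1 / 2048.0)
        for _ in range(500):
            p = rng.exponential(1.0, freqs.size)
            assert median_frequency(freqs, p) == pytest.approx(
                brute_force_mdf(freqs, p), abs=1e-9)


# ---------------------------------------------------------------------------
# mono-exponential fit
# ---------------------------------------------------------------------------

def grid_search_monoexp(x, y, rates):
    """Independent dense-grid oracle: best (b, alpha, c) over a rate grid."""
    best = None
    for r in rates:
        e = np.exp(r * x)
        design = np.column_stack([e, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((design @ coef - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, coef[0], r, coef[1])
    return best


class TestFitMonoexp:
    def test_exact_recovery(self):
        x = np.linspace(0, 10, 50)
        y = 10 * np.exp(-0.5 * x) + 2
        f = fit_monoexp(x, y)
        assert f.converged
        assert (f.b, f.alpha, f.c) == pytest.approx((10, -0.5, 2), rel=1e-6)

    @pytest.mark.parametrize("b", [1.0, 10.0, 100.0])
    @pytest.mark.parametrize("alpha", [-2.0, -0.5, -0.05])
    @pytest.mark.parametrize("c", [0.0, 2.0, -5.0])
    def test_noise_free_grid(self, b, alpha, c):
        x = np.linspace(0, 4.0 / abs(alpha), 40)
        y = b * np.exp(alpha * x) + c
        f = fit_monoexp(x, y)
        assert f.converged
        scale = max(abs(b), abs(c), 1.0)
        assert abs(f.b - b) / scale < 1e-4
        assert abs(f.alpha - alpha) / abs(alpha) < 1e-4
        assert abs(f.c - c) / scale < 1e-4

    def test_constant_y_flagged_unidentifiable(self):
        x = np.linspace(0, 5, 10)
        f = fit_monoexp(x, np.full(10, 3.0))
        assert not f.converged
        assert f.b == pytest.approx(0.0)
        assert f.c == pytest.approx(3.0)

    def test_beats_independent_grid_search(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 8, 60)
        y = 4 * np.exp(-0.7 * x) + 1 + rng.normal(0, 0.02, 60)
        f = fit_monoexp(x, y)
        rss_o, b_o, r_o, c_o = grid_search_monoexp(
            x, y, -np.linspace(0.01, 3.0, 600))
        assert f.rss <= rss_o + 1e-12
        assert f.alpha == pytest.approx(r_o, abs=0.02)

    def test_growth_allowed(self):
        x = np.array([58.0, 77.0, 93.0])
        y = -0.03 * np.exp(0.071 * x)
        f = fit_monoexp(x, y, fix_c=True)
        assert f.alpha == pytest.approx(0.071, abs=1e-6)


class TestLinearSlope:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_slope(x, 2 * x + 1)
        assert (fit.slope, fit.intercept, fit.r2) == pytest.approx((2, 1, 1))

    def test_constant_y(self):
        fit = linear_slope(np.arange(5.0), np.full(5, 3.0))
        assert fit.slope == pytest.approx(0.0)

    def test_noisy_line_within_3se(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 1000)
        y = 3.5 * x - 2 + rng.normal(0, 1, 1000)
        fit = linear_slope(x, y)
        assert abs(fit.slope - 3.5) < 3 * fit.stderr

    def test_degenerate_x(self):
        with pytest.raises(DataError):
            linear_slope(np.ones(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# repetition segmentation
# ---------------------------------------------------------------------------

def make_velocity(bursts, fs=148.0, total_s=60.0, level=1.0):
    v = np.zeros(int(total_s * fs))
    for (a, b) in bursts:
        v[int(a * fs): int(b * fs)] = level
    return UniformSignal(fs, v)


class TestSegmentation:
    def test_zero_velocity_empty(self):
        segs = segment_repetitions(make_velocity([]), v_thresh=0.1)
        assert segs == []

    def test_counts_and_series(self):
        bursts = [(1 + 2 * k, 2 + 2 * k) for k in range(3)]
        bursts += [(20 + 2 * k, 21 + 2 * k) for k in range(3)]
        segs = segment_repetitions(make_velocity(bursts), v_thresh=0.1)
        assert len(segs) == 6
        assert [s.series for s in segs] == [1, 1, 1, 2, 2, 2]
        assert [s.idx for s in segs] == list(range(1, 7))

    def test_short_bursts_discarded(self):
        segs = segment_repetitions(make_velocity([(1.0, 1.05), (3.0, 4.0)]),
                                   v_thresh=0.1)
        assert len(segs) == 1

    def test_invariant_to_added_rest(self):
        bursts = [(1, 2), (4, 5)]
        a = segment_repetitions(make_velocity(bursts, total_s=30), v_thresh=0.1)
        b = segment_repetitions(make_velocity(bursts, total_s=90), v_thresh=0.1)
        assert [(s.i0, s.i1, s.series) for s in a] == \
            [(s.i0, s.i1, s.series) for s in b]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 4))
    def test_generator_burst_count_recovered(self, n_reps, n_sets):
        bursts = []
        t = 2.0
        for s in range(n_sets):
            for _ in range(n_reps):
                bursts.append((t, t + 1.0))
                t += 2.0
            t += 8.0
        segs = segment_repetitions(
            make_velocity(bursts, total_s=t + 5), v_thresh=0.1)
        assert len(segs) == n_reps * n_sets
        assert segs[-1].series == n_sets
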