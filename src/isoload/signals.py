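"""Shared biosignal operators.

Filtering, windowed RMS, STFT power spectra, median frequency,
mono-exponential / linear fits and repetition segmentation — the numeric
primitives every downstream feature (RFD, EMG fatigue markers, HR and
VO2 kinetics) is built from.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps, stats

from .exceptions import DataError, DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "UniformSignal",
    "MonoExpFit",
    "PSDFrame",
    "LinearFit",
    "RepetitionSegment",
    "moving_average",
    "butter_lowpass",
    "rms_windowed",
    "stft_psd",
    "median_frequency",
    "fit_monoexp",
    "linear_slope",
    "segment_repetitions",
]


@dataclass
class UniformSignal:
    """A uniformly sampled channel.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz, strictly positive.
    values : ndarray
        Sample values. Must be non-empty.
    t0 : float
        Time of the first sample in seconds.
    """

    fs: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ParameterError("sampling frequency must be positive")
        if self.values.size == 0:
            raise DegenerateInputError("signal must contain at least one sample")

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def slice_time(self, t_start: float, t_end: float) -> "UniformSignal":
        """Return the sub-signal on the closed interval [t_start, t_end]."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.fs - 1e-9)))
        i1 = min(self.values.size,
                 int(np.floor((t_end - self.t0) * self.fs + 1e-9)) + 1)
        if i1 <= i0:
            raise DegenerateInputError("requested window contains no samples")
        return UniformSignal(self.fs, self.values[i0:i1], self.t0 + i0 / self.fs)


@dataclass
class MonoExpFit:
    """Parameters of the mono-exponential model f(x) = b * exp(alpha * x) + c.

    ``alpha`` is negative for a decay and positive for a growth. ``b`` is the
    gain (amplitude at x = 0 above the asymptote ``c``).
    """

    b: float
    alpha: float
    c: float
    rss: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.b * np.exp(self.alpha * np.asarray(x, dtype=float)) + self.c


@dataclass
class PSDFrame:
    """Per-window one-sided power spectra from a short-time Fourier transform.

    ``power[i]`` holds the spectrum of window ``i``; each row sums to the
    time-domain energy of that (window-function-weighted) segment.
    """

    freqs: np.ndarray
    power: np.ndarray  # shape (n_windows, n_freqs)
    window_times: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.power.shape[0]


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    stderr: float = np.nan


@dataclass
class RepetitionSegment:
    """Half-open sample window [i0, i1) of one repetition.

    ``idx`` counts repetitions cumulatively across sets; ``series`` is the
    1-based set index. ``onset_idx`` is filled in by torque-onset detection
    and defaults to the segment start.
    """

    idx: int
    series: int
    i0: int
    i1: int
    onset_idx: int | None = None

    def __post_init__(self) -> None:
        if self.i0 >= self.i1:
            raise DataError("repetition segment must satisfy i0 < i1")
        if self.onset_idx is not None and not (self.i0 <= self.onset_idx < self.i1):
            raise DataError("onset_idx must lie within [i0, i1)")

    @property
    def n_samples(self) -> int:
        return self.i1 - self.i0


# ---------------------------------------------------------------------------
# Smoothing and envelopes
# ---------------------------------------------------------------------------

def moving_average(x: UniformSignal, window_s: float) -> UniformSignal:
    """Centered moving average with edge shrinkage.

    The window shrinks near the edges so the output has the same length as
    the input and constant signals pass through unchanged.
    """
    w = int(round(window_s * x.fs))
    if w < 1:
        raise ParameterError("window must span at least one sample")
    if w > x.values.size:
        raise DegenerateInputError("window longer than signal")
    if w % 2 == 1:
        kernel = np.ones(w)
    else:
        # even spans cannot be centered on a sample; use a symmetric
        # trapezoid (half-weight endpoints) with the same effective width
        kernel = np.ones(w + 1)
        kernel[0] = kernel[-1] = 0.5
    num = np.convolve(x.values, kernel, mode="same")
    den = np.convolve(np.ones_like(x.values), kernel, mode="same")
    return UniformSignal(x.fs, num / den, x.t0)


def butter_lowpass(x: UniformSignal, cutoff: float, order: int = 2) -> UniformSignal:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Two passes double the attenuation: the effective response at the cutoff
    is -6 dB (amplitude ratio 0.5) rather than the single-pass -3 dB.
    """
    nyq = x.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=x.fs, output="sos")
    return UniformSignal(x.fs, sps.sosfiltfilt(sos, x.values), x.t0)


def rms_windowed(x: UniformSignal, window_s: float) -> UniformSignal:
    """Running root-mean-square over a centered window (edge shrinkage)."""
    sq = UniformSignal(x.fs, x.values**2, x.t0)
    return UniformSignal(x.fs, np.sqrt(moving_average(sq, window_s).values), x.t0)


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------

def stft_psd(
    x: UniformSignal,
    win_s: float = 0.250,
    hop_s: float = 0.125,
    window: str = "hann",
) -> PSDFrame:
    """Short-time one-sided power spectra on overlapping windows.

    Windows are ``win_s`` long and hop by ``hop_s`` (50% overlap at the
    defaults); the window count is floor((N - win) / hop) + 1.  Each row is
    normalized so that its sum equals the time-domain energy of the
    window-weighted segment (Parseval), which makes relative measures such
    as the median frequency independent of the normalization choice.
    """
    nwin = int(round(win_s * x.fs))
    nhop = int(round(hop_s * x.fs))
    n = x.values.size
    if nwin < 2 or nhop < 1:
        raise ParameterError("window and hop must span at least 2 and 1 samples")
    if n < nwin:
        raise DegenerateInputError("signal shorter than one STFT window")
    n_windows = (n - nwin) // nhop + 1
    w = sps.get_window(window, nwin, fftbins=True)
    idx = np.arange(nwin)[None, :] + nhop * np.arange(n_windows)[:, None]
    frames = x.values[idx] * w
    spec = np.fft.rfft(frames, axis=1)
    power = np.abs(spec) ** 2 / nwin
    # one-sided: double everything except DC (and Nyquist when nwin is even)
    if nwin % 2 == 0:
        power[:, 1:-1] *= 2.0
    else:
        power[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(nwin, d=1.0 / x.fs)
    times = x.t0 + (np.arange(n_windows) * nhop + nwin / 2.0) / x.fs
    return PSDFrame(freqs=freqs, power=power, window_times=times)


def median_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    """Frequency splitting a power spectrum into two equal-power halves.

    Each bin is treated as a uniform density over its width; the crossing
    point of the cumulative power at half the total is located by linear
    interpolation inside the crossing bin, so a flat spectrum on [0, F]
    returns exactly F/2.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if freqs.ndim != 1 or power.shape != freqs.shape:
        raise ParameterError("freqs and power must be 1-D and equal length")
    if np.any(power < 0):
        raise DataError("power spectrum must be nonnegative")
    total = power.sum()
    if total <= 0:
        raise DataError("median frequency undefined for an all-zero spectrum")
    if freqs.size == 1:
        return float(freqs[0])
    # bin widths: midpoints between neighbours, half-width at the ends
    widths = np.empty_like(freqs)
    widths[1:-1] = (freqs[2:] - freqs[:-2]) / 2.0
    widths[0] = freqs[1] - freqs[0]
    widths[-1] = freqs[-1] - freqs[-2]
    lower_edges = freqs - widths / 2.0
    cum = np.cumsum(power)
    half = total / 2.0
    j = int(np.searchsorted(cum, half, side="left"))
    prev = cum[j - 1] if j > 0 else 0.0
    frac = (half - prev) / power[j] if power[j] > 0 else 0.5
    return float(lower_edges[j] + frac * widths[j])


# ---------------------------------------------------------------------------
# Curve fits
# ---------------------------------------------------------------------------

def _monoexp_linear_solve(x, y, rate, fix_c):
    """For a fixed rate, solve the (b, c) linear subproblem and return rss."""
    e = np.exp(rate * x)
    if fix_c:
        denom = float(e @ e)
        if denom <= 0:
            return None
        b = float(e @ y) / denom
        c = 0.0
    else:
        design = np.column_stack([e, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        b, c = float(coef[0]), float(coef[1])
    resid = y - (b * e + c)
    return b, c, float(resid @ resid)


def fit_monoexp(
    x: np.ndarray,
    y: np.ndarray,
    fix_c: bool = False,
    rate_sign: int = 0,
) -> MonoExpFit:
    """Least-squares fit of y = b * exp(alpha * x) + c.

    Uses variable projection: for each candidate rate on a multi-start grid
    the (b, c) subproblem is solved linearly, then the best start is polished
    with a bounded nonlinear refinement. ``rate_sign`` restricts the search
    to decays (-1), growths (+1) or both (0). ``fix_c`` pins the asymptote
    at zero, useful when three points must identify the rate.

    A constant (or numerically constant) ``y`` leaves the rate
    unidentifiable: the fit returns b = 0, c = mean(y) and
    ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    min_pts = 3 if fix_c else 4
    if x.size != y.size or x.size < min_pts:
        raise ParameterError(f"need at least {min_pts} points")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise DataError("x and y must be finite")
    x_span = np.ptp(x)
    if x_span <= 0:
        raise DataError("x values must not all coincide")

    y_span = np.ptp(y)
    if y_span == 0 or y_span < 1e-12 * max(1.0, np.abs(y).max()):
        return MonoExpFit(b=0.0, alpha=np.nan, c=float(np.mean(y)), rss=0.0,
                          converged=False)

    # multi-start grid of rate constants scaled to the x range
    base = np.array([5.0, 2.0, 1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01, 0.001]) / x_span
    rates = []
    if rate_sign <= 0:
        rates.extend(-base)
    if rate_sign >= 0:
        rates.extend(base)

    # log-linear initial guess (decay toward min or growth from max)
    for c0 in (np.min(y), np.max(y)):
        z = y - c0
        sgn = np.sign(z[np.argmax(np.abs(z))])
        z = sgn * z
        mask = z > 1e-12 * y_span
        if mask.sum() >= 2:
            slope, _ = np.polyfit(x[mask], np.log(z[mask]), 1)
            if np.isfinite(slope) and slope != 0:
                if (rate_sign == 0) or (np.sign(slope) == np.sign(rate_sign)):
                    rates.append(float(slope))

    best = None
    for r in rates:
        sol = _monoexp_linear_solve(x, y, r, fix_c)
        if sol is None:
            continue
        b, c, rss = sol
        if best is None or rss < best[3]:
            best = (b, r, c, rss)
    if best is None:
        return MonoExpFit(b=np.nan, alpha=np.nan, c=np.nan, rss=np.inf,
                          converged=False)

    b0, r0, c0, _ = best

    def residuals(theta):
        b, r, c = (theta[0], theta[1], theta[2]) if not fix_c else (theta[0], theta[1], 0.0)
        with np.errstate(over="ignore"):
            return b * np.exp(np.clip(r * x, -700, 700)) + c - y

    theta0 = [b0, r0] if fix_c else [b0, r0, c0]
    try:
        res = optimize.least_squares(residuals, theta0, method="lm", max_nfev=5000)
    except Exception:  # pragma: no cover - LM rarely raises
        res = None
    if res is not None and np.isfinite(res.cost):
        if fix_c:
            b, r = res.x
            c = 0.0
        else:
            b, r, c = res.x
        rss = float(2 * res.cost)
        # keep the polished solution only if it did not diverge
        if rss <= best[3] + 1e-12:
            best = (float(b), float(r), float(c), rss)

    b, r, c, rss = best
    ok = np.isfinite([b, r, c]).all()
    return MonoExpFit(b=b, alpha=r, c=c, rss=rss, converged=bool(ok))


def linear_slope(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least-squares line fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ParameterError("need at least two points")
    if np.ptp(x) == 0:
        raise DataError("x values must not all coincide")
    with warnings.catch_warnings():
        # constant y makes r undefined; we report r2 = 0 in that case
        warnings.simplefilter("ignore")
        res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r2=r2, stderr=float(res.stderr))


# ---------------------------------------------------------------------------
# Repetition segmentation
# ---------------------------------------------------------------------------

def segment_repetitions(
    velocity: UniformSignal,
    v_thresh: float | None = None,
    proto_velocity: float | None = None,
    min_dur_s: float = 0.2,
    rest_thresh_s: float = 5.0,
) -> list[RepetitionSegment]:
    """Detect concentric repetitions from the angular-velocity channel.

    A repetition is a maximal run of samples with velocity above
    ``v_thresh`` (default 10% of the protocol velocity) lasting at least
    ``min_dur_s``. Repetitions separated by more than ``rest_thresh_s`` are
    assigned to different series (sets). Returns an empty list (with a
    warning log) when nothing crosses the threshold.
    """
    if v_thresh is None:
        if proto_velocity is None or proto_velocity <= 0:
            raise ParameterError("provide v_thresh or a positive proto_velocity")
        v_thresh = 0.1 * proto_velocity
    v = velocity.values
    above = v > v_thresh
    if not above.any():
        logger.warning("no repetitions found above velocity threshold %.3g", v_thresh)
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [v.size]])
    min_n = int(np.ceil(min_dur_s * velocity.fs))
    keep = (ends - starts) >= min_n
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        logger.warning("all velocity bursts shorter than %.3g s", min_dur_s)
        return []
    segs: list[RepetitionSegment] = []
    series = 1
    rest_n = rest_thresh_s * velocity.fs
    for k, (i0, i1) in enumerate(zip(starts, ends)):
        if k > 0 and (i0 - ends[k - 1]) > rest_n:
            series += 1
        segs.append(RepetitionSegment(idx=k + 1, series=series,
                                      i0=int(i0), i1=int(i1)))
    return segs
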