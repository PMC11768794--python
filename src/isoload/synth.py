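"""Synthetic isokinetic-session generator with recoverable ground truth.

Emulates a single-joint isokinetic leg-extension session: per-repetition
torque ramps whose peak rate of force development (RFD) declines linearly
with accumulated repetitions, surface EMG whose median frequency shifts
downward and whose RMS amplitude drifts upward with fatigue, heart-rate and
oxygen-uptake exercise rise with mono-exponential recovery, NIRS
oxygenation-index decline during contractions, and intensity/volume
dependent blood-lactate and perceived-exertion responses.

Every stochastic choice is parameterized and the generating values are
returned alongside the recording (``SessionRecording.truth``) so each
downstream estimator can be tested against a known answer.

Fatigue model
-------------
The per-repetition peak RFD at relative intensity I (%MVC) follows

    RFDpeak(n) = RFD0(I) + s(I) * (n - 1),      RFD0(I) = rfd_base * I/100
    s(I) = fatigue_gain * exp(-fatigue_alpha * I)

with ``fatigue_gain`` < 0 and ``fatigue_alpha`` < 0, so higher intensities
produce a steeper (more negative) per-repetition decline — the
mono-exponential law that the training-load calibration recovers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .exceptions import ConfigurationError, ParameterError, SamplingError

__all__ = [
    "ParticipantTruth",
    "ProtocolSpec",
    "NoiseConfig",
    "ResponseModel",
    "MechChannels",
    "EMGChannels",
    "SampledSeries",
    "NIRSChannels",
    "SessionTruth",
    "SessionRecording",
    "DEFAULT_RANGES",
    "generate_participant",
    "generate_session",
    "default_protocols",
    "rfd_slope_law",
]

ALL_CHANNELS = ("mech", "emg", "hr", "vo2", "nirs", "lactate", "rpe")

#: Sampling ranges for participant truth parameters (uniform draws).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mvc": (200.0, 320.0),           # N.m
    "v0": (3.5, 4.5),                # rad/s, zero-torque velocity of the T-V line
    "rfd_base": (900.0, 1500.0),     # N.m/s at 100 %MVC
    "fatigue_alpha": (-0.071, -0.071),  # 1/%MVC
    "fatigue_gain": (-0.05, -0.03),  # N.m/s per rep at I -> 0
    "hr_rest": (55.0, 75.0),         # bpm
    "hr_alpha": (-0.030, -0.020),    # 1/s, HR recovery rate
    "vo2_rest": (250.0, 400.0),      # mL/min
    "vo2_alpha": (-0.022, -0.015),   # 1/s, VO2 recovery rate
    "lact_base": (0.8, 1.5),         # mmol/L
}


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground-truth physiology of one simulated participant."""

    id: str
    mvc: float
    tv_shape: str
    tv_params: dict
    rfd_base: float
    fatigue_alpha: float
    fatigue_gain: float
    hr_rest: float
    hr_alpha: float
    vo2_rest: float
    vo2_alpha: float
    lact_base: float
    rng_seed: int

    def __post_init__(self):
        if self.mvc <= 0 or self.rfd_base <= 0:
            raise ParameterError("mvc and rfd_base must be positive")
        if not 40 <= self.hr_rest <= 100:
            raise ParameterError("hr_rest must lie in [40, 100] bpm")
        if self.tv_shape not in ("linear", "hyperbolic"):
            raise ParameterError("tv_shape must be 'linear' or 'hyperbolic'")


@dataclass(frozen=True)
class ProtocolSpec:
    """One exercise protocol: sets x reps at a relative intensity."""

    label: str
    relative_intensity: float  # %MVC
    n_sets: int
    reps_per_set: int
    interset_rest_s: float
    angular_velocity: float  # rad/s
    fs_mech: float = 148.0
    fs_emg: float = 2048.0
    rom_rad: float = 1.5
    inter_rep_gap_s: float = 1.0
    baseline_s: float = 60.0
    recovery_s: float = 180.0

    def __post_init__(self):
        if not 0 < self.relative_intensity <= 100:
            raise ParameterError("relative_intensity must lie in (0, 100]")
        if self.n_sets < 1 or self.reps_per_set < 1:
            raise ParameterError("n_sets and reps_per_set must be >= 1")
        if self.interset_rest_s < 0:
            raise ParameterError("interset_rest_s must be nonnegative")
        if self.angular_velocity <= 0:
            raise ParameterError("angular_velocity must be positive")

    @property
    def n_reps(self) -> int:
        return self.n_sets * self.reps_per_set

    @property
    def rep_duration_s(self) -> float:
        return self.rom_rad / self.angular_velocity

    @property
    def total_rest_s(self) -> float:
        return (self.n_sets - 1) * self.interset_rest_s


def default_protocols() -> dict[str, ProtocolSpec]:
    """The three volume-equated study conditions.

    24, 9 and 3 theoretical repetition maxima map (via the Reynolds
    equation) to 58, 77 and 93 %MVC; volume-equating 24 reps at 58% gives
    2x9 at 77% and 5x3 at 93%. Angular velocities follow a typical linear
    T-V profile with a 4 rad/s zero-torque velocity.
    """
    return {
        "LI": ProtocolSpec("LI", 58.0, 1, 24, 0.0, 1.68),
        "MI": ProtocolSpec("MI", 77.0, 2, 9, 180.0, 0.92),
        "HI": ProtocolSpec("HI", 93.0, 5, 3, 240.0, 0.28),
    }


@dataclass(frozen=True)
class NoiseConfig:
    """Noise scales of the generator; all zero gives a noiseless session."""

    torque_peak_rel_sd: float = 0.02   # per-rep peak-torque multiplier
    rfd_rel_sd: float = 0.03           # per-rep peak-RFD multiplier
    mech_sd_nm: float = 0.5            # additive torque sensor noise
    velocity_sd: float = 0.005         # rad/s
    emg_floor_mv: float = 0.005        # resting EMG amplitude
    rr_jitter_s: float = 0.003         # per-beat R-R jitter
    vo2_breath_sd: float = 10.0        # mL/min per breath
    nirs_sd_um: float = 0.1            # micromolar
    tsi_sd: float = 0.05               # % points
    lactate_sd: float = 0.2            # mmol/L
    rpe_jitter: int = 1                # +/- integer steps

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)


@dataclass(frozen=True)
class ResponseModel:
    """Deterministic physiological response parameters of the generator."""

    # EMG
    mdf0_hz: float = 85.0              # first-rep median frequency
    mdf_slope_base: float = 0.15       # Hz per rep at I -> 0
    mdf_slope_per_intensity: float = 0.006  # Hz per rep per %MVC
    mdf_band_sd_hz: float = 12.5       # spectral width of synthetic EMG
    emg_amp_mv: float = 0.4            # base contraction RMS at 100 %MVC
    rms_drift_per_rep: float = 0.01    # relative RMS gain per rep
    # heart rate
    hr_delta0: float = 50.0            # bpm rise at I -> 0
    hr_delta_per_intensity: float = 0.3
    hr_on_tau_s: float = 30.0
    hr_recovery_floor_bpm: float = 3.0  # asymptote above rest
    # oxygen uptake
    vo2_slope0: float = 8.0            # mL/min per s at I -> 0
    vo2_slope_per_intensity: float = 0.10
    vo2_cap: float = 3000.0
    # NIRS
    hbdiff_rate0: float = -2.0         # uM/s at I -> 0
    hbdiff_rate_per_intensity: float = -0.04
    hbdiff_rebound_tau_s: float = 5.0
    tsi_base: float = 70.0
    # lactate delta model: d = c_reps*V + c_int*I + c_rest/(1 + R/60)
    lact_c_reps: float = 0.25
    lact_c_intensity: float = -0.03
    lact_c_rest: float = 1.0
    lact_onset_bump: float = 0.3
    lact_post3_frac: float = 0.7
    # perceived exertion
    rpe_base: float = 0.18
    rpe_w_intensity: float = 0.5
    rpe_w_volume: float = 0.28


@dataclass
class MechChannels:
    fs: float
    torque: np.ndarray
    velocity: np.ndarray
    position: np.ndarray
    t0: float = 0.0

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.torque.size) / self.fs


@dataclass
class EMGChannels:
    fs: float
    vlat: np.ndarray
    vmed: np.ndarray
    rfem: np.ndarray
    t0: float = 0.0

    @property
    def muscles(self) -> dict[str, np.ndarray]:
        return {"vlat": self.vlat, "vmed": self.vmed, "rfem": self.rfem}


@dataclass
class SampledSeries:
    t: np.ndarray
    values: np.ndarray


@dataclass
class NIRSChannels:
    t: np.ndarray
    do2hb: np.ndarray
    dhhb: np.ndarray
    tsi: np.ndarray


@dataclass
class SessionTruth:
    """Generator-side ground truth for one session."""

    n_reps: int
    rep_start_s: np.ndarray
    rep_dur_s: np.ndarray
    rep_series: np.ndarray
    peak_torque: np.ndarray
    ramp_s: np.ndarray
    rfd_peak: np.ndarray
    rfd_0_100: np.ndarray
    impulse: np.ndarray
    work: np.ndarray
    rfd_slope: float                 # s(I) programmed into the decline
    mdf_hz: np.ndarray               # per-rep median frequency target
    emg_gain: np.ndarray             # per-rep RMS gain multiplier
    hr_recovery: dict | None = None  # {b, alpha, c, t_start, t_end}
    vo2_recovery: dict | None = None
    vo2_ex_slope: float | None = None
    ee_exercise_kj: float | None = None
    ee_total_kj: float | None = None
    hbdiff_rate: float | None = None
    lactate: dict | None = None
    rpe: float | None = None
    cr10: float | None = None


@dataclass
class SessionRecording:
    """All channels and metadata recorded for one session."""

    participant: str
    protocol: ProtocolSpec
    mech: MechChannels | None
    emg: EMGChannels | None
    rr_intervals: np.ndarray | None
    vo2: SampledSeries | None
    nirs: NIRSChannels | None
    lactate: dict | None
    rpe: float | None
    cr10: float | None
    session_duration_s: float
    events: dict
    truth: SessionTruth


# ---------------------------------------------------------------------------
# Participant generation
# ---------------------------------------------------------------------------

def generate_participant(
    seed: int,
    config: dict[str, tuple[float, float]] | None = None,
    pid: str | None = None,
) -> ParticipantTruth:
    """Draw one participant from uniform ranges (deterministic in seed)."""
    ranges = dict(DEFAULT_RANGES)
    if config:
        ranges.update(config)
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ConfigurationError(f"range for {name!r} has min > max")
    rng = np.random.default_rng(seed)
    draw = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in sorted(ranges.items())}
    return ParticipantTruth(
        id=pid if pid is not None else f"P{seed:04d}",
        mvc=draw["mvc"],
        tv_shape="linear",
        tv_params={"T0": draw["mvc"], "v0": draw["v0"]},
        rfd_base=draw["rfd_base"],
        fatigue_alpha=draw["fatigue_alpha"],
        fatigue_gain=draw["fatigue_gain"],
        hr_rest=draw["hr_rest"],
        hr_alpha=draw["hr_alpha"],
        vo2_rest=draw["vo2_rest"],
        vo2_alpha=draw["vo2_alpha"],
        lact_base=draw["lact_base"],
        rng_seed=seed,
    )


def rfd_slope_law(intensity: float, fatigue_gain: float, fatigue_alpha: float) -> float:
    """Per-repetition peak-RFD decline (N.m/s per rep) at a given %MVC."""
    return fatigue_gain * math.exp(-fatigue_alpha * intensity)


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _rep_timeline(proto: ProtocolSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Start times and series index of each repetition, plus total duration."""
    starts, series = [], []
    t = proto.baseline_s
    for s in range(proto.n_sets):
        for _ in range(proto.reps_per_set):
            starts.append(t)
            series.append(s + 1)
            t += proto.rep_duration_s + proto.inter_rep_gap_s
        t -= proto.inter_rep_gap_s  # no gap after the last rep of a set
        if s < proto.n_sets - 1:
            t += proto.interset_rest_s
    total = t + proto.recovery_s
    return np.asarray(starts), np.asarray(series, dtype=int), total


def _raised_cosine_torque(tau: np.ndarray, t_ramp: float, t_down: float,
                          dur: float, peak: float) -> np.ndarray:
    """Half-raised-cosine ramp to ``peak``, plateau, then fast release."""
    y = np.zeros_like(tau)
    up = tau < t_ramp
    y[up] = 0.5 * peak * (1.0 - np.cos(np.pi * tau[up] / t_ramp))
    flat = (tau >= t_ramp) & (tau < dur - t_down)
    y[flat] = peak
    down = (tau >= dur - t_down) & (tau < dur)
    y[down] = 0.5 * peak * (1.0 + np.cos(np.pi * (tau[down] - (dur - t_down)) / t_down))
    return y


def _mech_channels(proto, rep_starts, peaks, ramps, total_s, rng, noise):
    fs = proto.fs_mech
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    torque = np.zeros(n)
    velocity = np.zeros(n)
    dur = proto.rep_duration_s
    t_down = min(0.05, 0.2 * dur)
    return_v = 5.236
    return_dur = proto.rom_rad / return_v
    for t0, pk, tr in zip(rep_starts, peaks, ramps):
        i0 = int(round(t0 * fs))
        i1 = min(n, int(round((t0 + dur) * fs)))
        tau = t[i0:i1] - t0
        torque[i0:i1] = _raised_cosine_torque(tau, tr, t_down, dur, pk)
        velocity[i0:i1] = proto.angular_velocity
        # assisted return inside the inter-rep gap
        j0, j1 = i1, min(n, i1 + int(round(return_dur * fs)))
        velocity[j0:j1] = -return_v
    if noise.mech_sd_nm > 0:
        torque = np.clip(torque + rng.normal(0.0, noise.mech_sd_nm, n), 0.0, None)
    if noise.velocity_sd > 0:
        velocity = velocity + rng.normal(0.0, noise.velocity_sd, n)
    position = np.cumsum(velocity) / fs
    return MechChannels(fs=fs, torque=torque, velocity=velocity, position=position)


def _synth_emg_burst(n: int, fs: float, fc: float, band_sd: float,
                     rms: float, rng) -> np.ndarray:
    """Band-limited Gaussian noise with a symmetric spectrum centred at fc.

    White noise is shaped in the frequency domain by a Gaussian band
    (equivalent to band-pass filtering), which makes the expected median
    frequency equal to the centre frequency by symmetry.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.exp(-0.5 * ((freqs - fc) / band_sd) ** 2)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    r = np.sqrt(np.mean(x**2))
    return x * (rms / r) if r > 0 else x


def _emg_channels(proto, rep_starts, mdf_targets, gains, intensity,
                  total_s, rng, noise, model):
    fs = proto.fs_emg
    n = int(round(total_s * fs))
    dur = proto.rep_duration_s
    base_rms = model.emg_amp_mv * intensity / 100.0
    chans = {}
    for name in ("vlat", "vmed", "rfem"):
        x = (rng.normal(0.0, noise.emg_floor_mv, n) if noise.emg_floor_mv > 0
             else np.zeros(n))
        for t0, fc, g in zip(rep_starts, mdf_targets, gains):
            i0 = int(round(t0 * fs))
            i1 = min(n, int(round((t0 + dur) * fs)))
            x[i0:i1] += _synth_emg_burst(i1 - i0, fs, fc, model.mdf_band_sd_hz,
                                         base_rms * g, rng)
        chans[name] = x
    return EMGChannels(fs=fs, **chans)


def _piecewise_response(grid, work_windows, rise, decay, y0):
    """Sequential rise-during-work / decay-during-rest trajectory on a grid.

    ``rise(t_rel, y_start)`` and ``decay(t_rel, y_start)`` give closed-form
    values within a segment given its entry value.
    """
    y = np.empty_like(grid)
    boundaries = []
    for (a, b) in work_windows:
        boundaries.append((a, b))
    cur = 0
    y_val = y0
    t_prev = grid[0]
    segments = []
    t_cursor = grid[0]
    for (a, b) in boundaries:
        if a > t_cursor:
            segments.append((t_cursor, a, "rest"))
        segments.append((a, b, "work"))
        t_cursor = b
    if t_cursor < grid[-1]:
        segments.append((t_cursor, grid[-1] + 1e-9, "rest"))
    for (a, b, kind) in segments:
        mask = (grid >= a) & (grid < b)
        if not mask.any():
            continue
        t_rel = grid[mask] - a
        y[mask] = rise(t_rel, y_val) if kind == "work" else decay(t_rel, y_val)
        # entry value of the next segment = closed form at the boundary
        y_val = (rise(np.array([b - a]), y_val) if kind == "work"
                 else decay(np.array([b - a]), y_val))[0]
    return y


def _set_windows(proto, rep_starts):
    """(start, end) of each set, treating inter-rep gaps as work time."""
    out = []
    per = proto.reps_per_set
    for s in range(proto.n_sets):
        first = rep_starts[s * per]
        last = rep_starts[s * per + per - 1] + proto.rep_duration_s
        out.append((float(first), float(last)))
    return out


def generate_session(
    participant: ParticipantTruth,
    proto: ProtocolSpec,
    seed: int,
    noise: NoiseConfig | None = None,
    model: ResponseModel | None = None,
    channels: tuple[str, ...] = ALL_CHANNELS,
) -> SessionRecording:
    """Simulate one session; deterministic for fixed (participant, protocol, seed).

    One integer seed fans out to per-channel substreams in the fixed order
    (mech, emg, hr, vo2, nirs, lactate, rpe), so restricting ``channels``
    to a subset never perturbs the channels that are generated.
    """
    noise = noise if noise is not None else NoiseConfig()
    model = model if model is not None else ResponseModel()
    bad = set(channels) - set(ALL_CHANNELS)
    if bad:
        raise ParameterError(f"unknown channels: {sorted(bad)}")
    if proto.rep_duration_s * proto.fs_mech < 8:
        raise SamplingError("fs_mech too low to represent the repetition profile")

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(len(ALL_CHANNELS))]
    rng_by = dict(zip(ALL_CHANNELS, streams))

    I = proto.relative_intensity
    rep_starts, rep_series, total_s = _rep_timeline(proto)
    n_reps = proto.n_reps
    dur = proto.rep_duration_s

    # --- mechanical ground truth -------------------------------------------
    rng_m = rng_by["mech"]
    eps_t = rng_m.normal(0.0, noise.torque_peak_rel_sd, n_reps) if noise.torque_peak_rel_sd > 0 else np.zeros(n_reps)
    eps_r = rng_m.normal(0.0, noise.rfd_rel_sd, n_reps) if noise.rfd_rel_sd > 0 else np.zeros(n_reps)
    peaks = I / 100.0 * participant.mvc * (1.0 + eps_t)
    rfd0 = participant.rfd_base * I / 100.0
    slope = rfd_slope_law(I, participant.fatigue_gain, participant.fatigue_alpha)
    rfd_targets = (rfd0 + slope * np.arange(n_reps)) * (1.0 + eps_r)
    rfd_targets = np.maximum(rfd_targets, 0.2 * rfd0)
    ramps = np.pi * peaks / (2.0 * rfd_targets)
    t_down = min(0.05, 0.2 * dur)
    ramps = np.clip(ramps, 3.0 / proto.fs_mech, 0.9 * (dur - t_down))
    rfd_actual = np.pi * peaks / (2.0 * ramps)
    # closed-form per-rep metrics of the raised-cosine / plateau profile.
    # The RFD0-100 truth is the secant from the 2.5%-of-peak crossing (the
    # onset any threshold detector sees on a raised cosine), not from the
    # mathematical ramp start where the slope is zero.
    onset_frac = 0.025
    t_on = ramps / np.pi * np.arccos(1.0 - 2.0 * onset_frac)
    t_end100 = t_on + 0.1
    torque_at_end = np.where(
        t_end100 < ramps,
        0.5 * peaks * (1.0 - np.cos(np.pi * t_end100 / ramps)),
        peaks)
    rfd_0_100 = (torque_at_end - onset_frac * peaks) / 0.1
    impulse = peaks * (dur - ramps / 2.0 - t_down / 2.0)
    work = proto.angular_velocity * impulse

    mdf_slope = model.mdf_slope_base + model.mdf_slope_per_intensity * I
    mdf_targets = model.mdf0_hz - mdf_slope * np.arange(n_reps)
    gains = 1.0 + model.rms_drift_per_rep * np.arange(n_reps)

    truth = SessionTruth(
        n_reps=n_reps, rep_start_s=rep_starts, rep_dur_s=np.full(n_reps, dur),
        rep_series=rep_series, peak_torque=peaks, ramp_s=ramps,
        rfd_peak=rfd_actual, rfd_0_100=rfd_0_100, impulse=impulse, work=work,
        rfd_slope=slope, mdf_hz=mdf_targets, emg_gain=gains,
    )

    mech = (_mech_channels(proto, rep_starts, peaks, ramps, total_s, rng_m, noise)
            if "mech" in channels else None)
    emg = (_emg_channels(proto, rep_starts, mdf_targets, gains, I, total_s,
                         rng_by["emg"], noise, model)
           if "emg" in channels else None)

    work_windows = _set_windows(proto, rep_starts)
    ex_start = work_windows[0][0]
    ex_end = work_windows[-1][1]

    # --- heart rate ---------------------------------------------------------
    rr = None
    if "hr" in channels:
        rng_h = rng_by["hr"]
        hr_target = participant.hr_rest + model.hr_delta0 + model.hr_delta_per_intensity * I
        c_rec = participant.hr_rest + model.hr_recovery_floor_bpm
        tau_on = model.hr_on_tau_s
        a_hr = participant.hr_alpha

        def hr_rise(t_rel, y0):
            return hr_target + (y0 - hr_target) * np.exp(-t_rel / tau_on)

        def hr_decay(t_rel, y0):
            # the recovery floor sits slightly above rest; below it (the
            # pre-exercise baseline) heart rate simply stays put
            c_eff = c_rec if y0 > c_rec else y0
            return c_eff + (y0 - c_eff) * np.exp(a_hr * t_rel)

        grid = np.arange(0.0, total_s, 0.25)
        hr_true = _piecewise_response(grid, work_windows, hr_rise, hr_decay,
                                      participant.hr_rest)
        hr_end = float(np.interp(ex_end, grid, hr_true))
        truth.hr_recovery = {"b": hr_end - c_rec, "alpha": a_hr, "c": c_rec,
                             "t_start": ex_end, "t_end": total_s}
        beats = []
        t = 0.0
        while t < total_s:
            # an R-R interval ends at the beat: 60/rr equals the HR there,
            # so solve rr = 60 / hr(t + rr) by one fixed-point sweep
            step = 60.0 / float(np.interp(t, grid, hr_true))
            step = 60.0 / float(np.interp(t + step, grid, hr_true))
            if noise.rr_jitter_s > 0:
                step = max(0.2, step + rng_h.normal(0.0, noise.rr_jitter_s))
            beats.append(step)
            t += step
        rr = np.asarray(beats)

    # --- oxygen uptake ------------------------------------------------------
    vo2 = None
    if "vo2" in channels:
        rng_v = rng_by["vo2"]
        v_slope = model.vo2_slope0 + model.vo2_slope_per_intensity * I
        a_v = participant.vo2_alpha
        v_rest = participant.vo2_rest

        def v_rise(t_rel, y0):
            return np.minimum(y0 + v_slope * t_rel, model.vo2_cap)

        def v_decay(t_rel, y0):
            return v_rest + (y0 - v_rest) * np.exp(a_v * t_rel)

        grid = np.arange(0.0, total_s, 0.25)
        v_true = _piecewise_response(grid, work_windows, v_rise, v_decay, v_rest)
        v_end = float(np.interp(ex_end, grid, v_true))
        truth.vo2_recovery = {"b": v_end - v_rest, "alpha": a_v, "c": v_rest,
                              "t_start": ex_end, "t_end": total_s}
        truth.vo2_ex_slope = v_slope
        net = np.clip(v_true - v_rest, 0.0, None) / 60.0  # mL per second
        ex_mask = (grid >= ex_start) & (grid <= ex_end)
        truth.ee_exercise_kj = float(np.trapezoid(net[ex_mask], grid[ex_mask]) * 21.3 / 1000.0)
        full_mask = grid >= ex_start
        truth.ee_total_kj = float(np.trapezoid(net[full_mask], grid[full_mask]) * 21.3 / 1000.0)
        t_b, vals = [], []
        t = 0.0
        while t < total_s:
            t_b.append(t)
            v = float(np.interp(t, grid, v_true))
            if noise.vo2_breath_sd > 0:
                v += rng_v.normal(0.0, noise.vo2_breath_sd)
            vals.append(max(v, 0.0))
            # breathing frequency rises with uptake (~12/min at rest)
            f_breath = 12.0 + 12.0 * max(0.0, float(np.interp(t, grid, v_true)) - v_rest) / 1000.0
            step = 60.0 / f_breath
            t += step * rng_v.uniform(0.9, 1.1) if noise.vo2_breath_sd > 0 else step
        vo2 = SampledSeries(t=np.asarray(t_b), values=np.asarray(vals))

    # --- NIRS ----------------------------------------------------------------
    nirs = None
    if "nirs" in channels:
        rng_n = rng_by["nirs"]
        rate = model.hbdiff_rate0 + model.hbdiff_rate_per_intensity * I
        tau_reb = model.hbdiff_rebound_tau_s
        rep_windows = [(float(t0), float(t0 + dur)) for t0 in rep_starts]

        def hb_fall(t_rel, y0):
            return y0 + rate * t_rel

        def hb_rebound(t_rel, y0):
            return y0 * np.exp(-t_rel / tau_reb)

        grid = np.arange(0.0, total_s, 0.1)
        hb = _piecewise_response(grid, rep_windows, hb_fall, hb_rebound, 0.0)
        truth.hbdiff_rate = rate
        m = grid.size
        noise_hb = (rng_n.normal(0.0, noise.nirs_sd_um, (2, m))
                    if noise.nirs_sd_um > 0 else np.zeros((2, m)))
        do2hb = 0.5 * hb + noise_hb[0]
        dhhb = -0.5 * hb + noise_hb[1]
        tsi = model.tsi_base + 0.5 * hb
        if noise.tsi_sd > 0:
            tsi = tsi + rng_n.normal(0.0, noise.tsi_sd, m)
        nirs = NIRSChannels(t=grid, do2hb=do2hb, dhhb=dhhb, tsi=tsi)

    # --- lactate -------------------------------------------------------------
    lactate = None
    if "lactate" in channels:
        rng_l = rng_by["lactate"]
        R = proto.total_rest_s
        delta1 = (model.lact_c_reps * n_reps + model.lact_c_intensity * I
                  + model.lact_c_rest / (1.0 + R / 60.0))
        delta1 = max(delta1, 0.0)
        onset = participant.lact_base + model.lact_onset_bump
        truth.lactate = {"baseline": participant.lact_base, "onset": onset,
                         "delta_1min": delta1,
                         "delta_3min": model.lact_post3_frac * delta1}
        jit = (rng_l.normal(0.0, noise.lactate_sd, 4) if noise.lactate_sd > 0
               else np.zeros(4))
        lactate = {
            "t_baseline": max(0.2, participant.lact_base + jit[0]),
            "t_onset": max(0.2, onset + jit[1]),
            "t_post1": max(0.2, onset + delta1 + jit[2]),
            "t_post3": max(0.2, onset + model.lact_post3_frac * delta1 + jit[3]),
        }

    # --- perceived exertion --------------------------------------------------
    rpe = cr10 = None
    if "rpe" in channels:
        rng_r = rng_by["rpe"]
        effort = (model.rpe_base + model.rpe_w_intensity * I / 100.0
                  + model.rpe_w_volume * n_reps / 24.0)
        rpe_f = 6.0 + 14.0 * min(effort, 1.0)
        truth.rpe = rpe_f
        truth.cr10 = (rpe_f - 6.0) * 10.0 / 14.0
        jitter = int(rng_r.integers(-noise.rpe_jitter, noise.rpe_jitter + 1)) if noise.rpe_jitter > 0 else 0
        rpe = float(np.clip(round(rpe_f) + jitter, 6, 20))
        cr10 = float(np.clip(round((rpe - 6.0) * 10.0 / 14.0), 0, 10))

    events = {
        "baseline_s": proto.baseline_s,
        "exercise_start_s": float(ex_start),
        "exercise_end_s": float(ex_end),
        "set_windows": [[float(a), float(b)] for (a, b) in work_windows],
        "recovery_window": [float(ex_end), float(total_s)],
        "total_rest_s": proto.total_rest_s,
    }
    return SessionRecording(
        participant=participant.id, protocol=proto, mech=mech, emg=emg,
        rr_intervals=rr, vo2=vo2, nirs=nirs, lactate=lactate,
        rpe=rpe, cr10=cr10, session_duration_s=float(total_s),
        events=events, truth=truth,
    )
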