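"""Torque-velocity profiling and volume-equated session prescription.

The torque-velocity (T-V) profile of a muscle group maps angular velocity
to the peak torque attainable at that velocity. Its intercept at zero
velocity is the theoretical maximal voluntary contraction torque (MVC),
the reference for all relative intensities. The Reynolds non-linear
equation maps a theoretical repetition maximum (RM) to a relative
intensity in %MVC, which lets sessions at different intensities be
volume-equated (equal reps x intensity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import DataError, ParameterError
from .signals import linear_slope

__all__ = [
    "TVProfile",
    "Prescription",
    "REYNOLDS_GAIN",
    "REYNOLDS_RATE",
    "REYNOLDS_ASYMPTOTE",
    "fit_tv_profile",
    "reynolds_intensity",
    "reynolds_rm",
    "prescribe_volume_equated",
]

# Reynolds et al. RM -> %MVC mapping: y = 55.51 exp(-0.0723 x) + 48.47
REYNOLDS_GAIN = 55.51
REYNOLDS_RATE = 0.0723
REYNOLDS_ASYMPTOTE = 48.47


@dataclass
class TVProfile:
    """A fitted torque-velocity profile.

    ``shape`` is ``linear`` (T(v) = T0 (1 - v/v0)) or ``hyperbolic``
    (Hill form (T + a)(v + b) = b (T0 + a)). ``mvc`` is the predicted
    torque at zero velocity.
    """

    shape: str
    params: dict
    mvc: float
    fit_r2: float
    points: np.ndarray  # (n, 2) velocity, torque pairs used
    monotone: bool = True

    def predict(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.shape == "linear":
            return self.params["T0"] * (1.0 - v / self.params["v0"])
        a, b, t0 = self.params["a"], self.params["b"], self.params["T0"]
        return b * (t0 + a) / (v + b) - a


@dataclass
class Prescription:
    sessions: list[dict] = field(default_factory=list)
    vl_target: float = 0.0


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def fit_tv_profile(points: np.ndarray, shape: str = "linear") -> TVProfile:
    """Fit a T-V profile to (velocity, peak torque) pairs.

    Least squares; the torque value per velocity should be the best (peak)
    torque across the repetitions performed at that velocity. A fit that is
    not non-increasing in velocity over the sampled range is flagged via
    ``monotone=False`` rather than rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array of (velocity, torque)")
    v, t = pts[:, 0], pts[:, 1]
    if np.unique(v).size != v.size:
        raise DataError("velocities must be distinct")
    if shape == "linear":
        if v.size < 3:
            raise ParameterError("linear profile needs at least 3 points")
        fit = linear_slope(v, t)
        t0 = fit.intercept
        if fit.slope >= 0 or t0 <= 0:
            raise DataError("torque must decrease with velocity with positive MVC")
        v0 = -t0 / fit.slope
        params = {"T0": t0, "v0": v0}
        pred = t0 * (1.0 - v / v0)
    elif shape == "hyperbolic":
        if v.size < 4:
            raise ParameterError("hyperbolic profile needs at least 4 points")
        t_max = t.max()

        def model(vv, a, b, t0):
            return b * (t0 + a) / (vv + b) - a

        p0 = (0.3 * t_max, 0.3 * (v.max() - v.min() + 1.0), t_max)
        popt, _ = optimize.curve_fit(
            model, v, t, p0=p0, maxfev=20000,
            bounds=([1e-6, 1e-6, 1e-6], [np.inf, np.inf, np.inf]),
        )
        a, b, t0 = (float(p) for p in popt)
        params = {"a": a, "b": b, "T0": t0}
        pred = model(v, a, b, t0)
    else:
        raise ParameterError(f"unknown profile shape {shape!r}")

    prof = TVProfile(shape=shape, params=params, mvc=float(params["T0"]),
                     fit_r2=_r2(t, pred), points=pts)
    grid = np.linspace(v.min(), v.max(), 200)
    prof.monotone = bool(np.all(np.diff(prof.predict(grid)) <= 1e-9))
    return prof


def reynolds_intensity(rm: float) -> float:
    """Relative intensity (%MVC) for a theoretical repetition maximum."""
    if rm <= 0:
        raise ParameterError("repetition maximum must be positive")
    return REYNOLDS_GAIN * math.exp(-REYNOLDS_RATE * rm) + REYNOLDS_ASYMPTOTE


def reynolds_rm(intensity: float) -> float:
    """Theoretical repetition maximum for a relative intensity (%MVC).

    Analytic inverse of :func:`reynolds_intensity`; the intensity must lie
    strictly between the asymptote (48.47) and the zero-RM limit (103.98).
    """
    lo = REYNOLDS_ASYMPTOTE
    hi = REYNOLDS_ASYMPTOTE + REYNOLDS_GAIN
    if not lo < intensity < hi:
        raise ParameterError(f"intensity must lie in ({lo}, {hi})")
    return -math.log((intensity - REYNOLDS_ASYMPTOTE) / REYNOLDS_GAIN) / REYNOLDS_RATE


def prescribe_volume_equated(
    mvc: float,
    intensities: list[float],
    reference: dict | None = None,
    rest_s: dict | float | None = None,
) -> Prescription:
    """Volume-equate sessions across intensities (the VL method).

    The reference session (default 24 reps at its Reynolds intensity for
    24 RM) fixes the volume-load target reps x %MVC; at every other
    intensity the repetition count is the rounded target / intensity, split
    into sets no larger than the theoretical RM at that intensity.
    """
    if mvc <= 0:
        raise ParameterError("mvc must be positive")
    if reference is None:
        reference = {"reps": 24, "intensity": reynolds_intensity(24)}
    ref_i = float(reference["intensity"])
    if ref_i <= 0:
        raise ParameterError("reference intensity must be positive")
    vl_target = reference["reps"] * ref_i
    sessions = []
    for inten in intensities:
        if inten <= 0:
            raise ParameterError("intensity must be positive")
        reps = int(round(vl_target / inten))
        rm = reynolds_rm(inten)
        cap = max(1, int(math.floor(rm + 1e-9)))
        n_sets = int(math.ceil(reps / cap))
        per_set = int(math.ceil(reps / n_sets))
        if isinstance(rest_s, dict):
            rest = rest_s.get(round(inten), rest_s.get(inten, 180.0))
        else:
            rest = 0.0 if n_sets == 1 else (rest_s if rest_s is not None else 180.0)
        sessions.append({
            "label": f"{inten:g}%MVC",
            "intensity": float(inten),
            "theoretical_rm": rm,
            "n_sets": n_sets,
            "reps_per_set": per_set,
            "rest_s": float(rest),
            "torque_target": mvc * inten / 100.0,
        })
    return Prescription(sessions=sessions, vl_target=vl_target)
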