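"""Training-load (TL) indexes for resistance-exercise sessions.

Covers the conventional objective index (volume load, VL = reps x %MVC),
the subjective session-RPE family, and the fatigue-weighted TL_RFD family

    TL_RFD   = V * I * exp(-alpha * I)
    TL_RFD,d = TL_RFD / R
    TL_RFD*  = (sum of repetition torque impulses) * exp(-alpha * I)

where V is the repetition count, I the relative intensity in %MVC, R the
total inter-set recovery time in seconds, and alpha (< 0) the rate constant
of the mono-exponential law relating the per-repetition decay of peak RFD
to exercise intensity. With alpha negative the weight exp(-alpha * I)
grows with intensity, so sessions that impair neuromuscular function
faster are credited with a larger load than volume load alone implies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, ParameterError
from .signals import MonoExpFit, fit_monoexp

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHA",
    "TLRecord",
    "AlphaCalibration",
    "volume_load",
    "tl_rfd",
    "tl_rfd_density",
    "tl_rfd_star",
    "calibrate_alpha",
    "rpe_indexes",
]

#: Published rate constant of the RFD-decay-vs-intensity law (1/%MVC).
DEFAULT_ALPHA = -0.071


@dataclass
class TLRecord:
    """All training-load indexes for one session.

    Density fields are ``None`` (missing), not zero, for single-set
    sessions where the total inter-set rest R is zero.
    """

    vl: float
    dens_vl: float | None
    wmech: float | None
    rpe: float | None
    cr10: float | None
    srpe: float | None
    srpe_cr10: float | None
    dens_rpe: float | None
    dens_rpe_cr10: float | None
    tl_rfd: float
    tl_rfd_dens: float | None
    tl_rfd_star: float | None
    alpha: float = DEFAULT_ALPHA
    alpha_source: str = "paper_default"


@dataclass
class AlphaCalibration:
    """Fitted fatigue rate constant alpha (1/%MVC) with its provenance."""

    alpha: float
    fit: MonoExpFit | None
    source: str  # "fitted" or "paper_default"


def volume_load(reps_by_set: list[int], intensity: float,
                total_rest_s: float = 0.0) -> tuple[float, float | None]:
    """Volume load (reps x %MVC) and its density per second of rest."""
    if intensity <= 0:
        raise ParameterError("intensity must be positive")
    reps = np.asarray(reps_by_set, dtype=float)
    if np.any(reps < 0):
        raise ParameterError("repetition counts must be nonnegative")
    vl = float(reps.sum() * intensity)
    dens = vl / total_rest_s if total_rest_s > 0 else None
    return vl, dens


def tl_rfd(v: float, i: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Fatigue-weighted load V * I * exp(-alpha * I).

    At alpha = 0 this reduces exactly to the volume load V * I.
    """
    if v < 0:
        raise ParameterError("repetition count must be nonnegative")
    if i <= 0:
        raise ParameterError("intensity must be positive")
    return v * i * math.exp(-alpha * i)


def tl_rfd_density(tl: float, total_rest_s: float) -> float | None:
    """TL_RFD per second of inter-set recovery; missing when R <= 0."""
    if total_rest_s <= 0:
        logger.warning("no inter-set rest: TL_RFD density undefined")
        return None
    return tl / total_rest_s


def tl_rfd_star(rep_impulses: list[float], i: float,
                alpha: float = DEFAULT_ALPHA) -> float:
    """Impulse-based variant: total torque impulse times the fatigue weight."""
    if i <= 0:
        raise ParameterError("intensity must be positive")
    imp = np.asarray(rep_impulses, dtype=float)
    if imp.size == 0:
        logger.warning("empty impulse list: TL_RFD* is 0")
        return 0.0
    if np.any(imp < 0):
        raise DataError("repetition impulses must be nonnegative")
    return float(imp.sum() * math.exp(-alpha * i))


def calibrate_alpha(
    slopes: list[float],
    intensities: list[float],
    fix_asymptote_zero: bool = True,
) -> AlphaCalibration:
    """Fit the fatigue rate constant from RFD decay slopes vs intensity.

    ``slopes`` are the mean per-repetition rate decays of peak RFD
    (negative, in N.m.s^-1 per repetition) observed at each relative
    intensity. The model is slope(I) = b * exp(-alpha * I) (+ c when
    ``fix_asymptote_zero`` is False); with three intensities the asymptote
    is fixed at zero by default because three points cannot identify three
    parameters robustly. Falls back to the published default alpha when
    the fit does not converge.
    """
    s = np.asarray(slopes, dtype=float)
    i = np.asarray(intensities, dtype=float)
    if s.size != i.size or s.size < 3:
        logger.warning("alpha calibration needs >= 3 points; using default")
        return AlphaCalibration(alpha=DEFAULT_ALPHA, fit=None,
                                source="paper_default")
    fit = fit_monoexp(i, s, fix_c=fix_asymptote_zero)
    if not fit.converged or not np.isfinite(fit.alpha):
        logger.warning("alpha calibration did not converge; using default")
        return AlphaCalibration(alpha=DEFAULT_ALPHA, fit=fit,
                                source="paper_default")
    # fit model is b*exp(rate*I); the TL_RFD convention is b*exp(-alpha*I)
    return AlphaCalibration(alpha=-float(fit.alpha), fit=fit, source="fitted")


def rpe_indexes(
    rpe: float | None,
    cr10: float | None,
    duration_min: float,
    reps: int,
    total_rest_s: float,
) -> dict:
    """Session-RPE family: rating x duration, and rating x reps per rest second.

    The duration basis is the full session duration in minutes; density
    variants are missing (None) for single-set sessions without inter-set
    rest.
    """
    if rpe is not None and not 6 <= rpe <= 20:
        raise ParameterError("Borg RPE must lie in [6, 20]")
    if cr10 is not None and not 0 <= cr10 <= 10:
        raise ParameterError("CR10 must lie in [0, 10]")
    if duration_min < 0 or reps < 0:
        raise ParameterError("duration and reps must be nonnegative")
    out = {
        "srpe": None if rpe is None else rpe * duration_min,
        "srpe_cr10": None if cr10 is None else cr10 * duration_min,
        "dens_rpe": None,
        "dens_rpe_cr10": None,
    }
    if total_rest_s > 0:
        if rpe is not None:
            out["dens_rpe"] = rpe * reps / total_rest_s
        if cr10 is not None:
            out["dens_rpe_cr10"] = cr10 * reps / total_rest_s
    return out
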