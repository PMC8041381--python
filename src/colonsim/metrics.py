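"""Scalar exposure metrics from concentration–time profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ExposureSummary:
    auc_0t: float   # μg·h/mL
    cmax: float     # μg/mL
    tmax: float     # h
    t_last: float   # h

    def __post_init__(self) -> None:
        if self.auc_0t < 0:
            raise ValueError("auc_0t must be >= 0")
        if self.tmax > self.t_last:
            raise ValueError("tmax cannot exceed t_last")


def _validate_profile(times, concentrations) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0:
        raise ValueError("empty profile")
    if t.size != c.size:
        raise ValueError("times and concentrations differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    return t, c


def auc_0_t(times, concentrations, t_last: float | None = None) -> float:
    """Linear trapezoidal AUC from time zero to ``t_last``, μg·h/mL.

    ``t_last`` defaults to the final sample; a value inside the sampled range
    cuts the profile there (with linear interpolation of the boundary
    concentration), beyond it is an error.  A single sample gives 0.
    """
    t, c = _validate_profile(times, concentrations)
    if t_last is None:
        t_last = float(t[-1])
    if t_last > t[-1] + 1e-12:
        raise ValueError(f"t_last={t_last} beyond last sampled time {t[-1]}")
    if t.size == 1:
        return 0.0
    mask = t <= t_last
    tt, cc = t[mask], c[mask]
    if tt[-1] < t_last:
        tt = np.append(tt, t_last)
        cc = np.append(cc, np.interp(t_last, t, c))
    lo = max(0.0, float(tt[0]))
    if tt[0] < 0.0:
        cc = cc[tt >= 0.0]
        tt = tt[tt >= 0.0]
    if tt.size < 2:
        return 0.0
    return float(np.trapezoid(cc, tt)) if lo <= t_last else 0.0


def resample_profile(times, concentrations, schedule) -> np.ndarray:
    """Linear interpolation of a simulated profile onto an observed schedule."""
    t, c = _validate_profile(times, concentrations)
    return np.interp(np.asarray(schedule, dtype=float), t, c)


def cmax_tmax(times, concentrations) -> tuple[float, float]:
    """Peak concentration and its earliest occurrence time."""
    t, c = _validate_profile(times, concentrations)
    i = int(np.argmax(c))   # argmax returns the first maximum
    return float(c[i]), float(t[i])


def exposure_summary(times, concentrations, t_last: float | None = None) -> ExposureSummary:
    t, _ = _validate_profile(times, concentrations)
    cmax, tmax = cmax_tmax(times, concentrations)
    t_last = float(t[-1]) if t_last is None else t_last
    return ExposureSummary(
        auc_0t=auc_0_t(times, concentrations, t_last),
        cmax=cmax, tmax=tmax, t_last=t_last,
    )


def relative_bioavailability(
    auc_test: float, dose_test: float, auc_ref: float, dose_ref: float
) -> float:
    """Dose-normalized relative bioavailability (AUC/dose) / (AUC_ref/dose_ref).

    At equal doses this reduces to the plain AUC ratio.
    """
    if auc_ref <= 0:
        raise ValueError("reference AUC must be > 0")
    if dose_test <= 0 or dose_ref <= 0:
        raise ValueError("doses must be > 0")
    return (auc_test / dose_test) / (auc_ref / dose_ref)
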