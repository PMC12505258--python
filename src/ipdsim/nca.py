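"""Noncompartmental analysis of plasma profiles and prediction-error scoring.

Cmax/Tmax come from the observed maximum (earliest time on ties), AUC0-t
from the trapezoid (linear on rising segments, log-linear on declining
ones — exact for exponential decline on sparse late sampling grids; a
plain linear rule is exposed), the terminal rate constant lambda_z from a
log-linear regression on the last positive concentrations, and
AUC0-inf = AUC0-t + Clast / lambda_z.

Prediction error against an observed metric is PE = 100 (pred - obs) / obs,
and the fold error is pred / obs, so PE = 100 (fold - 1) identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gi_pbpk import PlasmaProfile

__all__ = [
    "NcaInputError",
    "PkMetrics",
    "compute_nca",
    "prediction_error",
    "fold_error",
]


class NcaInputError(ValueError):
    """The profile cannot support the requested NCA computation."""


@dataclass(frozen=True)
class PkMetrics:
    """Noncompartmental summary of one plasma profile.

    ``auc0inf``, ``lambda_z`` and ``extrap_pct`` are NaN when the terminal
    phase does not decline (non-positive lambda_z); the reason is recorded
    in ``warnings``.
    """

    cmax: float           # ng/mL
    tmax: float           # h
    auc0t: float          # ng*h/mL
    auc0inf: float        # ng*h/mL, NaN if undefined
    lambda_z: float       # 1/h, NaN if undefined
    extrap_pct: float     # % of AUC0-inf extrapolated, NaN if undefined
    warnings: tuple[str, ...] = ()


def _auc_trapezoid(t: np.ndarray, c: np.ndarray, method: str) -> float:
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method == "linear-up-log-down":
        auc = 0.0
        for i in range(len(t) - 1):
            dt = t[i + 1] - t[i]
            c1, c2 = c[i], c[i + 1]
            if c2 < c1 and c1 > 0 and c2 > 0:
                auc += dt * (c1 - c2) / math.log(c1 / c2)
            else:
                auc += dt * (c1 + c2) / 2.0
        return auc
    raise ValueError(f"unknown AUC method {method!r}")


def compute_nca(
    profile: PlasmaProfile,
    n_terminal_points: int = 3,
    auc_method: str = "linear-up-log-down",
) -> PkMetrics:
    """Noncompartmental metrics for one concentration-time profile.

    Parameters
    ----------
    n_terminal_points : int
        Number of trailing positive concentrations used in the log-linear
        lambda_z regression (>= 3).
    auc_method : {"linear-up-log-down", "linear"}
        Trapezoid rule for AUC0-t.  The default uses the log rule on
        declining segments, which is exact for exponential decline.
    """
    if n_terminal_points < 3:
        raise NcaInputError("n_terminal_points must be >= 3")
    t = profile.times_h
    c = profile.conc_ng_ml
    pos = np.flatnonzero(c > 0)
    if pos.size < 3:
        raise NcaInputError("need at least 3 positive concentrations")

    i_max = int(np.argmax(c))     # argmax returns the earliest tie
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc0t = _auc_trapezoid(t, c, auc_method)

    warns: list[str] = []
    tail = pos[-n_terminal_points:]
    lam = math.nan
    if tail.size >= 3 and c[tail[0]] > c[tail[-1]]:   # tail must decline
        slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
        if slope < 0:
            lam = float(-slope)
    if math.isnan(lam):
        warns.append(
            "terminal phase does not decline; lambda_z and AUC0-inf undefined"
        )
        auc0inf = math.nan
        extrap = math.nan
    else:
        clast = float(c[pos[-1]])
        auc0inf = auc0t + clast / lam
        extrap = 100.0 * (clast / lam) / auc0inf

    return PkMetrics(
        cmax=cmax, tmax=tmax, auc0t=auc0t, auc0inf=auc0inf,
        lambda_z=lam, extrap_pct=extrap, warnings=tuple(warns),
    )


def prediction_error(predicted: float, observed: float) -> float:
    """Percent prediction error 100 (predicted - observed) / observed."""
    if not observed > 0:
        raise NcaInputError(f"observed metric must be > 0, got {observed}")
    return 100.0 * (predicted - observed) / observed


def fold_error(predicted: float, observed: float) -> float:
    """Fold error predicted / observed."""
    if not observed > 0:
        raise NcaInputError(f"observed metric must be > 0, got {observed}")
    return predicted / observed
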