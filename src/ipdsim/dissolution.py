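"""Biopharmaceutic calculators and the constrained Weibull dissolution model.

For a poorly permeable drug, luminal sink conditions are lost as soon as the
dose cannot fully dissolve in the small gastrointestinal fluid volume.  Two
dimensionless screens quantify this: the Dose number

    Do = (D / V0) / S

(dose over ingestion volume, relative to aqueous solubility; Do > 1 flags
incomplete dissolution in a 250 mL glass of water), and the solubility-capped
maximum release

    Wmax = min(100, S * V * 100 / D)   [% of dose]

which is the plateau a dissolution profile can reach in a vessel of volume V.

Release kinetics are described by the empirical Weibull curve

    W(t) = Wmax * (1 - exp(-(t - tlag)^beta / alpha)),   t > tlag

which collapses to the first-order model when beta = 1 and tlag = 0.  Fitting
holds Wmax (from the cap above) and tlag fixed and estimates only alpha and
beta by least squares, which keeps the model from overfitting sparse profiles.

Note on parameterization: the scale enters as exp(-(t-tlag)^beta / alpha),
so alpha carries units of min^beta.  The common alternative
exp(-((t-tlag)/alpha')^beta) maps onto it by alpha = alpha'^beta; the fitted
curves are identical, only the reported scale value differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "InvalidParameterError",
    "FitConvergenceError",
    "SolubilityContext",
    "MediumSpec",
    "DissolutionProfile",
    "WeibullParams",
    "WeibullFit",
    "compute_wmax",
    "compute_dose_number",
    "volume_to_dissolve",
    "weibull_pct",
    "fit_weibull",
]


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class FitConvergenceError(RuntimeError):
    """The dissolution fit cannot converge (e.g. an all-zero profile)."""


@dataclass(frozen=True)
class SolubilityContext:
    """Solubility/dose/volume bundle for the biopharmaceutic calculators.

    Parameters
    ----------
    s : float
        Drug solubility in the dissolution medium, mg/mL at 37 degC.
    d : float
        Dose strength, mg.
    v : float
        Dissolution medium volume, mL.
    s_min : float
        Lowest biorelevant solubility, mg/mL.  Default 2.33 (pH 5.8).
    v0 : float
        Reference ingestion volume, mL.  Default 250 (a glass of water).
    """

    s: float
    d: float
    v: float
    s_min: float = 2.33
    v0: float = 250.0

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise InvalidParameterError(f"solubility must be > 0, got {self.s}")
        if not self.s_min > 0:
            raise InvalidParameterError(f"s_min must be > 0, got {self.s_min}")
        if self.d < 0:
            raise InvalidParameterError(f"dose must be >= 0, got {self.d}")
        if not self.v > 0:
            raise InvalidParameterError(f"volume must be > 0, got {self.v}")
        if not self.v0 > 0:
            raise InvalidParameterError(f"v0 must be > 0, got {self.v0}")


def compute_wmax(ctx: SolubilityContext) -> float:
    """Maximum percentage of the dose that can dissolve in the vessel.

    Wmax = S * V * 100 / D, capped at 100% (a profile cannot exceed complete
    release).  A zero dose returns 100 by convention: there is nothing for
    solubility to limit.
    """
    if ctx.d == 0:
        return 100.0
    return min(100.0, ctx.s * ctx.v * 100.0 / ctx.d)


def compute_dose_number(ctx: SolubilityContext) -> float:
    """Dimensionless Dose number Do = (D / V0) / S_min.

    Uses the lowest biorelevant solubility and the reference ingestion
    volume.  Returned at full precision; round only for display.
    """
    return (ctx.d / ctx.v0) / ctx.s_min


def volume_to_dissolve(dose_mg: float, solubility_mg_ml: float) -> float:
    """Volume of medium (mL) needed to dissolve ``dose_mg`` completely: D/S."""
    if not solubility_mg_ml > 0:
        raise InvalidParameterError(
            f"solubility must be > 0, got {solubility_mg_ml}"
        )
    if dose_mg < 0:
        raise InvalidParameterError(f"dose must be >= 0, got {dose_mg}")
    return dose_mg / solubility_mg_ml


@dataclass(frozen=True)
class WeibullParams:
    """Weibull release parameters.

    alpha : time-scale parameter, units min^beta (see module note).
    beta  : shape parameter, dimensionless.
    tlag  : lag time, min.
    wmax  : maximum percentage released, % of dose.
    """

    alpha: float
    beta: float
    tlag: float = 0.0
    wmax: float = 100.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")
        if self.tlag < 0:
            raise InvalidParameterError(f"tlag must be >= 0, got {self.tlag}")
        if not 0 < self.wmax <= 100:
            raise InvalidParameterError(
                f"wmax must be in (0, 100], got {self.wmax}"
            )

    def t63(self) -> float:
        """Time (min) to reach 63.2% of wmax: tlag + alpha^(1/beta)."""
        return self.tlag + self.alpha ** (1.0 / self.beta)


def weibull_pct(t, p: WeibullParams):
    """Percent of dose released at time ``t`` (min) under ``p``.

    Returns 0 for t <= tlag; nondecreasing in t; bounded by ``p.wmax``.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - p.tlag, 0.0)
    with np.errstate(over="ignore"):
        out = p.wmax * -np.expm1(-(dt**p.beta) / p.alpha)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MediumSpec:
    """Dissolution medium/apparatus descriptor."""

    ph: float
    volume_ml: float
    rpm: float
    apparatus: str = "mini-paddle"
    dose_mg: float = 0.0


@dataclass(frozen=True)
class DissolutionProfile:
    """Replicate percent-dissolved curves on a shared time grid.

    times : 1-D array of sampling times in minutes, strictly increasing,
        first point > 0.
    pct_dissolved : array of shape (n_replicates, n_times), % of labeled dose.
    medium : optional medium descriptor.
    """

    times: np.ndarray
    pct_dissolved: np.ndarray
    medium: MediumSpec | None = None

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        pct = np.atleast_2d(np.asarray(self.pct_dissolved, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pct_dissolved", pct)
        if times.ndim != 1 or times.size < 1:
            raise InvalidParameterError("times must be a 1-D array")
        if not times[0] > 0:
            raise InvalidParameterError("first sampling time must be > 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if pct.shape[1] != times.size:
            raise InvalidParameterError(
                f"replicates have {pct.shape[1]} points for {times.size} times"
            )
        if np.any(pct < 0):
            raise InvalidParameterError("percent dissolved must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.pct_dissolved.shape[0]

    def replicate_mean(self) -> np.ndarray:
        return self.pct_dissolved.mean(axis=0)


@dataclass(frozen=True)
class WeibullFit:
    """Result of a constrained Weibull fit."""

    params: WeibullParams
    sse: float
    n_points: int
    warnings: tuple[str, ...] = ()

    @property
    def rmse(self) -> float:
        return math.sqrt(self.sse / self.n_points)


_ALPHA_BOUNDS = (1e-9, 1e6)
_BETA_BOUNDS = (0.1, 10.0)


def _initial_alpha(times: np.ndarray, y: np.ndarray, wmax: float, tlag: float) -> float:
    """Start alpha at the observed time to 63.2% of wmax (with beta = 1)."""
    target = (1.0 - math.exp(-1.0)) * wmax
    if y[-1] >= target:
        t63 = float(np.interp(target, y, times))  # y nondecreasing in the mean
    else:
        t63 = float(times[-1])
    return float(np.clip(t63 - tlag, *_ALPHA_BOUNDS))


def fit_weibull(
    profile: DissolutionProfile,
    wmax_fixed: float,
    tlag_fixed: float = 0.0,
    objective: str = "mean",
) -> WeibullFit:
    """Fit alpha and beta with Wmax and tlag held fixed.

    Parameters
    ----------
    profile : DissolutionProfile
        Observed data; at least 3 distinct time points.
    wmax_fixed : float
        Fixed maximum release (%), normally from :func:`compute_wmax`.
    tlag_fixed : float
        Fixed lag time (min), normally 0 for immediate-release tablets.
    objective : {"mean", "pooled"}
        Least squares on replicate means (default) or on all replicate
        points pooled.

    Observed means exceeding ``wmax_fixed`` are tolerated (experimental
    profiles can overshoot the theoretical cap); a warning is recorded in
    the diagnostics and the fit proceeds.
    """
    if not 0 < wmax_fixed <= 100:
        raise InvalidParameterError(
            f"wmax_fixed must be in (0, 100], got {wmax_fixed}"
        )
    if tlag_fixed < 0:
        raise InvalidParameterError(f"tlag_fixed must be >= 0, got {tlag_fixed}")
    if len(np.unique(profile.times)) < 3:
        raise InvalidParameterError("need at least 3 distinct time points")

    mean = profile.replicate_mean()
    if objective == "mean":
        t_obs, y_obs = profile.times, mean
    elif objective == "pooled":
        t_obs = np.tile(profile.times, profile.n_replicates)
        y_obs = profile.pct_dissolved.ravel()
    else:
        raise ValueError(f"unknown objective {objective!r}")

    if np.all(y_obs == 0):
        raise FitConvergenceError("profile is identically zero; nothing to fit")

    warns: list[str] = []
    if np.any(mean > wmax_fixed):
        warns.append(
            f"observed mean exceeds the fixed Wmax of {wmax_fixed:g}% "
            f"(max observed {mean.max():.2f}%)"
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        p = WeibullParams(alpha=x[0], beta=x[1], tlag=tlag_fixed, wmax=wmax_fixed)
        return weibull_pct(t_obs, p) - y_obs

    x0 = np.array([_initial_alpha(profile.times, mean, wmax_fixed, tlag_fixed), 1.0])
    sol = least_squares(
        residuals,
        x0,
        bounds=([_ALPHA_BOUNDS[0], _BETA_BOUNDS[0]], [_ALPHA_BOUNDS[1], _BETA_BOUNDS[1]]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not sol.success:
        raise FitConvergenceError(f"Weibull fit did not converge: {sol.message}")

    params = WeibullParams(
        alpha=float(sol.x[0]), beta=float(sol.x[1]), tlag=tlag_fixed, wmax=wmax_fixed
    )
    return WeibullFit(
        params=params,
        sse=float(np.sum(sol.fun**2)),
        n_points=int(y_obs.size),
        warnings=tuple(warns),
    )
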