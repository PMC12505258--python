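"""Synthetic inputs: noisy dissolution datasets and virtual "observed"
plasma profiles generated from known ground truth.

No clinical or laboratory dataset ships with the package; everything the
pipeline consumes can be generated here from stated true parameters, which
is what makes fit-recovery and end-to-end tests possible.  Dissolution
replicates are Weibull curves with multiplicative (assay-like, 2% CV
default) and optional additive noise on the standard sampling grid
(5-120 min); plasma "observations" are PBPK simulations with multiplicative
residual error (15% CV default, the scale of bioanalytical plus model
residual noise for a highly variable drug) on the clinical 0-24 h grid.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dissolution import (
    DissolutionProfile,
    InvalidParameterError,
    MediumSpec,
    WeibullParams,
    weibull_pct,
)
from .gi_pbpk import CLINICAL_GRID_H, PbpkModel, SimulationResult, PlasmaProfile, simulate_plasma

__all__ = [
    "DISSOLUTION_GRID_MIN",
    "SyntheticScenario",
    "make_dissolution_dataset",
    "make_observed_plasma",
    "make_product_pair",
]

#: Standard in vitro sampling grid, minutes.
DISSOLUTION_GRID_MIN = np.array([5, 10, 15, 20, 30, 45, 60, 90, 120], dtype=float)


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth and noise model for synthetic datasets.

    ``true_params`` maps product labels to their true Weibull parameters.
    Noise: multiplicative CV% applied per observation (plus optional
    additive SD in % dissolved) for dissolution; multiplicative residual
    CV% for plasma.
    """

    true_params: dict[str, WeibullParams]
    medium: MediumSpec | None = None
    noise_cv_pct: float = 2.0
    additive_sd_pct: float = 0.0
    n_replicates: int = 3
    dissolution_grid_min: np.ndarray = field(
        default_factory=lambda: DISSOLUTION_GRID_MIN.copy()
    )
    plasma_grid_h: np.ndarray = field(default_factory=lambda: CLINICAL_GRID_H.copy())
    plasma_residual_cv_pct: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_cv_pct < 0 or self.additive_sd_pct < 0 \
                or self.plasma_residual_cv_pct < 0:
            raise InvalidParameterError("noise parameters must be >= 0")
        if self.n_replicates < 1:
            raise InvalidParameterError("need at least 1 replicate")
        for grid in (self.dissolution_grid_min, self.plasma_grid_h):
            g = np.asarray(grid, dtype=float)
            if g.size > 1 and not np.all(np.diff(g) > 0):
                raise InvalidParameterError("grids must be strictly increasing")


def make_dissolution_dataset(
    scenario: SyntheticScenario,
    product: str | None = None,
    rng: np.random.Generator | None = None,
) -> DissolutionProfile:
    """Noisy replicate dissolution curves for one product.

    Each replicate is the true Weibull curve times (1 + eps) with
    eps ~ Normal(0, CV), plus optional additive noise, clipped at 0.
    Deterministic under ``scenario.seed``.
    """
    if product is None:
        product = next(iter(scenario.true_params))
    truth = scenario.true_params[product]
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    grid = np.asarray(scenario.dissolution_grid_min, dtype=float)
    curve = np.asarray(weibull_pct(grid, truth), dtype=float)
    shape = (scenario.n_replicates, grid.size)
    pct = curve * (1.0 + rng.normal(0.0, scenario.noise_cv_pct / 100.0, shape))
    if scenario.additive_sd_pct > 0:
        pct = pct + rng.normal(0.0, scenario.additive_sd_pct, shape)
    return DissolutionProfile(
        times=grid, pct_dissolved=np.clip(pct, 0.0, None), medium=scenario.medium
    )


def make_observed_plasma(
    scenario: SyntheticScenario,
    model: PbpkModel,
    dose_mg: float,
    product: str | None = None,
    n_subjects: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[list[PlasmaProfile], SimulationResult]:
    """Virtual "observed" plasma profiles plus the noiseless ground truth.

    Simulates the true release through the PBPK model on the clinical grid
    and overlays per-sample multiplicative residual error.  Returns
    (noisy profiles, noiseless simulation result); the latter carries the
    ground-truth curve and ledger for recovery tests.
    """
    if product is None:
        product = next(iter(scenario.true_params))
    truth = scenario.true_params[product]
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    base = simulate_plasma(
        model, dose_mg, truth,
        horizon_h=float(scenario.plasma_grid_h[-1]),
        grid_h=np.asarray(scenario.plasma_grid_h, dtype=float),
        subject=f"truth:{product}",
    )
    cv = scenario.plasma_residual_cv_pct / 100.0
    profiles = []
    for i in range(n_subjects):
        noisy = base.profile.conc_ng_ml * (
            1.0 + rng.normal(0.0, cv, base.profile.conc_ng_ml.shape)
        )
        profiles.append(
            PlasmaProfile(
                times_h=base.profile.times_h,
                conc_ng_ml=np.clip(noisy, 0.0, None),
                dose_mg=dose_mg,
                subject=f"{product}:{i + 1}",
            )
        )
    return profiles, base


def make_product_pair(
    ref: WeibullParams,
    slowdown_factor: float = 1.0,
    wmax_shift: float = 0.0,
) -> tuple[WeibullParams, WeibullParams]:
    """Derive a test product from a reference by slowing release and/or
    shifting the plateau.

    ``slowdown_factor`` scales the 63.2%-release time (alpha is multiplied
    by factor**beta, so factor 2 doubles t63); ``wmax_shift`` is added to
    wmax and must keep it in (0, 100].
    """
    if not slowdown_factor > 0:
        raise InvalidParameterError("slowdown factor must be > 0")
    new_wmax = ref.wmax + wmax_shift
    if not 0 < new_wmax <= 100:
        raise InvalidParameterError(
            f"shifted wmax must be in (0, 100], got {new_wmax}"
        )
    test = dataclasses.replace(
        ref,
        alpha=ref.alpha * slowdown_factor**ref.beta,
        wmax=new_wmax,
    )
    return ref, test
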