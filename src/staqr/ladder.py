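"""The five-model comparison ladder.

Model 1: Gaussian linear regression, every covariate as a fixed effect
(continuous ones linear). Model 2: linear quantile regression, fixed
categorical effects only. Model 3: additive quantile regression, adding
RW2 smooths of the three continuous covariates. Model 4: spatial
quantile regression, fixed effects plus the ICAR district effect.
Model 5: the structured spatial additive quantile regression combining
smooths and the spatial effect. Models are ranked by DIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import ChildDataset
from .gibbs import FitResult, ModelSpec, gibbs_fit
from .structures import AdjacencyGraph

LEVELS = (1, 2, 3, 4, 5)
DESCRIPTIONS = {
    1: "simple linear regression (Gaussian mean model)",
    2: "linear quantile regression",
    3: "additive quantile regression",
    4: "spatial quantile regression",
    5: "structured spatial additive quantile regression",
}


@dataclass(frozen=True)
class CovariateRoles:
    """Which dataset columns play which role in the ladder."""

    categorical: tuple[str, ...]
    child_age: str = "child_age"
    mother_age: str = "mother_age"
    breastfeeding: str = "breastfeeding"
    district: str = "district"

    @property
    def smooth_covariates(self) -> tuple[str, str, str]:
        return (self.child_age, self.mother_age, self.breastfeeding)


def build_model(level: int, theta: float, roles: CovariateRoles) -> ModelSpec:
    """ModelSpec for one rung of the ladder at quantile level ``theta``."""
    if level not in LEVELS:
        raise ValueError(f"model level must be in {LEVELS}, got {level}")
    if level == 1:
        return ModelSpec(theta=None, likelihood="gaussian",
                         fixed_terms=roles.categorical,
                         linear_terms=roles.smooth_covariates)
    smooths = roles.smooth_covariates if level in (3, 5) else ()
    spatial = roles.district if level in (4, 5) else None
    return ModelSpec(theta=theta, likelihood="asymmetric-laplace",
                     fixed_terms=roles.categorical, smooth_terms=smooths,
                     spatial_term=spatial)


def fit_ladder(data: ChildDataset, graph: AdjacencyGraph,
               roles: CovariateRoles, theta: float, *,
               levels=LEVELS, iters: int = 12000, burnin: int = 2000,
               thin: int = 5, seed: int = 0) -> dict[int, FitResult]:
    """Fit the requested ladder levels on one dataset; level ``k`` uses
    seed ``seed + k`` so chains are independent but reproducible."""
    fits = {}
    for level in levels:
        spec = build_model(level, theta, roles)
        fits[level] = gibbs_fit(spec, data, graph, iters=iters,
                                burnin=burnin, thin=thin, seed=seed + level)
    return fits


def compare_models(fits: Mapping[int, FitResult]) -> pd.DataFrame:
    """DIC comparison table (rows DIC, pD, D; one column per model).

    The argmin-DIC model is flagged in ``df.attrs['selected']`` and in a
    ``selected`` indicator row. All fits must be on identical data.
    """
    if len(fits) < 2:
        raise ValueError("model comparison needs at least 2 fits")
    digests = {f.meta.get("y_digest") for f in fits.values()}
    if len(digests) != 1:
        raise ValueError("fits were not computed on identical data")
    levels = sorted(fits)
    for lv in levels:
        if fits[lv].dic is None:
            raise ValueError(f"fit for model {lv} has no DIC (too few draws)")
    table = pd.DataFrame(
        {lv: {"DIC": fits[lv].dic.DIC, "pD": fits[lv].dic.pD,
              "D": fits[lv].dic.D_at_mean} for lv in levels})
    table.columns = [f"model_{lv}" for lv in levels]
    selected = levels[int(np.argmin([fits[lv].dic.DIC for lv in levels]))]
    table.loc["selected"] = [float(lv == selected) for lv in levels]
    table.attrs["selected"] = selected
    return table
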