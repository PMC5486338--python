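"""Exploratory stage: anemia categories, cross-tabulation, screening.

Anemia severity follows the WHO hemoglobin cut-offs for children under
five. Association between the binary anemia flag (Hb < 11 g/dL) and each
categorical covariate is screened with the classical Pearson chi-square;
covariates with p below a liberal 0.2 threshold enter the regression
models. A small helper maps an anemia prevalence to the quantile level
theta at which the regression is read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .data import ANEMIA_CUTOFF, ChildDataset


class AnemiaCategory(enum.Enum):
    """Severity classes partitioning the Hb line (g/dL): severe [0, 7),
    moderate [7, 10), mild [10, 11), non-anemic [11, inf)."""

    SEVERE = ("severe", 0.0, 7.0)
    MODERATE = ("moderate", 7.0, 10.0)
    MILD = ("mild", 10.0, 11.0)
    NON_ANEMIC = ("non-anemic", 11.0, float("inf"))

    def __init__(self, label: str, lo: float, hi: float) -> None:
        self.label = label
        self.bounds = (lo, hi)

    @property
    def severity(self) -> int:
        """Rank from most severe (0) to non-anemic (3)."""
        return list(AnemiaCategory).index(self)


def classify_anemia(hb: float) -> AnemiaCategory:
    """Severity category of a hemoglobin value.

    Half-open intervals: a value on a boundary belongs to the interval
    whose lower bound it equals (11.0 is non-anemic, 10.0 is mild).
    """
    hb = float(hb)
    if hb < 0:
        raise ValueError(f"hemoglobin cannot be negative, got {hb}")
    for cat in AnemiaCategory:
        lo, hi = cat.bounds
        if lo <= hb < hi:
            return cat
    return AnemiaCategory.NON_ANEMIC


def _round1(x: float) -> float:
    """Round half-up to 1 decimal, matching printed-table display."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossTab:
    """Anemic / non-anemic counts by covariate level with row percentages
    and a Pearson chi-square test of association."""

    variable: str
    levels: tuple[str, ...]
    counts: np.ndarray  # levels x 2 (anemic, non-anemic)
    row_pct: np.ndarray  # levels x 2, half-up rounded to 1 dp
    chi2: float
    df: int
    p: float

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"level": self.levels,
             "anemic": self.counts[:, 0], "non_anemic": self.counts[:, 1],
             "anemic_pct": self.row_pct[:, 0],
             "non_anemic_pct": self.row_pct[:, 1]})
        out["chi2"] = self.chi2
        out["df"] = self.df
        out["p"] = self.p
        return out


def crosstab(data: ChildDataset, variable: str,
             weights: np.ndarray | None = None) -> CrossTab:
    """Cross-tabulate the anemia flag against one categorical variable.

    Rows with a missing level are dropped. With ``weights``, cell counts
    are weighted sums; the chi-square is always the classical Pearson
    statistic on the (possibly weighted) table, without survey design
    corrections.
    """
    if variable not in data.df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    col = data.df[variable]
    keep = col.notna().to_numpy()
    col = col[keep]
    anemic = data.anemic[keep]
    w = np.ones(keep.sum()) if weights is None else \
        np.asarray(weights, dtype=float)[keep]
    levels = tuple(pd.unique(col))
    counts = np.zeros((len(levels), 2))
    vals = col.to_numpy()
    for i, lvl in enumerate(levels):
        m = vals == lvl
        counts[i, 0] = w[m & anemic].sum()
        counts[i, 1] = w[m & ~anemic].sum()
    if (counts.sum(axis=1) == 0).any():
        raise ValueError(f"variable {variable!r} has a level with zero total")
    row_tot = counts.sum(axis=1, keepdims=True)
    pct = 100.0 * counts / row_tot
    row_pct = np.vectorize(_round1)(pct)
    if (counts.sum(axis=0) == 0).any() or len(levels) < 2:
        chi2, p, df = 0.0, 1.0, max(len(levels) - 1, 0)
    else:
        chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return CrossTab(variable=variable, levels=levels, counts=counts,
                    row_pct=row_pct, chi2=float(chi2), df=int(df),
                    p=float(p))


def screen_variables(tabs: list[CrossTab], alpha: float = 0.2) -> list[str]:
    """Names of variables whose chi-square p-value is below ``alpha``,
    in the original order. The liberal default keeps any covariate with
    even weak marginal association for the multivariable models."""
    if not tabs:
        raise ValueError("no cross-tabulations given")
    return [t.variable for t in tabs if t.p < alpha]


def prevalence_to_theta(hb, cutoff: float = ANEMIA_CUTOFF) -> float:
    """Empirical CDF of hemoglobin at ``cutoff``: the proportion strictly
    below, i.e. the quantile level at which the conditional-quantile model
    reads off that anemia category."""
    hb = np.asarray(hb, dtype=float)
    if hb.size == 0:
        raise ValueError("empty hemoglobin vector")
    return float(np.mean(hb < cutoff))


def eda_summary(data: ChildDataset, variables=None,
                weights: np.ndarray | None = None,
                alpha: float = 0.2) -> tuple[list[CrossTab], list[str]]:
    """Cross-tabulate every categorical variable and screen at ``alpha``."""
    variables = list(variables or data.categorical)
    tabs = [crosstab(data, v, weights) for v in variables]
    return tabs, screen_variables(tabs, alpha)
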