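"""Output surfaces: fixed effects across quantiles, smooth-effect curves
with credible bands, and per-district spatial effect summaries.

A positive effect raises hemoglobin and therefore lowers anemia risk;
districts with a positive posterior-mean spatial effect are coded
"lower-risk" and negative ones "higher-risk", mirroring the usual
disease-mapping legend. Significance is flagged when the central 95%
credible interval excludes zero. CSV is the canonical output; plots are
optional and headless-safe.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gibbs import FitResult


def _summ(draws: np.ndarray) -> tuple[np.ndarray, ...]:
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return mean, sd, lo, hi


def effects_table(fits: Mapping[float, FitResult]) -> pd.DataFrame:
    """Fixed-effect summaries per quantile level.

    One row per coefficient (reference-category coding), with posterior
    mean, sd, 95% interval and a significance flag per theta. All fits
    must share the same fixed-effect structure.
    """
    if not fits:
        raise ValueError("no fits given")
    thetas = sorted(fits)
    names = fits[thetas[0]].colnames
    for th in thetas:
        if fits[th].colnames != names:
            raise ValueError("fits have inconsistent fixed-effect coding")
    frames = []
    for th in thetas:
        mean, sd, lo, hi = _summ(fits[th].beta)
        frames.append(pd.DataFrame(
            {(th, "mean"): mean, (th, "sd"): sd, (th, "q2.5"): lo,
             (th, "q97.5"): hi, (th, "significant"): (lo > 0) | (hi < 0)},
            index=names))
    out = pd.concat(frames, axis=1)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["theta", "stat"])
    return out


def smooth_curves(fit: FitResult, term: str) -> pd.DataFrame:
    """Posterior summary of one smooth: grid, mean and 2.5/97.5% bands.

    ``term`` may be the covariate name or the stored block name
    ``s(covariate)``; the grid is the covariate's sorted unique values.
    """
    key = term if term in fit.smooths else f"s({term})"
    if key not in fit.smooths or not key.startswith("s("):
        raise KeyError(f"no smooth term {term!r} in this fit")
    mean, sd, lo, hi = _summ(fit.smooths[key])
    return pd.DataFrame({"grid": fit.grids[key], "mean": mean, "sd": sd,
                         "q2.5": lo, "q97.5": hi})


def spatial_table(fit: FitResult) -> pd.DataFrame:
    """Per-district posterior summary of the spatial effect with the
    two-class risk coding (mean > 0 -> lower-risk)."""
    key = next((k for k in fit.smooths if k.startswith("spat(")), None)
    if key is None:
        raise ValueError("fit has no spatial term")
    mean, sd, lo, hi = _summ(fit.smooths[key])
    return pd.DataFrame(
        {"district": fit.grids[key], "mean": mean, "sd": sd,
         "q2.5": lo, "q97.5": hi,
         "risk": np.where(mean > 0, "lower-risk", "higher-risk"),
         "significant": (lo > 0) | (hi < 0)})


def plot_smooth(fit: FitResult, term: str, path: str | Path) -> None:
    """Save a smooth-effect curve with its 95% band as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cur = smooth_curves(fit, term)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(cur["grid"], cur["q2.5"], cur["q97.5"], alpha=0.3,
                    label="95% credible band")
    ax.plot(cur["grid"], cur["mean"], lw=2)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(term)
    ax.set_ylabel("effect on Hb (g/dL)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
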