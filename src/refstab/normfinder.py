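"""Model-based stability estimation (NormFinder-style).

The working scale is x = log2 relative quantity. Within each experimental
group g the model is additive:

    x_igj = alpha_ig + beta_gj + eps_igj

with gene effect alpha, sample (loading) effect beta, and residual noise
eps_igj ~ N(0, sigma²_ig). Because the per-sample effect must be estimated
from the very genes being scored, the naive residual variance s²_ig is
contaminated by every other gene's noise: E[s²_i] = σ²_i(1 − 2/k) + (1/k²)Σσ².
Solving that expectation gives the corrected estimator

    σ̂²_ig = max{ (k/(k−2)) · (s²_ig − s̄²_g/(k−1)), 0 }

which is unbiased for σ²_ig before clipping. With several groups a gene may
also be systematically shifted between groups; the group difference d_ig is
shrunk toward 0 by the ratio of the between-group variance γ̂²_i to its
total uncertainty (an empirical-Bayes estimate), and the stability value
combines bias and noise:

    ρ_ig = |d̃_ig| + sqrt( γ̂²_i·(σ̂²_ig/n_g) / (γ̂²_i + σ̂²_ig/n_g) ),
    ρ_i  = mean over groups.

Lower ρ means more stable. With a single group ρ_i = σ̂_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_data import QuantityTable

__all__ = [
    "NormfinderResult",
    "estimate_group_variances",
    "stability_single_group",
    "stability_multi_group",
    "normfinder",
]

_EPS = 1e-12  # floor inside the shrinkage quotient; avoids 0/0


@dataclass
class NormfinderResult:
    """Per-gene stability values and the components behind them."""

    rho: pd.Series  # stability value, log2 units, ≥ 0; lower = more stable
    ranking: pd.Series  # 1 = most stable; ties broken by gene id
    sigma2: pd.DataFrame  # genes × groups corrected intragroup variances
    d_tilde: pd.DataFrame | None  # genes × groups shrunk group differences
    grouping: list[str]  # group labels in column order


def _complete_log2(x: QuantityTable | pd.DataFrame) -> pd.DataFrame:
    df = x.log2() if isinstance(x, QuantityTable) else pd.DataFrame(x).astype(float)
    keep = df.columns[~df.isna().any(axis=0)]
    dropped = df.shape[1] - len(keep)
    if dropped:
        warnings.warn(
            f"model-based estimation uses complete cases: dropping {dropped} sample(s)",
            stacklevel=3,
        )
    return df[keep]


def _align_groups(x: pd.DataFrame, groups: pd.Series | dict | None) -> pd.Series:
    if groups is None:
        return pd.Series("all", index=x.columns)
    g = pd.Series(groups)
    missing = [s for s in x.columns if s not in g.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    return g.loc[x.columns].astype(str)


def _raw_group_s2(xg: np.ndarray) -> np.ndarray:
    """Naive residual variances s²_i within one group (genes × samples)."""
    z = xg - xg.mean(axis=1, keepdims=True) - xg.mean(axis=0, keepdims=True) + xg.mean()
    n = xg.shape[1]
    return (z**2).sum(axis=1) / (n - 1)


def estimate_group_variances(
    x: QuantityTable | pd.DataFrame, groups: pd.Series | dict | None = None
) -> pd.DataFrame:
    """Contamination-corrected intragroup variances σ̂²_ig (genes × groups).

    Needs ≥3 genes for the correction (with k < 3 the naive s² is returned
    with a warning) and ≥2 complete samples per group.
    """
    xdf = _complete_log2(x)
    glab = _align_groups(xdf, groups)
    k = xdf.shape[0]
    cols: dict[str, np.ndarray] = {}
    for label in pd.unique(glab):
        sub = xdf.loc[:, glab[glab == label].index]
        n_g = sub.shape[1]
        if n_g < 2:
            raise ValueError(f"group {label!r} has {n_g} complete sample(s); need ≥2")
        s2 = _raw_group_s2(sub.to_numpy())
        if k < 3:
            warnings.warn(
                "fewer than 3 genes: cross-gene contamination cannot be "
                "corrected, returning naive residual variances",
                stacklevel=2,
            )
            cols[label] = s2
        else:
            corrected = (k / (k - 2)) * (s2 - s2.mean() / (k - 1))
            cols[label] = np.maximum(corrected, 0.0)
    return pd.DataFrame(cols, index=xdf.index)


def _rank_ascending(score: pd.Series) -> pd.Series:
    order = sorted(score.index, key=lambda g: (score[g], g))
    return pd.Series(
        {g: i + 1 for i, g in enumerate(order)}, name="rank"
    ).loc[score.index]


def stability_single_group(
    x: QuantityTable | pd.DataFrame, sigma2: pd.DataFrame | None = None
) -> NormfinderResult:
    """Single-group stability: ρ_i = σ̂_i (no group bias term)."""
    if sigma2 is None:
        sigma2 = estimate_group_variances(x, None)
    rho = np.sqrt(sigma2.iloc[:, 0]).rename("rho")
    return NormfinderResult(
        rho=rho,
        ranking=_rank_ascending(rho),
        sigma2=sigma2,
        d_tilde=None,
        grouping=list(sigma2.columns),
    )


def stability_multi_group(
    x: QuantityTable | pd.DataFrame, groups: pd.Series | dict
) -> NormfinderResult:
    """Multi-group stability combining shrunk group bias and intragroup noise.

    Group differences use unweighted group means, so unequal group sizes
    treat every condition symmetrically. A single group delegates to
    :func:`stability_single_group`.
    """
    xdf = _complete_log2(x)
    glab = _align_groups(xdf, groups)
    labels = list(pd.unique(glab))
    if len(labels) < 2:
        return stability_single_group(xdf)
    sigma2 = estimate_group_variances(xdf, glab)[labels]
    genes = list(xdf.index)
    G = len(labels)

    group_mean = pd.DataFrame(
        {lab: xdf.loc[:, glab[glab == lab].index].mean(axis=1) for lab in labels}
    )  # x̄_ig·
    n_g = pd.Series({lab: (glab == lab).sum() for lab in labels}, dtype=float)
    gene_mean = group_mean.mean(axis=1)  # x̄_i·· (unweighted over groups)
    overall_group = group_mean.mean(axis=0)  # x̄_··g
    grand = overall_group.mean()  # x̄_···
    d = group_mean.sub(gene_mean, axis=0).sub(overall_group, axis=1) + grand

    se2 = sigma2 / n_g  # σ̂²_ig / n_g, genes × groups
    gamma2 = (d**2).sum(axis=1) / (G - 1) - se2.mean(axis=1)
    gamma2 = gamma2.clip(lower=0.0)

    denom = (gamma2.to_numpy()[:, None] + se2.to_numpy()) + _EPS
    shrink = gamma2.to_numpy()[:, None] / denom
    d_tilde = pd.DataFrame(d.to_numpy() * shrink, index=genes, columns=labels)
    var_term = (gamma2.to_numpy()[:, None] * se2.to_numpy()) / denom
    rho_ig = np.abs(d_tilde.to_numpy()) + np.sqrt(var_term)
    rho = pd.Series(rho_ig.mean(axis=1), index=genes, name="rho")
    return NormfinderResult(
        rho=rho,
        ranking=_rank_ascending(rho),
        sigma2=sigma2,
        d_tilde=d_tilde,
        grouping=labels,
    )


def normfinder(
    x: QuantityTable | pd.DataFrame, groups: pd.Series | dict | None = None
) -> NormfinderResult:
    """Dispatch on grouping: single-group σ̂ ranking or the full
    bias-plus-variance combination."""
    if groups is None:
        return stability_single_group(x)
    return stability_multi_group(x, groups)
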