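"""BestKeeper-style descriptive analysis of raw CT values.

Unlike geNorm and NormFinder, this method works on the CT scale directly.
Each candidate is summarised by location (geometric/arithmetic mean CT,
min, max) and dispersion; candidates with low dispersion are combined into
the BestKeeper index — the per-sample geometric mean of their CTs — and
each gene's CT profile is correlated with that index. A dispersion above
1 cycle (~2-fold variation) conventionally disqualifies a candidate.

The default dispersion is the mean absolute deviation from the arithmetic
mean CT — the original tool's characteristically small "SD (± CP)" — with
the ordinary sample standard deviation available as an alternative since
"SD" is often read that way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ct_data import CtTable

__all__ = [
    "BestkeeperResult",
    "descriptive_stats",
    "bestkeeper_index",
    "correlate_with_index",
    "bestkeeper_rank",
    "bestkeeper",
]

SD_CUTOFF = 1.0  # cycles; genes above this are flagged "inconsistent"


@dataclass
class BestkeeperResult:
    """Per-gene descriptive block, per-sample index, and ranking."""

    stats: pd.DataFrame  # geo_mean, ar_mean, min, max, sd_value, cv_percent, ...
    index: pd.Series  # per-sample BestKeeper index CT
    ranking: pd.Series
    dispersion_mode: str
    included_genes: list[str]  # genes entering the index (sd ≤ cutoff)


def _dispersion(ct_row: np.ndarray, mode: str) -> float:
    if mode == "mad":
        return float(np.mean(np.abs(ct_row - ct_row.mean())))
    if mode == "sd":
        return float(np.std(ct_row, ddof=1))
    raise ValueError(f"unknown dispersion mode {mode!r} (expected 'mad' or 'sd')")


def descriptive_stats(table: CtTable, mode: str = "mad") -> pd.DataFrame:
    """Per-gene location and dispersion of raw CT, pairwise-complete.

    Columns: geo_mean, ar_mean, min, max, sd_value (per ``mode``),
    cv_percent = 100·sd/ar_mean, n. Each gene needs ≥2 observed samples.
    """
    rows = []
    for gene in table.gene_ids:
        ct = table.ct.loc[gene].dropna().to_numpy()
        if ct.size < 2:
            raise ValueError(f"gene {gene!r} has {ct.size} CT value(s); need ≥2")
        ar = float(ct.mean())
        sd = _dispersion(ct, mode)
        rows.append(
            {
                "gene": gene,
                "geo_mean": float(stats.gmean(ct)),
                "ar_mean": ar,
                "min": float(ct.min()),
                "max": float(ct.max()),
                "sd_value": sd,
                "cv_percent": 100.0 * sd / ar,
                "n": int(ct.size),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def bestkeeper_index(table: CtTable, included_genes: Sequence[str]) -> pd.Series:
    """Per-sample index: geometric mean CT of the included candidates.

    Samples missing a CT for any included gene are excluded from the index
    with a warning (the geometric mean would otherwise silently change
    meaning between samples).
    """
    included = list(included_genes)
    if not included:
        raise ValueError("BestKeeper index needs a nonempty gene set")
    block = table.ct.loc[included]
    ok = ~block.isna().any(axis=0)
    if (~ok).any():
        warnings.warn(
            f"index skips {int((~ok).sum())} sample(s) with missing CTs "
            f"in the included genes",
            stacklevel=2,
        )
    return pd.Series(
        stats.gmean(block.loc[:, ok].to_numpy(), axis=0),
        index=block.columns[ok],
        name="bestkeeper_index",
    )


def correlate_with_index(table: CtTable, index: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each gene's CT with the index.

    Two-sided p-value from the t transform with n−2 df. A gene (or index)
    with zero variance over the paired samples gets r = NaN and a flag
    rather than an error.
    """
    rows = []
    for gene in table.gene_ids:
        ct = table.ct.loc[gene]
        paired = pd.concat([ct, index], axis=1, join="inner").dropna()
        n = paired.shape[0]
        if n < 3:
            raise ValueError(f"gene {gene!r}: <3 paired observations with the index")
        x, y = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"gene": gene, "r": np.nan, "p_value": np.nan,
                         "n": n, "undefined_r": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"gene": gene, "r": float(r), "p_value": float(p),
                     "n": n, "undefined_r": False})
    return pd.DataFrame(rows).set_index("gene")


def bestkeeper_rank(stats_df: pd.DataFrame) -> pd.Series:
    """Rank ascending by sd_value; ties broken by higher |r| (when a
    correlation column is present), then by gene id."""
    def key(g: str):
        sd = stats_df.loc[g, "sd_value"]
        r = stats_df.loc[g, "r"] if "r" in stats_df.columns else np.nan
        r_abs = -abs(r) if np.isfinite(r) else 0.0
        return (sd, r_abs, g)

    order = sorted(stats_df.index, key=key)
    return pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").loc[
        stats_df.index
    ]


def bestkeeper(
    table: CtTable, mode: str = "mad", sd_cutoff: float = SD_CUTOFF
) -> BestkeeperResult:
    """Full BestKeeper run.

    Genes with dispersion above ``sd_cutoff`` are flagged inconsistent and
    left out of the index, but they are still ranked and correlated.
    """
    desc = descriptive_stats(table, mode)
    desc["inconsistent"] = desc["sd_value"] > sd_cutoff
    included = list(desc.index[~desc["inconsistent"]])
    if not included:
        warnings.warn(
            "every gene exceeds the dispersion cutoff; building the index "
            "from all genes instead",
            stacklevel=2,
        )
        included = list(desc.index)
    index = bestkeeper_index(table, included)
    corr = correlate_with_index(table, index)
    full = desc.join(corr[["r", "p_value", "undefined_r"]])
    ranking = bestkeeper_rank(full)
    full["rank"] = ranking
    return BestkeeperResult(
        stats=full,
        index=index,
        ranking=ranking,
        dispersion_mode=mode,
        included_genes=included,
    )
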