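"""Comparative ΔCt stability method.

Each pair of candidates is compared by the standard deviation, across
samples, of their CT difference; a gene's score is the mean of its pairwise
SDs. On the log2 scale the CT difference equals (up to a constant) the
negative log-ratio of base-2 relative quantities, so on complete data this
score is algebraically identical to the geNorm M value computed on the
full gene set without iteration — the method is the CT-scale, one-shot
member of the four-method battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ct_data import CtTable

__all__ = ["DeltaCtResult", "delta_ct_scores"]


@dataclass
class DeltaCtResult:
    """Mean pairwise ΔCT SDs (cycles), the full SD matrix, and ranking."""

    scores: pd.Series  # mean pairwise SD per gene, ascending = stable
    sd_matrix: pd.DataFrame  # symmetric, zero diagonal
    ranking: pd.Series


def delta_ct_scores(table: CtTable) -> DeltaCtResult:
    """Score genes by mean pairwise SD of CT differences.

    Missingness is handled pairwise: each (j, k) SD uses the samples
    observed for both genes. A pair with fewer than 2 shared samples is
    excluded from both genes' means with a warning. Needs ≥3 genes.
    """
    genes = table.gene_ids
    if len(genes) < 3:
        raise ValueError("comparative ΔCt needs at least 3 genes")
    k = len(genes)
    sd = pd.DataFrame(0.0, index=genes, columns=genes)
    valid = pd.DataFrame(False, index=genes, columns=genes)
    for gj, gk in combinations(genes, 2):
        pair = table.ct.loc[[gj, gk]].dropna(axis=1)
        if pair.shape[1] < 2:
            warnings.warn(
                f"pair ({gj!r}, {gk!r}) has <2 shared samples; excluded",
                stacklevel=2,
            )
            sd.loc[gj, gk] = sd.loc[gk, gj] = np.nan
            continue
        val = float(np.std(pair.loc[gj] - pair.loc[gk], ddof=1))
        sd.loc[gj, gk] = sd.loc[gk, gj] = val
        valid.loc[gj, gk] = valid.loc[gk, gj] = True
    scores = {}
    for g in genes:
        partners = sd.loc[g, valid.loc[g]]
        if partners.empty:
            raise ValueError(f"gene {g!r} has no valid pair; cannot be scored")
        scores[g] = float(partners.mean())
    score_s = pd.Series(scores, name="mean_pairwise_sd").loc[genes]
    order = sorted(genes, key=lambda g: (score_s[g], g))
    ranking = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").loc[genes]
    return DeltaCtResult(scores=score_s, sd_matrix=sd, ranking=ranking)
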