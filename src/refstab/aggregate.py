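"""RefFinder-style comprehensive ranking.

Each stability method contributes an integer rank per gene (1 = most
stable); the aggregate weight is the geometric mean of a gene's ranks
across methods, and the final order sorts ascending by that weight, ties
broken by gene id. geNorm's structurally tied top pair is split into
ranks 1 and 2 by lexicographic gene id so every method's ranks form a
permutation; the tie is recorded, never hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["AggregateRanking", "ranks_from_scores", "method_ranks", "reffinder_weight"]


@dataclass
class AggregateRanking:
    """Per-method ranks, geometric-mean weights, and the final order."""

    ranks: pd.DataFrame  # genes × methods, integer ranks
    weight: pd.Series  # geometric mean of ranks, ≥ 1
    final_rank: pd.Series
    final_order: list[str]
    methods: list[str] = field(default_factory=list)
    ties: dict[str, tuple[str, ...]] = field(default_factory=dict)


def ranks_from_scores(scores: pd.Series) -> pd.Series:
    """Ascending-score integer ranks, ties broken by gene id."""
    order = sorted(scores.index, key=lambda g: (scores[g], g))
    return pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").loc[
        scores.index
    ]


def method_ranks(
    method_scores: Mapping[str, pd.Series],
    precomputed_ranks: Mapping[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Integer ranks per method from stability scores.

    ``precomputed_ranks`` supplies methods that rank genes directly (e.g.
    geNorm's elimination order with its tied top pair); tied rank values
    there are split by lexicographic gene id into consecutive integers and
    the tie is reported. All methods must score the same gene set.
    """
    ranks: dict[str, pd.Series] = {}
    ties: dict[str, tuple[str, ...]] = {}
    gene_set: set[str] | None = None

    def check_genes(method: str, idx) -> None:
        nonlocal gene_set
        s = set(idx)
        if gene_set is None:
            gene_set = s
        elif s != gene_set:
            raise ValueError(
                f"method {method!r} scores a different gene set: "
                f"extra={sorted(s - gene_set)}, missing={sorted(gene_set - s)}"
            )

    for method, scores in method_scores.items():
        check_genes(method, scores.index)
        ranks[method] = ranks_from_scores(scores)
    if precomputed_ranks:
        for method, r in precomputed_ranks.items():
            check_genes(method, r.index)
            tied = r[r.duplicated(keep=False)]
            if not tied.empty:
                ties[method] = tuple(sorted(tied.index))
            order = sorted(r.index, key=lambda g: (r[g], g))
            ranks[method] = pd.Series(
                {g: i + 1 for i, g in enumerate(order)}, name="rank"
            ).loc[r.index]
    if not ranks:
        raise ValueError("no methods supplied")
    genes = sorted(gene_set)  # type: ignore[arg-type]
    return pd.DataFrame({m: ranks[m].loc[genes] for m in ranks}, index=genes), ties


def reffinder_weight(
    ranks: pd.DataFrame, ties: dict[str, tuple[str, ...]] | None = None
) -> AggregateRanking:
    """Geometric-mean weight over ≥2 methods and the final stability order.

    A gene missing a rank under some method (NaN) is weighted over its
    available methods, with a logged count, rather than being imputed the
    worst rank.
    """
    if ranks.shape[1] < 2:
        raise ValueError("aggregation needs at least 2 methods")
    arr = ranks.to_numpy(dtype=float)
    n_avail = np.sum(~np.isnan(arr), axis=1)
    if (n_avail == 0).any():
        bad = list(ranks.index[n_avail == 0])
        raise ValueError(f"gene(s) ranked by no method: {bad}")
    if (n_avail < ranks.shape[1]).any():
        n_part = int((n_avail < ranks.shape[1]).sum())
        warnings.warn(
            f"{n_part} gene(s) missing under some method; geometric mean "
            "taken over available methods",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        weight = np.exp(np.nansum(np.log(arr), axis=1) / n_avail)
    weight_s = pd.Series(weight, index=ranks.index, name="geomean_weight")
    final_order = sorted(ranks.index, key=lambda g: (weight_s[g], g))
    final_rank = pd.Series(
        {g: i + 1 for i, g in enumerate(final_order)}, name="final_rank"
    ).loc[ranks.index]
    return AggregateRanking(
        ranks=ranks,
        weight=weight_s,
        final_rank=final_rank,
        final_order=final_order,
        methods=list(ranks.columns),
        ties=dict(ties or {}),
    )
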