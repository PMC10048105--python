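"""geNorm stability analysis.

geNorm scores a candidate reference gene by the expression stability
measure M: the mean, over all other candidates, of the standard deviation
of the log2 ratio of relative quantities across samples. Two genes that are
perfect references keep a constant ratio, so their pairwise SD is 0; a
regulated or noisy gene inflates its ratio SD with every partner. Genes are
ranked by iteratively discarding the worst (highest-M) gene and recomputing
M on the survivors until two remain — those two cannot be separated by M
(each is the other's only partner) and are jointly most stable.

The pairwise variation V(n/n+1) between normalization factors built from
the top n and top n+1 genes decides how many references to use: the
smallest n with V ≤ 0.15 suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ct_data import QuantityTable

__all__ = [
    "GenormResult",
    "pairwise_variation",
    "m_values",
    "genorm_rank",
    "normalization_factor",
    "v_series",
    "recommend_n",
    "genorm",
]

V_THRESHOLD = 0.15


def _log2_complete(q: QuantityTable | pd.DataFrame) -> pd.DataFrame:
    """log2 quantities restricted to listwise-complete samples."""
    df = q.q if isinstance(q, QuantityTable) else q
    keep = df.columns[~df.isna().any(axis=0)]
    dropped = df.shape[1] - len(keep)
    if dropped:
        warnings.warn(
            f"geNorm uses complete cases: dropping {dropped} sample(s) "
            "with missing quantities",
            stacklevel=3,
        )
    return np.log2(df[keep].astype(float))


def pairwise_variation(q: QuantityTable | pd.DataFrame, gene_j: str, gene_k: str) -> float:
    """V_jk: sample standard deviation of log2(Q_j / Q_k) across samples.

    Symmetric in its arguments; 0 iff the two genes keep an exactly
    constant ratio. Requires ≥2 samples complete for the pair.
    """
    df = q.q if isinstance(q, QuantityTable) else q
    pair = df.loc[[gene_j, gene_k]].dropna(axis=1)
    if pair.shape[1] < 2:
        raise ValueError(
            f"pairwise variation of ({gene_j!r}, {gene_k!r}) needs ≥2 complete samples"
        )
    ratios = np.log2(pair.loc[gene_j] / pair.loc[gene_k])
    return float(np.std(ratios, ddof=1))


def _m_from_log(x: pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """M values from log2 quantities restricted to ``genes``."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("M values need at least 2 genes")
    sub = x.loc[genes]
    if sub.shape[1] < 2:
        raise ValueError("M values need at least 2 complete samples")
    # SD of log-ratio differences: V_jk = SD(x_j − x_k)
    arr = sub.to_numpy()
    k = len(genes)
    m = np.empty(k)
    for j in range(k):
        diffs = arr[j][None, :] - arr  # (k, n) of x_j − x_k
        sds = np.std(diffs, axis=1, ddof=1)
        m[j] = sds.sum() / (k - 1)  # own row SD is 0
    return pd.Series(m, index=genes, name="M")


def m_values(q: QuantityTable | pd.DataFrame, gene_set: Sequence[str] | None = None) -> pd.Series:
    """Stability measure M_j: mean of V_jk over all partners k ≠ j."""
    x = _log2_complete(q)
    genes = list(gene_set) if gene_set is not None else list(x.index)
    return _m_from_log(x, genes)


@dataclass
class GenormResult:
    """Outcome of the full geNorm procedure.

    ``m`` holds each gene's M value at the round it was eliminated (for the
    final pair, their shared M on that pair). ``ranking`` is competition
    style: the final two genes both get rank 1, the next gene rank 3, the
    first eliminated rank k. ``order`` is a strict most-to-least-stable
    ordering (the tied pair split lexicographically) used to build
    normalization factors.
    """

    m: pd.Series
    elimination_order: list[str]
    ranking: pd.Series
    order: list[str]
    tied_top_pair: tuple[str, str]
    v: dict[int, float] = field(default_factory=dict)
    recommended_n: int | None = None
    insufficient_stability: bool = False


def genorm_rank(q: QuantityTable | pd.DataFrame) -> GenormResult:
    """Iterative worst-gene exclusion; requires ≥3 genes.

    Ties on the highest M are broken by removing the lexicographically
    last gene id (deterministic; recorded in the elimination order).
    """
    x = _log2_complete(q)
    genes = list(x.index)
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs at least 3 genes")
    surviving = list(genes)
    elimination: list[str] = []
    final_m: dict[str, float] = {}
    while len(surviving) > 2:
        m = _m_from_log(x, surviving)
        worst_val = m.max()
        candidates = sorted(m.index[m == worst_val])
        worst = candidates[-1]  # lexicographically last among exact ties
        final_m[worst] = float(m[worst])
        surviving.remove(worst)
        elimination.append(worst)
    pair_m = _m_from_log(x, surviving)
    a, b = sorted(surviving)
    final_m[a] = float(pair_m[a])
    final_m[b] = float(pair_m[b])
    order = [a, b] + list(reversed(elimination))
    ranking = pd.Series(index=genes, dtype=int, name="rank")
    ranking[a] = 1
    ranking[b] = 1
    for pos, g in enumerate(reversed(elimination)):
        ranking[g] = 3 + pos
    return GenormResult(
        m=pd.Series(final_m).loc[genes].rename("M"),
        elimination_order=elimination,
        ranking=ranking.loc[genes],
        order=order,
        tied_top_pair=(a, b),
    )


def normalization_factor(
    q: QuantityTable | pd.DataFrame, gene_subset: Iterable[str]
) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the subset's
    relative quantities."""
    df = q.q if isinstance(q, QuantityTable) else q
    subset = list(gene_subset)
    if not subset:
        raise ValueError("normalization factor needs a nonempty gene subset")
    block = df.loc[subset]
    if (block.to_numpy() <= 0).any():
        raise ValueError("normalization factor requires positive quantities")
    return np.exp2(np.log2(block).mean(axis=0)).rename("NF")


def v_series(
    q: QuantityTable | pd.DataFrame, ranking: Sequence[str]
) -> dict[int, float]:
    """Pairwise variation V(n/n+1) = SD over samples of log2(NF_n / NF_{n+1})
    for n = 2..k−1, with NF_n built from the n top-ranked genes."""
    df = q.q if isinstance(q, QuantityTable) else q
    ranking = list(ranking)
    if set(ranking) != set(df.index):
        raise ValueError("ranking must cover exactly the genes in the table")
    k = len(ranking)
    if k < 3:
        raise ValueError("V series needs at least 3 genes")
    x = _log2_complete(df)
    out: dict[int, float] = {}
    for n in range(2, k):
        nf_n = x.loc[ranking[:n]].mean(axis=0)  # log2 of geometric mean
        nf_n1 = x.loc[ranking[: n + 1]].mean(axis=0)
        out[n] = float(np.std(nf_n - nf_n1, ddof=1))
    return out


def recommend_n(
    v: dict[int, float] | Sequence[float], threshold: float = V_THRESHOLD
) -> tuple[int, bool]:
    """Smallest n with V(n/n+1) ≤ threshold.

    Accepts either a {n: V} mapping or a plain sequence taken as
    V(2/3), V(3/4), ... Returns ``(n, insufficient)`` where ``insufficient``
    is True when no V meets the threshold; then n = k (the full panel) and
    the caller should warn that even all genes do not stabilise the factor.
    """
    if isinstance(v, dict):
        items = sorted(v.items())
    else:
        items = list(enumerate(v, start=2))
    if not items:
        raise ValueError("empty V series")
    for n, val in items:
        if val <= threshold:
            return n, False
    k = items[-1][0] + 1
    return k, True


def genorm(
    q: QuantityTable | pd.DataFrame, threshold: float = V_THRESHOLD
) -> GenormResult:
    """Full geNorm run: ranking, V series, and the gene-number decision."""
    result = genorm_rank(q)
    result.v = v_series(q, result.order)
    n, insufficient = recommend_n(result.v, threshold)
    result.recommended_n = n
    result.insufficient_stability = insufficient
    if insufficient:
        warnings.warn(
            "no V(n/n+1) at or below the threshold: even the full panel "
            "does not stabilise the normalization factor",
            stacklevel=2,
        )
    return result
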