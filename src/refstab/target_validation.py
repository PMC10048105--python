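"""ΔΔCt relative quantification of a target gene against reference sets.

The Livak 2^−ΔΔCT method: ΔCT = CT_target − CT_ref, where for a multi-gene
reference set CT_ref is the arithmetic mean of the reference CTs
(equivalently the geometric mean of their quantities); ΔΔCT subtracts the
calibrator sample's ΔCT, so the calibrator's relative quantity is exactly 1
and a one-cycle drop of the target doubles RQ. Per-gene amplification
efficiencies E% replace the base 2 by 1 + E/100 when supplied.

Comparing RQ profiles obtained under rival reference sets quantifies how
much the choice of references matters: a reference that drifts with the
condition drags the apparent target expression with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ct_data import CtTable

__all__ = [
    "RelativeExpression",
    "relative_expression",
    "compare_normalizations",
    "summarize_replicates",
]


@dataclass
class RelativeExpression:
    """Per-sample relative quantities of one target under one reference set."""

    rq: pd.Series  # RQ > 0; calibrator exactly 1
    reference_set: list[str]
    calibrator: str


def _composite_ref_log(
    references: CtTable,
    reference_set: Sequence[str],
    efficiencies: Mapping[str, float] | None,
) -> pd.Series:
    """Per-sample reference signal on the log2-quantity scale:
    mean over references of CT_r·log2(b_r)."""
    logs = []
    for r in reference_set:
        ct = references.ct.loc[r]
        b = 2.0 if efficiencies is None else 1.0 + float(efficiencies[r]) / 100.0
        logs.append(ct * np.log2(b))
    return pd.concat(logs, axis=1).mean(axis=1)


def relative_expression(
    target_ct: pd.Series,
    references: CtTable,
    reference_set: Sequence[str],
    calibrator: str,
    efficiencies: Mapping[str, float] | None = None,
    target_gene: str | None = None,
) -> RelativeExpression:
    """2^−ΔΔCT relative quantification of a target against a reference set.

    ``target_ct`` is indexed by sample id; ``references`` holds the
    reference genes' CTs over (at least) the same samples. With
    efficiencies the exponent base is per-gene: RQ multiplies
    b_t^−ΔΔCT_t by the reference composite on the log2-quantity scale.
    Samples lacking the target or any used reference CT are dropped with a
    warning; the calibrator itself must be complete.
    """
    reference_set = list(reference_set)
    if not reference_set:
        raise ValueError("reference set must be nonempty")
    missing_ref = [r for r in reference_set if r not in references.ct.index]
    if missing_ref:
        raise KeyError(f"reference gene(s) not in table: {missing_ref}")
    if calibrator not in target_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} has no target CT")

    common = [s for s in target_ct.index if s in references.ct.columns]
    tct = target_ct.loc[common].astype(float)
    ref_block = references.ct.loc[reference_set, common]
    usable = (~tct.isna()) & (~ref_block.isna().any(axis=0))
    if calibrator not in usable.index or not usable[calibrator]:
        raise ValueError(f"calibrator {calibrator!r} is missing a CT value")
    dropped = list(usable.index[~usable])
    if dropped:
        warnings.warn(f"dropping sample(s) with missing CTs: {dropped}", stacklevel=2)
    samples = list(usable.index[usable])

    if efficiencies is not None:
        missing_e = [g for g in reference_set if g not in efficiencies]
        if missing_e:
            raise ValueError(f"no efficiency for reference(s): {missing_e}")
        b_t = (
            2.0
            if target_gene is None or target_gene not in efficiencies
            else 1.0 + float(efficiencies[target_gene]) / 100.0
        )
    else:
        b_t = 2.0

    ref_log = _composite_ref_log(references, reference_set, efficiencies).loc[samples]
    # log2 RQ before calibration: reference signal minus target signal
    log_rq = ref_log - tct.loc[samples] * np.log2(b_t)
    log_rq = log_rq - log_rq.loc[calibrator]
    rq = np.exp2(log_rq).rename("rq")
    return RelativeExpression(rq=rq, reference_set=reference_set, calibrator=calibrator)


def summarize_replicates(
    rq: pd.Series, condition: pd.Series
) -> pd.DataFrame:
    """Mean ± standard error of RQ across biological replicates per condition."""
    df = pd.DataFrame({"rq": rq, "condition": condition.loc[rq.index]})
    g = df.groupby("condition")["rq"]
    return pd.DataFrame(
        {"mean": g.mean(), "sem": g.sem(), "n": g.size()}
    )


def compare_normalizations(
    target_ct: pd.Series,
    references: CtTable,
    reference_sets: Mapping[str, Sequence[str]],
    calibrator: str,
    efficiencies: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RQ profiles of one target under rival reference sets.

    Returns (profiles, divergence): ``profiles`` has one RQ column per
    named reference set over the shared samples; ``divergence`` lists, for
    each pair of sets, the maximum absolute log2 fold-difference between
    their profiles — 0 for identical sets, and about δ when one set drifts
    by δ log2 units under some condition.
    """
    if len(reference_sets) < 2:
        raise ValueError("need at least 2 reference sets to compare")
    profiles = {}
    for name, refs in reference_sets.items():
        profiles[name] = relative_expression(
            target_ct, references, refs, calibrator, efficiencies
        ).rq
    prof = pd.DataFrame(profiles).dropna()
    rows = []
    for a, b in combinations(prof.columns, 2):
        diff = np.abs(np.log2(prof[a]) - np.log2(prof[b]))
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "max_abs_log2_divergence": float(diff.max()),
                "at_sample": str(diff.idxmax()),
            }
        )
    return prof, pd.DataFrame(rows)
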