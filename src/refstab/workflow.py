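"""End-to-end stability workflow: four methods, aggregation, reporting.

This is the layer the command line and the analysis drivers call: it takes
one CT table (plus optional design), runs the requested stability methods
on the appropriate working scales, aggregates them RefFinder-style, and
writes a deterministic bundle of CSV/JSON reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .aggregate import AggregateRanking, method_ranks, reffinder_weight
from .bestkeeper import BestkeeperResult, bestkeeper as _run_bestkeeper
from .ct_data import CtTable, SampleDesign, ct_to_quantity
from .delta_ct import DeltaCtResult, delta_ct_scores
from .genorm import GenormResult, genorm as _run_genorm
from .normfinder import NormfinderResult, normfinder as _run_normfinder

__all__ = ["StabilityConfig", "StabilityBundle", "run_stability", "write_bundle"]

ALL_METHODS = ("genorm", "normfinder", "bestkeeper", "delta_ct")


@dataclass
class StabilityConfig:
    """Options of one stability run; defaults follow common practice
    (V threshold 0.15, base-2 quantities, min-CT referencing)."""

    methods: tuple[str, ...] = ALL_METHODS
    quantity_mode: str = "base2"  # or "efficiency"
    efficiencies: Mapping[str, float] | None = None
    reference: str = "min"
    v_threshold: float = 0.15
    dispersion_mode: str = "mad"
    group_fields: tuple[str, ...] = ("stress", "timepoint_h")

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if not self.methods:
            raise ValueError("no methods selected")


@dataclass
class StabilityBundle:
    """Everything one run produced, ready for reporting."""

    genorm: GenormResult | None = None
    normfinder: NormfinderResult | None = None
    bestkeeper: BestkeeperResult | None = None
    delta_ct: DeltaCtResult | None = None
    aggregate: AggregateRanking | None = None
    summary: dict = field(default_factory=dict)


def run_stability(
    table: CtTable,
    design: SampleDesign | None = None,
    config: StabilityConfig | None = None,
) -> StabilityBundle:
    """Run the selected methods on one CT table and aggregate their ranks.

    geNorm and NormFinder work on relative quantities (complete cases);
    BestKeeper and comparative ΔCt work on raw CT (pairwise-complete).
    NormFinder uses the design's group labels when a design is given,
    otherwise a single group. Aggregation needs ≥2 methods; with fewer the
    bundle simply reports the single method.
    """
    cfg = config or StabilityConfig()
    if design is not None:
        design.validate_against(table)
    bundle = StabilityBundle()
    q = None
    if {"genorm", "normfinder"} & set(cfg.methods):
        q = ct_to_quantity(
            table, cfg.efficiencies, mode=cfg.quantity_mode, reference=cfg.reference
        )

    scores: dict[str, pd.Series] = {}
    pre_ranks: dict[str, pd.Series] = {}
    if "genorm" in cfg.methods:
        bundle.genorm = _run_genorm(q, threshold=cfg.v_threshold)
        pre_ranks["genorm"] = bundle.genorm.ranking
    if "normfinder" in cfg.methods:
        groups = None
        if design is not None:
            groups = SampleDesign(
                design.table.reset_index(drop=True), cfg.group_fields
            ).group_labels(table.sample_ids)
        bundle.normfinder = _run_normfinder(q, groups)
        scores["normfinder"] = bundle.normfinder.rho
    if "bestkeeper" in cfg.methods:
        bundle.bestkeeper = _run_bestkeeper(table, mode=cfg.dispersion_mode)
        pre_ranks["bestkeeper"] = bundle.bestkeeper.ranking
    if "delta_ct" in cfg.methods:
        bundle.delta_ct = delta_ct_scores(table)
        scores["delta_ct"] = bundle.delta_ct.scores

    if len(cfg.methods) >= 2:
        ranks, ties = method_ranks(scores, pre_ranks)
        bundle.aggregate = reffinder_weight(ranks, ties)

    summary: dict = {"methods": list(cfg.methods), "n_genes": table.n_genes(),
                     "n_samples": table.n_samples()}
    if bundle.genorm is not None:
        summary["genorm_top_pair"] = list(bundle.genorm.tied_top_pair)
        summary["recommended_n"] = bundle.genorm.recommended_n
        summary["insufficient_stability"] = bundle.genorm.insufficient_stability
        summary["v_series"] = {str(n): v for n, v in bundle.genorm.v.items()}
    if bundle.aggregate is not None:
        summary["final_order"] = bundle.aggregate.final_order
        summary["top_2"] = bundle.aggregate.final_order[:2]
    bundle.summary = summary
    return bundle


def write_bundle(bundle: StabilityBundle, outdir: str | Path) -> list[Path]:
    """Write per-method CSVs plus an aggregate CSV and a JSON summary.

    All numeric columns go out with 4 decimal places; reruns with the same
    inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, float_format="%.4f")
        written.append(p)

    if bundle.genorm is not None:
        g = bundle.genorm
        elim_round = {gene: i + 1 for i, gene in enumerate(g.elimination_order)}
        df = pd.DataFrame(
            {
                "final_M": g.m,
                "rank": g.ranking,
                "elimination_round": pd.Series(elim_round).reindex(g.m.index),
            }
        )
        df.index.name = "gene"
        save(df, "genorm.csv")
        vdf = pd.DataFrame(
            {"n": list(g.v.keys()), "V_n_n+1": list(g.v.values())}
        ).set_index("n")
        save(vdf, "genorm_v_series.csv")
    if bundle.normfinder is not None:
        r = bundle.normfinder
        df = pd.DataFrame({"rho": r.rho, "rank": r.ranking})
        for grp in r.sigma2.columns:
            df[f"sigma2[{grp}]"] = r.sigma2[grp]
        if r.d_tilde is not None:
            for grp in r.d_tilde.columns:
                df[f"d_tilde[{grp}]"] = r.d_tilde[grp]
        df.index.name = "gene"
        save(df, "normfinder.csv")
    if bundle.bestkeeper is not None:
        save(bundle.bestkeeper.stats.rename_axis("gene"), "bestkeeper.csv")
        save(
            bundle.bestkeeper.index.rename_axis("sample").to_frame(),
            "bestkeeper_index.csv",
        )
    if bundle.delta_ct is not None:
        df = pd.DataFrame(
            {"mean_pairwise_sd": bundle.delta_ct.scores, "rank": bundle.delta_ct.ranking}
        )
        df.index.name = "gene"
        save(df, "delta_ct.csv")
    if bundle.aggregate is not None:
        a = bundle.aggregate
        df = a.ranks.copy()
        df.columns = [f"rank_{m}" for m in df.columns]
        df["geomean_weight"] = a.weight
        df["final_rank"] = a.final_rank
        df.index.name = "gene"
        save(df.sort_values("final_rank"), "aggregate.csv")
    p = outdir / "summary.json"
    p.write_text(json.dumps({"schema": 1, **bundle.summary}, indent=2, sort_keys=True))
    written.append(p)
    return written
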