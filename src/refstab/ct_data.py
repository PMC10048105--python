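"""CT (quantification-cycle) tables: data model, I/O, validation, and
transformation to relative quantities.

A :class:`CtTable` is the universal input of every stability method in this
package: a genes × samples matrix of Cq values, with ``NaN`` marking missing
wells. CT is a log2-scale abundance measure — one cycle ≈ one doubling of
template — so all downstream statistics operate either on CT directly
(BestKeeper, comparative ΔCt) or on relative quantities ``b^(−ΔCT)``
derived here (geNorm, NormFinder), where the base ``b`` is 2 for an ideal
reaction or ``1 + E/100`` for a measured amplification efficiency E%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CT_MAX",
    "CtTable",
    "SampleDesign",
    "QuantityTable",
    "CollapseReport",
    "read_ct_table",
    "write_ct_table",
    "read_design",
    "collapse_technical_replicates",
    "ct_to_quantity",
]

#: Upper bound accepted for a Cq value, in cycles. Runs of 40 cycles are the
#: norm but some instruments report calls slightly beyond; values above this
#: are treated as data errors rather than "undetermined" codes.
CT_MAX = 45.0

TISSUES = ("leaf", "root", "stem")
STRESSES = ("cold", "salt", "drought", "control")
TIMEPOINTS_H = (0, 6, 12, 24)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValueError(f"duplicate {what} ids: {dups}")


@dataclass
class CtTable:
    """Genes × samples matrix of quantification-cycle values.

    ``ct`` is indexed by gene id with sample ids as columns; missing wells
    are ``NaN``. Every non-missing value must be finite and in (0, CT_MAX].
    """

    ct: pd.DataFrame

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.ct.index = self.ct.index.astype(str).rename("gene")
        self.ct.columns = self.ct.columns.astype(str).rename(None)
        _check_unique(list(self.ct.index), "gene")
        _check_unique(list(self.ct.columns), "sample")
        vals = self.ct.to_numpy()
        bad = ~np.isnan(vals) & (~np.isfinite(vals) | (vals <= 0) | (vals > CT_MAX))
        if bad.any():
            gi, sj = np.argwhere(bad)[0]
            raise ValueError(
                f"CT value {vals[gi, sj]!r} for gene {self.ct.index[gi]!r}, "
                f"sample {self.ct.columns[sj]!r} is outside (0, {CT_MAX}]"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def missing(self) -> pd.DataFrame:
        """Boolean mask, True where the well is missing."""
        return self.ct.isna()

    def n_genes(self) -> int:
        return self.ct.shape[0]

    def n_samples(self) -> int:
        return self.ct.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "CtTable":
        genes = list(genes)
        missing = [g for g in genes if g not in self.ct.index]
        if missing:
            raise KeyError(f"genes not in table: {missing}")
        return CtTable(self.ct.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "CtTable":
        samples = list(samples)
        missing = [s for s in samples if s not in self.ct.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CtTable(self.ct[samples])

    def complete_samples(self) -> list[str]:
        """Samples with a CT for every gene (listwise-complete cases)."""
        return list(self.ct.columns[~self.ct.isna().any(axis=0)])

    def drop_incomplete_samples(self, warn: bool = True) -> "CtTable":
        """Listwise deletion: drop samples with any missing gene.

        geNorm and NormFinder require complete cases; BestKeeper and the
        comparative ΔCt method handle missingness pairwise instead.
        """
        keep = self.complete_samples()
        dropped = [s for s in self.sample_ids if s not in keep]
        if dropped and warn:
            warnings.warn(
                f"dropping {len(dropped)} sample(s) with missing CTs: {dropped}",
                stacklevel=2,
            )
        return CtTable(self.ct[keep])


@dataclass
class SampleDesign:
    """Experimental annotation of samples: tissue, stress, timepoint, replicate.

    ``group_label`` is a deterministic function of the chosen grouping
    fields; the default groups samples by stress × timepoint, matching a
    per-tissue analysis where each stress/time combination is one
    biological condition.
    """

    table: pd.DataFrame
    group_fields: tuple[str, ...] = ("stress", "timepoint_h")

    REQUIRED = ("sample", "tissue", "stress", "timepoint_h", "replicate")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"design table missing column {col!r}")
        df["sample"] = df["sample"].astype(str)
        _check_unique(list(df["sample"]), "design sample")
        bad_t = set(df["tissue"]) - set(TISSUES)
        if bad_t:
            raise ValueError(f"unknown tissue value(s): {sorted(bad_t)}")
        bad_s = set(df["stress"]) - set(STRESSES)
        if bad_s:
            raise ValueError(f"unknown stress value(s): {sorted(bad_s)}")
        df["timepoint_h"] = df["timepoint_h"].astype(int)
        bad_tp = set(df["timepoint_h"]) - set(TIMEPOINTS_H)
        if bad_tp:
            raise ValueError(f"unknown timepoint(s): {sorted(bad_tp)}")
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")
        unknown = set(self.group_fields) - {"tissue", "stress", "timepoint_h"}
        if unknown:
            raise ValueError(f"unknown grouping field(s): {sorted(unknown)}")
        self.table = df.set_index("sample", drop=False)

    def validate_against(self, table: CtTable) -> None:
        """Every sample in the CT table must have exactly one design row."""
        missing = [s for s in table.sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without a design row: {missing}")

    def group_labels(self, samples: Iterable[str] | None = None) -> pd.Series:
        """Deterministic group label per sample, joining the group fields."""
        df = self.table if samples is None else self.table.loc[list(samples)]
        parts = [df[f].astype(str) for f in self.group_fields]
        out = parts[0]
        for p in parts[1:]:
            out = out + ":" + p
        return out.rename("group")

    def subset(self, **conditions) -> "SampleDesign":
        """Filter rows, e.g. ``design.subset(tissue="leaf", stress="cold")``."""
        df = self.table
        for col, val in conditions.items():
            if col not in df.columns:
                raise KeyError(f"no design column {col!r}")
            df = df[df[col] == val]
        return SampleDesign(df.reset_index(drop=True), self.group_fields)


@dataclass
class QuantityTable:
    """Relative quantities ``Q = b^(ref_CT − CT)`` on the same axes as a CtTable.

    Under min-CT referencing (the geNorm convention) the sample with the
    lowest CT of each gene has quantity exactly 1 and all others are < 1.
    ``base`` records the per-gene amplification base b used.
    """

    q: pd.DataFrame
    base: pd.Series

    def __post_init__(self) -> None:
        vals = self.q.to_numpy()
        if (~np.isnan(vals) & (vals <= 0)).any():
            raise ValueError("relative quantities must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.q.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.q.columns)

    def log2(self) -> pd.DataFrame:
        """log2 quantities — the working scale of NormFinder."""
        return np.log2(self.q)


@dataclass
class CollapseReport:
    """Technical-replicate collapse diagnostics: sets whose CT spread
    (max − min) exceeded the tolerance."""

    flagged: list[tuple[str, str, float]] = field(default_factory=list)

    def add(self, gene: str, merged: str, spread: float) -> None:
        self.flagged.append((gene, merged, spread))


# ---------------------------------------------------------------------------
# I/O


def read_design(path: str | Path, group_fields=("stress", "timepoint_h")) -> SampleDesign:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return SampleDesign(pd.read_csv(path, sep=sep), tuple(group_fields))


def read_ct_table(
    path: str | Path,
    layout: str = "wide",
    design_path: str | Path | None = None,
) -> tuple[CtTable, SampleDesign | None]:
    """Read a CT table from CSV/TSV in wide or long layout.

    Wide: first column ``gene``, one column per sample, cells CT or empty.
    Long: columns ``gene,sample,ct``. Both layouts parse to the identical
    CtTable; missing wells stay missing (never dropped). A duplicate
    (gene, sample) pair is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    if layout == "wide":
        df = pd.read_csv(path, sep=sep)
        first = df.columns[0]
        if first != "gene":
            raise ValueError(f"wide layout requires first column 'gene', got {first!r}")
        df = df.set_index("gene")
        table = CtTable(df)
    elif layout == "long":
        df = pd.read_csv(path, sep=sep)
        need = {"gene", "sample", "ct"}
        if not need.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(need)}")
        dup = df.duplicated(subset=["gene", "sample"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate (gene, sample) pair: ({row['gene']!r}, {row['sample']!r})"
            )
        wide = df.pivot(index="gene", columns="sample", values="ct")
        # preserve file order of first appearance
        wide = wide.loc[
            pd.unique(df["gene"]).astype(str), pd.unique(df["sample"]).astype(str)
        ]
        wide.index.name = "gene"
        table = CtTable(wide)
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'wide' or 'long')")
    design = None
    if design_path is not None:
        design = read_design(design_path)
        design.validate_against(table)
    return table, design


def write_ct_table(table: CtTable, path: str | Path, layout: str = "wide") -> None:
    """Write CSV/TSV with 4 decimal places; wide or long layout."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    if layout == "wide":
        out = table.ct.copy()
        out.index.name = "gene"
        out.to_csv(path, sep=sep, float_format="%.4f")
    elif layout == "long":
        long = (
            table.ct.rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="sample", value_name="ct")
        )
        long = long.dropna(subset=["ct"])
        long.to_csv(path, sep=sep, index=False, float_format="%.4f")
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# Transformations


def collapse_technical_replicates(
    table: CtTable,
    replicate_map: Mapping[str, Sequence[str]],
    max_spread: float = 0.5,
) -> tuple[CtTable, CollapseReport]:
    """Average technical replicates into one column per biological sample.

    ``replicate_map`` maps each merged sample id to the technical-replicate
    columns it absorbs (a partition of the columns used). Per gene the
    arithmetic mean CT of non-missing replicates is taken; replicate sets
    whose spread (max − min) exceeds ``max_spread`` cycles are flagged in
    the report but still collapsed.
    """
    report = CollapseReport()
    cols: dict[str, pd.Series] = {}
    for merged, members in replicate_map.items():
        members = list(members)
        if not members:
            raise ValueError(f"empty technical-replicate set for {merged!r}")
        missing = [m for m in members if m not in table.ct.columns]
        if missing:
            raise KeyError(f"replicate columns not in table: {missing}")
        block = table.ct[members]
        mean = block.mean(axis=1, skipna=True)
        spread = block.max(axis=1) - block.min(axis=1)
        for gene in table.gene_ids:
            s = spread.loc[gene]
            if np.isfinite(s) and s > max_spread:
                report.add(gene, merged, float(s))
        cols[merged] = mean
    return CtTable(pd.DataFrame(cols)), report


def ct_to_quantity(
    table: CtTable,
    efficiencies: Mapping[str, float] | None = None,
    mode: str = "base2",
    reference: str = "min",
) -> QuantityTable:
    """Transform CT to relative quantities ``Q_ij = b_i^(refCT_i − CT_ij)``.

    mode "base2" uses b = 2 for every gene (perfect doubling); mode
    "efficiency" uses b_i = 1 + E_i/100 with the per-gene efficiency E_i%
    from ``efficiencies`` (must lie in (50, 150)). ``reference`` picks the
    per-gene anchor CT: "min" (the geNorm convention, so max Q = 1) or
    "mean". Missing CTs propagate to missing quantities.
    """
    if mode == "base2":
        base = pd.Series(2.0, index=table.ct.index)
    elif mode == "efficiency":
        if efficiencies is None:
            raise ValueError("efficiency mode requires per-gene efficiencies")
        missing = [g for g in table.gene_ids if g not in efficiencies]
        if missing:
            raise ValueError(f"no efficiency for gene(s): {missing}")
        eff = pd.Series({g: float(efficiencies[g]) for g in table.gene_ids})
        out_of_range = eff[(eff <= 50) | (eff >= 150)]
        if not out_of_range.empty:
            raise ValueError(
                f"efficiency % out of (50, 150) for: {list(out_of_range.index)}"
            )
        base = 1.0 + eff / 100.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if (base <= 0).any():
        raise ValueError("amplification base must be positive")
    if reference == "min":
        ref_ct = table.ct.min(axis=1, skipna=True)
    elif reference == "mean":
        ref_ct = table.ct.mean(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    delta = table.ct.sub(ref_ct, axis=0)  # CT − refCT ≥ 0 under "min"
    q = pd.DataFrame(
        np.power(base.to_numpy()[:, None], -delta.to_numpy()),
        index=table.ct.index,
        columns=table.ct.columns,
    )
    return QuantityTable(q=q, base=base)
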