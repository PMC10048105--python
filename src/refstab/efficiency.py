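"""Amplification-efficiency calibration from dilution-series standard curves.

A standard curve regresses CT on log10(relative template amount) over a
serial dilution. For an ideal reaction the template doubles each cycle, so
one log10 of input shifts CT by −log2(10) ≈ −3.3219 cycles; the per-cycle
gain follows from the slope as

    E% = (10^(−1/slope) − 1) × 100

with E = 100% at slope −3.3219. Curves are screened on E ∈ [90, 110] and
R² ≥ 0.99, the usual qPCR primer-acceptance window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "efficiency_from_slope",
    "efficiency_qc",
    "read_dilution_series",
    "fit_dilution_file",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of CT on log10(relative amount) for one primer pair."""

    slope: float  # cycles per log10(relative amount); < 0 for a valid curve
    intercept: float  # cycles
    r_squared: float
    efficiency_percent: float  # (10^(−1/slope) − 1) × 100, exact
    n_points: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "efficiency_percent": self.efficiency_percent,
            "n_points": self.n_points,
        }


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    E% = (10^(−1/slope) − 1) × 100; slope must be negative (CT falls as
    input rises). Returns the exact value; round to 2 decimals for
    reporting.
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope!r}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(
    relative_amounts: Sequence[float], ct_values: Sequence[float]
) -> StandardCurve:
    """Fit CT = slope·log10(amount) + intercept by ordinary least squares.

    All replicate points enter the fit (no pre-averaging per dilution
    level), so R² reflects replicate scatter. Requires ≥3 distinct
    dilution levels and positive amounts.
    """
    a = np.asarray(relative_amounts, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if a.shape != ct.shape:
        raise ValueError("relative_amounts and ct_values differ in length")
    if (a <= 0).any():
        raise ValueError("relative amounts must be positive")
    if not np.isfinite(ct).all():
        raise ValueError("CT values must be finite")
    x = np.log10(a)
    n_levels = np.unique(x).size
    if n_levels < 3:
        raise ValueError(f"need ≥3 distinct dilution levels, got {n_levels}")
    res = stats.linregress(x, ct)
    slope = float(res.slope)
    return StandardCurve(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency_percent=efficiency_from_slope(slope),
        n_points=int(x.size),
    )


def efficiency_qc(
    curves: Mapping[str, StandardCurve],
    e_range: tuple[float, float] = (90.0, 110.0),
    r2_min: float = 0.99,
) -> pd.DataFrame:
    """Flag genes whose efficiency or R² falls outside the accepted window.

    Nothing is removed — failing genes are flagged so the analyst decides.
    Returns a per-gene frame with efficiency, R², individual flags, and an
    overall pass column.
    """
    lo, hi = e_range
    rows = []
    for gene, c in curves.items():
        e_ok = lo <= c.efficiency_percent <= hi
        r2_ok = c.r_squared >= r2_min
        rows.append(
            {
                "gene": gene,
                "slope": c.slope,
                "efficiency_percent": c.efficiency_percent,
                "r_squared": c.r_squared,
                "efficiency_ok": e_ok,
                "r_squared_ok": r2_ok,
                "pass": e_ok and r2_ok,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def read_dilution_series(path: str | Path) -> pd.DataFrame:
    """Read a dilution CSV with columns gene,relative_amount,ct
    (one row per replicate point)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    need = {"gene", "relative_amount", "ct"}
    if not need.issubset(df.columns):
        raise ValueError(f"dilution file requires columns {sorted(need)}")
    return df


def fit_dilution_file(path: str | Path) -> dict[str, StandardCurve]:
    """Fit one standard curve per gene from a dilution CSV."""
    df = read_dilution_series(path)
    out: dict[str, StandardCurve] = {}
    for gene, block in df.groupby("gene", sort=False):
        out[str(gene)] = fit_standard_curve(
            block["relative_amount"].to_numpy(), block["ct"].to_numpy()
        )
    return out
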