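"""Published standard-curve parameters for the okra candidate-reference panel.

Eighteen candidate reference genes screened from an okra (*Abelmoschus
esculentus* L.) transcriptome, plus the MYB1R1 transcription factor used as
the validation target. For each primer pair the published dilution-series
regression (slope, intercept), its R², and the reported amplification
efficiency E% are stored, so efficiency-corrected quantification can be run
without refitting and the E = (10^(−1/slope) − 1) × 100 conversion can be
checked against the reported values.

Note: EF-1a and ARFA1E are listed with identical primer sequences and
amplicon sizes in the published panel but different slopes — almost
certainly a table erratum in the source; they are kept as distinct genes
with their printed slopes, with no attempt to guess intent.
"""

from __future__ import annotations

import pandas as pd

from .efficiency import StandardCurve, efficiency_from_slope

__all__ = [
    "OKRA_GENES",
    "OKRA_TARGET_GENE",
    "OKRA_STANDARD_CURVES",
    "okra_curve_table",
    "okra_standard_curves",
]

# gene: (slope, intercept, reported E%, reported R²)
_PANEL: dict[str, tuple[float, float, float, float]] = {
    "ACT7": (-3.5111, 29.777, 92.67, 0.9937),
    "HIS1": (-3.5239, 30.469, 92.21, 0.9974),
    "HIS6": (-3.4937, 29.442, 93.30, 0.9976),
    "UBC17": (-3.4411, 26.954, 95.26, 0.9971),
    "TUB-a": (-3.3538, 29.262, 98.69, 0.9967),
    "UBC5B": (-3.3125, 25.576, 100.39, 0.9929),
    "SAMDC": (-3.3157, 29.643, 100.26, 0.9986),
    "MUB1": (-3.3915, 28.576, 97.18, 0.9979),
    "CYP": (-3.4893, 30.282, 93.46, 0.9968),
    "UBQ": (-3.5635, 29.459, 90.82, 0.9998),
    "Eif": (-3.5559, 26.519, 91.08, 0.9992),
    "EF-1a": (-3.4148, 29.239, 96.27, 0.9922),
    "ARFA1E": (-3.3776, 25.795, 97.73, 0.9997),
    "GAPC1": (-3.4221, 29.247, 95.98, 0.9932),
    "TUA4": (-3.2557, 28.359, 102.84, 0.9946),
    "ARP": (-3.3273, 25.988, 99.78, 0.9913),
    "GAPDH": (-3.4732, 29.391, 94.05, 0.9964),
    "60s": (-3.5047, 28.514, 92.90, 0.9937),
    "MYB1R1": (-3.4389, 32.574, 95.34, 0.9926),
}

#: The 18 candidate reference genes, panel order.
OKRA_GENES: tuple[str, ...] = tuple(g for g in _PANEL if g != "MYB1R1")

#: Stress-responsive transcription factor used to validate the chosen
#: references by ΔΔCt quantification.
OKRA_TARGET_GENE = "MYB1R1"


def okra_curve_table(include_target: bool = True) -> pd.DataFrame:
    """Panel as a DataFrame: slope, intercept, reported_e_percent, r_squared."""
    genes = list(_PANEL) if include_target else list(OKRA_GENES)
    return pd.DataFrame(
        [(g, *_PANEL[g]) for g in genes],
        columns=["gene", "slope", "intercept", "reported_e_percent", "r_squared"],
    ).set_index("gene")


def okra_standard_curves(include_target: bool = True) -> dict[str, StandardCurve]:
    """StandardCurve objects for the panel, with E% recomputed from the slope
    (the exact value; the reported figure is this rounded to 2 decimals)."""
    genes = list(_PANEL) if include_target else list(OKRA_GENES)
    out = {}
    for g in genes:
        slope, intercept, _e, r2 = _PANEL[g]
        out[g] = StandardCurve(
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            efficiency_percent=efficiency_from_slope(slope),
            n_points=0,  # points not published; parameters only
        )
    return out


OKRA_STANDARD_CURVES = okra_standard_curves()
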