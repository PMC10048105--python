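"""Seeded simulation of RT-qPCR CT tables with known ground truth.

The generator reproduces the statistical structure every stability method
assumes, on the CT (log2) scale where qPCR noise lives:

    CT_is = B_i + L_s + δ_i,c(s) + ε_is

with per-gene baseline B_i (overall abundance, cycles), per-sample loading
effect L_s ~ N(0, σ_L²) shared by all genes of a sample (RNA input /
reverse-transcription yield), a per-gene, per-condition bias δ_ic for
deliberately unstable (condition-regulated) genes, and technical noise
ε_is ~ N(0, σ_i²). Loading effects are exactly what reference-gene
normalization removes, so every stability score must ignore L; condition
bias is the failure mode a regulated "housekeeping" gene exhibits.

The default experimental design mirrors a three-tissue (leaf/root/stem) ×
three-stress (cold/salt/drought) × four-timepoint (0/6/12/24 h) plant
stress experiment with 3 biological replicates — 36 samples per stress —
and an 18-gene candidate panel with baselines spread over CT ≈ 17–33.

What the simulation does not emulate: amplification-curve fluorescence,
efficiency drift between samples, PCR inhibitors, and CT-dependent
(heteroscedastic) noise. Recovery results on these tables show the
algorithms separate stable from unstable genes under the assumed model,
not that any particular real gene is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ct_data import CtTable, SampleDesign

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_ct",
    "okra_design_preset",
    "load_spec",
    "save_spec",
]

#: Panel-like CT baseline window (cycles); spread seen across a typical
#: candidate panel where the most abundant transcript sits near CT 17 and
#: the scarcest near 33.
BASELINE_RANGE = (17.0, 33.0)


@dataclass
class SimulationSpec:
    """Generative parameters for one synthetic CT experiment.

    ``condition_bias`` maps gene → {selector: δ cycles} where a selector is
    ``"field=value"`` (fields tissue, stress, timepoint_h) or several
    joined with ``&``, e.g. ``"stress=cold&timepoint_h=12"``. δ is added to
    the CT of matching samples (positive δ = apparent down-regulation).
    """

    gene_ids: list[str]
    baseline_ct: dict[str, float]  # B_i, cycles
    noise_sd: dict[str, float]  # σ_i, cycles
    loading_sd: float = 0.3  # σ_L, cycles
    condition_bias: dict[str, dict[str, float]] = field(default_factory=dict)
    tissues: list[str] = field(default_factory=lambda: ["leaf", "root", "stem"])
    stresses: list[str] = field(default_factory=lambda: ["cold", "salt", "drought"])
    timepoints_h: list[int] = field(default_factory=lambda: [0, 6, 12, 24])
    n_replicates: int = 3
    efficiency_percent: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in spec")
        for g in self.gene_ids:
            if g not in self.baseline_ct:
                raise ValueError(f"no baseline CT for gene {g!r}")
            if g not in self.noise_sd:
                raise ValueError(f"no noise SD for gene {g!r}")
        if any(s < 0 for s in self.noise_sd.values()) or self.loading_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_replicates < 1 or not self.tissues or not self.stresses:
            raise ValueError("design counts must be positive")

    def n_samples(self) -> int:
        return (
            len(self.tissues)
            * len(self.stresses)
            * len(self.timepoints_h)
            * self.n_replicates
        )


@dataclass
class GroundTruth:
    """What the generator knows: designated stable genes and true parameters."""

    stable_genes: list[str]  # no condition bias and minimal noise SD
    noise_sd: dict[str, float]
    condition_bias: dict[str, dict[str, float]]

    def as_dict(self) -> dict:
        return asdict(self)


def _parse_selector(selector: str) -> list[tuple[str, str]]:
    clauses = []
    for part in selector.split("&"):
        if "=" not in part:
            raise ValueError(f"bad condition selector {selector!r}")
        f, v = part.split("=", 1)
        f = f.strip()
        if f not in ("tissue", "stress", "timepoint_h"):
            raise ValueError(f"unknown selector field {f!r}")
        clauses.append((f, v.strip()))
    return clauses


def _stable_set(spec: SimulationSpec) -> list[str]:
    unbiased = [
        g
        for g in spec.gene_ids
        if not any(spec.condition_bias.get(g, {}).values())
    ]
    if not unbiased:
        raise ValueError("spec designates no unbiased gene; stable set empty")
    min_sd = min(spec.noise_sd[g] for g in unbiased)
    return [g for g in unbiased if spec.noise_sd[g] <= min_sd + 1e-12]


def simulate_ct(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[CtTable, SampleDesign, GroundTruth]:
    """Draw one CT table from the spec's generative model.

    The same spec and seed always give the identical table (a fresh
    ``default_rng`` per call; ``seed`` overrides ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    for tissue in spec.tissues:
        for stress in spec.stresses:
            for tp in spec.timepoints_h:
                for rep in range(1, spec.n_replicates + 1):
                    rows.append(
                        {
                            "sample": f"{tissue}_{stress}_{tp}h_r{rep}",
                            "tissue": tissue,
                            "stress": stress,
                            "timepoint_h": tp,
                            "replicate": rep,
                        }
                    )
    design_df = pd.DataFrame(rows)
    samples = design_df["sample"].to_numpy()
    n, k = len(samples), len(spec.gene_ids)

    loading = rng.normal(0.0, spec.loading_sd, size=n)
    baseline = np.array([spec.baseline_ct[g] for g in spec.gene_ids])
    sds = np.array([spec.noise_sd[g] for g in spec.gene_ids])
    eps = rng.normal(0.0, 1.0, size=(k, n)) * sds[:, None]

    bias = np.zeros((k, n))
    for gi, g in enumerate(spec.gene_ids):
        for selector, delta in spec.condition_bias.get(g, {}).items():
            mask = np.ones(n, dtype=bool)
            for f, v in _parse_selector(selector):
                col = design_df[f].astype(str).to_numpy()
                mask &= col == v
            bias[gi, mask] += float(delta)

    ct = baseline[:, None] + loading[None, :] + bias + eps
    table = CtTable(pd.DataFrame(ct, index=spec.gene_ids, columns=samples))
    design = SampleDesign(design_df)
    truth = GroundTruth(
        stable_genes=_stable_set(spec),
        noise_sd=dict(spec.noise_sd),
        condition_bias={g: dict(v) for g, v in spec.condition_bias.items()},
    )
    return table, design, truth


def okra_design_preset(seed: int = 0) -> SimulationSpec:
    """An 18-gene panel on the full 3-tissue × 3-stress × 4-timepoint × 3-rep
    design (36 samples per stress, 108 in total).

    Baselines are drawn (seeded) uniformly over the panel-like window
    CT 17–33. Three genes are designated stable (σ = 0.2 cycles, no bias);
    the rest get a seeded noise ladder σ ∈ [0.4, 1.2], and two genes are
    made condition-regulated: one cold-induced (δ = −1.5 cycles under cold
    at 6–24 h, the tubulin-style failure mode) and one drought-repressed
    (δ = +1.2 under drought at 12–24 h).
    """
    from .panels import OKRA_GENES

    genes = list(OKRA_GENES)
    rng = np.random.default_rng(seed)
    lo, hi = BASELINE_RANGE
    baseline = {g: float(b) for g, b in zip(genes, rng.uniform(lo, hi, len(genes)))}
    stable = ["HIS6", "Eif", "UBQ"]
    noisy = [g for g in genes if g not in stable]
    ladder = np.linspace(0.4, 1.2, len(noisy))
    noise = {g: 0.2 for g in stable}
    noise.update({g: float(s) for g, s in zip(noisy, rng.permutation(ladder))})
    bias = {
        "TUB-a": {
            "stress=cold&timepoint_h=6": -1.5,
            "stress=cold&timepoint_h=12": -1.5,
            "stress=cold&timepoint_h=24": -1.5,
        },
        "GAPDH": {
            "stress=drought&timepoint_h=12": 1.2,
            "stress=drought&timepoint_h=24": 1.2,
        },
    }
    return SimulationSpec(
        gene_ids=genes,
        baseline_ct=baseline,
        noise_sd=noise,
        loading_sd=0.3,
        condition_bias=bias,
        seed=seed,
    )


def save_spec(spec: SimulationSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)


def load_spec(path: str | Path) -> SimulationSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationSpec(**data)
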