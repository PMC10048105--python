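# Methods

## Data model and working scales

The package's universal input is a genes × samples matrix of
quantification cycles (CT), validated to lie in (0, 45] — instrument runs
are typically 40 cycles, but 45 is accepted to tolerate other platforms —
with missing wells kept as an explicit mask. CT is a log2-scale abundance
measure: one cycle ≈ one doubling. Relative quantities are
Q_ij = b_i^(refCT_i − CT_ij), with base b = 2 ("base2" mode) or
b = 1 + E_i/100 from a measured amplification efficiency ("efficiency"
mode; E constrained to (50, 150)%). The per-gene reference CT defaults to
the gene's minimum (the geNorm convention: the most abundant sample has
Q = 1), configurable to the mean. Base-2 and efficiency modes agree
exactly at E = 100.

Missing-data policy follows what each downstream method tolerates: geNorm
and NormFinder require complete cases, so samples with any missing gene
are dropped with a warning (listwise); BestKeeper and the comparative ΔCt
method use pairwise-complete samples. Technical replicates are collapsed
by arithmetic mean CT; replicate sets whose spread exceeds a tolerance
(default 0.5 cycles) are flagged, never silently discarded.

The sample design (tissue ∈ {leaf, root, stem}; stress ∈ {cold, salt,
drought, control}; timepoint ∈ {0, 6, 12, 24} h; replicate) carries the
grouping used by NormFinder; the default group label is stress × timepoint
(each stress/time combination is one biological condition within a
tissue), configurable to any subset of the design fields.

## Standard curves and efficiency

CT is regressed on log10(relative template amount) by OLS — the
orientation in which standard curves are conventionally reported
(y = slope·x + intercept with CT as y). All replicate points enter the fit
rather than dilution-level means, so R² reflects replicate scatter.
Efficiency is E% = (10^(−1/slope) − 1) × 100, reported to two decimals
with the exact value retained. QC flags (never removes) primer pairs
outside E ∈ [90, 110] or R² < 0.99. The bundled okra panel stores the
published slope/intercept/R²/E% of 18 candidate references plus the
MYB1R1 target; two panel entries (EF-1a, ARFA1E) carry identical primer
sequences with different slopes — almost certainly an erratum in the
source table — and are kept as distinct genes with their printed values.

## geNorm

M_j is the mean over partners of the sample SD of pairwise log2 quantity
ratios; the ranking removes the highest-M gene each round, recomputing M
on the survivors, until two genes remain. Those two are structurally
inseparable (each is the other's only partner) and share rank 1; during
aggregation the pair is split into ranks 1/2 by lexicographic gene id and
the tie is recorded. Ties on the removal step discard the
lexicographically last gene id — the underlying algorithm is silent on
ties, so the break is made deterministic and visible. V(n/n+1) is the
sample SD of log2(NF_n/NF_{n+1}) with NF the geometric mean of the top-n
quantities; the recommended gene number is the smallest n with
V ≤ 0.15 (inclusive comparison). When no V meets the threshold the full
panel size is returned with an explicit "insufficient stability" flag.
The published okra all-sample series {V2/3 = 0.123, V3/4 = 0.152,
V4/5 = 0.141} yields n = 2 under this rule; the accompanying V series is
always reported so an analyst preferring a more conservative 3–4 gene
combination can apply judgment.

## NormFinder-style model-based estimation

Within each group the additive model x_igj = α_ig + β_gj + ε_igj holds on
log2 quantities. Because the per-sample term β must be estimated from the
scored genes themselves, the naive residual variance is contaminated:
E[s²_i] = σ²_i(1 − 2/k) + (1/k²)Σσ². Inverting that expectation gives the
corrected estimator σ̂²_ig = max{(k/(k−2))(s²_ig − s̄²_g/(k−1)), 0},
unbiased before clipping (verified by simulation: mean σ̂² within ±8% of
truth over 500 panels, k = 10, n = 50, σ² = 0.25). With k < 3 the
correction is impossible and the naive s² is returned with a warning.

Across G ≥ 2 groups, the group difference d_ig (unweighted group means, so
unequal groups are treated symmetrically) is shrunk by
γ̂²/(γ̂² + σ̂²/n_g), where γ̂² is the clipped between-group variance, and
ρ_ig = |d̃_ig| + √(γ̂²·(σ̂²/n_g)/(γ̂² + σ̂²/n_g)); ρ_i averages over
groups. A 10⁻¹² floor in the shrinkage denominator avoids 0/0 in the
fully degenerate case.

Two limitations are worth knowing. First, variance clipping means genes
with below-panel-average noise can be estimated at exactly σ̂² = 0.
Second, when a gene's between-group variance clips to zero the whole
multi-group ρ collapses to 0 regardless of its within-group noise — the
multi-group stability value targets *detectable* group bias, and pure
technical noise is better caught by the single-group form or by the other
methods in the battery. This is why the aggregate combines four methods.

## BestKeeper

Operates on raw CT. The default dispersion is the mean absolute deviation
from the arithmetic mean CT (the original tool's characteristically small
"SD"), with the ordinary sample SD as an alternative since the name is
ambiguous; both appear in reports. Candidates with dispersion > 1 cycle
are flagged inconsistent and left out of the index but still ranked. The
index is the per-sample geometric mean CT of the retained candidates;
each gene is correlated with it (Pearson r, two-sided p from the t
transform with n − 2 df; zero-variance genes are flagged, not errors).
Ranking is ascending dispersion, ties broken by higher |r| then gene id.
Because dispersion is computed on raw CT, per-sample loading variation is
*not* removed by this method — unlike the three ratio/residual-based
methods, which are exactly loading-invariant (tested to 10⁻¹⁰).

## Comparative ΔCt and aggregation

The ΔCt score is the mean over partners of the SD of pairwise CT
differences. Under base-2 min-referenced quantities, log2(Q_j/Q_k) =
−(CT_j − CT_k) + const, so the score equals the one-shot geNorm M — an
identity the tests assert to 10⁻¹⁰. It is included in the aggregate by
default (the RefFinder convention) and can be excluded to reproduce a
strict three-method aggregate. Aggregation takes each method's integer
ranks (ascending score; documented tie-breaks) and sorts by their
geometric mean; genes unranked by some method use the geometric mean of
their available ranks rather than a worst-rank imputation, which would
penalize genes excluded for data reasons.

## ΔΔCt target validation

For a multi-gene reference set, the composite reference is the arithmetic
mean reference CT (geometric-mean quantity). RQ = 2^(−ΔΔCT) against a
calibrator sample (RQ = 1 exactly); supplying per-gene efficiencies
replaces each gene's base 2 by 1 + E/100 on the log2-quantity scale.
Biological replicates are summarised as mean ± SEM per condition.
`compare_normalizations` runs the same target against rival reference
sets and reports the maximum absolute log2 fold-difference between
profiles — the operational measure of how much the reference choice
distorts the target's story.

## Synthetic experiments

The generator draws CT_is = B_i + L_s + δ_i,c(s) + ε_is: per-gene baseline
B_i, per-sample loading L_s ~ N(0, σ_L²), per-gene per-condition bias
δ_ic (the "regulated housekeeping gene" failure mode, selected by design
fields, e.g. `stress=cold&timepoint_h=12`), and technical noise
ε ~ N(0, σ_i²), all on the CT scale where qPCR noise lives. Identical
spec + seed reproduces the table bit-for-bit. Ground truth designates the
stable set (no bias, minimal σ).

The default preset mirrors the okra design: 18 genes, 3 tissues × 3
stresses × 4 timepoints × 3 biological replicates (36 samples per stress,
108 total), baselines seeded uniformly over CT 17–33 (the spread of a
typical panel whose extremes sit near CT 16.6 and 33.9), loading
σ_L = 0.3 cycles, three designed-stable genes (HIS6, Eif, UBQ at σ = 0.2),
a σ ∈ [0.4, 1.2] noise ladder over the rest, a cold-induced TUB-a
(δ = −1.5 cycles at 6–24 h) and a drought-repressed GAPDH (δ = +1.2 at
12–24 h). These magnitudes are ordinary for plant stress qPCR: 0.2–0.3
cycles of technical noise, 1–2.5 cycles (2–6-fold) of regulation.

What the simulation does not emulate: fluorescence-level amplification
curves, per-sample efficiency drift, PCR inhibitors, CT-dependent
(heteroscedastic) noise, or missingness mechanisms. Passing recovery
tests therefore show the algorithms separate stable from unstable genes
*under the assumed additive model*, not that any particular real gene is
stable.

## Study sizes and numerical choices

Simulation-based checks are sized to run in seconds on one CPU while
keeping comfortable statistical margins: the aggregate-recovery study
uses 100 seeds of an 8-gene, 24-sample design (2 stable genes at σ = 0.15
among noisy σ ∈ [0.5, 1.2] and condition-biased δ = 1 genes; ≥95/100
required), the geNorm ladder study uses a geometric σ ladder 0.15–1.55
(ratio ≈1.6, so adjacent levels differ by ~4× the sampling error of an SD
at n = 40), the estimator-bias study uses 500 panels, and the NormFinder
recovery study uses 200 panels whose unstable genes carry non-constant
group-shift patterns — a constant offset in every group is, by the
model's own invariance, a *stable* gene, so instability must vary across
groups. The ΔΔCt divergence study uses technical noise of 0.05 cycles so
that the drift signal (1 log2 unit) dominates the noise floor by design.
Numeric output is written at 4 decimal places; all tie-breaks are
lexicographic and logged; every stochastic procedure takes an explicit
seed.
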