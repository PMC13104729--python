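# Methods

## Labeling model and estimator

`proteoturn` models deuterium incorporation into newly synthesised protein
as first-order rise-to-plateau kinetics of the relative isotopomer
abundance RIA = m1/(m0+m1). The estimator is deliberately the two-point
closed form, not a nonlinear fit: with baseline RIA_t0, window-end RIA_t1,
plateau RIA_plateau and protein abundance ratio P_t1/P_t0,

    f     = (RIA_t1 − RIA_t0) / (RIA_plateau − RIA_t0)
    k_deg = −ln(1 − f · P_t1/P_t0) / (t1 − t0)
    FSR   = 100 · k_deg   (%/h)

The plateau is 1 − 1/(1/(1−RIA_t0) + N·(DH_exp−DH_nat)), where N is the
peptide's total count of ²H-exchangeable H–C bonds. This parenthesization is
the unique reading consistent with two limits the model must satisfy, both
enforced bit-exactly in code and tests: N = 0 (or zero enrichment excess)
collapses the plateau to the baseline, and P_t1/P_t0 = 1 reduces k_deg to
the classic −ln(1−f)/Δt rise-to-plateau rate.

Assumptions: the precursor pool equilibrates quickly relative to the
labeling window (enrichment treated as constant at the media D₂O fraction);
turnover is first-order and at steady state apart from the explicit
abundance adjustment; m2 and higher isotopomers are ignored (the m0/m1 pair
carries the signal at low enrichment).

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| DH_exp | 0.04 | D:H ratio | 4% D₂O in the media, taken as precursor enrichment |
| DH_nat | 1.5576e−4 | D:H ratio | natural deuterium abundance (VSMOW) |
| t0, t1 | 12, 36 | h | labeling/analysis window |
| exchangeable H–C table | shipped CSV | per residue | standard literature values; editable data file, nothing hard-coded |
| ria_t0_mode | `control` | — | baseline from unlabeled (H₂O) samples; `first-timepoint` uses the labeled 12 h sample |

Whether the baseline should come from unlabeled controls or from the first
labeled time point is genuinely open in this design; both are implemented,
the mode actually used is recorded per record, and in the noise-free limit
the two coincide. Similarly, the abundance ratio is paired per replicate
(same condition, same replicate, 12 h vs 36 h) on the normalized matrix;
proteins without usable abundance fall back to a ratio of 1 and are flagged
`abundance_adjusted = False`.

### Validity flags

Records are flagged, not dropped or imputed: `zero isotopomer signal`
(m0+m1 = 0 or negative input), `no labeling headroom` (plateau ≤ baseline),
`RIA decreased` (f < 0), `labeling at/above plateau` (f·ratio ≥ 1, outside
the log domain). Only valid records enter the protein median, which is the
median FSR over unique peptides (peptides mapping to more than one
accession are excluded) with the even-count mean-of-central-pair
convention.

## Table handling

Inter-sample normalization scales each sample by one factor so that the
median protein-wise ratio to a reference sample is 1; the reference is the
sample whose median log-abundance sits at the overall median of sample
medians. This emulates the inter-sample abundance-ratio normalization of
label-free quantification software on tables; it is not a bit-exact clone.
Because the median of ratios is not transitive, re-selecting a reference on
already-normalized output could pick a different sample; the normalized
matrix therefore records its reference, and renormalizing against that
recorded reference yields factors of exactly 1 (the idempotency contract).
Zeros are measured values; missingness is an empty cell. Complete-case
filtering keeps only proteins quantified in every condition × replicate
cell, so no statistics ever rest on imputation.

## Statistics

One- and two-way fixed-effects ANOVA use the classical balanced
sum-of-squares decompositions, vectorized across proteins; the degenerate
all-constant case is defined as F = 0, p = 1, and zero within-group
variance with a real effect as p = 0. Both are cross-checked in tests
against scipy's `f_oneway`, statsmodels `anova_lm`, a label-permutation
p-value, and a loop-written sum-of-squares oracle. Treatment-vs-control
comparisons are 2-group ANOVAs (identically t²), run through the same
g-group code that serves the 3-condition mixed-FSR comparison.

Storey q-values estimate π₀ on the λ grid 0.05…0.95 (step 0.05) with a
cubic smoother extrapolated to λ = 1, clipped to (0, 1]; fewer than 10
p-values fall back to π₀ = 1. With π₀ = 1 the q-values are exactly
Benjamini–Hochberg (verified to 1e−10 against statsmodels). The smoother
variant was chosen over the bootstrap for determinism. Significance gates
downstream sets at p < 0.05 with q reported alongside.

Interaction clustering: proteins with condition×time interaction p < α are
clustered on z-scored condition×time cell-mean profiles by Ward linkage on
Euclidean distances, cut at k = 5 (configurable). The algorithm/linkage
choice is the conventional default for omics profile clustering and is
recorded in the output metadata. Rows are sorted by accession before
linkage and cluster ids assigned by descending size (ties by smallest
member accession), so the partition is independent of input order and
reruns are byte-identical.

Tukey HSD (scipy's studentized-range implementation) provides pairwise
treatment-vs-control p-values for subunit summaries; for two groups it
collapses to the pooled t-test.

## Ribosome profile

Candidates match the substring `ribosom` case-insensitively (catching
"ribosome" and "ribosomal"); subunits are assigned by a 40S/60S/28S/39S
token, which also fixes the compartment (cytosolic vs mitochondrial).
Candidates without a subunit token — typically biogenesis factors — remain
unclassified and are excluded from subunit summaries. Per (subunit,
condition, replicate) the summary is the median member FSR and the total
(sum; median available via config) member abundance at the window end;
condition-level percent change versus control uses replicate means.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets: 3
conditions × 3 replicates × 2 time points plus unlabeled controls, 4%
enrichment, ~0.9 %/h median baseline FSR with log-normal protein spread
(σ = 0.5 ln-units), tryptic-like peptide sequences (length 7–25, ending
K/R, 2–6 per protein), natural baseline RIA drawn uniformly in 0.25–0.45
(the realistic m1/(m0+m1) range for tryptic peptides of ~800–2500 Da), a
ribosomal subset (8% of proteins, split 40S/60S) with treatment synthesis
multipliers of 1.8 and end-of-window abundance gains of 17–18%, log-normal
peptide ion intensities (σ = 1 around 10⁶), and 5% multiplicative intensity
noise applied independently to m0 and m1.

The forward model is the exact algebraic inverse of the estimator,
RIA(t1) = RIA(t0) + (plateau − RIA(t0))·(1 − e^(−kΔt))/ratio, using the
*realized* normalized abundance ratios the analysis itself will compute.
Consequently, at zero intensity noise the pipeline recovers every true
k_deg to ~1e−14 relative error regardless of abundance noise or drift —
estimator correctness is testable independently of model misspecification.
An ODE-based labeling simulator is deliberately out of scope. Structure
(sequences, membership, rates) and noise draw from separate seeded streams,
so changing the noise level preserves the proteome, and (config, seed)
regenerates byte-identical files. Draws whose labeling would reach the
plateau are redrawn with a warning (bounded retries).

What the generator does *not* emulate: chromatographic interference,
charge-state splitting, missed-cleavage isotope effects, m2+ channels,
peptide-level ionization biases correlated within proteins, or biological
replicate-to-replicate variation in the true rates (replicates differ only
by measurement and abundance noise). Passing recovery tests therefore
demonstrates estimator and pipeline correctness under the stated noise
model, not robustness to every artifact of real LC–MS data.

## Measurement precision of the two-point estimator

A point worth making explicit, because it bounds what any pipeline can
recover under these study conditions: with 4% enrichment, ~0.9 %/h
turnover and a 24 h window, the expected RIA rise is only ≈ 0.06 absolute
(fractional rise f ≈ 0.19 of a ≈ 0.31 headroom). Independent 5%
multiplicative noise on m0 and m1 propagates to σ(RIA) ≈
RIA·(1−RIA)·0.05·√2 ≈ 0.016 at a natural baseline of 0.3 — i.e. roughly
30% relative error in k_deg per peptide-replicate measurement, plus a
shared per-peptide error of ~12% from the finite control baseline. A
median over 3 replicates × 3 peptides still carries ~10–15% error, so
under the default noise about half of protein–condition estimates land
within 10% of truth (the acceptance suite measures ≈ 0.50). Tight
per-protein accuracy at this enrichment requires either more peptides and
replicates, better than ~2% intensity CV, or longer labeling; group-level
contrasts (subunit summaries, condition medians) average this error away
and are recovered reliably, as the planted-effect tests show.

## Problem sizes

Tests and the acceptance script run at desk scale as the package's own
choice of problem size: 25–400 proteins with 1–6 peptides for pipeline and
recovery checks, 2000 proteins for null calibration, 50 seeds for
planted-effect detection, 10⁴ draws for closed-form grids. All sizes are
parameters of `SimConfig` and scale up unchanged.

## Known limitations

- The two-point closed form cannot flag model misfit the way a multi-point
  exponential fit could; aberrant peptides surface only through the
  log-domain validity flags and the robustness of the median.
- Normalization emulates ratio-based inter-sample scaling; outputs on real
  exports will differ slightly from vendor software.
- π₀ extrapolation by cubic polynomial can be unstable for small m or very
  non-uniform p distributions; it is clipped to (1/m, 1].
- Subunit summaries assume the provided descriptions contain the 40S/60S/
  28S/39S tokens; no orthology or accession-based lookup is attempted.
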