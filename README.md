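# proteoturn

Dynamic proteome profiling of protein turnover from deuterium-oxide (D₂O)
metabolic labeling. `proteoturn` takes post-quantification tables — peptide
mass-isotopomer intensities (m0, m1), protein abundances and a sample
design — and computes protein-specific fractional synthesis rates (FSR),
then runs the complete statistical layer used in treatment-versus-control
turnover studies of cultured muscle cells: per-protein ANOVA with Storey
q-values, condition×time interaction clustering, ribosomal-subunit turnover
summaries with Tukey post hoc contrasts, and synthesis–abundance
correlations. A ground-truth-known synthetic data generator makes every
stage testable by parameter recovery.

It is written for proteomics researchers who have already done peak picking
and label-free quantification upstream (e.g. in Progenesis QI) and need a
reproducible, scriptable implementation of the kinetics and statistics that
follow.

## The model

During labeling, newly synthesised peptides incorporate ²H at carbon-bound
positions, shifting signal from the monoisotopic (m0) into the first heavy
(m1) mass isotopomer. The relative isotopomer abundance

```
RIA = m1 / (m0 + m1)
```

rises from its natural baseline RIA_t0 toward a plateau fixed by the
peptide's number of exchangeable H–C bonds *N* (summed from a per-residue
standard table) and the precursor-pool enrichment excess:

```
RIA_plateau = 1 − 1 / ( 1/(1 − RIA_t0) + N·(DH_exp − DH_nat) )
```

The first-order turnover rate constant over a two-point window
(t₀ = 12 h, t₁ = 36 h by default), adjusted for the change in protein
abundance P across the window, is

```
f     = (RIA_t1 − RIA_t0) / (RIA_plateau − RIA_t0)
k_deg = −(1/(t1 − t0)) · ln(1 − f · P_t1/P_t0)        [h⁻¹]
FSR   = 100 · k_deg                                    [%/h]
```

Protein FSR is the median over the protein's unique peptides, per condition
and replicate. Records outside the log domain (RIA decrease, labeling at or
above plateau) are flagged and excluded from medians, never imputed;
proteins not quantified in every condition × replicate cell are removed
before statistics (complete-case filtering).

## Worked example

Simulate a small study (3 conditions VC/IBU/PEA × 3 replicates × 12/36 h,
4% D₂O, ribosomal proteins responding ~1.8× in synthesis) and run the whole
pipeline:

```
$ proteoturn all --out demo --seed 7 --n-proteins 120
isotopomer_rows: 9471
peptides: 451
peptide_records: 4059
peptide_records_valid: 3950
proteins_quantified: 120
proteins_complete_cases: 120
fsr_proteins: 120
abundance_proteins_complete_cases: 120
interaction_significant: 13
clusters: 5
ribosomal_candidates: 10
```

`demo/` now contains the peptide kinetics, protein FSR, contrast, cluster,
subunit and correlation tables. For example, the subunit-level percent
changes versus vehicle control (`demo/subunit_pct_change.csv`):

```
subunit,condition,metric,pct_change_vs_vc
40S,IBU,median_fsr,106.94177234452395
40S,PEA,median_fsr,114.36913994516593
40S,IBU,total_abundance,16.200479535187927
40S,PEA,total_abundance,18.68206281355099
60S,IBU,median_fsr,71.62005210737385
60S,PEA,median_fsr,104.46474677992757
```

reads: in this simulated study both treatments raised 40S/60S ribosomal
synthesis by roughly 70–115% and subunit abundance by ~16–23% relative to
control — the generator's planted effects (80% on synthesis, 17–18% on
abundance) recovered within sampling noise of a 10-member ribosomal set.
The corresponding Tukey-adjusted contrasts (`demo/subunit_contrasts.csv`)
flag all four synthesis increases at p < 0.05, and
`demo/correlations.csv` gives the per-treatment Pearson correlation of
log₂ fold changes in FSR versus abundance (here R² ≈ 0.18 for IBU,
0.20 for PEA).

The same stages are importable as a library (`proteoturn.kinetics`,
`proteoturn.tables`, `proteoturn.stats`, `proteoturn.ribosome`,
`proteoturn.simulate`, `proteoturn.pipeline`) for use on your own exported
tables; the expected CSV schemas are documented in
`proteoturn.tables` and `docs/methods.md`.

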