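# Methods

## Problem and model

Proximity labelling with an LC3B-fused APEX2 peroxidase biotinylates the
protein neighbourhood of autophagosomes. After proteinase-K digestion of
unprotected (cytosol-exposed) proteins and streptavidin enrichment,
label-free quantification (LFQ) compares vehicle-treated cells against
cells in which lysosomal degradation is blocked with bafilomycin A1
(BafA1). Genuine autophagosomal cargo accumulates under the block, so the
statistical task is a per-protein two-group comparison with three
field-specific complications this package models explicitly:

* **Left-censored missingness.** An LFQ value of 0 means "not quantified",
  and the probability of dropout rises as abundance falls (missing not at
  random). Treating zeros as measurements or dropping them biases fold
  changes; instead missing values are imputed from a downshifted
  distribution (below).
* **Spurious protection.** Some proteins resist proteinase K even with the
  membranes dissolved (RAPIGest detergent control). Such digestion-resistant
  proteins are not protected by autophagosomal membranes, so candidate sets
  are pruned by set difference against the control's candidate list.
* **Weak per-experiment power.** Candidates are called at raw p < 0.05 per
  experiment; correction for multiplicity happens only at the cross-
  experiment meta-analysis, where evidence is pooled before the
  Benjamini–Hochberg step.

## Pipeline stages and parameters

Stage order is fixed: flag removal → spectral-count filter → log2 →
imputation → background filter → t-test → proteinase-K exclusion → meta.
The background filter runs after imputation but uses the pre-imputation
observed mask, which is kept authoritative throughout; this is functionally
identical to filtering first.

**Spectral-count filter.** A protein needs MS/MS spectral counts summed over
the replicates of each condition group ≥ `min_msms_total` (default 3, i.e.
"more than two counts across the replicates"), in both groups. The wording
admits a per-replicate reading ("> 2 in every replicate"); the summed
reading is the laxer and more common inclusion rule and is the default, with
`mode="per_replicate"` available.

**Imputation** (`width_factor = 0.25`, `downshift = 1.8`, both unitless
multiples of each sample's observed sd). Each sample column's observed
values give a mean *m* and sample sd *s* (n − 1 denominator); missing
entries are independent draws from `Normal(m − 1.8 s, (0.25 s)²)`. The
"downshift in sd units" reading is the scale-free interpretation and matches
the Perseus downshifted-Gaussian convention this kind of analysis uses.
Imputation is per sample column (each sample has its own distribution), a
single seeded generator fills columns left to right and rows top to bottom
(bit-reproducible per seed), draws are not truncated, and a zero observed sd
degenerates to a point mass with a warning.

**Background filter** (`min_observed = 2`). Keep proteins with at least two
genuinely observed values within a single condition group, in any
experiment. Two is the count that makes a "both replicates in at least one
condition" rule literal; it is configurable. Proteins whose every value is
imputed are always removed.

**Differential test** (`alpha = 0.05`). Unpaired two-tailed equal-variance
Student's t (not Welch) on the imputed log2 values, df = n₁ + n₂ − 2;
imputed values participate. Candidates are exactly
{p < α} ∩ {log2FC > 0}. With zero pooled variance (identical groups) the
statistic is defined as t = 0, p = 1: such a protein carries no evidence.
No per-experiment multiple-testing correction is applied by design.

**Replicate QC.** Pearson correlations between within-condition replicate
pairs are computed on proteins genuinely observed in both members of the
pair; pairs sharing fewer than 3 such proteins report NaN.

**Meta-analysis** (`fdr_threshold = 0.05`). Signed Stouffer combination:
z_i = sign(log2FC)·Φ⁻¹(1 − p_i/2), so discordant experiments cancel;
weights are √n with n the experiment's TOTAL sample count (8 and 6 for the
default two-experiment design), not per-group n. p-values are floored at
1e-300 before the inverse normal to keep z finite. BH q-values are computed
across the intersection set only (proteins detected in every experiment),
by the standard step-up with q clipped at 1 and ties handled by the
min-over-suffix rule. More than two experiments are supported by the same
formulas.

## Synthetic data generator

`SimulationParams` defaults define the study conditions the pipeline
targets: 2000 proteins, 4 replicates per condition (repeat experiment: 3,
giving meta weights n = 8 and n = 6), 2% cargo spiked by
`cargo_log2fc = 2.22` log2 units under BafA1 (a 4.67-fold increase),
protein means `Normal(25, 3²)` on the log2 scale, replicate noise sd 0.5,
logistic dropout `P(observed) = 1/(1 + exp((22 − x)/1))` in true log2
intensity x, and spectral counts `Poisson(max(0, 0.5·(x − 22)) + 0.1)` when
observed. The logistic curve is the simplest missing-not-at-random model
consistent with left-censoring; at these defaults overall missingness is
roughly 10–20%, matching what the imputation stage assumes. The spectral-
count model exists solely so the inclusion filter has realistic behaviour.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide sharing, between-sample normalisation drift, correlated
(batch) noise, contaminant/decoy rows, and intensity-dependent variance.
Passing tests on synthetic data therefore demonstrate the statistical
machinery (calibration, recovery, determinism), not performance on any
particular real dataset.

## Numerical and design choices

* Protein identifier = first semicolon-separated accession of the majority-
  protein-ID column (deterministic; protein groups list many accessions).
* LFQ 0 and NaN cells are equivalent missing-value sentinels.
* The experiment design is a 4-column TSV (`sample_id`, `condition`,
  `replicate`, `experiment`); `dmso` is accepted as an alias for `vehicle`.
* Results TSVs serialise floats with 17 significant digits and are re-read
  with round-trip float parsing, so write→read is value-identical.
* Per-experiment imputation seeds are `config seed + experiment index`; a
  run manifest (seed, thresholds, versions) is written beside the results
  and, with the config, fully determines every output byte.
* The RAPIGest exclusion prunes candidate sets and the meta table; t-tests
  still run on all retained proteins, since the control identifies artefact
  *candidates* rather than invalid measurements.

## Problem sizes used in the test suite

Calibration and recovery checks run at 2000–4000 proteins with a fixed
seed: null type-I calibration uses the 99% binomial interval around α for
the two-tailed p < α rate (the directional candidate rate is about α/2
under a symmetric null and is checked against the interval's upper edge);
fold-change recovery uses ≥ 40 cargo proteins with dropout disabled and a
3-standard-error band; imputation moments use 10⁵ draws; the BH
implementation is compared exhaustively with a brute-force step-up oracle
on all grid vectors of length ≤ 6. The meta-analysis null FDR property is
additionally sampled at 500 proteins × 10 runs in the unit suite.

## Known limitations

* Equal-variance t-tests on partially imputed data understate uncertainty
  when many values in one group are imputed; the background filter bounds
  but does not eliminate this.
* No between-sample normalisation is applied (none beyond LFQ itself is
  assumed); systematic loading differences would propagate into fold
  changes.
* The weighted-Z meta-analysis assumes experiments are independent and
  two-tailed p-values are exact; heavily imputed proteins violate the
  second assumption mildly.
* Batch runs of more than two experiments use the same formulas but have no
  published reference behaviour to compare against.
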