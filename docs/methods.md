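# Methods

## The screen

`pgxscreen` looks for genes whose **basal expression** predicts how cancer
cell lines respond to whole **categories of drugs**, separately per cancer
subtype. The inputs are the four tables a CCLE/DepMap + GDSC-style resource
provides: a log2-scale expression matrix (genes × cell lines), a drug
response table with one AUC (area under the dose-response curve, in (0, 1];
higher = more resistant) per (drug, cell line), a drug catalog with curated
target-pathway categories, and cell-line tissue/subtype metadata.

The procedure:

1. **Curation.** Drug categories with overlapping target pathways are merged
   (defaults: EGFR signaling → ErbBs signaling, IGF1R signaling → RTK
   signaling, "Other, kinases" → Kinases); drugs without a usable category
   ("Other", "Unclassified", empty) are dropped; categories must retain at
   least `min_drugs_per_category` (10) drugs. Cell lines from blood, bone and
   soft tissue are excluded (solid tumors only). For each drug, cell lines
   lacking an expression profile are excluded, the remainder are stratified
   by tissue subtype, and any (drug, subtype) group with fewer than
   `min_lines_per_group` (10) lines is dropped. The number of distinct
   subtypes surviving this step, S, is fixed once per run.

2. **Correlation.** For every gene g and every (drug, subtype) group of size
   n, Pearson's r between expression and AUC is transformed to

       z = atanh(r) · √(n − 3),

   the variance-stabilized Fisher transform. Under the null z is
   approximately standard normal *whatever n is*, which is what makes a
   single cutoff comparable across groups of different size. |z| ≥ `z_cutoff`
   (default 1.7) is called significant; z ≥ +cutoff flags a resistance
   association, z ≤ −cutoff sensitivity. The two flags are mutually
   exclusive by construction.

3. **Global score.** For each (gene, category, direction),

       Score_global = 100 · n_sig / (n_drugs · S),

   where n_sig counts significant records of that direction among the
   category's drugs across all subtypes, n_drugs is the **full** curated
   category size and S the run-wide subtype count. Untested (drug, subtype)
   combinations therefore count as non-significant, making scores
   conservative. Sensitivity (Sen-Score_global) and resistance
   (Res-Score_global) grids are computed independently. A score is called
   significant iff it strictly exceeds the (1 − `score_tail`) quantile
   (default: upper 5%) of the score distribution over **all** genes ×
   categories for that direction — the screen is calibrated genome-wide,
   then a gene panel of interest is read off against that threshold.

4. **Subtype contributions.** For a (gene, category, direction), each
   subtype's contribution is the percentage of the category's drugs *tested*
   in that subtype (valid, finite correlation) that carry the flag. The
   per-subtype numerators sum exactly to the global n_sig. The tested-drug
   denominator (rather than the full category size) is used because subtypes
   differ in drug coverage; both counts are reported so either convention
   can be recovered.

5. **Clustering.** Score and z matrices are clustered row- and column-wise
   with Euclidean distance and unweighted average linkage (UPGMA) — common
   clustermap defaults; both are configurable. Labels are sorted before
   linkage so results are invariant to input order, with distance ties broken
   by label order. Missing cells (drug untested in a subtype) are filled
   with 0 — "no evidence" — for the distance computation only.

## Null calibration

The fixed cutoff 1.7 corresponds to a two-sided standard-normal tail mass of
2·(1 − Φ(1.7)) ≈ 0.089. As an optional validation, `permutation_null`
shuffles AUC values within each (drug, subtype) group (expression fixed),
recomputes z exactly as in the observed analysis, and `empirical_cutoff`
returns the (1 − 2·`tail_mass`) quantile of |z|. With `tail_mass = 0.0446`
on well-behaved data this lands near 1.7, confirming that the √(n − 3)
scaling renders z approximately standard normal. The within-group shuffle
was chosen because it preserves each group's expression structure and AUC
marginal; the randomization unit and tail mass are config keys
(`n_perm`, `tail_mass`, `calibrate`).

## What the synthetic generator does and does not emulate

`generate_dataset` draws expression as Normal(per-gene mean, `expr_sd`)
truncated at 0, with per-gene means uniform in [1, 8] log2 units — the
dynamic range of typical log2(TPM+1) data. AUC is built from a latent
standard-normal signal u mapped affinely to `auc_base_mean` + `auc_base_sd`·u
(defaults 0.85 and 0.08: a resistant-skewed, GDSC-like marginal) and clipped
into (0, 1]. Planted effects replace u for the affected (drug, subtype)
groups by

    u = target_r · standardize(expr_g) + √(1 − target_r²) · noise,

so the population correlation equals `target_r` before clipping. Effects are
planted at the correlation level rather than through dose-response
simulation because the analysis consumes AUC only — the correlation
structure is the sufficient statistic. Drug→category assignment is a
deterministic block partition, so `planted_truth` enumerates the affected
triples from the config alone.

With the default AUC scale, about 2–3% of draws exceed 1.0 and are clipped;
the generator warns whenever more than 1% of values are clipped, since heavy
clipping attenuates planted correlations (at `target_r = −0.6`, n = 25 the
empirical r still lands within ±0.25 of the target for well over 80% of
affected pairs).

Not emulated: dose-response curves and IC50s, measurement batch effects,
expression correlation between genes (genes are independent draws),
tissue-driven expression structure, and missingness patterns of real
screens. Passing tests on synthetic data therefore demonstrate the
*statistical machinery* — calibration, counting, thresholds, recovery of
known structure — not robustness to real-data artifacts such as confounded
lineages or heteroskedastic AUC noise.

## Numerical choices and degenerate inputs

- r is clamped to ±(1 − 1e−7) before atanh, so perfect correlations (common
  in tiny fixtures) give a large finite z rather than an error or infinity.
- Zero-variance expression or AUC within a group yields NaN r/z with both
  significance flags false; the record is retained so the drug still counts
  toward the score denominator ("tested, not significant") but is excluded
  from a subtype's tested-drug count.
- Quantiles (score cutoff, empirical z cutoff) use numpy's default linear
  interpolation; score significance is a *strict* inequality, so an
  all-equal score distribution calls nothing significant.
- Groups need n ≥ 3 for r and n ≥ 4 for z; the cohort default of 10 lines
  keeps well clear of both.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + inputs give identical outputs, byte-for-byte for the generator.

## Problem sizes

Unit and acceptance tests run on generated data at desk scale: the null
calibration uses 100 genes × 25 drugs × 4 subtypes × 30 lines (10,000
records); the planted-recovery study uses 200 genes × 60 drugs (three
20-drug categories) × 6 subtypes × 25 lines per subtype, 50 independent
seeds, with the score threshold taken genome-wide over all 200 genes. These
sizes give Monte-Carlo error comfortably inside the asserted bands while a
full run stays in the tens of seconds.

## Known limitations

- No multiple-testing correction at the per-correlation level; the method is
  a group-level screen (many weak correlations aggregated per category), not
  a detector of individual drug–gene pairs.
- The subtype roster is data-driven; results depend on the metadata's
  subtype granularity.
- Cluster adjacency conclusions depend on the metric/linkage choice; only
  the Euclidean/UPGMA defaults are exercised.
- Identifier matching is exact (normalized) string equality; no fuzzy
  cell-line name reconciliation across resources.
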