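# Methods

`dyadshare` implements a mother–infant gut-microbiome sharing analysis at
three resolutions — species presence, strain identity, and functional
(pathway) capacity — together with the statistics used to compare dyads
across multiple cohorts and a machine-learning harness that predicts sharing
in infants from maternal profiles. Because the real inputs are large
multi-cohort shotgun-metagenomics profile collections, the package ships a
synthetic cohort generator with known ground truth so that every stage is
testable end to end.

## Sharing model

A *dyad* is a matched mother–infant pair. A feature (species or pathway) is
*shared* by a dyad when its relative abundance is strictly positive in both
the mother's delivery-window sample and an infant sample, irrespective of
abundance. Mothers are represented at delivery by the windowed sample
nearest birth (smallest postnatal day, ties by sample id); dyads without a
delivery-window maternal sample are excluded. The *shared fraction* is
infant-referenced by default (shared count / infant feature count), because
the question posed is how much of the infant's community is of maternal
origin; a mother-referenced fraction is available. A dyad-level sharing
verdict aggregates over infant timepoints: shared at ≥ 1 timepoint counts.

The *core shared set* across a meta-analysis is the set of features shared
in at least `min_dyads_per_study` dyads (default 1) within **every** study.
This is monotone non-increasing in the threshold, which the tests assert.

Sampling days are discretized into the usual early-life bins — infants:
birth (0–1 d), 1 wk. (2–7), 1 mo. (8–30), 3 mo. (31–90), 6 mo. (91–180),
12 mo. (181–480); mothers: pregnancy (gestational days 189–224), delivery
(postnatal 0–7), postpartum (8–480). Days outside every range are labelled
`unbinned` and excluded from bin-stratified analyses. The day scale
(gestational vs postnatal) disambiguates maternal samples.

## Strain-level transmission calling

Each species contributes one aligned marker-gene SNP haplotype per sample
(the dominant strain, StrainPhlAn-style output; within-sample strain
mixtures are out of scope). Pairwise p-distances use pairwise deletion
(both-non-gap columns only). A neighbor-joining tree is built per species
from the p-distance matrix (scikit-bio's NJ; negative branch lengths are
clamped to zero); a user-supplied newick tree is accepted instead, so an
externally built maximum-likelihood tree can be dropped in unchanged.

The *strain distance* of a mother–infant pair is the patristic distance
between their leaves divided by a tree-wide normalizer. The default
normalizer is the maximum leaf-pair patristic distance, which bounds values
in [0, 1] and makes a fixed threshold meaningful; total branch length and
the median pair are selectable alternatives. Transmission (a *shared
strain*) is called when the normalized distance is **strictly below 0.1**;
a pair at exactly 0.1 is distinct. Species with fewer than three haplotypes
fall back to the p-distance normalized by the species' maximum pairwise
p-distance. Species absent in either member yield no call rather than a
negative call.

**Known limitation.** Max-pair normalization requires between-strain
diversity on the tree. If every haplotype of a species descends from a
single lineage (e.g. one carrier mother and her infant), the normalizer is
on the within-strain noise scale and a genuinely transmitted pair can
normalize near 1. Such degenerate species are rare in multi-cohort data but
the caller does not special-case them; analyses that need a guarantee
should require ≥ 2 lineages (or ≥ 2 carrier subjects) per species.

Within-subject strain stability is measured as haplotype similarity between
all cross-timepoint pairs of the same subject, stratified intra-mother vs
intra-infant; species enter the comparison only with ≥ 10 comparisons in
both strata, and per-species Wilcoxon rank-sum p-values are BH-corrected.

## Community statistics

* Alpha diversity: richness (features > 0), Shannon (−Σ p ln p, natural
  log), and Simpson reported as Gini–Simpson 1 − Σ p² (the variant is a
  choice; both conventions exist).
* Bray–Curtis dissimilarity Σ|p−q| / Σ(p+q); PCoA is classical MDS of the
  Gower-centered −½D² (scikit-bio), with negative-eigenvalue axes reported
  but dropped from coordinates.
* The two-group test blocked by study is the van Elteren form of the
  Wilcoxon rank-sum test: per block, mid-ranks are computed and the rank sum
  of group 1 is centered by its permutation mean; blocks are combined as
  Σ_b (W_b − E[W_b]) / √(Σ_b Var[W_b]) with the tie-corrected
  sampling-without-replacement variance, and a two-sided normal p. With one
  block this is exactly the tie-corrected rank-sum normal approximation.
  The k-group version builds the stratified Kruskal–Wallis chi-square from
  the same within-block rank moments (generalized-inverse quadratic form,
  k − 1 df); with two groups its p equals the Wilcoxon p. Both offer an
  exhaustive within-block permutation option for small blocks, which the
  tests verify against independent enumeration to 1e-9.
* Multiple testing uses Benjamini–Hochberg step-up q-values (statsmodels).
* Differential abundance tests **all** features (blocked Wilcoxon per
  feature, BH across the tested set); the prevalence/mean-abundance filters
  are applied for reporting only, as a `reportable` flag.
* PERMANOVA partitions the squared-distance matrix adonis-style:
  pseudo-F = (SS_between/df_b)/(SS_within/df_w), R² = SS_between/SS_total,
  with unrestricted label permutation (1000 by default) and
  p = (1 + exceedances)/(1 + permutations). The pseudo-F is cross-checked
  against scikit-bio's implementation in a test. The covariate variance
  scan runs one univariate PERMANOVA per (infant time bin × covariate) on
  Bray–Curtis of the shared-species subtable, drops samples missing the
  covariate, excludes a covariate in a bin when any group has fewer than
  three samples, skips bins with fewer than six samples, and BH-corrects
  across the scan.

## Covariate associations

Per-feature abundances (fractions) are variance-stabilized with
asin(√x) and modeled by ordinary least squares on the target covariate plus
fixed-effect adjusters (clinical covariates, infant age in days, sequencing
depth; numeric adjusters z-scaled). Categoricals are one-hot encoded against
fixed reference levels (vaginal, exclusive breastfeeding, no antibiotics,
normal BMI, …) so coefficient signs read as the effect of the non-reference
condition. Aliased design columns are dropped (target columns protected);
zero-variance features are skipped. The target coefficient's t-test
p-values are BH-corrected across features and q < 0.25 is flagged as
reported. The boosted feature-selection step of the original MaAsLin
procedure is deliberately not reproduced — the reported quantity is the
additive linear-model coefficient, and the selection heuristic is a
pre-filter; this is a documented fidelity gap.

## Prediction harness

For each admissible target (both label classes present in every study), a
classifier predicts the dyad's sharing label from the mother's
delivery-window species profile. Models: random forest with 1000 trees
(`mtry` at the classification default √p) and stochastic gradient boosting
(interaction depth 1, 100 trees, shrinkage 0.1, minimum 5 observations per
leaf). Evaluation is leave-one-study-out; performance is rank-based
(Mann–Whitney) AUC with ties counted ½. Feature filtering — caret-style
near-zero-variance (frequency ratio > 95/5 **and** unique fraction < 10%,
plus zero variance) followed by greedy |r| > 0.9 correlation removal — runs
on the training folds only by default; a pooled-filter option reproduces
the alternative of filtering once on the full maternal matrix (no label
leakage, but test-study marginals inform the filter). A poisoned-column
test asserts the no-leakage property. The top-k curve reranks features by
mean decrease in GINI on each training fold and retrains on the top k. The
R gbm notion of selecting the tree count by internal 5-fold CV has no
scikit-learn equivalent; the tree count is fixed at 100 instead.

## Synthetic cohort generator

The generator emulates the four inputs (species table in MetaPhlAn2 merged
dialect, pathway table in HUMAnN2 joined dialect with `|g__X.s__Y`
stratified rows, per-species aligned haplotype FASTA, metadata TSV) under a
transparent generative model; every distributional choice is a config
field, not a constant.

* **Strains.** Per species, one ancestral 1000-site sequence; a pool of 48
  population strains, each the ancestor mutated at the between-strain
  divergence (default 0.05/site). 1000 sites put the p-distance resolution
  (0.001) well below the threshold scale; 48 strains keep coincidental
  strain identity between unrelated hosts (~1/48 ≈ 2%) safely below the 5%
  false-call budget while remaining cheap to simulate.
* **Transmission.** A mother carries a species with its configured
  prevalence and hosts one strain. A carried species seeds her infant with
  probability `transmission_prob` (default 0.6), multiplied by
  `delivery_effect` for C-section births; the transmitted haplotype is the
  maternal strain mutated at the within-strain rate (default 0.001/site).
  Otherwise the infant may acquire an unrelated pool strain environmentally
  (`prevalence_infant_base`, scaled by `feeding_effect` for non-exclusive
  breastfeeding), detectable from a uniformly drawn acquisition day within
  the first year — so infant repertoires, and with them shared-species
  counts, grow with age. Every emitted haplotype adds i.i.d. per-sample
  noise at the within-strain rate; mothers switch dominant strains between
  timepoints with probability 0.15 per interval (infants 0, mirroring the
  higher longitudinal stability observed in infants).
* **Abundances.** Log-normal per carried species, renormalized to sum 100
  per sample (percent convention). A sample that would otherwise carry
  nothing has its earliest-acquired species forced detectable — stools are
  never sterile.
* **Pathways.** Pathway abundance = Σ carrier-species abundance ×
  per-species weight. Ten core pathways are carried by every species and
  each species adds ~6 accessory pathways, which couples function to
  taxonomy and forces the shared-pathway fraction to sit above the
  shared-species fraction, the ordering the functional-overlap analysis
  expects.
* **Design.** Defaults: 3 studies × 30 dyads, infants sampled at days 3,
  30, 120 and 330, mothers at postnatal days 0 and 60; P(C-section) = 0.3,
  P(exclusive breastfeeding) = 0.6; the remaining clinical covariates are
  drawn independently with plausible frequencies. Identical (config, seed)
  produces byte-identical output files.

**What the generator does not emulate:** read-level noise and depth effects,
within-sample strain mixtures, compositional correlation structure between
species, temporal strain replacement beyond i.i.d. switching, and a species
pool of realistic size. With only 12 species and high maternal prevalence,
infant-referenced shared fractions run far higher (~0.7–0.97) than in real
cohorts; passing tests therefore demonstrate correctness of the machinery
and recoverability of injected effects, not real-data effect sizes.

## Problem sizes and numerics

The test suite and the acceptance script run the pipeline at 3 studies ×
30–50 dyads (up to ~600 samples, ~2,000 evaluable strain calls), sizes at
which every property is already stable: ground-truth recovery of
transmission calling (recall/precision ≥ 0.95, estimated frequency inside
the exact binomial 95% CI of the configured 0.6), oracle equivalence of the
exact blocked test / NJ / PCoA / BH / AUC (1e-9), null calibration of
differential abundance, PERMANOVA and LOSO AUC, and recovery of an injected
delivery-mode effect by the variance scan, the association model and
stratified prediction. Ties take mid-ranks everywhere; permutation p-values
include the observed statistic (+1/+1); every stochastic operation takes an
explicit seed.
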