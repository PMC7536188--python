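# Methods

This note documents the models, numerical choices and limitations behind
`enoc-strat`. It is written for a reader who wants to know what each
component assumes, not how to call it (see the README for usage).

## Variant representation and consensus

Coordinates are 1-based and fully closed throughout. A variant key is
`(chrom, pos, ref, alt)` after parsimony trimming: shared allele suffix
bases are removed first, then shared prefix bases (advancing `pos`), so
equivalent spellings of the same InDel produced by different callers
collide on one key. Trimming may leave an empty allele for a pure
insertion or deletion; keys are internal identifiers, not VCF records.
Full left-alignment *through* a repeat run would require the reference
genome, which is not an input; consequently two spellings of an InDel
anchored at different points of a long homopolymer are only merged when
their flanking context is included in the alleles. Multi-allelic sites
are split and voted per alternate allele.

Consensus keeps keys supported by at least `min_callers` (default 2,
majority of three). `min_callers = 1` is the union of the call sets and
`min_callers = n` the intersection; tests verify this set-algebra
equivalence on random inputs.

## Filtering cascade

Quality filters are evaluated in a fixed order — depth < 20×, VAF < 10%
(boundary kept: VAF exactly 0.10 passes), population allele frequency
≥ 1% (the conventional common-variant cutoff; no explicit threshold was
available), orientation-bias artifact flag — and each removed variant is
tagged with its *first* failing reason so removal counts are additive for
flow-style reporting. The cascade is idempotent.

The functional filter applies a rule table: ClinVar pathogenic always
kept, ClinVar benign always dropped (including truncating variants with
an explicit benign assertion), synonymous dropped, truncating classes
(nonsense, frameshift, splice-site) kept, missense dropped only when
PolyPhen says benign *and* SIFT says tolerated, and anything with missing
predictions kept. Orientation-bias artifact detection itself needs
read-level data and is consumed as a per-variant boolean flag, not
re-implemented.

## Per-sample metrics

- **TMB** is the count of distinct variant keys after filtering.
  Hypermutated means TMB > 250, ultramutated TMB > 1000 (boundaries
  exclusive, so 250 is normal and 251 hypermutated).
- **MSI score** counts InDels with length difference 1–5 bp. "Short" is
  set at ≤ 5 bp and is configurable; the score is computed after the
  quality cascade but *before* the functional filter, since instability
  InDels are mostly passengers the functional filter would discard.
- **Substitution spectrum**: the twelve single-nucleotide changes are
  collapsed onto the six pyrimidine-reference classes (C>A, C>G, C>T,
  T>A, T>C, T>G); fractions sum to 1 and the spectrum is invariant to
  complementing every ref/alt pair.
- **MMR status** uses the eight-gene panel MLH1, MLH3, MSH2, MSH3, MSH4,
  MSH6, PMS1, PMS2 (configurable); any frameshift/nonsense/splice-site
  hit is high-impact, otherwise any hit is missense-only.
- **Copy-number calling** is a deliberate z-score simplification: given a
  precomputed genes × samples score matrix and a reference population
  (pooled *TP53*-wild-type samples in the intended use), a gene is a
  gain/loss in a sample when |z| > 5 reference standard deviations with
  two-sided normal p < 0.05. Genes with zero reference variance are
  skipped with a warning. Coverage-model internals of dedicated CNA
  pipelines are out of scope; the caller's false-positive behaviour is
  checked against 2·Φ(−threshold) on null data.

## Genomic complexity

MATH = 100 × MAD/median over a sample's VAFs, with MAD scaled by 1.4826
(normal consistency). It needs ≥ 2 VAFs and a positive median; otherwise
a not-computable signal distinct from 0 is raised. MATH is invariant to
rescaling all VAFs by a positive constant.

VAF peaks are counted by fitting 1-D Gaussian mixtures for k = 1..5 to
VAFs inside the clonal window (0.05, 0.75) — the upper clip keeps
LOH/copy-number-driven frequencies from dominating — selecting k by BIC
with ties resolved toward smaller k, and counting components with mixture
weight ≥ 5% (weights renormalised after the floor). Fits use k-means
initialisation with a fixed seed and `reg_covar = 1e-6` as a jitter guard
for near-constant VAFs, and are bit-reproducible given the seed. Fewer
than 10 in-window VAFs yields a degenerate single-peak result flagged
low-confidence. These peak-calling parameters are a declared rule, not a
claim of equivalence to any particular published heterogeneity tool.

The complexity threshold used by the classifier is the median MATH score
among samples with a single VAF peak.

## Stratification

Clustering follows a two-step recipe: the n × n product-moment
correlation matrix between sample binary mutation vectors is computed
(samples with zero-variance vectors get correlation 0 to all others, with
a warning), and each sample's *row of that correlation matrix* is then
the feature vector for agglomerative clustering with Euclidean distance
and Ward linkage. Clustering the raw binary matrix instead is available
behind a flag. Labels are reported at k = 2 and k = 3 and the full
dendrogram is exported as Newick text.

Pairwise association uses Fisher's exact test when any expected cell
count is below 5 and the chi-square test otherwise (the Fisher p-value is
always reported alongside); degenerate margins give p = 1 with an
undefined odds ratio. Swapping the two genes transposes the table, so the
p-value and odds ratio are both invariant. In pairwise scans the
Bonferroni family is the number of gene pairs tested.

The PRISTINE classifier is a total step-wise function: (1) *TP53*-mutant
wins regardless of *CTNNB1* (the rare co-mutant is grouped with the
TP53m subtype, consistent with the TP53-first taxonomy); (2) else
*CTNNB1*-mutant; (3) else MATH ≤ threshold → low complexity, MATH >
threshold → high complexity; (4) unresolved when complexity is
unavailable. Every call records the ordered rule trace.

Cross-tabulations exclude missing values from denominators ("evaluable
cases") and report row percentages at one decimal place.

## Survival

DSS treats death from disease as the event; other deaths are censored at
the death date. Kaplan–Meier intervals use the exponential Greenwood
(log-log) transform. Median follow-up is the reverse Kaplan–Meier median
(censoring inverted to the event); an unreached median is reported as
open-ended (infinity). Cox models use Efron tie handling, dummy-coded
group factors, listwise deletion of incomplete records (the n actually
fitted is reported), and stage entered as I/II vs III/IV in multivariable
models. A group level with no events produces monotone likelihood; the
affected terms are flagged non-estimable rather than reported as huge
hazard ratios. Mann–Whitney comparisons use the exact null distribution
for small tie-free samples and the tie-corrected normal approximation
otherwise; Bonferroni adjustment multiplies by the family size and caps
at 1.

## Synthetic cohorts

The generator encodes the cohort structure the analysis assumes, with
defaults fixed to the study conditions:

- 112 samples; driver gene frequencies CTNNB1 0.429, PIK3CA 0.429,
  ARID1A 0.357, PTEN 0.295, KRAS 0.259, TP53 0.259, SOX8 0.188,
  POLE 0.063.
- TP53 × CTNNB1 drawn jointly from an exclusivity table with co-mutant
  probability 1/112 (28/112 TP53-only, 47/112 CTNNB1-only, 36/112
  neither); the table is validated before sampling.
- MMR mutation conditional on POLE: 5/7 given POLE-mutant, 15/105
  otherwise (marginal ≈ 0.179); half of MMR-mutant samples carry a
  high-impact lesion, which raises their InDel fraction from 0.12 to
  0.35 so MSI scores separate by MMR class.
- TMB ~ negative binomial (dispersion 4, baseline mean 77.5 so that the
  cohort median including the tail is 78), multiplied ×6 for POLE-mutant
  or high-impact-MMR samples and ×20 for concurrent POLE+MMR, floored at
  20. This yields ≈ 8% hypermutated and ≈ 3% ultramutated samples.
- VAF architecture by subtype: TP53-wild-type samples are single-clone
  (one Beta component centred at 0.42); TP53-mutant samples draw 2 or 3
  clones (components at 0.42/0.18 or 0.45/0.25/0.12) with concentration
  160. Read depths are Poisson around a per-sample lognormal coverage
  with median 89.5×, and observed VAFs are binomial resamples of the true
  clone VAF.
- Survival: exponential per-subtype hazards anchored to the printed
  effect sizes — TP53m rate ln 2 / 3.78 per year (median DSS 3.78
  years), TP53wt/CTNNB1wt 0.37× that, CTNNB1m a further 0.31× — which
  implies a TP53m-vs-rest rate ratio of ≈ 4.4. Censoring is independent
  exponential (rate 0.055/year) plus an administrative cap at 25 years,
  giving roughly half the cohort censored.
- Stage, residual disease and concurrent-endometrial indicators are
  per-subtype Bernoulli at the printed subgroup rates; joint
  distributions not printed anywhere (e.g. stage × RD within a subtype)
  are filled by conditional independence, which is not identifiable from
  the published tables.

What the generator does **not** emulate: mutational signatures beyond a
C>T/C>A-rich class bias, copy-number segments (only per-gene scores),
read-level data, FFPE artifact structure, and correlation between TMB
and survival within a subtype. Passing recovery tests therefore
demonstrates that the pipeline's estimators recover the structure they
target under these idealised conditions — not that they would do so
against every artefact of real FFPE exome data.

The **fixture cohort** is a static 112-sample table whose marginal and
joint counts reproduce the published cross-tabulations (29 TP53m, 48
CTNNB1m with one co-mutant, SOX8 10/29 vs 11/83, 20 MMRm with 18 TP53wt,
7 POLEm with 5 MMRm, stage III/IV 14/29 vs 10/81 with 2 stage-missing,
macroscopic RD 12/27 vs 11/78 with 7 RD-missing, concurrent endometrial
1/29 vs 18/83, CTNNB1m subgroup 41/46 stage I/II and 40/46 zero-RD). The
published count for the last cell is internally inconsistent with its
published percentage (87.0%); the fixture encodes the percentage, which
is what validation checks. Missing stage/RD placements are deterministic
and chosen to preserve every evaluable denominator. Survival columns are
deterministic and ordered so the TP53m group has the poorest outcome;
they make survival code paths exercisable but are not calibrated to the
published hazard ratios, whose recovery is validated by simulation
instead. The fixture is validated against the full count table on every
construction, and the packaged CSV is tested for equality with the
constructor.

## Problem sizes used in validation

The hazard-ratio recovery study uses 200 replicate cohorts of n = 500
with a true hazard ratio of 4.43 (two-rate design: exposed group at
4.43× the reference rate, exposure probability 29/112); we report the
mean fitted ln HR and the empirical 95% CI coverage. MATH recovery uses
100 cohorts of 20 single-clone plus 20 multi-clone samples with 80 VAFs
each. Planted-partition clustering uses 50 cohorts of 24 samples over 16
genes in two disjoint blocks; CNA recovery plants three 8-SD
amplifications in a 500-gene, 30-reference-sample matrix. These sizes
give stable pass/fail behaviour at sub-minute runtimes.

## Known limitations

- Tumour-only design: no germline subtraction; common-variant and
  functional filters stand in for a matched normal.
- The CNA caller assumes approximately normal per-gene reference scores;
  heavy-tailed scores inflate calls.
- VAF-peak counting is resolution-limited: clones closer than roughly
  the binomial sampling noise at the observed depths merge into one
  component.
- Cox models assume proportional hazards; the generator's mixed "rest"
  group under the default survival rates violates this mildly, which is
  why the recovery study uses the two-rate design.
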