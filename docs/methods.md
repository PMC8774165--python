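# Methods

This note documents the models, conventions, and numerical choices behind
`comut`, and what the synthetic-data checks do and do not establish.

## Co-mutation enumeration

Entities are genes (gene level) or exact variants `(chrom, pos, ref, alt)`
(position level).  A subject contributes 1 to a pair's count when it carries
both entities, regardless of multiplicity; position-level pairs are counted
per subject, not per instance (consistent with the gene-level definition).
Pair frequency divides by the **full cohort size**, including subjects with
zero mutations — the frequency is "fraction of subjects harboring the pair"
with no exclusions.  The default threshold is `min_freq = 0.10`; a count
qualifies when `n_co / n_total ≥ min_freq` (evaluated with a 1e-9 slack so
exact boundary counts pass).

Enumeration is per subject with an accumulator keyed by the canonical pair
(lexicographic gene ids; natural chromosome order, then position, ref, alt
for variants), after a marginal prescreen: a pair can reach the threshold
only if both entities do marginally.  This avoids the quadratic
all-genes × all-genes loop; correctness is checked exactly against a
brute-force all-pairs oracle on random cohorts.  Same-gene position pairs
are emitted with a `same_gene` flag and excluded from cross-gene statistics,
keeping both behaviors separable.  Coordinates are 1-based inclusive
throughout (MAF and GTF agree); indel positions are the leftmost affected
reference base; duplicate identical mutation rows are deduplicated with a
logged count so frequencies count subjects once.

## Survival screen

Each entity (pair, single gene, or the continuous per-subject mutation
count) is fit with a single-covariate Cox proportional-hazards model.  The
solver is an in-package Newton iteration on the partial likelihood with the
**Efron** tie correction, step-halving, and Wald inference
(`se = information^-1/2`, 95% CI `exp(β ± 1.96·se)`).  It converges to the
same optimum as R's `survival::coxph` at `eps = 1e-12` (agreement to ~12
digits) and is cross-checked against lifelines in the test suite; a
hand-rolled solver is used because screens fit 10⁴+ models and per-fit
overhead dominates otherwise.  Monotone likelihoods (binary covariate with
all events in one group, |β| > 30, or non-positive information) return a
non-converged signal rather than a number.

Tiers: *imbalanced* — exactly one group has zero events and the other at
least `min_events = 10` (configurable; the rule is empirical because the HR
diverges); *significant* — BH-adjusted p < 0.05 (strict); *marginal* —
adjusted p in the **closed** interval [0.05, 0.1] (the boundary 0.05 is
marginal, not significant).  Imbalanced entities carry no valid p and are
excluded from the BH family, which is the set of converged fits within one
cohort's screen (the narrowest defensible family; recorded here because the
choice is otherwise invisible in output).  "Adds value over singles" uses
unadjusted p values (pair and single screens have different family sizes):
p-tier pairs must beat both singles strictly; imbalanced pairs add value iff
both single-gene mutant groups have ≥ 1 event.  Cohorts of ≤ 50 subjects are
refused (`min_cohort_size = 51`); screens with zero events are skipped with
a log entry.

## Phenotype screens

Families per variable: age — OLS of phenotype on status (Wald p on the
slope); sex — logistic regression with male coded 1, female 0; race —
multinomial regression with the most frequent category as reference and a
likelihood-ratio test of the whole status term against the intercept-only
model (one decision per pair).  Missing phenotype values are dropped per
test, never imputed; a screen requires ≥ 80% coverage.  Degenerate fits
(constant status or phenotype, separation, non-convergence) are flagged and
excluded from the BH family.  "Stronger than singles" means the pair's
unadjusted p is strictly smaller than both single-gene p values; equality is
not stronger, and a missing single-gene result yields false.  Note that a
mutant group containing only one sex is separation: the logistic MLE
diverges and the result is reported degenerate, not as an infinite log-odds.

## Dip test for load multimodality

The dip statistic is the smallest sup-norm distance between the sample's
empirical CDF and any unimodal CDF (convex below the mode, concave above,
an atom allowed only at the mode).  It is computed by binary search on that
distance: for a fixed band width, the empirical CDF induces vertical boxes
at the unique sample values, a convex nondecreasing path must thread the
boxes left of some mode (feasible iff the greatest convex minorant of the
upper bounds stays above the lower bounds, with the left tail anchored at
0), a concave path right of it (by reflection), and the convex piece's
minimal end value must not exceed the concave piece's maximal start (the
mode atom absorbs any upward jump; minimal/maximal values come from
chord-slope extrapolation of the box bounds).  Mode candidates are the
sample values.  The implementation reproduces known anchors (0.25 for two
equal point masses, 1/(2n) for equispaced distinct data, 0 for a point
mass) and agrees with an independent linear-programming formulation of the
definition to < 1e-6 on random samples with ties; binary-search resolution
is 1e-9.

p-values are Monte-Carlo calibrated against the uniform null — the standard
reference for the dip, and conservative for lighter-tailed unimodal data —
with 2000 replicates by default, `p = (1 + #{null ≥ obs}) / (B + 1)`, and a
null table cached per (n, B, seed).  Across cohorts, p-values are
BH-adjusted; cohorts under 10 subjects are skipped with a log entry.  The
top-mutated-genes table averages gene frequencies across cohorts
unweighted, imputing 0 where a gene is absent from a cohort's table, with
lexicographic tie-breaks; gene length is the TSS–TES distance (end − start,
strand-agnostic) and length rank 1 is the longest model gene.

## Binding-sequence gain/loss scanner

Motif classes are RNA-level elements: RBP binding sequences are matched as
given (U → T); miRNA seeds and miRNA-matching 3′-UTR sequences are matched
via the reverse complement of the given sequence against the sense strand.
IUPAC ambiguity codes are expanded to concrete ACGT patterns at load time so
matching is exact string equality.  For a variant with edited span of length
r (r = 0 for insertions, which insert before the given position) and motif
length L, the scan window spans L − 1 bases either side of the span; a
shorter context is scanned as-is and flagged truncated.  Occurrences are
compared between the reference and the variant window by alignment keys:
absolute start for occurrences entirely left of the edit, offset from the
span end for occurrences entirely right (so indel coordinate shifts cancel),
and start relative to the span start for occurrences overlapping the edit.
An occurrence key present only in the variant is a gain; only in the
reference, a loss; one event is emitted per (variant, motif, direction) with
the site count.  Minus-strand genes are scanned on the reverse-complemented
context.  The window convention makes the scan exactly equivalent to
diffing the full reference and variant sequences, which is how it is tested
(brute-force full-sequence oracle plus ref/alt swap symmetry).

## Impact scores, tiers, and dysregulation

The eight predictor scores are min–max normalized per algorithm over the
observed values; SIFT, LRT, and FATHMM are inverted (1 − scaled) so higher
always means stronger impact.  The orientation map ships as an overridable
default.  Constant raw scores normalize to 0.5 with a warning.  Pair impact
is the unweighted mean of normalized scores over all scored single-base
substitutions in the pair's two genes; indels are unscored and excluded.
Survival tiers take the k smallest, the k largest, and a k-block starting at
`(n − k) // 2` of the p-sorted associations (k = 1000 by default, shrunk to
⌊n/3⌋ with a warning when fewer results exist); the three blocks are always
disjoint.  Differential expression uses Welch t-tests on log2(x + 1) — the
same test family as the drug-sensitivity analysis, which applies Welch
t-tests per drug with per-drug NaN dropping and a ≥ 3-per-group minimum.
Genes constant across all subjects are skipped and recorded non-significant;
a drug identical in both groups reports t = 0, p = 1.  Panel comparison
tabulates all 2^k − 1 membership patterns over the panel union (counts sum
to the union size) plus covered/uncovered counts of the co-mutation genes.

## Synthetic-data generator

The generator encodes the data-generating assumptions the analyses rely on,
with one named RNG seeded once (identical config + seed is byte-identical):

- **Loads** — subject i draws Poisson(rate) distinct mutated genes, rate =
  `background_rate` (default 30) times `hypermutator_multiplier` (default 8)
  for a `hypermutator_fraction` (default 0.15) of subjects; genes are drawn
  without replacement with probability proportional to gene length.  Draws
  are truncated at the gene-table size, which biases the realized
  hypermutator/normal ratio slightly below the multiplier.
- **Planted pairs** — pair-mutant subjects are Bernoulli(joint_frequency);
  both genes are added for them, and accidental background co-occurrence in
  other subjects is broken (one gene removed), so the observed co-occurrence
  count equals the binomial draw exactly.
- **Survival** — exponential baseline hazard (default 0.02 per time unit,
  i.e. median ≈ 35 units) multiplied by each planted pair's hazard ratio for
  its mutants; independent uniform censoring on [0, m], with m solved by
  root finding so the baseline censoring probability equals
  `censoring_rate` (default 0.30; the realized rate in effect groups departs
  slightly, by construction).
- **Phenotypes** — age Normal(60, 12) plus per-pair additive shifts; sex via
  a logistic model on pair status (male = 1); race from stated category
  probabilities.
- **Expression / drugs** — per-gene log2-space baselines Uniform(3, 8) with
  unit noise, planted log2 fold changes in pair-mutant subjects; drug
  responses standard normal with planted mean shifts.
- **Motif fixtures** — each planted gain/loss occupies its own well-
  separated window; windows are re-randomized until the planted event is
  the only occurrence-set change for *any* motif in the set, so the truth
  list is exact by construction.  Substitutions, insertions, and deletions
  all occur.

Defaults are one-time choices of plausible cohort-scale values, not fits to
any real dataset.  The generator deliberately does **not** mimic
trinucleotide mutational signatures, real allele-frequency spectra,
covariate correlations (e.g. age–burden), or inter-gene mutation-rate
heterogeneity beyond length.  Passing tests therefore establish that the
statistical machinery is correct and calibrated under its stated model —
not that real cohorts satisfy that model.

## Problem sizes and reproducibility checks

The automated checks use desk-scale cohorts chosen as the smallest sizes at
which the targeted behavior is statistically decidable: enumeration oracles
on 100 random cohorts (≤ 30 subjects, ≤ 40 genes, ≤ 200 mutations);
hazard-ratio recovery on 100 cohorts of n = 500 with HR 2.5 and 30%
censoring (CI coverage on 200 null cohorts); screen error control on 100
cohorts of n = 300 with 200 null pairs each; scanner fidelity on 120
planted events; determinism on full pipeline reruns.  All randomness
derives from a single command-line seed.

## Known limitations

- Single-covariate models only (no covariate-adjusted Cox or regressions),
  matching the screening design; no proportional-hazards diagnostics.
- The dip-test mode candidates are the observed sample values; an optimal
  mode strictly inside a gap between values with an interior atom is not
  searched.  The LP cross-check bounds any such effect below 1e-6 on tested
  samples, and Monte-Carlo calibration uses the same statistic for sample
  and null, so test validity is unaffected.
- Motif matching is exact; no position-weight-matrix scoring, no
  transcription-factor motif class.
- The pipeline treats whatever (time, event) columns are supplied as the
  endpoint; it does not distinguish overall from disease-specific survival.
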