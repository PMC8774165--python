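# comut — somatic co-mutation analysis

Tumor genomes rarely carry driver mutations in isolation, and two mutations
that co-occur in the same genome can mark a biology — and a prognosis — that
neither single mutation shows.  `comut` implements a pan-cancer co-mutation
analysis pipeline for somatic mutation cohorts: it enumerates co-mutation
pairs, screens them against phenotypes and survival, quantifies their
functional consequences, and asks throughout whether the *pair* carries more
information than its constituent single mutations.  It is written for
cancer-genomics analysts working from MAF-like somatic mutation tables plus
the usual companion tables (clinical, expression, drug sensitivity).

## The model

**Co-mutation.**  At the *gene level*, genes A and B form a co-mutation pair
in a subject as soon as any cross-gene concurrent mutations appear; the
number of instances is ignored.  At the *position level*, each exact variant
(chrom, pos, ref, alt) is an entity, so a subject with 2 mutations in A and
3 in B contributes one gene pair but 2 × 3 = 6 position pairs.  The pair
frequency is the fraction of the whole cohort carrying the pair, and the
default screen keeps pairs with frequency ≥ 10%.  Pairs are classified as
coding:coding / coding:non-coding / non-coding:non-coding and as intra- vs
inter-chromosome.

**Screens.**  Phenotype screens regress each phenotype on the binary pair
status with the family matched to the variable (age: linear; sex: logistic
with male = 1; race: multinomial with a likelihood-ratio test).  The
survival screen fits a single-covariate Cox proportional-hazards model per
pair (Efron ties; HR > 1 = higher hazard in the mutant group) and labels
each pair with one of three significance tiers after Benjamini–Hochberg
adjustment:

1. **imbalanced** — one group has zero death events and the other at least
   10; the partial likelihood is monotone (the fitted HR diverges), so the
   pair is asserted significant empirically and kept out of the BH family;
2. **significant** — adjusted p < 0.05;
3. **marginal** — adjusted p in [0.05, 0.1].

A pair *adds prognostic value* when its unadjusted p beats both single-gene
p values (p-tier), or when both single-gene mutant groups have events while
the pair's mutant group has none (imbalanced tier).

**Functional consequences.**  Variants are scanned for exact-match gains and
losses of RNA-level binding sequences (RBP binding sequences, miRNA seeds,
and miRNA-matching 3′-UTR sites, the latter two matched via the reverse
complement of the given sequence); eight impact-predictor scores (SIFT,
PolyPhen2 HDIV/HVAR, LRT, FATHMM, CADD, VEST3, MetaSVM) are min–max
normalized to [0, 1] with higher = stronger impact and averaged per pair;
survival associations are split into top/medium/bottom tiers of k by
ascending p; expression and drug-sensitivity shifts in pair-mutant subjects
are tested per gene / per drug with Welch t-tests; and co-mutation genes are
intersected with clinical panel gene lists.

**Cohort description.**  Per-subject mutated-gene loads are flagged for
mismatch-repair (MLH1, MLH3, MSH3, MSH6, PMS1, PMS2, PMS2L3) and POLE
mutations, and load-distribution multimodality is tested with Hartigan's dip
statistic (implemented in-package; Monte-Carlo calibrated against the
uniform null, BH-adjusted across cohorts).

A synthetic-cohort generator (`comut.synthetic`) plants all of these
structures — hypermutator subpopulations, co-mutation pairs at exact joint
frequencies, hazard ratios under censoring, phenotype disparities,
expression/drug shifts, and motif gain/loss fixtures — so every stage is
testable without any external download.

## Worked example

```bash
python examples/03_survival_screen.py
```

generates a 400-subject cohort with the pair G0003:G0007 planted at joint
frequency 0.25 and hazard ratio 2.5 under 30% censoring, enumerates pairs,
and screens survival.  It prints:

```
pairs screened: 3094
planted pair HR 2.41 (95% CI 1.86-3.13), tier: significant
tier counts: {'not_significant': 3080, 'significant': 13, 'marginal': 1}
pair p 3.71e-11 vs singles 1.21e-05 / 1.77e-08; adds value: True
mutational-burden HR per mutation: 1.0026 (95% CI 0.9994-1.0058)
```

The planted hazard ratio is recovered inside its confidence interval, the
pair survives BH adjustment, and its p value beats both single genes — the
co-mutation carries prognostic information the singles do not.  (The dozen
other "significant" pairs are gene pairs overlapping the planted mutant
subjects.)  The other `examples/` scripts demonstrate cohort simulation and
load summaries, pair enumeration, phenotype screens, motif gain/loss
scanning, and the impact/expression/drug/panel analyses, one capability per
script.

A thin CLI mirrors the library (`comut simulate | summarize | enumerate |
survive | validate | run-all`); `comut run-all --config cfg.yaml` runs every
stage over one set of input files and writes TSV outputs plus a manifest
with row counts and checksums (reruns are byte-identical).

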