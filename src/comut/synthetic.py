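"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the features of consortium somatic-mutation cohorts
that the downstream screens rely on, without mimicking any real dataset:

* per-subject mutated-gene counts with a hypermutator subpopulation —
  each subject draws Poisson(background_rate) mutated genes, multiplied by
  ``hypermutator_multiplier`` for the hypermutator fraction, giving the
  bimodal load distributions the dip test should flag;
* gene mutability proportional to gene length (TSS-TES distance), so long
  genes accumulate mutations faster;
* planted co-mutation pairs at exact joint frequencies — pair-mutant
  subjects are a Bernoulli(joint_frequency) draw, and accidental background
  co-occurrence outside that draw is broken so the observed co-occurrence
  count is exactly Binomial(n_subjects, joint_frequency);
* proportional-hazards survival — exponential baseline hazard, multiplied
  by each planted pair's hazard ratio for its mutant subjects, with
  independent uniform censoring calibrated to the requested censoring rate;
* phenotype disparities — a logistic sex effect (male = 1) and an additive
  age shift per planted pair; race drawn from stated marginals;
* expression and drug-sensitivity effects in pair-mutant subjects.

All randomness flows from a single seed through one named generator, so an
identical config + seed yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    CODING,
    NON_CODING,
    GeneRecord,
    MutationRecord,
    mutations_to_frame,
    write_gene_model,
)
from .impact import GAIN, LOSS, Motif, diff_occurrences

BASES = np.array(list("ACGT"))

_CODING_CLASSES = ["missense", "nonsense", "frameshift", "splice"]
_CODING_CLASS_P = [0.80, 0.10, 0.05, 0.05]


@dataclass(frozen=True)
class PlantedPair:
    """A co-mutation pair planted with known phenotype and survival effects."""

    gene_a: str
    gene_b: str
    joint_frequency: float
    hazard_ratio: float = 1.0
    sex_log_odds: float = 0.0
    age_shift_years: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.joint_frequency <= 1.0:
            raise ValueError("joint_frequency must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")


@dataclass(frozen=True)
class ExpressionEffect:
    genes: tuple[str, ...]
    log2_fc: float
    pair_index: int = 0


@dataclass(frozen=True)
class DrugEffect:
    drugs: tuple[str, ...]
    shift: float
    pair_index: int = 0


@dataclass(frozen=True)
class PhenotypeMarginals:
    age_mean: float = 60.0
    age_sd: float = 12.0
    male_proportion: float = 0.5
    race_probs: tuple[tuple[str, float], ...] = (
        ("white", 0.70), ("black", 0.15), ("asian", 0.10), ("other", 0.05),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    gene_table: tuple[GeneRecord, ...]
    n_subjects: int = 500
    background_rate: float = 30.0
    hypermutator_fraction: float = 0.15
    hypermutator_multiplier: float = 8.0
    planted_pairs: tuple[PlantedPair, ...] = ()
    censoring_rate: float = 0.30
    baseline_hazard: float = 0.02
    expression_effect: ExpressionEffect | None = None
    drug_effect: DrugEffect | None = None
    phenotype_marginals: PhenotypeMarginals = PhenotypeMarginals()
    positions_per_gene_mutation: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_drugs: int = 40
    cohort_id: str = "SYN"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for prop, name in (
            (self.hypermutator_fraction, "hypermutator_fraction"),
            (self.censoring_rate, "censoring_rate"),
        ):
            if not 0.0 <= prop <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hypermutator_multiplier < 1:
            raise ValueError("hypermutator_multiplier must be >= 1")
        gene_ids = {g.gene_id for g in self.gene_table}
        for pair in self.planted_pairs:
            for g in (pair.gene_a, pair.gene_b):
                if g not in gene_ids:
                    raise ValueError(
                        f"planted pair gene {g!r} is not in the gene table"
                    )
        if abs(sum(self.positions_per_gene_mutation) - 1.0) > 1e-9:
            raise ValueError("positions_per_gene_mutation must sum to 1")


@dataclass
class SyntheticCohort:
    mutations: list[MutationRecord]
    clinical: pd.DataFrame
    expression: pd.DataFrame
    drug_response: pd.DataFrame
    gene_table: tuple[GeneRecord, ...]
    truth: dict

    @property
    def subjects(self) -> list[str]:
        return list(self.clinical["subject_id"])

    def write(self, outdir: str | Path) -> Path:
        """Write the cohort in the formats the pipeline reads, plus truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mutations_to_frame(self.mutations).to_csv(
            outdir / "mutations.tsv", sep="\t", index=False, lineterminator="\n")
        self.clinical.to_csv(
            outdir / "clinical.tsv", sep="\t", index=False, lineterminator="\n")
        self.expression.to_csv(
            outdir / "expression.tsv", sep="\t", lineterminator="\n")
        self.drug_response.to_csv(
            outdir / "drugs.tsv", sep="\t", lineterminator="\n")
        write_gene_model(self.gene_table, outdir / "genes.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return outdir


def make_gene_table(
    n_genes: int = 400,
    seed: int = 0,
    coding_fraction: float = 0.8,
    include_hypermutation_genes: bool = False,
) -> tuple[GeneRecord, ...]:
    """A synthetic gene model with log-normal lengths on five chromosomes.

    With ``include_hypermutation_genes`` the mismatch-repair genes and POLE
    are appended under their standard symbols, for load-summary flagging.
    """
    rng = np.random.default_rng(seed)
    genes = []
    cursor = {f"chr{i}": 10_000 for i in range(1, 6)}
    for i in range(n_genes):
        chrom = f"chr{(i % 5) + 1}"
        length = int(np.exp(rng.normal(9.5, 1.0)))  # median ~13 kb
        start = cursor[chrom]
        cursor[chrom] = start + length + 5_000
        genes.append(GeneRecord(
            gene_id=f"G{i:04d}", symbol=f"G{i:04d}", chromosome=chrom,
            start=start, end=start + length,
            strand="+" if rng.random() < 0.5 else "-",
            biotype=CODING if rng.random() < coding_fraction else NON_CODING,
        ))
    if include_hypermutation_genes:
        for j, sym in enumerate(
            ["MLH1", "MLH3", "MSH3", "MSH6", "PMS1", "PMS2", "PMS2L3", "POLE"]
        ):
            chrom = f"chr{(j % 5) + 1}"
            start = cursor[chrom]
            cursor[chrom] = start + 20_000 + 5_000
            genes.append(GeneRecord(
                gene_id=sym, symbol=sym, chromosome=chrom,
                start=start, end=start + 20_000, strand="+", biotype=CODING,
            ))
    return tuple(genes)


def _censoring_horizon(baseline_hazard: float, censoring_rate: float) -> float:
    """Uniform-censoring horizon m with P(C < T) = censoring_rate at baseline.

    C ~ U(0, m), T ~ Exp(h): P(C < T) = (1 - exp(-h m)) / (h m), decreasing
    in m; solved by root finding.
    """
    h = baseline_hazard

    def frac(m):
        return (1.0 - np.exp(-h * m)) / (h * m) - censoring_rate

    return brentq(frac, 1e-12 / h, 1e12 / h, maxiter=200)


def _draw_sites(rng, gene: GeneRecord, k: int):
    span = gene.end - gene.start + 1
    k = min(k, span)
    offsets = rng.choice(span, size=k, replace=False)
    sites = []
    for off in np.sort(offsets):
        ref = str(rng.choice(BASES))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sites.append((gene.chromosome, int(gene.start + off), ref, alt))
    return sites


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort (mutations, clinical, expression, drugs).

    Deterministic given config + seed.  The returned ``truth`` records the
    generating parameters and realized assignments (hypermutators, pair-mutant
    subject sets); its distributional choices are generator stand-ins, not a
    reproduction of any real cohort.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_table
    n = config.n_subjects
    subjects = [f"S{i:05d}" for i in range(n)]
    lengths = np.array([max(g.length, 1) for g in genes], dtype=float)
    weights = lengths / lengths.sum()
    gene_by_id = {g.gene_id: g for g in genes}

    hyper = rng.random(n) < config.hypermutator_fraction
    rates = np.where(
        hyper,
        config.background_rate * config.hypermutator_multiplier,
        config.background_rate,
    )
    n_mut_genes = np.minimum(rng.poisson(rates), len(genes))

    mutated: list[set[str]] = []
    for i in range(n):
        k = int(n_mut_genes[i])
        chosen = rng.choice(len(genes), size=k, replace=False, p=weights) if k else []
        mutated.append({genes[j].gene_id for j in chosen})

    # plant pairs: selected subjects carry both genes; accidental background
    # co-occurrence outside the draw is broken so the observed co-occurrence
    # count equals the Bernoulli draw exactly
    pair_status = np.zeros((len(config.planted_pairs), n), dtype=np.int8)
    for pi, pair in enumerate(config.planted_pairs):
        sel = rng.random(n) < pair.joint_frequency
        pair_status[pi] = sel
        for i in range(n):
            if sel[i]:
                mutated[i].add(pair.gene_a)
                mutated[i].add(pair.gene_b)
            elif pair.gene_a in mutated[i] and pair.gene_b in mutated[i]:
                mutated[i].discard(pair.gene_b)

    pos_counts = np.array([1, 2, 3])
    records: list[MutationRecord] = []
    for i, subject in enumerate(subjects):
        for gene_id in sorted(mutated[i]):
            gene = gene_by_id[gene_id]
            k = int(rng.choice(pos_counts, p=config.positions_per_gene_mutation))
            for chrom, pos, ref, alt in _draw_sites(rng, gene, k):
                vclass = (
                    str(rng.choice(_CODING_CLASSES, p=_CODING_CLASS_P))
                    if gene.biotype == CODING else "non_coding"
                )
                records.append(MutationRecord(
                    subject_id=subject, cohort_id=config.cohort_id,
                    gene_id=gene_id, chromosome=chrom, position=pos,
                    ref_allele=ref, alt_allele=alt, variant_class=vclass,
                ))

    # clinical: age / sex / race with planted disparities, then survival
    pm = config.phenotype_marginals
    age = rng.normal(pm.age_mean, pm.age_sd, n)
    logit_male = np.full(n, np.log(pm.male_proportion / (1 - pm.male_proportion)))
    log_hr = np.zeros(n)
    for pi, pair in enumerate(config.planted_pairs):
        sel = pair_status[pi].astype(bool)
        age[sel] += pair.age_shift_years
        logit_male[sel] += pair.sex_log_odds
        log_hr[sel] += np.log(pair.hazard_ratio)
    sex = np.where(rng.random(n) < 1 / (1 + np.exp(-logit_male)), "male", "female")
    race_labels = [r for r, _ in pm.race_probs]
    race_p = np.array([p for _, p in pm.race_probs])
    race = rng.choice(race_labels, size=n, p=race_p / race_p.sum())

    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        horizon = _censoring_horizon(config.baseline_hazard, config.censoring_rate)
        t_cens = rng.uniform(0, horizon, n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    clinical = pd.DataFrame({
        "subject_id": subjects,
        "cohort_id": config.cohort_id,
        "age": np.round(age, 2),
        "sex": sex,
        "race": race,
        "time": np.round(time, 4),
        "event": event,
    })

    # expression: log2-space baseline per gene, planted fold change in mutants
    gene_ids = [g.gene_id for g in genes]
    base_mu = rng.uniform(3.0, 8.0, len(genes))
    log_expr = base_mu[:, None] + rng.normal(0.0, 1.0, (len(genes), n))
    if config.expression_effect is not None:
        eff = config.expression_effect
        sel = pair_status[eff.pair_index].astype(bool)
        rows = [gene_ids.index(g) for g in eff.genes]
        log_expr[np.ix_(rows, np.nonzero(sel)[0])] += eff.log2_fc
    expression = pd.DataFrame(
        np.maximum(np.exp2(log_expr) - 1.0, 0.0).round(3),
        index=pd.Index(gene_ids, name="gene_id"), columns=subjects,
    )

    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    drug_vals = rng.normal(0.0, 1.0, (config.n_drugs, n))
    if config.drug_effect is not None:
        eff = config.drug_effect
        sel = pair_status[eff.pair_index].astype(bool)
        rows = [drugs.index(d) for d in eff.drugs]
        drug_vals[np.ix_(rows, np.nonzero(sel)[0])] += eff.shift
    drug_response = pd.DataFrame(
        drug_vals.round(4), index=pd.Index(drugs, name="drug"), columns=subjects,
    )

    truth = {
        "note": (
            "generator stand-in distributions; parameters below are the "
            "planted ground truth, not a reproduction of any real cohort"
        ),
        "config": _config_to_jsonable(config),
        "hypermutator_subjects": [subjects[i] for i in np.nonzero(hyper)[0]],
        "pair_mutant_subjects": {
            f"{p.gene_a}:{p.gene_b}": [
                subjects[i] for i in np.nonzero(pair_status[pi])[0]
            ]
            for pi, p in enumerate(config.planted_pairs)
        },
    }
    return SyntheticCohort(
        mutations=records, clinical=clinical, expression=expression,
        drug_response=drug_response, gene_table=genes, truth=truth,
    )


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["gene_table"] = f"{len(config.gene_table)} genes"
    return json.loads(json.dumps(d, default=str))


# ---------------------------------------------------------------------------
# motif-scan fixture


@dataclass
class MotifFixture:
    reference: dict[str, str]
    motifs: list[Motif]
    mutations: list[MutationRecord]
    truth: set  # of ((chrom, pos, ref, alt), motif_id, direction)


def _random_seq(rng, k: int) -> str:
    return "".join(rng.choice(BASES, size=k))


def generate_motif_fixture(
    seed: int = 0, n_events: int = 60, n_motifs: int = 8
) -> MotifFixture:
    """Reference sequences with planted motif gains and losses.

    Each event occupies its own well-separated window of one synthetic
    chromosome: a loss plants a motif occurrence that the variant destroys; a
    gain plants a near-occurrence that the variant completes.  Event types
    cycle through substitutions, insertions, and deletions.  Windows are
    re-randomized until the planted event is the only occurrence-set change
    for any motif in the set, so ``truth`` enumerates the events exactly.
    """
    rng = np.random.default_rng(seed)
    classes = ["RBP", "RBP", "miRNA_seed", "miRNA_3UTR"]
    motifs = []
    for i in range(n_motifs):
        length = int(rng.integers(5, 8))
        motifs.append(Motif(
            motif_id=f"M{i:02d}",
            motif_class=classes[i % len(classes)],
            sequence=_random_seq(rng, length),
        ))
    max_len = max(len(m.sequence) for m in motifs)
    stride = 4 * max_len + 12
    chrom = "chrS"
    windows: list[str] = []
    mutations: list[MutationRecord] = []
    truth: set = set()

    all_patterns = [(m.motif_id, m.scan_patterns()) for m in motifs]

    def window_diff(ref_w: str, alt_w: str, e_start: int, r_len: int, a_len: int):
        found = set()
        for mid, pats in all_patterns:
            gains, losses = diff_occurrences(ref_w, alt_w, pats, e_start, r_len, a_len)
            if gains:
                found.add((mid, GAIN, gains))
            if losses:
                found.add((mid, LOSS, losses))
        return found

    for ev in range(n_events):
        motif = motifs[ev % n_motifs]
        pattern = str(rng.choice(motif.scan_patterns()))
        L = len(pattern)
        direction = GAIN if ev % 2 == 0 else LOSS
        edit_kind = ("snv", "ins", "del")[ev % 3]
        placed = None
        for _attempt in range(500):
            win = list(_random_seq(rng, stride))
            anchor = stride // 2 - L // 2  # occurrence start within window
            j = int(rng.integers(0, L))   # edited offset within the occurrence
            if direction == LOSS:
                planted = pattern
            else:
                if edit_kind == "snv":
                    wrong = str(rng.choice([b for b in "ACGT" if b != pattern[j]]))
                    planted = pattern[:j] + wrong + pattern[j + 1:]
                elif edit_kind == "ins":
                    planted = pattern[:j] + pattern[j + 1:]  # missing base
                else:  # del: junk base inserted into the occurrence
                    junk = str(rng.choice(BASES))
                    planted = pattern[:j] + junk + pattern[j:]
            win[anchor:anchor + len(planted)] = list(planted)
            ref_w = "".join(win)
            pos_in_w = anchor + j  # 0-based edit offset
            if direction == LOSS:
                if edit_kind == "snv":
                    ref_a = ref_w[pos_in_w]
                    alt_a = str(rng.choice([b for b in "ACGT" if b != ref_a]))
                elif edit_kind == "ins":
                    ref_a = ""
                    alt_a = str(rng.choice(BASES))
                else:
                    ref_a, alt_a = ref_w[pos_in_w], ""
            else:
                if edit_kind == "snv":
                    ref_a, alt_a = ref_w[pos_in_w], pattern[j]
                elif edit_kind == "ins":
                    ref_a, alt_a = "", pattern[j]
                else:
                    ref_a, alt_a = ref_w[pos_in_w], ""
            if ref_a and ref_w[pos_in_w:pos_in_w + len(ref_a)] != ref_a:
                continue
            if ref_a == alt_a:
                continue
            alt_w = ref_w[:pos_in_w] + alt_a + ref_w[pos_in_w + len(ref_a):]
            found = window_diff(ref_w, alt_w, pos_in_w, len(ref_a), len(alt_a))
            if found == {(motif.motif_id, direction, 1)}:
                placed = (ref_w, pos_in_w, ref_a, alt_a)
                break
        if placed is None:
            raise RuntimeError("could not place a clean motif event fixture")
        ref_w, pos_in_w, ref_a, alt_a = placed
        offset = len("".join(windows))
        windows.append(ref_w)
        genome_pos = offset + pos_in_w + 1  # 1-based
        site_ref = ref_a if ref_a else "-"
        site_alt = alt_a if alt_a else "-"
        mutations.append(MutationRecord(
            subject_id=f"F{ev:03d}", cohort_id="FIX", gene_id=f"MG{ev:03d}",
            chromosome=chrom, position=genome_pos,
            ref_allele=site_ref, alt_allele=site_alt,
            variant_class="non_coding",
        ))
        truth.add(((chrom, genome_pos, site_ref, site_alt), motif.motif_id, direction))

    return MotifFixture(
        reference={chrom: "".join(windows)},
        motifs=motifs,
        mutations=mutations,
        truth=truth,
    )
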