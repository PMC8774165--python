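"""Functional consequences of prognostic co-mutations.

Four analysis families live here:

* binding-sequence gain/loss scanning — for each somatic variant, exact-match
  occurrences of RNA-level motifs (RBP binding sequences, miRNA seeds,
  miRNA-matching 3'-UTR sites) are compared between the reference window and
  the variant window; an occurrence present only in the variant is a gain,
  only in the reference a loss.  miRNA seeds and 3'-UTR site sequences are
  matched through the reverse complement of the given sequence against the
  sense strand; minus-strand genes are scanned on their reverse-complemented
  context.  Windows span max(motif length) - 1 bases either side of the
  edited span; across indels, occurrences are aligned by window-relative
  offset on the unedited flanks so coordinate shifts do not produce spurious
  calls.
* impact-score normalization and per-pair averaging — eight prediction
  algorithms' raw scores are min-max normalized to [0, 1] with
  lower-is-damaging algorithms inverted, then averaged over all scored point
  mutations in a pair's two genes.
* survival tiering — screened associations sorted by ascending p are split
  into top / medium / bottom groups of k (medium centered at the median rank).
* empirical dysregulation — Welch t-tests per gene on log2(x+1) expression
  and per drug on sensitivity, mutant vs wildtype, BH-adjusted; plus clinical
  gene-panel membership-pattern (upset-style) counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MutationRecord

logger = logging.getLogger(__name__)

MOTIF_CLASSES = ("RBP", "miRNA_seed", "miRNA_3UTR")
#: classes whose given sequence is matched via its reverse complement
REVCOMP_CLASSES = ("miRNA_seed", "miRNA_3UTR")

GAIN = "gain"
LOSS = "loss"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = str.maketrans("ACGT", "TGCA")

#: the eight impact predictors and their raw-score orientation
SCORE_ORIENTATION = {
    "SIFT": "lower_is_damaging",
    "PolyPhen2-HDIV": "higher_is_damaging",
    "PolyPhen2-HVAR": "higher_is_damaging",
    "LRT": "lower_is_damaging",
    "FATHMM": "lower_is_damaging",
    "CADD": "higher_is_damaging",
    "VEST3": "higher_is_damaging",
    "MetaSVM": "higher_is_damaging",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Motif:
    motif_id: str
    motif_class: str
    sequence: str

    def scan_patterns(self) -> tuple[str, ...]:
        """Concrete ACGT patterns matched against the sense strand.

        IUPAC ambiguity codes are expanded; U becomes T; miRNA-derived
        classes are reverse-complemented (the site on the target strand).
        """
        seq = self.sequence.upper().replace("U", "T")
        choices = []
        for ch in seq:
            if ch not in IUPAC:
                raise ValueError(f"motif {self.motif_id}: unknown symbol {ch!r}")
            choices.append(IUPAC[ch])
        pats = ["".join(p) for p in product(*choices)]
        if self.motif_class in REVCOMP_CLASSES:
            pats = [reverse_complement(p) for p in pats]
        return tuple(pats)


def load_motifs(source: str | pd.DataFrame) -> list[Motif]:
    """Load a motif table (motif_id, class, sequence) from TSV or DataFrame."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    required = {"motif_id", "class", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"motif table missing columns {sorted(missing)}")
    motifs = []
    for _, row in df.iterrows():
        cls = str(row["class"])
        if cls not in MOTIF_CLASSES:
            raise ValueError(f"motif {row['motif_id']}: unknown class {cls!r}")
        motifs.append(Motif(str(row["motif_id"]), cls, str(row["sequence"])))
    return motifs


@dataclass(frozen=True)
class MotifAlterationEvent:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    motif_id: str
    motif_class: str
    direction: str
    n_sites: int = 1

    @property
    def mutation(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ScanOutcome:
    events: tuple[MotifAlterationEvent, ...]
    truncated: bool = False

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


def _normalize_allele(allele: str) -> str:
    return "" if allele in ("-", ".", "") else allele.upper()


def occurrence_keys(seq: str, patterns: Sequence[str], edit_start: int, edit_len: int) -> set:
    """Alignment keys of motif occurrences relative to an edited span.

    Occurrences entirely left of the span key on their absolute start;
    entirely right, on their offset from the span end (so indel shifts
    cancel); overlapping, on their start relative to the span start.
    """
    L = len(patterns[0])
    keys = set()
    for s in range(len(seq) - L + 1):
        window = seq[s:s + L]
        if any(window == p for p in patterns):
            if s + L <= edit_start:
                keys.add(("L", s))
            elif s >= edit_start + edit_len:
                keys.add(("R", s - (edit_start + edit_len)))
            else:
                keys.add(("E", s - edit_start))
    return keys


def diff_occurrences(
    ref_seq: str, alt_seq: str, patterns: Sequence[str], edit_start: int,
    ref_len: int, alt_len: int,
) -> tuple[int, int]:
    """(gains, losses) of one motif between a reference and a variant sequence."""
    ref_keys = occurrence_keys(ref_seq, patterns, edit_start, ref_len)
    alt_keys = occurrence_keys(alt_seq, patterns, edit_start, alt_len)
    return len(alt_keys - ref_keys), len(ref_keys - alt_keys)


def scan_motif_alterations(
    mutation: tuple[str, int, str, str],
    context: str,
    motifs: Sequence[Motif],
    context_start: int = 1,
    strand: str = "+",
) -> ScanOutcome:
    """Gain/loss events of every motif caused by one variant.

    ``context`` is the plus-strand reference sequence starting at genomic
    position ``context_start`` (1-based); it should cover the mutation plus
    max(motif length) - 1 flanking bases on each side — a shorter context is
    scanned as-is and flagged truncated.  Insertions (empty/"-" ref) insert
    the alternate allele before ``position``.  The reference allele must
    match the context at the mutation site.
    """
    chrom, pos, ref, alt = mutation
    ref_n, alt_n = _normalize_allele(ref), _normalize_allele(alt)
    context = context.upper()
    p0 = pos - context_start  # 0-based offset of the edit in the context
    if p0 < 0 or p0 + len(ref_n) > len(context):
        raise ValueError(f"context does not cover mutation at {chrom}:{pos}")
    if ref_n and context[p0:p0 + len(ref_n)] != ref_n:
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: "
            f"context has {context[p0:p0 + len(ref_n)]!r}, record says {ref_n!r}"
        )
    alt_context = context[:p0] + alt_n + context[p0 + len(ref_n):]
    edit_start, ref_len, alt_len = p0, len(ref_n), len(alt_n)
    if strand == "-":
        n = len(context)
        context, alt_context = reverse_complement(context), reverse_complement(alt_context)
        edit_start = n - (p0 + ref_len)
    max_len = max((len(m.sequence) for m in motifs), default=0)
    truncated = edit_start < max_len - 1 or (
        len(context) - (edit_start + ref_len) < max_len - 1
    )
    events = []
    for motif in motifs:
        patterns = motif.scan_patterns()
        gains, losses = diff_occurrences(
            context, alt_context, patterns, edit_start, ref_len, alt_len
        )
        if gains:
            events.append(MotifAlterationEvent(
                chrom, pos, ref, alt, motif.motif_id, motif.motif_class, GAIN, gains))
        if losses:
            events.append(MotifAlterationEvent(
                chrom, pos, ref, alt, motif.motif_id, motif.motif_class, LOSS, losses))
    return ScanOutcome(tuple(events), truncated)


def scan_mutations(
    records: Sequence[MutationRecord],
    reference: Mapping[str, str],
    motifs: Sequence[Motif],
    strand_of_gene: Mapping[str, str] | None = None,
) -> list[MotifAlterationEvent]:
    """Scan a cohort's distinct variants against a reference sequence set."""
    max_len = max((len(m.sequence) for m in motifs), default=1)
    events: list[MotifAlterationEvent] = []
    seen: set[tuple] = set()
    for rec in records:
        if rec.site in seen:
            continue
        seen.add(rec.site)
        if rec.chromosome not in reference:
            logger.info("scan_mutations: no reference sequence for %s", rec.chromosome)
            continue
        seq = reference[rec.chromosome]
        ref_n = _normalize_allele(rec.ref_allele)
        lo = max(0, rec.position - 1 - (max_len - 1))
        hi = min(len(seq), rec.position - 1 + len(ref_n) + (max_len - 1))
        context = seq[lo:hi]
        strand = (strand_of_gene or {}).get(rec.gene_id, "+")
        outcome = scan_motif_alterations(
            rec.site, context, motifs, context_start=lo + 1, strand=strand
        )
        events.extend(outcome.events)
    return events


def events_to_frame(events: Sequence[MotifAlterationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.chromosome, e.position, e.ref_allele, e.alt_allele,
             e.motif_id, e.motif_class, e.direction, e.n_sites)
            for e in events
        ],
        columns=["chromosome", "position", "ref_allele", "alt_allele",
                 "motif_id", "motif_class", "direction", "n_sites"],
    )


def summarize_alterations(
    events: Sequence[MotifAlterationEvent],
    mutation_frequency: Mapping[tuple, float],
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Gain/loss counts per motif class, with a plotting subset at >= 1% frequency.

    ``mutation_frequency`` maps (chrom, pos, ref, alt) to the cohort fraction
    carrying the variant; events at frequency >= ``min_fraction`` are flagged
    ``plotted`` (the overall totals are unaffected by the threshold).
    """
    df = events_to_frame(events)
    if df.empty:
        df["frequency"] = pd.Series(dtype=float)
        df["plotted"] = pd.Series(dtype=bool)
        return df
    df["frequency"] = [
        mutation_frequency.get((r.chromosome, r.position, r.ref_allele, r.alt_allele), 0.0)
        for r in df.itertuples()
    ]
    df["plotted"] = df["frequency"] >= min_fraction
    return df


def normalize_scores(
    raw: pd.DataFrame,
    orientation: Mapping[str, str] = SCORE_ORIENTATION,
) -> pd.DataFrame:
    """Min-max normalize raw predictor scores to [0, 1], higher = stronger impact.

    ``raw`` is long-format with columns (chromosome, position, ref_allele,
    alt_allele, algorithm, raw_score).  Lower-is-damaging algorithms are
    inverted after scaling.  An algorithm with constant raw scores normalizes
    to 0.5 everywhere, with a warning.
    """
    required = {"algorithm", "raw_score"}
    if not required <= set(raw.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    out = raw.copy()
    out["normalized"] = np.nan
    for algo, grp in raw.groupby("algorithm"):
        vals = grp["raw_score"].astype(float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            warnings.warn(f"impact scores for {algo} are constant; normalized to 0.5")
            norm = pd.Series(0.5, index=grp.index)
        else:
            norm = (vals - lo) / (hi - lo)
        if orientation.get(algo, "higher_is_damaging") == "lower_is_damaging":
            norm = 1.0 - norm
        out.loc[grp.index, "normalized"] = norm
    return out


def pair_impact_score(
    pair_genes: tuple[str, str],
    normalized: pd.DataFrame,
    records: Sequence[MutationRecord],
) -> pd.Series:
    """Per-algorithm mean normalized score over a pair's scored point mutations.

    The mean is unweighted over all scored single-base substitutions in the
    two genes; indels carry no predictor score and are excluded.  Returns an
    all-NaN series when the pair has no scored point mutation.
    """
    sites = {
        rec.site
        for rec in records
        if rec.gene_id in pair_genes
        and len(_normalize_allele(rec.ref_allele)) == 1
        and len(_normalize_allele(rec.alt_allele)) == 1
    }
    algos = sorted(normalized["algorithm"].unique())
    if not sites:
        return pd.Series(np.nan, index=algos, name="mean_impact")
    keyed = normalized.set_index(
        ["chromosome", "position", "ref_allele", "alt_allele"]
    )
    hits = keyed.loc[keyed.index.isin(sites)]
    return hits.groupby("algorithm")["normalized"].mean().reindex(algos).rename("mean_impact")


def tier_groups(p_values: Sequence[float], k: int = 1000) -> dict[str, np.ndarray]:
    """Indices of the top / medium / bottom k associations by ascending p.

    Top = k smallest, bottom = k largest, medium = a block of k centered at
    the median rank.  If fewer than 3k results exist, k shrinks to
    floor(n/3) with a warning.  The returned index arrays are disjoint.
    """
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n < 3 * k:
        k = n // 3
        warnings.warn(f"fewer than 3k results; tier size shrunk to {k}")
    if k == 0:
        return {"top": np.array([], int), "medium": np.array([], int), "bottom": np.array([], int)}
    order = np.argsort(p, kind="stable")
    mid_start = (n - k) // 2
    return {
        "top": order[:k],
        "medium": order[mid_start:mid_start + k],
        "bottom": order[n - k:],
    }


def _welch_by_row(values: pd.DataFrame | np.ndarray, status: np.ndarray, min_group: int):
    """Row-wise Welch t-tests mutant vs wildtype with NaN dropping.

    Rows where both groups are constant report t=0, p=1 when the means agree
    and are skipped otherwise; rows with too few finite values per group are
    skipped.
    """
    arr = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    mut = np.asarray(status) == 1
    a, b = arr[:, mut], arr[:, ~mut]
    n = arr.shape[0]
    stats_out = np.full(n, np.nan)
    ps = np.full(n, np.nan)
    tested = np.zeros(n, dtype=bool)
    for i in range(n):
        ai, bi = a[i], b[i]
        ai, bi = ai[np.isfinite(ai)], bi[np.isfinite(bi)]
        if ai.size < min_group or bi.size < min_group:
            continue
        if ai.std(ddof=1) == 0 and bi.std(ddof=1) == 0:
            if ai.mean() == bi.mean():
                stats_out[i], ps[i], tested[i] = 0.0, 1.0, True
            continue
        t, p = stats.ttest_ind(ai, bi, equal_var=False)
        stats_out[i], ps[i], tested[i] = float(t), float(p), True
    return stats_out, ps, tested


def differential_expression(
    expression: pd.DataFrame,
    status: np.ndarray,
    alpha: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(x+1) expression, mutant vs wildtype.

    ``expression`` is genes x subjects, column order matching ``status``.
    Genes constant in both groups are skipped and recorded non-significant;
    BH adjustment runs across the tested genes.
    """
    status = np.asarray(status)
    if expression.shape[1] != status.size:
        raise ValueError("status length must match expression columns")
    logged = np.log2(expression.astype(float) + 1.0)
    t, p, tested = _welch_by_row(logged, status, min_group)
    constant = logged.nunique(axis=1).to_numpy() <= 1
    t[constant], p[constant], tested[constant] = np.nan, np.nan, False
    df = pd.DataFrame({
        "gene_id": expression.index, "statistic": t, "p": p, "tested": tested,
    })
    df["adjusted_p"] = np.nan
    if tested.any():
        df.loc[tested, "adjusted_p"] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
    df["significant"] = df["adjusted_p"] < alpha
    return df


def drug_sensitivity_assoc(
    drug_response: pd.DataFrame,
    status: np.ndarray,
    single_status_a: np.ndarray | None = None,
    single_status_b: np.ndarray | None = None,
    alpha: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-drug t-tests of sensitivity, co-mutation mutant vs wildtype.

    ``drug_response`` is drugs x subjects (cell lines); missing values are
    dropped per drug, and drugs with fewer than ``min_group`` lines in either
    group are skipped.  When the two single-gene status vectors are supplied,
    each drug also reports whether the pair's p is strictly smaller than both
    single-gene p values for that drug.
    """
    status = np.asarray(status)
    if drug_response.shape[1] != status.size:
        raise ValueError("status length must match drug-response columns")
    t, p, tested = _welch_by_row(drug_response, status, min_group)
    df = pd.DataFrame({
        "drug": drug_response.index, "statistic": t, "p": p, "tested": tested,
    })
    df["adjusted_p"] = np.nan
    if tested.any():
        df.loc[tested, "adjusted_p"] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
    df["significant"] = df["adjusted_p"] < alpha
    if single_status_a is not None and single_status_b is not None:
        _, pa, _ = _welch_by_row(drug_response, np.asarray(single_status_a), min_group)
        _, pb, _ = _welch_by_row(drug_response, np.asarray(single_status_b), min_group)
        with np.errstate(invalid="ignore"):
            df["stronger_than_singles"] = (
                np.isfinite(p) & np.isfinite(pa) & np.isfinite(pb)
                & (p < pa) & (p < pb)
            )
    return df


def panel_intersections(
    panels: Mapping[str, Iterable[str]],
    comut_genes: Iterable[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Upset-style membership-pattern counts of clinical panels, plus coverage.

    Returns (pattern table over the union of panel genes, coverage dict with
    ``covered`` = co-mutation genes in any panel and ``uncovered`` = in none).
    Pattern counts sum to the size of the panel union.
    """
    if not panels:
        raise ValueError("at least one panel required")
    panel_sets = {name: set(genes) for name, genes in panels.items()}
    names = sorted(panel_sets)
    union = set().union(*panel_sets.values())
    patterns: dict[tuple[bool, ...], int] = {}
    for gene in union:
        key = tuple(gene in panel_sets[n] for n in names)
        patterns[key] = patterns.get(key, 0) + 1
    rows = [
        {**{n: k for n, k in zip(names, key)}, "count": c}
        for key, c in sorted(patterns.items(), reverse=True)
    ]
    table = pd.DataFrame(rows)
    comut = set(comut_genes)
    coverage = {
        "covered": len(comut & union),
        "uncovered": len(comut - union),
        "union_size": len(union),
    }
    return table, coverage
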