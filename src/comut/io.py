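"""Gene models, somatic mutation tables, and the subject x gene matrix.

Coordinates are 1-based inclusive throughout (MAF and GTF agree on this, so
no shift is applied).  Gene length is the TSS-TES distance, i.e. end - start
of the gene body, strand-agnostic.  Biotypes are collapsed to a two-value
scheme: ``protein_coding`` maps to ``coding``, everything else (lincRNA,
miRNA, pseudogene, ...) to ``non-coding``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

CODING = "coding"
NON_CODING = "non-coding"

#: canonical MAF-like column names written and read by this package
MAF_COLUMNS = [
    "subject_id",
    "cohort_id",
    "gene_id",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "variant_class",
]

_MANDATORY = [c for c in MAF_COLUMNS if c != "cohort_id"]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.biotype not in (CODING, NON_CODING):
            raise ValueError(f"gene {self.gene_id}: biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        """TSS-TES distance."""
        return self.end - self.start


@dataclass(frozen=True)
class MutationRecord:
    subject_id: str
    gene_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    cohort_id: str = ""
    known_gene: bool = True

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(
                f"mutation at {self.chromosome}:{self.position}: positions are 1-based"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"mutation at {self.chromosome}:{self.position}: ref == alt"
            )

    @property
    def site(self) -> tuple[str, int, str, str]:
        """Position-level entity identity."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


def collapse_biotype(raw: str) -> str:
    raw = raw.strip()
    if raw in (CODING, NON_CODING):
        return raw
    return CODING if raw == "protein_coding" else NON_CODING


def _read_gtf_genes(path: str | Path) -> list[GeneRecord]:
    import pyranges

    gr = pyranges.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    df = df[df["Feature"] == "gene"]
    biotype_col = "gene_type" if "gene_type" in df.columns else "gene_biotype"
    records = []
    for row in df.itertuples(index=False):
        gene_id = getattr(row, "gene_id")
        symbol = getattr(row, "gene_name", gene_id) or gene_id
        records.append(
            GeneRecord(
                gene_id=str(gene_id),
                symbol=str(symbol),
                chromosome=str(row.Chromosome),
                start=int(row.Start) + 1,  # pyranges is 0-based half-open
                end=int(row.End),
                strand=str(getattr(row, "Strand", "+")),
                biotype=collapse_biotype(str(getattr(row, biotype_col))),
            )
        )
    return records


def _read_gene_tsv(path: str | Path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene_id", "chromosome", "start", "end", "strand", "biotype"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"gene table {path}: missing columns {missing}")
        col = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                records.append(
                    GeneRecord(
                        gene_id=parts[col["gene_id"]],
                        symbol=parts[col["symbol"]] if "symbol" in col else parts[col["gene_id"]],
                        chromosome=parts[col["chromosome"]],
                        start=int(parts[col["start"]]),
                        end=int(parts[col["end"]]),
                        strand=parts[col["strand"]],
                        biotype=collapse_biotype(parts[col["biotype"]]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: unparseable line {lineno}: {exc}") from exc
    return records


def read_gene_model(path: str | Path) -> list[GeneRecord]:
    """Read a GTF or a simplified tab-separated gene table.

    Returns one :class:`GeneRecord` per gene with the biotype collapsed to
    coding / non-coding.  Raises on duplicate gene ids (naming the id) and on
    unparseable gene-table lines (naming the line number).
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        records = _read_gtf_genes(path)
    else:
        records = _read_gene_tsv(path)
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in {path}")
        seen.add(rec.gene_id)
    return records


def write_gene_model(genes: Sequence[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.symbol, g.chromosome, g.start, g.end, g.strand, g.biotype)
            for g in genes
        ],
        columns=["gene_id", "symbol", "chromosome", "start", "end", "strand", "biotype"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def gene_index(model: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    return {g.gene_id: g for g in model}


def read_mutations(
    path: str | Path, model: Sequence[GeneRecord] | None = None
) -> list[MutationRecord]:
    """Read a MAF-like TSV into mutation records.

    Mutations in genes absent from ``model`` are retained but flagged
    (``known_gene=False``).  Duplicate identical rows are deduplicated with a
    logged count, so frequencies count each subject once.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if "cohort_id" not in df.columns:
        df["cohort_id"] = ""
    before = len(df)
    df = df.drop_duplicates(subset=MAF_COLUMNS)
    dropped = before - len(df)
    if dropped:
        logger.info("read_mutations: deduplicated %d identical rows from %s", dropped, path)
    known = gene_index(model).keys() if model is not None else None
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MutationRecord(
                subject_id=row.subject_id,
                cohort_id=row.cohort_id,
                gene_id=row.gene_id,
                chromosome=row.chromosome,
                position=int(row.position),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                variant_class=row.variant_class,
                known_gene=(known is None or row.gene_id in known),
            )
        )
    return records


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    df = mutations_to_frame(records)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def mutations_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.subject_id,
                r.cohort_id,
                r.gene_id,
                r.chromosome,
                r.position,
                r.ref_allele,
                r.alt_allele,
                r.variant_class,
            )
            for r in records
        ],
        columns=MAF_COLUMNS,
    )


def filter_synonymous(
    records: Sequence[MutationRecord], model: Sequence[GeneRecord]
) -> list[MutationRecord]:
    """Drop synonymous mutations from the protein-coding mutation set.

    Only records with ``variant_class == "synonymous"`` in a gene of coding
    biotype are removed; a synonymous-classed record in a non-coding gene is
    retained (the drop applies to the protein-coding set only).
    """
    idx = gene_index(model)
    kept = []
    for rec in records:
        gene = idx.get(rec.gene_id)
        if rec.variant_class == "synonymous" and gene is not None and gene.biotype == CODING:
            continue
        kept.append(rec)
    return kept


@dataclass
class MutationMatrix:
    """Sparse subject x gene presence structure with per-cell position lists.

    ``presence[s, g] == 1`` iff ``positions[(subject, gene)]`` is non-empty.
    Subject order is stable and includes subjects with zero mutations.
    """

    subjects: list[str]
    genes: list[str]
    presence: sparse.csr_matrix
    positions: dict[tuple[str, str], list[tuple[str, int, str, str]]]
    subject_index: dict[str, int] = field(repr=False, default_factory=dict)
    gene_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.subject_index:
            self.subject_index = {s: i for i, s in enumerate(self.subjects)}
        if not self.gene_index:
            self.gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def mutated_gene_counts(self) -> np.ndarray:
        """Distinct mutated genes per subject, in subject order."""
        return np.asarray(self.presence.sum(axis=1)).ravel().astype(int)

    def mutation_burden(self) -> np.ndarray:
        """Total mutation count (all positions) per subject."""
        burden = np.zeros(len(self.subjects), dtype=int)
        for (subj, _), sites in self.positions.items():
            burden[self.subject_index[subj]] += len(sites)
        return burden

    def gene_status(self, gene: str) -> np.ndarray:
        """Binary mutated-indicator over subjects for one gene."""
        if gene not in self.gene_index:
            return np.zeros(len(self.subjects), dtype=np.int8)
        col = self.presence.getcol(self.gene_index[gene]).toarray().ravel()
        return (col > 0).astype(np.int8)

    def subjects_with_gene(self, gene: str) -> set[str]:
        status = self.gene_status(gene)
        return {self.subjects[i] for i in np.nonzero(status)[0]}


def build_matrix(
    records: Sequence[MutationRecord], subjects: Sequence[str] | None = None
) -> MutationMatrix:
    """Build the subject x gene mutation matrix.

    ``subjects`` fixes the row order (and includes unmutated subjects); if
    omitted it defaults to the sorted distinct subjects of ``records``.
    """
    if subjects is None:
        subjects = sorted({r.subject_id for r in records})
    subjects = list(subjects)
    sidx = {s: i for i, s in enumerate(subjects)}
    for rec in records:
        if rec.subject_id not in sidx:
            raise ValueError(f"record subject {rec.subject_id!r} not in subject list")
    genes = sorted({r.gene_id for r in records})
    gidx = {g: i for i, g in enumerate(genes)}
    positions: dict[tuple[str, str], list[tuple[str, int, str, str]]] = {}
    for rec in records:
        positions.setdefault((rec.subject_id, rec.gene_id), []).append(rec.site)
    # deduplicate identical sites within a cell
    rows, cols = [], []
    for (subj, gene), sites in positions.items():
        positions[(subj, gene)] = sorted(set(sites), key=_site_key)
        rows.append(sidx[subj])
        cols.append(gidx[gene])
    presence = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(subjects), len(genes)),
    )
    return MutationMatrix(subjects, genes, presence, positions, sidx, gidx)


def _chrom_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(c)) if c.isdigit() else (1, c)


def _site_key(site: tuple[str, int, str, str]) -> tuple:
    chrom, pos, ref, alt = site
    return (*_chrom_key(chrom), pos, ref, alt)


def gene_mutation_frequency(matrix: MutationMatrix) -> pd.Series:
    """Fraction of subjects with at least one mutation per gene."""
    if matrix.n_subjects == 0:
        raise ValueError("mutation matrix has zero subjects")
    counts = np.asarray((matrix.presence > 0).sum(axis=0)).ravel()
    return pd.Series(counts / matrix.n_subjects, index=matrix.genes, name="frequency")
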