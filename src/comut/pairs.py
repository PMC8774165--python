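"""Co-mutation pair enumeration, classification, and cross-cohort sharing.

Two genes form a gene-level co-mutation pair in a subject as soon as any
cross-gene concurrent mutations appear; the number of instances is not
counted (a subject with two mutations in gene A and three in gene B
contributes one A:B gene pair but 2 x 3 = 6 position-level pairs).  Pair
frequency is the fraction of the full cohort (including subjects with zero
mutations) harboring the pair, and the default screen keeps pairs with
frequency >= 10%.

Enumeration is per subject with an accumulator keyed by the canonical pair,
after a marginal prescreen (a pair can reach the frequency threshold only if
both entities do marginally), avoiding the quadratic all-genes x all-genes
loop.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneRecord, MutationMatrix, MutationRecord, _site_key, gene_index

GENE_LEVEL = "gene"
POSITION_LEVEL = "position"


@dataclass(frozen=True)
class ComutationPair:
    level: str
    entity_a: str | tuple
    entity_b: str | tuple
    n_co: int
    n_total: int
    pair_type: str | None = None
    chrom_relation: str | None = None
    same_gene: bool = False
    unclassified: bool = False

    @property
    def frequency(self) -> float:
        return self.n_co / self.n_total

    @property
    def pair_id(self) -> str:
        return f"{_entity_label(self.entity_a)}:{_entity_label(self.entity_b)}"


def _entity_label(entity) -> str:
    if isinstance(entity, tuple):
        chrom, pos, ref, alt = entity
        return f"{chrom}_{pos}_{ref}_{alt}"
    return str(entity)


def _min_count(n_total: int, min_freq: float) -> int:
    """Smallest co-occurrence count satisfying count / n_total >= min_freq."""
    return int(np.ceil(min_freq * n_total - 1e-9))


def enumerate_gene_pairs(
    matrix: MutationMatrix, min_freq: float = 0.10
) -> list[ComutationPair]:
    """All unordered gene pairs co-mutated at frequency >= ``min_freq``.

    Each qualifying subject contributes exactly 1 to a pair's count, no
    matter how many mutations it carries in either gene.
    """
    n_total = matrix.n_subjects
    if n_total == 0:
        raise ValueError("empty mutation matrix")
    need = max(_min_count(n_total, min_freq), 1)
    marginals = np.asarray((matrix.presence > 0).sum(axis=0)).ravel()
    eligible = {matrix.genes[i] for i in np.nonzero(marginals >= need)[0]}
    counts: Counter = Counter()
    indptr, indices = matrix.presence.indptr, matrix.presence.indices
    for s in range(n_total):
        genes_s = sorted(
            matrix.genes[j]
            for j in indices[indptr[s]:indptr[s + 1]]
            if matrix.genes[j] in eligible
        )
        counts.update(combinations(genes_s, 2))
    return [
        ComutationPair(GENE_LEVEL, a, b, c, n_total)
        for (a, b), c in sorted(counts.items())
        if c >= need
    ]


def enumerate_position_pairs(
    records: Sequence[MutationRecord],
    n_total: int | None = None,
    min_freq: float = 0.10,
    include_same_gene: bool = True,
) -> list[ComutationPair]:
    """All unordered pairs of exact variant sites co-mutated per subject.

    Entities are distinct (chromosome, position, ref, alt) tuples; a pair's
    count is the number of subjects (not instances) carrying both sites.
    Same-gene pairs are emitted flagged ``same_gene`` (and can be excluded).
    """
    by_subject: dict[str, dict[tuple, str]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, {})[rec.site] = rec.gene_id
    if n_total is None:
        n_total = len(by_subject)
    if n_total == 0:
        raise ValueError("no subjects")
    need = max(_min_count(n_total, min_freq), 1)
    counts: Counter = Counter()
    genes_of: dict[tuple, tuple[str, str]] = {}
    for sites in by_subject.values():
        ordered = sorted(sites, key=_site_key)
        for a, b in combinations(ordered, 2):
            if not include_same_gene and sites[a] == sites[b]:
                continue
            counts[(a, b)] += 1
            genes_of[(a, b)] = (sites[a], sites[b])
    return [
        ComutationPair(
            POSITION_LEVEL, a, b, c, n_total,
            same_gene=(genes_of[(a, b)][0] == genes_of[(a, b)][1]),
        )
        for (a, b), c in sorted(counts.items(), key=lambda kv: (_site_key(kv[0][0]), _site_key(kv[0][1])))
        if c >= need
    ]


def classify_pair(
    pair: ComutationPair, model: Sequence[GeneRecord] | Mapping[str, GeneRecord]
) -> ComutationPair:
    """Fill pair_type (from the two biotypes) and chrom_relation (intra/inter).

    Gene-level pairs with a gene missing from the model are flagged
    ``unclassified`` and retained.
    """
    idx = model if isinstance(model, Mapping) else gene_index(model)
    if pair.level == POSITION_LEVEL:
        chrom_a, chrom_b = pair.entity_a[0], pair.entity_b[0]
        return replace(
            pair, chrom_relation="intra" if chrom_a == chrom_b else "inter"
        )
    ga, gb = idx.get(pair.entity_a), idx.get(pair.entity_b)
    if ga is None or gb is None:
        return replace(pair, unclassified=True)
    pair_type = ":".join(sorted([ga.biotype, gb.biotype]))
    relation = "intra" if ga.chromosome == gb.chromosome else "inter"
    return replace(pair, pair_type=pair_type, chrom_relation=relation)


def cross_cohort_sharing(
    pairs_by_cohort: Mapping[str, Sequence[ComutationPair]]
) -> pd.DataFrame:
    """How many cohorts contain each (filtered) pair, ranked descending.

    Ties in the sharing count break on the canonical pair id.
    """
    if len(pairs_by_cohort) < 2:
        raise ValueError("cross-cohort sharing requires at least two cohorts")
    membership: dict[tuple, set[str]] = {}
    for cohort, pairs in pairs_by_cohort.items():
        for p in pairs:
            membership.setdefault((p.level, p.entity_a, p.entity_b), set()).add(cohort)
    rows = [
        (level, _entity_label(a), _entity_label(b), len(cohorts), ",".join(sorted(cohorts)))
        for (level, a, b), cohorts in membership.items()
    ]
    df = pd.DataFrame(
        rows, columns=["level", "entity_a", "entity_b", "n_cohorts", "cohorts"]
    )
    return df.sort_values(
        ["n_cohorts", "entity_a", "entity_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def pairs_to_frame(pairs: Sequence[ComutationPair]) -> pd.DataFrame:
    """Serialize pairs to the output table layout."""
    return pd.DataFrame(
        [
            (
                p.level,
                _entity_label(p.entity_a),
                _entity_label(p.entity_b),
                p.n_co,
                p.n_total,
                p.frequency,
                p.pair_type or "",
                p.chrom_relation or "",
                p.same_gene,
                p.unclassified,
            )
            for p in pairs
        ],
        columns=[
            "level", "entity_a", "entity_b", "n_co", "n_total", "frequency",
            "pair_type", "chrom_relation", "same_gene", "unclassified",
        ],
    )
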