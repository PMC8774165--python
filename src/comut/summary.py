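"""Per-subject mutation-load summaries and cross-cohort gene rankings.

Covers the descriptive layer of the pipeline: mutated-gene counts per
subject with hypermutation flags (mismatch-repair / POLE), Hartigan dip
testing for multimodal load distributions across cohorts, and the
top-mutated-genes table with gene-length ranks.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._dip import dip_test
from .io import GeneRecord, MutationMatrix

logger = logging.getLogger(__name__)

#: DNA mismatch-repair genes whose mutation frequently accompanies hypermutation
MMR_GENES = frozenset({"MLH1", "MLH3", "MSH3", "MSH6", "PMS1", "PMS2", "PMS2L3"})
POLE_GENE = "POLE"


def subject_loads(
    matrix: MutationMatrix,
    mmr_genes: Iterable[str] = MMR_GENES,
    pole_gene: str = POLE_GENE,
) -> pd.DataFrame:
    """Mutated-gene count and hypermutation flag per subject.

    Flag is ``MMR`` if any mismatch-repair gene is mutated, ``POLE`` if the
    polymerase-epsilon gene is mutated, ``both`` if both criteria hold, and
    ``other`` otherwise.
    """
    counts = matrix.mutated_gene_counts()
    mmr_present = [g for g in mmr_genes if g in matrix.gene_index]
    mmr_status = np.zeros(matrix.n_subjects, dtype=bool)
    for g in mmr_present:
        mmr_status |= matrix.gene_status(g).astype(bool)
    pole_status = matrix.gene_status(pole_gene).astype(bool)
    flags = np.where(
        mmr_status & pole_status, "both",
        np.where(mmr_status, "MMR", np.where(pole_status, "POLE", "other")),
    )
    return pd.DataFrame(
        {
            "subject_id": matrix.subjects,
            "mutated_gene_count": counts,
            "hypermutation_flag": flags,
        }
    )


def test_multimodality(
    loads_by_cohort: Mapping[str, Sequence[float]],
    min_subjects: int = 10,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hartigan dip test of the per-subject load distribution per cohort.

    Cohorts with fewer than ``min_subjects`` subjects are skipped with a log
    entry.  p-values are Monte-Carlo calibrated against the uniform null and
    Benjamini-Hochberg adjusted across the tested cohorts.
    """
    rows = []
    for cohort, loads in loads_by_cohort.items():
        loads = np.asarray(loads, dtype=float)
        if loads.size < min_subjects:
            logger.info(
                "test_multimodality: skipping cohort %s (%d < %d subjects)",
                cohort, loads.size, min_subjects,
            )
            continue
        stat, p = dip_test(loads, n_boot=n_boot, seed=seed)
        rows.append((cohort, loads.size, stat, p))
    df = pd.DataFrame(rows, columns=["cohort", "n", "dip", "p"])
    if len(df):
        df["adjusted_p"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["adjusted_p"] < alpha
    else:
        df["adjusted_p"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def top_frequent_genes(
    freqs_by_cohort: Mapping[str, pd.Series],
    model: Sequence[GeneRecord],
    n: int = 20,
) -> pd.DataFrame:
    """Top genes by unweighted mean mutation frequency across cohorts.

    A gene absent from a cohort's frequency table contributes frequency 0 in
    that cohort.  Ties in mean frequency break lexicographically on gene id.
    ``length_rank`` ranks the gene's TSS-TES length among all model genes
    (rank 1 = longest).
    """
    if not freqs_by_cohort:
        raise ValueError("top_frequent_genes requires at least one cohort")
    table = pd.DataFrame(freqs_by_cohort).fillna(0.0)
    table.columns = [f"freq_{c}" for c in freqs_by_cohort]
    table["mean_freq"] = table.mean(axis=1)
    table = table.assign(gene_id=table.index).sort_values(
        ["mean_freq", "gene_id"], ascending=[False, True]
    )
    top = table.head(min(n, len(table))).copy()
    lengths = pd.Series({g.gene_id: g.length for g in model})
    length_rank = lengths.rank(ascending=False, method="min").astype(int)
    top["length"] = top["gene_id"].map(lengths)
    top["length_rank"] = top["gene_id"].map(length_rank)
    top.insert(0, "rank", np.arange(1, len(top) + 1))
    cols = ["rank", "gene_id", "mean_freq"] + [
        c for c in top.columns if c.startswith("freq_")
    ] + ["length", "length_rank"]
    return top[cols].reset_index(drop=True)


def subjects_mutated_in_all(genes: Iterable[str], matrix: MutationMatrix) -> int:
    """Number of subjects mutated in every listed gene."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    status = np.ones(matrix.n_subjects, dtype=bool)
    for g in genes:
        status &= matrix.gene_status(g).astype(bool)
    return int(status.sum())
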