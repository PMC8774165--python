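import numpy as np
import pytest

from comut import (
    GeneRecord,
    MutationRecord,
    PlantedPair,
    SyntheticConfig,
    build_matrix,
    generate_cohort,
    make_gene_table,
)


@pytest.fixture(scope="session")
def toy_model():
    """Five genes on three chromosomes, mixed biotypes (TP53/KRAS-like pair)."""
    return [
        GeneRecord("TP53", "TP53", "chr17", 7_668_402, 7_687_550, "-", "coding"),
        GeneRecord("KRAS", "KRAS", "chr12", 25_205_246, 25_250_936, "-", "coding"),
        GeneRecord("GENE_NC", "GENE_NC", "chr17", 100, 5_100, "+", "non-coding"),
        GeneRecord("GENE_C2", "GENE_C2", "chr17", 10_000, 40_000, "+", "coding"),
        GeneRecord("GENE_S", "GENE_S", "chr1", 500, 900, "+", "coding"),
    ]


def make_record(subject, gene, chrom="chr1", pos=1000, ref="A", alt="T",
                vclass="missense", cohort="COH"):
    return MutationRecord(
        subject_id=subject, cohort_id=cohort, gene_id=gene, chromosome=chrom,
        position=pos, ref_allele=ref, alt_allele=alt, variant_class=vclass,
    )


@pytest.fixture()
def worked_example_matrix():
    """One sample with 2 mutations in gene A and 3 in gene B."""
    records = [
        make_record("S1", "A", "chr1", 100, "A", "T"),
        make_record("S1", "A", "chr1", 200, "C", "G"),
        make_record("S1", "B", "chr2", 300, "A", "C"),
        make_record("S1", "B", "chr2", 400, "G", "T"),
        make_record("S1", "B", "chr2", 500, "T", "A"),
    ]
    return records, build_matrix(records, ["S1"])


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject cohort with one planted pair (survival + phenotype effects)."""
    table = make_gene_table(n_genes=80, seed=11)
    config = SyntheticConfig(
        gene_table=table,
        n_subjects=300,
        background_rate=10.0,
        hypermutator_fraction=0.15,
        hypermutator_multiplier=8.0,
        planted_pairs=(
            PlantedPair("G0003", "G0007", 0.25, hazard_ratio=2.5,
                        sex_log_odds=1.2, age_shift_years=-8.0),
        ),
        seed=5,
    )
    cohort = generate_cohort(config)
    matrix = build_matrix(cohort.mutations, cohort.subjects)
    return cohort, matrix


def random_records(rng, n_subjects=30, n_genes=40, n_mutations=200, cohort="R"):
    """A random small mutation set for brute-force oracle comparisons."""
    records = []
    seen = set()
    for _ in range(n_mutations):
        s = f"S{rng.integers(n_subjects):03d}"
        g = rng.integers(n_genes)
        pos = int(rng.integers(1, 5000))
        ref = "ACGT"[rng.integers(4)]
        alt = "ACGT"[(("ACGT".index(ref)) + 1 + rng.integers(3)) % 4]
        key = (s, g, pos, ref, alt)
        if key in seen:
            continue
        seen.add(key)
        records.append(make_record(
            s, f"G{g:03d}", chrom=f"chr{g % 5 + 1}", pos=pos, ref=ref, alt=alt,
            cohort=cohort,
        ))
    subjects = [f"S{i:03d}" for i in range(n_subjects)]
    return records, subjects
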