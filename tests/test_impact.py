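"""Motif gain/loss scanning, score normalization, tiers, DE, drugs, panels."""

import numpy as np
import pandas as pd
import pytest

from comut import (
    Motif,
    differential_expression,
    drug_sensitivity_assoc,
    generate_motif_fixture,
    normalize_scores,
    pair_impact_score,
    panel_intersections,
    scan_motif_alterations,
    summarize_alterations,
    tier_groups,
)
from comut.impact import GAIN, LOSS, reverse_complement, scan_mutations

from conftest import make_record


# --- independent full-sequence brute-force oracle -------------------------

def brute_force_events(reference, mutations, motifs):
    """Scan entire reference and variant chromosome sequences for every
    motif, aligning occurrences on the unedited flanks, with plain string
    search (no windows)."""
    events = set()
    for rec in mutations:
        seq = reference[rec.chromosome]
        ref = "" if rec.ref_allele == "-" else rec.ref_allele
        alt = "" if rec.alt_allele == "-" else rec.alt_allele
        p0 = rec.position - 1
        alt_seq = seq[:p0] + alt + seq[p0 + len(ref):]
        for motif in motifs:
            pats = motif.scan_patterns()
            L = len(pats[0])

            def keys(s, elen):
                out = set()
                for i in range(len(s) - L + 1):
                    if s[i:i + L] in pats:
                        if i + L <= p0:
                            out.add(("L", i))
                        elif i >= p0 + elen:
                            out.add(("R", i - (p0 + elen)))
                        else:
                            out.add(("E", i - p0))
                return out

            rk, ak = keys(seq, len(ref)), keys(alt_seq, len(alt))
            if ak - rk:
                events.add((rec.site, motif.motif_id, GAIN))
            if rk - ak:
                events.add((rec.site, motif.motif_id, LOSS))
    return events


def test_snv_destroying_planted_motif_is_one_loss():
    motif = Motif("M1", "RBP", "ACGTAC")
    context = "TTTTTTACGTACTTTTTT"
    out = scan_motif_alterations(("chr1", 9, "G", "A"), context, [motif], context_start=1)
    assert [(e.motif_id, e.direction) for e in out] == [("M1", LOSS)]
    assert not out.truncated


def test_snv_creating_motif_is_one_gain():
    motif = Motif("M1", "RBP", "ACGTAC")
    context = "TTTTTTACGAACTTTTTT"  # one base off the motif
    out = scan_motif_alterations(("chr1", 10, "A", "T"), context, [motif], context_start=1)
    assert [(e.motif_id, e.direction) for e in out] == [("M1", GAIN)]


def test_motif_matching_both_windows_is_no_event():
    motif = Motif("M1", "RBP", "ACNTAC")  # ambiguity: matches ref and alt
    context = "TTTTTTACGTACTTTTTT"
    out = scan_motif_alterations(("chr1", 9, "G", "C"), context, [motif], context_start=1)
    assert len(out) == 0


def test_ref_mismatch_names_coordinate():
    motif = Motif("M1", "RBP", "ACGTA")
    with pytest.raises(ValueError, match="chr1:5"):
        scan_motif_alterations(("chr1", 5, "G", "A"), "AAAAAAAAAA", [motif])


def test_truncated_window_flagged():
    motif = Motif("M1", "RBP", "ACGTACG")
    out = scan_motif_alterations(("chr1", 2, "A", "T"), "AACGT", [motif], context_start=1)
    assert out.truncated


def test_minus_strand_scanning():
    # motif present on the minus strand only; the SNV destroys it
    motif = Motif("M1", "RBP", "AACCGG")
    plus = "TTTT" + reverse_complement("AACCGG") + "TTTT"  # CCGGTT on plus
    pos = 7  # inside the occurrence
    ref = plus[pos - 1]
    out_plus = scan_motif_alterations(("chr1", pos, ref, "A" if ref != "A" else "C"),
                                      plus, [motif], strand="+")
    out_minus = scan_motif_alterations(("chr1", pos, ref, "A" if ref != "A" else "C"),
                                       plus, [motif], strand="-")
    assert len(out_plus) == 0
    assert [(e.motif_id, e.direction) for e in out_minus] == [("M1", LOSS)]


def test_mirna_classes_match_by_reverse_complement():
    seed = Motif("mir", "miRNA_seed", "ACCGGUU")  # RNA alphabet
    site = reverse_complement("ACCGGTT")
    context = "TTTT" + site + "TTTT"
    pos = 5 + 2
    out = scan_motif_alterations(
        ("chr1", pos, context[pos - 1], "G" if context[pos - 1] != "G" else "C"),
        context, [seed],
    )
    assert [(e.motif_id, e.direction) for e in out] == [("mir", LOSS)]


def test_swapping_ref_and_alt_swaps_gains_and_losses():
    fixture = generate_motif_fixture(seed=9, n_events=24)
    for rec in fixture.mutations[:12]:
        seq = fixture.reference[rec.chromosome]
        ref = "" if rec.ref_allele == "-" else rec.ref_allele
        alt = "" if rec.alt_allele == "-" else rec.alt_allele
        p0 = rec.position - 1
        alt_seq = seq[:p0] + alt + seq[p0 + len(ref):]
        fwd = scan_motif_alterations(rec.site, seq, fixture.motifs, context_start=1)
        back = scan_motif_alterations(
            (rec.chromosome, rec.position, rec.alt_allele, rec.ref_allele),
            alt_seq, fixture.motifs, context_start=1,
        )
        assert {(e.motif_id, e.direction) for e in fwd} == {
            (e.motif_id, GAIN if e.direction == LOSS else LOSS) for e in back
        }


@pytest.mark.parametrize("seed", [1, 2])
def test_scanner_equals_truth_and_brute_force(seed):
    """>=50 planted events per fixture, including insertions and deletions."""
    fixture = generate_motif_fixture(seed=seed, n_events=60)
    kinds = {("-" == m.ref_allele, "-" == m.alt_allele) for m in fixture.mutations}
    assert (True, False) in kinds and (False, True) in kinds  # ins and del present
    got = {
        (e.mutation, e.motif_id, e.direction)
        for e in scan_mutations(fixture.mutations, fixture.reference, fixture.motifs)
    }
    assert got == fixture.truth
    assert got == brute_force_events(fixture.reference, fixture.mutations, fixture.motifs)


def test_summarize_alterations_threshold():
    fixture = generate_motif_fixture(seed=4, n_events=12)
    events = scan_mutations(fixture.mutations, fixture.reference, fixture.motifs)
    freqs = {e.mutation: (0.02 if i % 2 else 0.001) for i, e in enumerate(events)}
    table = summarize_alterations(events, freqs, min_fraction=0.01)
    assert len(table) == len(events)  # totals unaffected by the threshold
    assert table["plotted"].tolist() == [f >= 0.01 for f in table["frequency"]]
    empty = summarize_alterations([], {}, 0.01)
    assert empty.empty


def _score_table(rng, n=50):
    rows = []
    for i in range(n):
        for algo in ("SIFT", "CADD", "VEST3", "FATHMM"):
            rows.append(("chr1", i + 1, "A", "G", algo, float(rng.random() * 30)))
    return pd.DataFrame(
        rows, columns=["chromosome", "position", "ref_allele", "alt_allele",
                       "algorithm", "raw_score"],
    )


def test_normalization_endpoints_and_inversion():
    df = pd.DataFrame({
        "algorithm": ["CADD"] * 3 + ["SIFT"] * 3,
        "raw_score": [1.0, 2.0, 5.0, 0.0, 0.5, 1.0],
    })
    out = normalize_scores(df)
    cadd = out[out.algorithm == "CADD"]["normalized"].tolist()
    assert cadd[0] == 0.0 and cadd[-1] == 1.0  # higher_is_damaging: min -> 0
    sift = out[out.algorithm == "SIFT"]["normalized"].tolist()
    assert sift[0] == 1.0 and sift[-1] == 0.0  # lower_is_damaging: min -> 1


def test_normalization_matches_two_pass_oracle_and_is_monotone():
    rng = np.random.default_rng(5)
    df = _score_table(rng)
    out = normalize_scores(df)
    for algo, grp in out.groupby("algorithm"):
        lo, hi = grp["raw_score"].min(), grp["raw_score"].max()
        scaled = (grp["raw_score"] - lo) / (hi - lo)
        from comut.impact import SCORE_ORIENTATION

        if SCORE_ORIENTATION[algo] == "lower_is_damaging":
            scaled = 1 - scaled
        assert np.allclose(grp["normalized"], scaled)
        order_raw = np.argsort(grp["raw_score"].to_numpy())
        order_norm = np.argsort(grp["normalized"].to_numpy())
        if SCORE_ORIENTATION[algo] == "lower_is_damaging":
            order_norm = order_norm[::-1]
        assert (order_raw == order_norm).all()
    assert out["normalized"].between(0, 1).all()


def test_constant_scores_normalize_to_half_with_warning():
    df = pd.DataFrame({"algorithm": ["CADD"] * 4, "raw_score": [7.0] * 4})
    with pytest.warns(UserWarning, match="constant"):
        out = normalize_scores(df)
    assert (out["normalized"] == 0.5).all()


def test_pair_impact_score_averaging():
    records = [
        make_record("S1", "A", "chr1", 1, "A", "G"),
        make_record("S2", "B", "chr1", 2, "A", "G"),
        make_record("S3", "B", "chr1", 3, "AT", "-", vclass="frameshift"),  # indel: unscored
        make_record("S4", "C", "chr1", 4, "A", "G"),  # other gene: excluded
    ]
    norm = pd.DataFrame({
        "chromosome": ["chr1"] * 3, "position": [1, 2, 4],
        "ref_allele": ["A"] * 3, "alt_allele": ["G"] * 3,
        "algorithm": ["CADD"] * 3, "raw_score": [0.0] * 3,
        "normalized": [0.2, 0.8, 0.9],
    })
    means = pair_impact_score(("A", "B"), norm, records)
    assert means["CADD"] == pytest.approx(0.5)  # (0.2 + 0.8) / 2
    single = pair_impact_score(("A", "ZZ"), norm, records)
    assert single["CADD"] == pytest.approx(0.2)
    missing = pair_impact_score(("Y", "ZZ"), norm, records)
    assert missing.isna().all()


def test_tier_groups_partition_and_centering():
    p = np.linspace(0.001, 0.9, 30)
    groups = tier_groups(p, k=10)
    assert sorted(groups["top"]) == list(range(10))
    assert sorted(groups["medium"]) == list(range(10, 20))  # ranks 11-20
    assert sorted(groups["bottom"]) == list(range(20, 30))
    # shrinkage with warning when n < 3k
    with pytest.warns(UserWarning, match="shrunk"):
        small = tier_groups(np.linspace(0, 1, 8), k=10)
    assert all(len(v) == 2 for v in small.values())
    all_idx = np.concatenate(list(small.values()))
    assert len(all_idx) == len(set(all_idx))  # disjoint


def test_tier_groups_concentrate_planted_effects():
    rng = np.random.default_rng(8)
    p = rng.uniform(0.05, 1.0, 300)
    planted = rng.choice(300, 40, replace=False)
    p[planted] = rng.uniform(0, 1e-4, 40)
    groups = tier_groups(p, k=50)
    assert len(set(planted) & set(groups["top"])) == 40
    assert len(set(planted) & set(groups["bottom"])) == 0


def test_differential_expression_null_and_power():
    rng = np.random.default_rng(11)
    n_genes, n = 2000, 100
    status = np.r_[np.ones(50, int), np.zeros(50, int)]
    base = rng.uniform(3, 8, n_genes)
    log_expr = base[:, None] + rng.normal(0, 1, (n_genes, n))
    expr_null = pd.DataFrame(np.exp2(log_expr) - 1, columns=[f"S{i}" for i in range(n)])
    out = differential_expression(expr_null, status)
    # under the null the BH-significant count stays within the binomial bound
    bound = int(np.ceil(n_genes * 0.05 + 3 * np.sqrt(n_genes * 0.05 * 0.95)))
    assert out["significant"].sum() <= bound
    # planted 2-fold change in 100 genes
    log_expr2 = log_expr.copy()
    log_expr2[:100, status == 1] += 1.0
    out2 = differential_expression(
        pd.DataFrame(np.exp2(log_expr2) - 1, columns=expr_null.columns), status)
    assert out2["significant"][:100].sum() >= 70


def test_differential_expression_constant_gene_skipped():
    status = np.r_[np.ones(5, int), np.zeros(5, int)]
    expr = pd.DataFrame(np.vstack([np.full(10, 4.0), np.random.default_rng(0).random(10)]))
    out = differential_expression(expr, status)
    assert not out.loc[0, "tested"]
    assert not out.loc[0, "significant"]


def test_drug_sensitivity_null_power_and_degenerate():
    rng = np.random.default_rng(12)
    n = 80
    status = np.r_[np.ones(40, int), np.zeros(40, int)]
    drugs = pd.DataFrame(rng.normal(0, 1, (500, n)))
    out = drug_sensitivity_assoc(drugs, status)
    frac = out["significant"].mean()
    assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 500)
    # planted 1.5 SD shift in one drug
    shifted = drugs.copy()
    shifted.iloc[0, :40] += 1.5
    out2 = drug_sensitivity_assoc(shifted, status)
    assert out2.loc[0, "significant"]
    # identical values in both groups: t = 0, p = 1
    flat = pd.DataFrame(np.tile(np.arange(n, dtype=float), (1, 1)))
    flat.iloc[0] = 3.0
    out3 = drug_sensitivity_assoc(flat, status)
    assert out3.loc[0, "statistic"] == 0.0 and out3.loc[0, "p"] == 1.0


def test_drug_sensitivity_stronger_than_singles():
    rng = np.random.default_rng(13)
    n = 90
    a = (rng.random(n) < 0.5).astype(int)
    b = (rng.random(n) < 0.5).astype(int)
    both = a * b
    drugs = pd.DataFrame(rng.normal(0, 1, (20, n)))
    drugs.iloc[0] += 2.0 * both  # interaction-only drug effect
    out = drug_sensitivity_assoc(drugs, both, a, b)
    assert "stronger_than_singles" in out.columns
    assert bool(out.loc[0, "stronger_than_singles"])


def test_panel_intersections_patterns_and_coverage():
    panels = {"P1": {"A", "B", "C"}, "P2": {"B", "C", "D"}, "P3": {"E"}}
    table, coverage = panel_intersections(panels, {"A", "E", "Z", "Q"})
    assert table["count"].sum() == 5  # |union|
    # brute-force membership tabulation
    union = {"A", "B", "C", "D", "E"}
    expected = {}
    for g in union:
        key = (g in panels["P1"], g in panels["P2"], g in panels["P3"])
        expected[key] = expected.get(key, 0) + 1
    got = {tuple(r[["P1", "P2", "P3"]]): r["count"] for _, r in table.iterrows()}
    assert got == expected
    assert coverage == {"covered": 2, "uncovered": 2, "union_size": 5}
    # identical panels: everything in the intersection
    t2, _ = panel_intersections({"A": {"X", "Y"}, "B": {"X", "Y"}}, set())
    assert len(t2) == 1 and t2["count"].iloc[0] == 2
    # disjoint panels: no pairwise intersection patterns
    t3, _ = panel_intersections({"A": {"X"}, "B": {"Y"}}, set())
    assert set(map(tuple, t3[["A", "B"]].to_numpy())) == {(True, False), (False, True)}
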