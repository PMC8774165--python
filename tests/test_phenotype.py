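"""Phenotype regression screens: family behavior, calibration, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from comut import (
    associate,
    build_matrix,
    compare_to_single,
    enumerate_gene_pairs,
    pair_status_vector,
    screen_phenotype,
)
from comut.phenotype import add_single_comparison, encode_sex, screen_single_genes_phenotype


def test_pair_status_vector(small_cohort):
    cohort, matrix = small_cohort
    pairs = enumerate_gene_pairs(matrix, 0.10)
    planted = next(p for p in pairs if {p.entity_a, p.entity_b} == {"G0003", "G0007"})
    status = pair_status_vector(planted, matrix)
    assert status.sum() == planted.n_co
    # a subject with only one of the genes is 0
    only_a = matrix.gene_status("G0003").astype(bool) & ~matrix.gene_status("G0007").astype(bool)
    assert not status[only_a].any()
    truth = set(cohort.truth["pair_mutant_subjects"]["G0003:G0007"])
    assert {matrix.subjects[i] for i in np.nonzero(status)[0]} == truth


def test_linear_null_type_one_error():
    """Slope p under independence is uniform: rejection rate ~ alpha."""
    rng = np.random.default_rng(0)
    n, reps = 300, 1000
    hits = 0
    for _ in range(reps):
        status = (rng.random(n) < 0.3).astype(float)
        age = rng.normal(60, 10, n)
        if associate(status, age, "linear").p < 0.05:
            hits += 1
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(hits / reps - 0.05) <= 2 * se + 1e-12


def test_planted_age_shift_recovered(small_cohort):
    cohort, matrix = small_cohort
    pairs = enumerate_gene_pairs(matrix, 0.10)
    planted = next(p for p in pairs if {p.entity_a, p.entity_b} == {"G0003", "G0007"})
    status = pair_status_vector(planted, matrix)
    age = cohort.clinical["age"].to_numpy()
    res = associate(status, age, "linear")
    n1, n0 = status.sum(), (1 - status).sum()
    sd = cohort.clinical["age"].std()
    se = sd * np.sqrt(1 / n1 + 1 / n0)
    assert res.coefficient < 0
    assert abs(res.coefficient - (-8.0)) < 2 * se


def test_logistic_against_grid_likelihood_oracle():
    """Constructed 20-subject table: mostly-male mutants give a positive
    log-odds matching an independent numeric likelihood maximization."""
    status = np.array([1] * 6 + [0] * 14, dtype=float)
    sex = np.array(["male"] * 5 + ["female"] * 1 + ["male"] * 5 + ["female"] * 9)
    res = associate(status, sex, "logistic")
    y = encode_sex(sex)

    def nll(params):
        b0, b1 = params
        eta = b0 + b1 * status
        return -(y * eta - np.log1p(np.exp(eta))).sum()

    opt = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    assert res.coefficient > 0
    assert res.coefficient == pytest.approx(opt.x[1], abs=1e-4)
    # Wald p from the numeric Hessian at the oracle optimum
    eps = 1e-5
    h = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            pij = np.array(opt.x, float); pij[i] += eps; pij[j] += eps
            pi = np.array(opt.x, float); pi[i] += eps
            pj = np.array(opt.x, float); pj[j] += eps
            h[i, j] = (nll(pij) - nll(pi) - nll(pj) + nll(opt.x)) / eps**2
    se = np.sqrt(np.linalg.inv(h)[1, 1])
    p_oracle = 2 * stats.norm.sf(abs(opt.x[1]) / se)
    assert res.p == pytest.approx(p_oracle, abs=1e-3)


def test_logistic_separation_is_degenerate():
    status = np.array([1] * 5 + [0] * 15, dtype=float)
    sex = np.array(["male"] * 5 + ["female"] * 15)  # mutants all male: separation
    res = associate(status, sex, "logistic")
    assert res.degenerate


def test_logistic_sign_flips_with_coding():
    rng = np.random.default_rng(2)
    status = (rng.random(200) < 0.4).astype(float)
    p_male = 1 / (1 + np.exp(-(0.2 + 1.0 * status)))
    sex = np.where(rng.random(200) < p_male, "male", "female")
    res = associate(status, sex, "logistic")
    flipped = np.where(sex == "male", "female", "male")
    res_flip = associate(status, flipped, "logistic")
    assert res_flip.coefficient == pytest.approx(-res.coefficient, abs=1e-6)
    assert res_flip.p == pytest.approx(res.p, abs=1e-9)


def test_multinomial_lrt():
    rng = np.random.default_rng(3)
    n = 400
    status = (rng.random(n) < 0.4).astype(float)
    race = np.where(
        (status == 1) & (rng.random(n) < 0.5), "asian",
        rng.choice(["white", "black", "asian"], n, p=[0.6, 0.25, 0.15]),
    )
    res = associate(status, race, "multinomial")
    assert isinstance(res.coefficient, dict)
    assert set(res.coefficient) == {"black", "asian"}  # white is the reference
    assert res.p < 0.01
    # null: no association
    res0 = associate(status, rng.choice(["white", "black"], n), "multinomial")
    assert res0.p > 0.001
    assert associate(status, np.repeat("white", n), "multinomial").degenerate


def test_constant_status_degenerate():
    assert associate(np.zeros(50), np.arange(50.0), "linear").degenerate


def test_screen_single_pair_bh_identity(small_cohort):
    cohort, matrix = small_cohort
    pairs = enumerate_gene_pairs(matrix, 0.10)[:1]
    values = cohort.clinical.set_index("subject_id")["age"]
    out = screen_phenotype(matrix, pairs, values, "age")
    assert len(out) == 1
    assert out["adjusted_p"].iloc[0] == pytest.approx(out["p"].iloc[0])


def test_screen_requires_coverage(small_cohort):
    cohort, matrix = small_cohort
    pairs = enumerate_gene_pairs(matrix, 0.10)[:1]
    values = cohort.clinical.set_index("subject_id")["age"].iloc[:100]  # 33% coverage
    with pytest.raises(ValueError, match="available"):
        screen_phenotype(matrix, pairs, values, "age")


def test_screen_order_invariance(small_cohort):
    cohort, matrix = small_cohort
    pairs = enumerate_gene_pairs(matrix, 0.12)
    values = cohort.clinical.set_index("subject_id")["age"]
    a = screen_phenotype(matrix, pairs, values, "age").sort_values("pair_id").reset_index(drop=True)
    b = screen_phenotype(matrix, list(reversed(pairs)), values, "age").sort_values("pair_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_planted_sex_effect_detected_among_nulls():
    """A pair with a planted log-odds of 1.5 should survive BH among ~100
    null pairs in most replicates."""
    n, n_null, n_seeds = 600, 100, 25
    wins = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        effect = (rng.random(n) < 0.25).astype(float)
        p_male = 1 / (1 + np.exp(-(0.0 + 1.5 * effect)))
        sex = np.where(rng.random(n) < p_male, 1.0, 0.0)
        rows = [associate(effect, sex, "logistic").p]
        for _ in range(n_null):
            null_status = (rng.random(n) < 0.25).astype(float)
            rows.append(associate(null_status, sex, "logistic").p)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(rows, method="fdr_bh")[1]
        if adj[0] < 0.05:
            wins += 1
    assert wins >= 0.8 * n_seeds


def test_compare_to_single_rules():
    assert compare_to_single(1e-6, 1e-3, 1e-4)
    assert not compare_to_single(1e-3, 1e-3, 1e-2)  # equality is not stronger
    assert not compare_to_single(1e-6, None, 1e-4)  # missing single: False


def test_interaction_only_phenotype_effect_beats_singles():
    """Age shifted only in double-mutants: the pair's p beats both singles."""
    wins, n_seeds = 0, 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(500 + seed)
        n = 500
        a = (rng.random(n) < 0.35).astype(float)
        b = (rng.random(n) < 0.35).astype(float)
        both = a * b
        age = rng.normal(60, 10, n) - 6.0 * both
        pp = associate(both, age, "linear").p
        pa = associate(a, age, "linear").p
        pb = associate(b, age, "linear").p
        if compare_to_single(pp, pa, pb):
            wins += 1
    assert wins >= 0.8 * n_seeds


def test_add_single_comparison(small_cohort):
    cohort, matrix = small_cohort
    pairs = enumerate_gene_pairs(matrix, 0.12)
    values = cohort.clinical.set_index("subject_id")["age"]
    screen = screen_phenotype(matrix, pairs, values, "age")
    genes = sorted({g for p in pairs for g in (p.entity_a, p.entity_b)})
    singles = screen_single_genes_phenotype(matrix, genes, values, "age")
    out = add_single_comparison(screen, singles, pairs)
    assert "stronger_than_singles" in out.columns
    sp = singles.set_index("gene")["p"]
    by_id = {p.pair_id: p for p in pairs}
    for row in out.itertuples():
        pair = by_id[row.pair_id]
        expected = compare_to_single(row.p, sp.get(pair.entity_a), sp.get(pair.entity_b))
        assert row.stronger_than_singles == expected
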