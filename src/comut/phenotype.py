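"""Regression screens of co-mutation status against age, sex, and race.

The regression family follows the phenotype's nature: age uses linear
regression (phenotype ~ status, Wald p on the slope), sex uses logistic
regression with male coded 1 and female 0, and race uses multinomial
regression with a likelihood-ratio test of the whole status term against the
intercept-only model (reference level = most frequent category).  Subjects
with a missing phenotype value are dropped per test, and Benjamini-Hochberg
adjustment is applied across all pairs within one cohort x phenotype screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io import MutationMatrix
from .pairs import ComutationPair
from .survival import pair_status

logger = logging.getLogger(__name__)

FAMILY_BY_PHENOTYPE = {"age": "linear", "sex": "logistic", "race": "multinomial"}
SEX_CODES = {"male": 1, "female": 0}


@dataclass(frozen=True)
class Association:
    coefficient: float | dict[str, float] | None
    p: float
    degenerate: bool = False
    message: str = ""

    @property
    def direction(self) -> int | None:
        if self.degenerate or not isinstance(self.coefficient, float):
            return None
        return int(np.sign(self.coefficient))


def _degenerate(message: str) -> Association:
    return Association(None, float("nan"), True, message)


def encode_sex(values: Sequence) -> np.ndarray:
    """Code male as 1 and female as 0; numeric input passes through."""
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if isinstance(v, str):
            key = v.strip().lower()
            if key not in SEX_CODES:
                out[i] = np.nan
            else:
                out[i] = SEX_CODES[key]
        else:
            out[i] = float(v) if v is not None else np.nan
    return out


def pair_status_vector(pair: ComutationPair, matrix: MutationMatrix) -> np.ndarray:
    """Binary co-mutation status per subject: 1 iff both genes mutated."""
    return pair_status(pair, matrix)


def associate(status, values, family: str) -> Association:
    """Regress one phenotype on one binary status vector.

    Returns a degenerate result (flagged, excluded from BH families) on
    constant status, constant phenotype, separation, or non-convergence.
    """
    status = np.asarray(status, dtype=float)
    if family == "linear":
        y = np.asarray(values, dtype=float)
    elif family == "logistic":
        y = encode_sex(values)
    elif family == "multinomial":
        y = pd.Series(values).astype(str).to_numpy()
        y = np.where(pd.isna(values), None, y)
    else:
        raise ValueError(f"unknown family {family!r}")
    if family == "multinomial":
        keep = np.array([v is not None and v != "nan" for v in y])
    else:
        keep = np.isfinite(y)
    status, y = status[keep], y[keep]
    if status.size == 0 or np.ptp(status) == 0:
        return _degenerate("constant status")
    if len(np.unique(y)) < 2:
        return _degenerate("constant phenotype")
    X = sm.add_constant(status)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if family == "linear":
                res = sm.OLS(y, X).fit()
                return Association(float(res.params[1]), float(res.pvalues[1]))
            if family == "logistic":
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    return _degenerate("logistic fit did not converge")
                if abs(res.params[1]) > 30:
                    return _degenerate("separation")
                return Association(float(res.params[1]), float(res.pvalues[1]))
            # multinomial: LRT of the status term, most-frequent reference level
            levels = pd.Series(y).value_counts()
            ref = levels.index[0]
            cats = [ref] + sorted(l for l in levels.index if l != ref)
            codes = pd.Categorical(y, categories=cats).codes
            full = sm.MNLogit(codes, X).fit(disp=0, maxiter=300)
            null = sm.MNLogit(codes, X[:, :1]).fit(disp=0, maxiter=300)
            if not full.mle_retvals.get("converged", True):
                return _degenerate("multinomial fit did not converge")
            lr = 2.0 * (full.llf - null.llf)
            df = len(cats) - 1
            p = float(stats.chi2.sf(max(lr, 0.0), df))
            coefs = {
                cats[j + 1]: float(full.params[1, j])
                for j in range(full.params.shape[1])
            }
            return Association(coefs, p)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        return _degenerate(f"fit failed: {exc}")


def screen_phenotype(
    matrix: MutationMatrix,
    pairs: Sequence[ComutationPair],
    phenotype_values: pd.Series,
    phenotype: str,
    alpha: float = 0.05,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """One association per pair for one phenotype, BH-adjusted within the screen.

    ``phenotype_values`` is indexed by subject id; it must cover at least
    ``min_coverage`` of the cohort (missing values are dropped per test).
    """
    family = FAMILY_BY_PHENOTYPE[phenotype]
    values = phenotype_values.reindex(matrix.subjects)
    coverage = values.notna().mean() if len(values) else 0.0
    if coverage < min_coverage:
        raise ValueError(
            f"{phenotype} available for {coverage:.0%} of subjects (< {min_coverage:.0%})"
        )
    rows = []
    for pair in pairs:
        status = pair_status_vector(pair, matrix)
        res = associate(status, values.to_numpy(), family)
        if res.degenerate:
            logger.info("screen_phenotype: %s degenerate (%s)", pair.pair_id, res.message)
        rows.append((pair.pair_id, res))
    df = pd.DataFrame(
        [
            (
                pid,
                res.coefficient if isinstance(res.coefficient, float) else np.nan,
                repr(res.coefficient) if isinstance(res.coefficient, dict) else "",
                res.p,
                res.direction if res.direction is not None else 0,
                res.degenerate,
            )
            for pid, res in rows
        ],
        columns=["pair_id", "coefficient", "level_coefficients", "p", "direction", "degenerate"],
    )
    df["phenotype"] = phenotype
    df["adjusted_p"] = np.nan
    fam = (~df["degenerate"]).to_numpy()
    if fam.any():
        df.loc[fam, "adjusted_p"] = multipletests(df.loc[fam, "p"], method="fdr_bh")[1]
    df["significant"] = df["adjusted_p"] < alpha
    return df


def screen_single_genes_phenotype(
    matrix: MutationMatrix,
    genes: Sequence[str],
    phenotype_values: pd.Series,
    phenotype: str,
    alpha: float = 0.05,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Same screen with single-gene mutated status (the comparison baseline)."""
    family = FAMILY_BY_PHENOTYPE[phenotype]
    values = phenotype_values.reindex(matrix.subjects)
    coverage = values.notna().mean() if len(values) else 0.0
    if coverage < min_coverage:
        raise ValueError(
            f"{phenotype} available for {coverage:.0%} of subjects (< {min_coverage:.0%})"
        )
    rows = []
    for gene in genes:
        res = associate(matrix.gene_status(gene), values.to_numpy(), family)
        rows.append((gene, res.coefficient if isinstance(res.coefficient, float) else np.nan,
                     res.p, res.degenerate))
    df = pd.DataFrame(rows, columns=["gene", "coefficient", "p", "degenerate"])
    fam = (~df["degenerate"]).to_numpy()
    df["adjusted_p"] = np.nan
    if fam.any():
        df.loc[fam, "adjusted_p"] = multipletests(df.loc[fam, "p"], method="fdr_bh")[1]
    df["significant"] = df["adjusted_p"] < alpha
    return df


def compare_to_single(
    pair_p: float, single_p_a: float | None, single_p_b: float | None
) -> bool:
    """True iff the pair's unadjusted p is strictly smaller than both singles'.

    A missing single-gene result yields False.
    """
    if single_p_a is None or single_p_b is None:
        return False
    if any(pd.isna(v) for v in (pair_p, single_p_a, single_p_b)):
        return False
    return pair_p < single_p_a and pair_p < single_p_b


def add_single_comparison(
    pair_screen: pd.DataFrame,
    single_screen: pd.DataFrame,
    pairs: Sequence[ComutationPair],
) -> pd.DataFrame:
    """Annotate a pair screen with the stronger-than-singles flag."""
    singles = single_screen.set_index("gene")["p"].to_dict()
    by_id = {p.pair_id: p for p in pairs}
    flags = []
    for row in pair_screen.itertuples():
        pair = by_id[row.pair_id]
        flags.append(
            compare_to_single(
                row.p, singles.get(pair.entity_a), singles.get(pair.entity_b)
            )
        )
    out = pair_screen.copy()
    out["stronger_than_singles"] = flags
    return out
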