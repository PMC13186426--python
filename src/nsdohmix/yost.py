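"""Yost-type one-dimensional SES comparator index.

Seven standardized area-level SES variables are projected onto the leading
eigenvector of their correlation matrix; tracts are ranked by the resulting
score and cut into quintiles (quintile 1 = lowest SES).  Variables whose
natural direction is "more = more disadvantage" are sign-flipped before
standardization, and the component is oriented so the score correlates
positively with income.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

YOST_VARIABLES = (
    "median_income",
    "education",
    "below_150_poverty",
    "median_house_value",
    "median_gross_rent",
    "unemployment_rate",
    "working_class",
)
# variables where larger raw values mean *lower* SES
DEFAULT_DISADVANTAGE = ("below_150_poverty", "unemployment_rate", "working_class")


def yost_index(
    raw: pd.DataFrame,
    variables: tuple[str, ...] = YOST_VARIABLES,
    disadvantage: tuple[str, ...] = DEFAULT_DISADVANTAGE,
    income_var: str = "median_income",
    id_col: str = "tract_id",
) -> pd.DataFrame:
    """First-principal-component SES score and quintile per tract.

    Returns a frame with columns ``tract_id``, ``score``, ``quintile``
    (1..5, 1 = lowest SES).  Quintile ties are broken by stable input
    order, so tie-free quintile sizes differ by at most one.
    """
    missing = [v for v in variables if v not in raw.columns]
    if missing:
        raise KeyError(f"missing SES variables: {missing}")
    ids = raw[id_col].to_numpy() if id_col in raw.columns else np.arange(len(raw))
    x = raw[list(variables)].apply(pd.to_numeric).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("SES variables contain missing values")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant SES variable(s): {bad}")

    sign = np.array([-1.0 if v in disadvantage else 1.0 for v in variables])
    zmat = sign * (x - x.mean(axis=0)) / sd

    corr = np.corrcoef(zmat, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    leading = eigvecs[:, -1]
    score = zmat @ leading
    if income_var in variables:
        r = np.corrcoef(score, zmat[:, list(variables).index(income_var)])[0, 1]
        if r < 0:
            score, leading = -score, -leading

    order = np.argsort(score, kind="stable")
    quintile = np.empty(len(score), dtype=np.int64)
    for q, chunk in enumerate(np.array_split(order, 5), start=1):
        quintile[chunk] = q
    out = pd.DataFrame({"tract_id": ids, "score": score, "quintile": quintile})
    out.attrs["loadings"] = pd.Series(leading, index=list(variables))
    out.attrs["leading_eigenvalue"] = float(eigvals[-1])
    return out


def compare_indices(
    ses: pd.DataFrame, assignments: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Quintile x profile cross-tabulation with a chi-square association test.

    Tracts present in only one of the two tables are logged and excluded.
    """
    merged = ses.merge(assignments, on="tract_id", how="inner")
    n_unmatched = len(ses) + len(assignments) - 2 * len(merged)
    if n_unmatched:
        logger.warning("excluded %d unmatched tracts from comparison", n_unmatched)
    table = pd.crosstab(merged["quintile"], merged["profile"])
    chi2, pval, dof, _ = stats.chi2_contingency(table)
    summary = {
        "chi2": float(chi2),
        "dof": int(dof),
        "p_value": float(pval),
        "n": int(len(merged)),
    }
    return table, summary
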