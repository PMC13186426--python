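"""Median-dichotomization of raw tract-level indicator tables.

Each indicator is cut at its empirical state median: tracts strictly above
the median are coded 1 (high exposure / disadvantage).  Two indicators are
special-cased: median household income is reverse-coded (at/above the state
median codes to 0, below codes to 1), and incomplete plumbing -- whose state
median is 0 -- codes to 1 for any positive value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .catalog import VariableCatalog, default_catalog
from .containers import BinaryDesignMatrix

logger = logging.getLogger(__name__)


def _check_columns(raw: pd.DataFrame, catalog: VariableCatalog) -> None:
    missing = [name for name in catalog.names if name not in raw.columns]
    if missing:
        raise KeyError(f"raw table is missing catalog variables: {missing}")


def compute_state_medians(
    raw: pd.DataFrame, catalog: VariableCatalog | None = None
) -> pd.DataFrame:
    """Empirical median and IQR of each catalog variable over tracts.

    Rows with any missing catalog value are dropped (and counted in a logged
    warning) before the medians are taken.  Returns a frame indexed by
    variable name with columns ``median`` and ``iqr``.
    """
    catalog = catalog or default_catalog()
    _check_columns(raw, catalog)
    sub = raw[catalog.names].apply(pd.to_numeric)
    n_missing = int(sub.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d tracts with missing indicator values", n_missing)
        sub = sub.dropna()
    med = sub.median()
    iqr = sub.quantile(0.75) - sub.quantile(0.25)
    return pd.DataFrame({"median": med, "iqr": iqr}).loc[catalog.names]


def binarize(
    raw: pd.DataFrame,
    medians: pd.DataFrame | pd.Series | None = None,
    catalog: VariableCatalog | None = None,
    id_col: str = "tract_id",
    proportion_scale: float = 1.0,
) -> BinaryDesignMatrix:
    """Dichotomize a raw indicator table at the state medians.

    Coding rules per variable direction:

    * standard: 1 iff value strictly greater than the median (ties code 0);
    * reversed (income): 0 iff value >= median, else 1;
    * zero_threshold (plumbing): 0 iff value == 0, else 1.

    Proportion variables (everything except income) must lie in
    ``[0, proportion_scale]``; pass ``proportion_scale=100`` for
    percent-scale extracts.
    """
    catalog = catalog or default_catalog()
    _check_columns(raw, catalog)
    if medians is None:
        medians = compute_state_medians(raw, catalog)
    med = medians["median"] if isinstance(medians, pd.DataFrame) else medians

    sub = raw[catalog.names].apply(pd.to_numeric)
    keep = ~sub.isna().any(axis=1)
    if not keep.all():
        logger.warning("dropping %d tracts with missing indicator values", int((~keep).sum()))
        sub = sub[keep]
    ids = (
        raw.loc[keep, id_col].to_numpy()
        if id_col in raw.columns
        else np.asarray(raw.index[keep])
    )

    cols = {}
    for var in catalog:
        x = sub[var.name].to_numpy(dtype=float)
        if var.direction != "reversed":  # income exempt from the bound check
            if (x < 0).any() or (x > proportion_scale).any():
                raise ValueError(
                    f"variable {var.name!r} has values outside [0, {proportion_scale}]"
                )
        if var.direction == "standard":
            cols[var.name] = (x > med[var.name]).astype(np.uint8)
        elif var.direction == "reversed":
            cols[var.name] = (x < med[var.name]).astype(np.uint8)
        else:  # zero_threshold
            cols[var.name] = (x != 0).astype(np.uint8)

    values = np.column_stack([cols[name] for name in catalog.names])
    return BinaryDesignMatrix(values, ids, catalog.names)
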