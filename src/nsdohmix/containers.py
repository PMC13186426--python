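"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BinaryDesignMatrix:
    """An n x p matrix of 0/1 tract-by-indicator exposures.

    Rows are census tracts (``tract_ids``), columns are disadvantage
    indicators (``variable_names``); entry (i, j) = 1 means tract i has high
    exposure to indicator j.
    """

    values: np.ndarray
    tract_ids: np.ndarray
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(np.asarray(self.values))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if np.any(pd.isna(self.values)):
            raise ValueError("binary design matrix contains missing entries")
        vals = self.values.astype(np.int64)
        if not np.array_equal(vals, self.values.astype(float)):
            raise ValueError("binary design matrix entries must be integers")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary design matrix entries must be 0 or 1")
        self.values = vals.astype(np.uint8)
        self.tract_ids = np.asarray(self.tract_ids)
        if self.tract_ids.shape[0] != self.values.shape[0]:
            raise ValueError("tract_ids length does not match number of rows")
        if len(np.unique(self.tract_ids)) != len(self.tract_ids):
            raise ValueError("tract_ids must be unique")
        self.variable_names = list(self.variable_names)
        if len(self.variable_names) != self.values.shape[1]:
            raise ValueError("variable_names length does not match number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, id_col: str = "tract_id") -> "BinaryDesignMatrix":
        cols = [c for c in frame.columns if c != id_col]
        ids = frame[id_col].to_numpy() if id_col in frame.columns else np.arange(len(frame))
        return cls(frame[cols].to_numpy(), ids, cols)

    def to_frame(self, id_col: str = "tract_id") -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=self.variable_names)
        out.insert(0, id_col, self.tract_ids)
        return out
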