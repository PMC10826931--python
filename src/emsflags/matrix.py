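"""Named-column numeric matrices aligned to cohort record ids.

All featurizers emit a :class:`FeatureMatrix`; models consume one and align
columns by name, so matrices from different featurizers never mix silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """A dense numeric matrix with row ids and unique column names.

    Parameters
    ----------
    record_ids : list of str
        One id per row, in cohort order.
    column_names : list of str
        Unique names, one per column.
    values : ndarray of shape (n_records, n_columns)
        Finite numeric values; no missing cells are permitted.
    """

    record_ids: list = field(repr=False)
    column_names: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.record_ids = list(self.record_ids)
        self.column_names = list(self.column_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.record_ids):
            raise ValueError(
                f"{len(self.record_ids)} record ids but {n} matrix rows"
            )
        if p != len(self.column_names):
            raise ValueError(
                f"{len(self.column_names)} column names but {p} matrix columns"
            )
        if len(set(self.column_names)) != p:
            raise ValueError("column names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite cells")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def select(self, names) -> "FeatureMatrix":
        """Reorder/subset columns by name (raises on unknown names)."""
        idx = [self.column_names.index(c) for c in names]
        return FeatureMatrix(self.record_ids, list(names), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.record_ids, columns=self.column_names
        )


def hstack(matrices) -> FeatureMatrix:
    """Concatenate feature matrices sharing identical record ids."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to stack")
    ids = matrices[0].record_ids
    for m in matrices[1:]:
        if m.record_ids != ids:
            raise ValueError("record ids differ between matrices")
    names = [c for m in matrices for c in m.column_names]
    return FeatureMatrix(ids, names, np.hstack([m.values for m in matrices]))
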