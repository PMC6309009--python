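"""Symmetric dyadic matrices keyed by individual identity.

Every pairwise quantity in the pipeline (association indices, structural
predictors, affiliation residuals) lives in a :class:`DyadMatrix`: a symmetric
``n x n`` float array plus the ordered list of individual ids that labels its
rows and columns.  The diagonal is undefined and stored as NaN; dyads whose
value is undefined (e.g. a pair never observed at the same time) are also NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DyadMatrix", "upper_indices"]


def upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle of an n x n matrix."""
    return np.triu_indices(n, k=1)


@dataclass
class DyadMatrix:
    """A symmetric individual-by-individual matrix.

    Parameters
    ----------
    ids
        Ordered individual identifiers labelling rows and columns.
    values
        Symmetric float array; the diagonal is forced to NaN on construction.
    kind
        Free tag describing what the values are ("HWI", "HWIG", "GAI",
        "PREDICTOR", ...).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "HWI"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids and matrix size disagree")
        off = ~np.eye(v.shape[0], dtype=bool)
        a, b = v[off], v.T[off]
        ok = np.isclose(a, b, equal_nan=True, rtol=1e-9, atol=1e-12)
        if not ok.all():
            raise ValueError("matrix is not symmetric")
        np.fill_diagonal(v, np.nan)
        self.values = v

    # -- basic introspection -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(str(individual_id))

    def offdiag(self) -> np.ndarray:
        """Values of the strict upper triangle (one entry per dyad)."""
        iu, ju = upper_indices(self.n)
        return self.values[iu, ju]

    def dyads(self) -> Iterable[tuple[str, str, float]]:
        iu, ju = upper_indices(self.n)
        for i, j in zip(iu, ju):
            yield self.ids[i], self.ids[j], float(self.values[i, j])

    # -- conversions ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = [(a, b, v) for a, b, v in self.dyads()]
        return pd.DataFrame(rows, columns=["id1", "id2", "value"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "HWI") -> "DyadMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("square frame with matching index/columns required")
        return cls(list(frame.index), frame.to_numpy(dtype=float), kind=kind)

    def reorder(self, ids: Sequence[str]) -> "DyadMatrix":
        """Return a copy with rows/columns in the given id order."""
        idx = [self.index_of(i) for i in ids]
        return DyadMatrix(list(ids), self.values[np.ix_(idx, idx)], kind=self.kind)

    def masked(self) -> np.ndarray:
        """Boolean matrix of undefined (NaN) off-diagonal entries."""
        m = np.isnan(self.values)
        np.fill_diagonal(m, False)
        return m
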