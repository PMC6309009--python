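"""Dyadic association counts and the half-weight family of indices.

Two animals photographed in the same group on the same survey day are scored
as associated on that sampling occasion.  From each dyad's counts

* ``x``     - occasions on which both were identified in one group,
* ``y_ab``  - occasions on which both were identified but never co-grouped,
* ``y_a``   - occasions on which only the first was identified,
* ``y_b``   - occasions on which only the second was identified,

the half-weight index ``HWI = x / (x + y_ab + 0.5 * (y_a + y_b))`` estimates
the proportion of time a pair spends together while down-weighting occasions
where identification was one-sided (the reason the index is favoured for
photo-identification data).  The gregariousness-corrected variant HWIG
rescales each dyad by the total sociality of its two members so that 1 is the
random-association expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import DyadMatrix

__all__ = [
    "AssociationCounts",
    "tally_counts",
    "hwi",
    "hwig",
    "typical_group_size",
]


@dataclass
class AssociationCounts:
    """Sufficient statistics for dyadic association indices.

    ``x`` counts co-grouped occasions per dyad, ``n_both`` counts occasions on
    which both members were identified (in any group), and ``seen`` counts the
    occasions each individual was identified.  ``y_ab``, ``y_a``, ``y_b`` are
    derived, avoiding n**2 storage of occasion sets.
    """

    ids: list[str]
    x: np.ndarray
    n_both: np.ndarray
    seen: np.ndarray
    n_occasions: int

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def y_ab(self) -> np.ndarray:
        return self.n_both - self.x

    @property
    def y_a(self) -> np.ndarray:
        """Occasions where the row individual (only) was identified."""
        return self.seen[:, None] - self.n_both

    @property
    def y_b(self) -> np.ndarray:
        return self.seen[None, :] - self.n_both

    def hwi_denominator(self) -> np.ndarray:
        """x + y_ab + 0.5 (y_a + y_b), which reduces to (seen_a + seen_b)/2."""
        return self.x + self.y_ab + 0.5 * (self.y_a + self.y_b)

    def sampling_denominator(self) -> np.ndarray:
        """x + y_ab + y_a + y_b: occasions on which either member was seen."""
        return self.seen[:, None] + self.seen[None, :] - self.n_both

    def validate(self) -> None:
        assert (self.x >= 0).all() and (self.n_both >= self.x).all()
        assert np.array_equal(self.x, self.x.T)
        assert np.array_equal(self.n_both, self.n_both.T)
        off = ~np.eye(self.n, dtype=bool)
        assert (self.sampling_denominator()[off] <= self.n_occasions).all()


def tally_counts(records: pd.DataFrame, ids: list[str] | None = None) -> AssociationCounts:
    """Count co-grouped and co-identified occasions for every dyad.

    Within one occasion a dyad sharing at least one group scores a single
    association event; repeat co-sightings on the same day collapse (the day
    is the sampling period).
    """
    if records.duplicated(["occasion_id", "group_id", "individual_id"]).any():
        raise ValueError("duplicate (occasion, group, individual) rows")
    if ids is None:
        ids = sorted(records["individual_id"].astype(str).unique())
    idx = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    x = np.zeros((n, n), dtype=np.int64)
    n_both = np.zeros((n, n), dtype=np.int64)
    seen = np.zeros(n, dtype=np.int64)

    occasions = records.groupby("occasion_id", sort=False)
    for _, occ in occasions:
        present: set[int] = set()
        co: set[tuple[int, int]] = set()
        for _, grp in occ.groupby("group_id", sort=False):
            members = sorted({idx[i] for i in grp["individual_id"].astype(str) if i in idx})
            present.update(members)
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    co.add((members[a], members[b]))
        pres = sorted(present)
        for k, i in enumerate(pres):
            seen[i] += 1
            for j in pres[k + 1 :]:
                n_both[i, j] += 1
                n_both[j, i] += 1
        for i, j in co:
            x[i, j] += 1
            x[j, i] += 1
    counts = AssociationCounts(list(ids), x, n_both, seen, occasions.ngroups)
    counts.validate()
    return counts


def hwi(counts: AssociationCounts) -> DyadMatrix:
    """Half-weight index matrix; zero-denominator dyads are NaN (undefined)."""
    denom = counts.hwi_denominator()
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, counts.x / np.where(denom > 0, denom, 1.0), np.nan)
    return DyadMatrix(counts.ids, values, kind="HWI")


def hwig(hwi_matrix: DyadMatrix) -> DyadMatrix:
    """Gregariousness-corrected half-weight index.

    ``HWIG_ab = HWI_ab * sum(all HWI) / (sum_a HWI * sum_b HWI)`` where the
    row sums exclude the diagonal.  Equals 1 for every dyad when all pairs
    associate at random given their gregariousness.  Rows whose total HWI is
    zero are undefined and returned as NaN.
    """
    if hwi_matrix.n < 3:
        raise ValueError("HWIG needs at least 3 individuals")
    v = hwi_matrix.values
    row = np.nansum(v, axis=1)
    # grand total over all ordered pairs (= sum of the row sums)
    total = float(row.sum())
    if (row == 0).any():
        warnings.warn("individual(s) with zero total HWI: HWIG rows undefined",
                      stacklevel=2)
    denom = np.outer(row, row)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = v * total / denom
    out[denom == 0] = np.nan
    return DyadMatrix(hwi_matrix.ids, out, kind="HWIG")


def typical_group_size(records: pd.DataFrame) -> tuple[pd.Series, float]:
    """Mean identified group size experienced by each individual.

    Group size is the number of identified individuals in the group, including
    the focal animal.  Also returns the across-individual standard deviation,
    the statistic of the gregariousness permutation test.
    """
    sizes = records.groupby(["occasion_id", "group_id"])["individual_id"].transform(
        "nunique"
    )
    per = (
        records.assign(_gs=sizes)
        .groupby("individual_id")["_gs"]
        .mean()
        .rename("typical_group_size")
    )
    sd = float(per.std(ddof=1)) if len(per) > 1 else 0.0
    return per, sd
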