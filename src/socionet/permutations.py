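"""Constrained permutation null models for association data.

The null model follows the Bejder/Manly "swap" construction: within each
sampling occasion, the group-by-individual incidence matrix is perturbed by
random 2x2 checkerboard swaps.  Every swap exchanges two individuals between
two groups of the same occasion, so group sizes, the number of groups per
occasion and each individual's per-occasion membership count are all
conserved; only *who* is with *whom* changes.  Permuted datasets are produced
as a sequential chain (each differs from the previous one by a configured
number of swaps), the SOCPROG practice, with a burn-in from the observed data.

Test statistics compared against this null:

* SD / CV of the association index (upper tail -> long-term preferred
  companionship),
* mean association index (lower tail -> short-term preference),
* proportion of nonzero dyads (lower tail -> avoidance),
* SD of the typical group size (upper tail -> gregariousness differences).

All p-values are permutation p-values ``(k + 1) / (N + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from numba import njit

from .matrices import DyadMatrix, upper_indices

__all__ = [
    "PermutationConfig",
    "NullResult",
    "OccasionIncidence",
    "build_incidence",
    "permute_within_occasions",
    "null_model_battery",
    "companionship_test",
    "gregariousness_test",
    "mantel_class_test",
]


# ---------------------------------------------------------------------------
# incidence representation
# ---------------------------------------------------------------------------

@dataclass
class OccasionIncidence:
    """Per-occasion group membership in a flat, kernel-friendly layout.

    ``inc`` stacks the group-by-individual boolean incidence matrices of all
    occasions; groups of occasion ``t`` occupy rows
    ``occ_start[t]:occ_start[t+1]``.
    """

    ids: list[str]
    inc: np.ndarray          # bool (total groups, n individuals)
    occ_start: np.ndarray    # int64 (n_occasions + 1,)
    occasion_ids: list

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_occasions(self) -> int:
        return len(self.occ_start) - 1

    def copy(self) -> "OccasionIncidence":
        return OccasionIncidence(
            list(self.ids), self.inc.copy(), self.occ_start.copy(), list(self.occasion_ids)
        )

    def eligible_occasions(self) -> np.ndarray:
        """Occasions with >= 2 groups, the only ones a swap can touch."""
        sizes = np.diff(self.occ_start)
        elig = np.where(sizes >= 2)[0].astype(np.int64)
        if elig.size == 0:
            warnings.warn("no occasion has two groups; swaps are impossible",
                          stacklevel=2)
        return elig


def build_incidence(records: pd.DataFrame, ids: list[str] | None = None) -> OccasionIncidence:
    """Compile sighting records into per-occasion incidence matrices.

    Individuals appearing in more than one group on the same occasion keep
    only their first membership (the engine permutes single memberships).
    """
    if ids is None:
        ids = sorted(records["individual_id"].astype(str).unique())
    idx = {ind: k for k, ind in enumerate(ids)}
    rows: list[np.ndarray] = []
    occ_start = [0]
    occ_ids = []
    n = len(ids)
    for occ_id, occ in records.groupby("occasion_id", sort=True):
        taken: set[int] = set()
        for _, grp in occ.groupby("group_id", sort=True):
            row = np.zeros(n, dtype=bool)
            for ind in grp["individual_id"].astype(str):
                k = idx.get(ind)
                if k is not None and k not in taken:
                    row[k] = True
                    taken.add(k)
            if row.any():
                rows.append(row)
        occ_start.append(len(rows))
        occ_ids.append(occ_id)
    inc = np.array(rows, dtype=bool) if rows else np.zeros((0, n), dtype=bool)
    return OccasionIncidence(list(ids), inc, np.asarray(occ_start, dtype=np.int64), occ_ids)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _do_flips(inc, occ_start, eligible, n_flips):
    """Apply ``n_flips`` checkerboard swaps in place; returns swaps done.

    Each attempt draws an eligible occasion, two distinct groups in it and one
    member of each; the swap is valid when neither individual already sits in
    the other group.  Attempts are capped at 200 per requested flip so that
    datasets with almost no feasible checkerboard cannot hang the chain.
    """
    n = inc.shape[1]
    done = 0
    attempts = 0
    max_attempts = 200 * n_flips + 1000
    members_a = np.empty(n, np.int64)
    members_b = np.empty(n, np.int64)
    while done < n_flips and attempts < max_attempts:
        attempts += 1
        t = eligible[np.random.randint(eligible.shape[0])]
        g0 = occ_start[t]
        ng = occ_start[t + 1] - g0
        ga = g0 + np.random.randint(ng)
        gb = g0 + np.random.randint(ng)
        if ga == gb:
            continue
        ma = 0
        mb = 0
        for i in range(n):
            if inc[ga, i]:
                members_a[ma] = i
                ma += 1
            if inc[gb, i]:
                members_b[mb] = i
                mb += 1
        if ma == 0 or mb == 0:
            continue
        i = members_a[np.random.randint(ma)]
        j = members_b[np.random.randint(mb)]
        if inc[gb, i] or inc[ga, j]:
            continue
        inc[ga, i] = False
        inc[gb, i] = True
        inc[gb, j] = False
        inc[ga, j] = True
        done += 1
    return done


@njit(cache=True)
def _counts(inc, occ_start):
    """Dyadic sufficient statistics of an incidence stack.

    Returns co-grouped occasion counts ``x``, co-identified occasion counts
    ``both``, per-individual occasion counts ``seen`` and the per-individual
    typical-group-size sum/count accumulators.
    """
    n = inc.shape[1]
    n_occ = occ_start.shape[0] - 1
    x = np.zeros((n, n), np.int64)
    both = np.zeros((n, n), np.int64)
    seen_tot = np.zeros(n, np.int64)
    tgs_sum = np.zeros(n, np.float64)
    tgs_cnt = np.zeros(n, np.int64)
    members = np.empty(n, np.int64)
    seen = np.zeros(n, np.bool_)
    pres = np.empty(n, np.int64)
    for t in range(n_occ):
        for i in range(n):
            seen[i] = False
        for g in range(occ_start[t], occ_start[t + 1]):
            m = 0
            for i in range(n):
                if inc[g, i]:
                    members[m] = i
                    m += 1
            for a in range(m):
                i = members[a]
                seen[i] = True
                tgs_sum[i] += m
                tgs_cnt[i] += 1
                for b in range(a + 1, m):
                    j = members[b]
                    x[i, j] += 1
                    x[j, i] += 1
        np_pres = 0
        for i in range(n):
            if seen[i]:
                pres[np_pres] = i
                np_pres += 1
                seen_tot[i] += 1
        for a in range(np_pres):
            i = pres[a]
            for b in range(a + 1, np_pres):
                j = pres[b]
                both[i, j] += 1
                both[j, i] += 1
    return x, both, seen_tot, tgs_sum, tgs_cnt


# ---------------------------------------------------------------------------
# statistics on one incidence state
# ---------------------------------------------------------------------------

def _index_matrix(x, both, seen, which: str) -> np.ndarray:
    denom = 0.5 * (seen[:, None] + seen[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        hwi = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(hwi, np.nan)
    if which == "hwi":
        return hwi
    row = np.nansum(hwi, axis=1)
    total = row.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = hwi * total / np.outer(row, row)
    out[np.outer(row, row) == 0] = np.nan
    return out


_STATS = ("mean", "sd", "cv", "prop_nonzero", "tgs_sd")


def _state_stats(x, both, seen, tgs_sum, tgs_cnt, which: str) -> np.ndarray:
    n = seen.shape[0]
    iu, ju = upper_indices(n)
    vals = _index_matrix(x, both, seen, which)[iu, ju]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        mean = sd = cv = pnz = 0.0
    else:
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        cv = sd / mean if mean > 0 else 0.0
        pnz = float((vals > 0).mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        tgs = tgs_sum[tgs_cnt > 0] / tgs_cnt[tgs_cnt > 0]
    tgs_sd = float(np.std(tgs, ddof=1)) if tgs.size > 1 else 0.0
    return np.array([mean, sd, cv, pnz, tgs_sd])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    """Settings of the swap chain.

    Defaults mirror the full-scale analysis (40,000 recorded permutations,
    1,000 swaps between consecutive recordings); test suites run the same
    machinery at reduced counts.
    """

    n_permutations: int = 40_000
    flips_per_permutation: int = 1_000
    burn_in: int = 1_000
    seed: int = 0
    index: str = "hwi"  # or "hwig"

    def __post_init__(self) -> None:
        if self.n_permutations < 1 or self.flips_per_permutation < 1:
            raise ValueError("n_permutations and flips must be >= 1")
        if self.index not in ("hwi", "hwig"):
            raise ValueError("index must be 'hwi' or 'hwig'")


@dataclass
class NullResult:
    """Observed statistic against its permutation distribution."""

    statistic: str
    real_value: float
    null_values: np.ndarray
    tail: str  # "upper" or "lower"

    @property
    def null_mean(self) -> float:
        return float(self.null_values.mean())

    @property
    def p_value(self) -> float:
        k = (
            int((self.null_values >= self.real_value).sum())
            if self.tail == "upper"
            else int((self.null_values <= self.real_value).sum())
        )
        return (k + 1) / (len(self.null_values) + 1)

    def trace(self) -> np.ndarray:
        """Running p-value after each recorded permutation (stabilisation)."""
        if self.tail == "upper":
            k = np.cumsum(self.null_values >= self.real_value)
        else:
            k = np.cumsum(self.null_values <= self.real_value)
        n = np.arange(1, len(self.null_values) + 1)
        return (k + 1) / (n + 1)


def _run_chain(
    incidence: OccasionIncidence, config: PermutationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Observed stats and the (n_permutations x n_stats) null stats matrix."""
    work = incidence.copy()
    elig = work.eligible_occasions()
    real = _state_stats(*_counts(work.inc, work.occ_start), config.index)
    _seed(np.uint32(config.seed))
    if elig.size:
        _do_flips(work.inc, work.occ_start, elig, config.burn_in)
    null = np.empty((config.n_permutations, len(_STATS)))
    for p in range(config.n_permutations):
        if elig.size:
            _do_flips(work.inc, work.occ_start, elig, config.flips_per_permutation)
        null[p] = _state_stats(*_counts(work.inc, work.occ_start), config.index)
    return real, null


def permute_within_occasions(
    incidence: OccasionIncidence, config: PermutationConfig
) -> Iterator[OccasionIncidence]:
    """Yield successive states of the swap chain (after burn-in).

    The yielded object is the chain's working copy: consume it immediately or
    ``copy()`` it.  Used by the network-metric comparison, which needs whole
    permuted datasets rather than scalar statistics.
    """
    work = incidence.copy()
    elig = work.eligible_occasions()
    _seed(np.uint32(config.seed))
    if elig.size:
        _do_flips(work.inc, work.occ_start, elig, config.burn_in)
    for _ in range(config.n_permutations):
        if elig.size:
            _do_flips(work.inc, work.occ_start, elig, config.flips_per_permutation)
        yield work


_TAILS = {
    "mean": "lower",
    "sd": "upper",
    "cv": "upper",
    "prop_nonzero": "lower",
    "tgs_sd": "upper",
}


def null_model_battery(
    records: pd.DataFrame,
    config: PermutationConfig | None = None,
    ids: list[str] | None = None,
) -> dict[str, NullResult]:
    """All five swap-null tests from a single permutation chain."""
    config = config or PermutationConfig()
    incidence = build_incidence(records, ids)
    real, null = _run_chain(incidence, config)
    return {
        stat: NullResult(stat, float(real[k]), null[:, k], _TAILS[stat])
        for k, stat in enumerate(_STATS)
    }


def companionship_test(
    records: pd.DataFrame,
    config: PermutationConfig | None = None,
    ids: list[str] | None = None,
) -> dict[str, NullResult]:
    """Population-level preferred/avoided companionship tests.

    Returns :class:`NullResult` for the SD, CV, mean and proportion-nonzero of
    the association index, each against the within-occasion swap null.
    """
    battery = null_model_battery(records, config, ids)
    return {k: battery[k] for k in _STATS[:4]}


def gregariousness_test(
    records: pd.DataFrame,
    config: PermutationConfig | None = None,
    ids: list[str] | None = None,
) -> NullResult:
    """SD of the typical group size against the swap null (upper tail).

    A significantly high SD indicates individuals that are consistently found
    in larger (or smaller) groups than others, the cue for preferring the
    gregariousness-corrected index.
    """
    return null_model_battery(records, config, ids)["tgs_sd"]


def mantel_class_test(
    dyad_matrix: DyadMatrix,
    class_labels: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Do same-class dyads associate more than different-class dyads?

    The statistic is the within-class minus between-class mean difference,
    standardised by its permutation spread (random relabelling of individuals,
    the matrix-permutation construction of Schnell-style Mantel tests).
    Returns ``(t, p)`` with a one-sided upper-tail p-value.
    """
    labels = class_labels.reindex(dyad_matrix.ids)
    if labels.isna().any():
        raise ValueError("class label missing for some individuals")
    counts = labels.value_counts()
    small = counts[counts < 2]
    if len(small):
        warnings.warn(
            f"classes with <2 members contribute no within-class dyads: "
            f"{list(small.index)}",
            stacklevel=2,
        )
    lab = labels.to_numpy()
    v = dyad_matrix.values
    iu, ju = upper_indices(dyad_matrix.n)
    vals = v[iu, ju]
    ok = ~np.isnan(vals)

    def diff(l: np.ndarray) -> float:
        same = l[iu] == l[ju]
        w = vals[ok & same]
        b = vals[ok & ~same]
        if w.size == 0 or b.size == 0:
            return 0.0
        return float(w.mean() - b.mean())

    rng = np.random.default_rng(seed)
    d_obs = diff(lab)
    null = np.array([diff(rng.permutation(lab)) for _ in range(n_perm)])
    spread = null.std(ddof=1)
    t = (d_obs - null.mean()) / spread if spread > 0 else 0.0
    p = (int((null >= d_obs).sum()) + 1) / (n_perm + 1)
    return t, p
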