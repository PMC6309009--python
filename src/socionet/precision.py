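"""Social differentiation (S) and sampling precision (r).

How variable are the *true* association probabilities in the population, and
how faithfully does the estimated association matrix reflect them?  Following
Whitehead's likelihood approach, each dyad's co-occurrence count is modelled
as ``x_ab ~ Binomial(d_ab, p_ab)`` with the latent association probabilities
``p_ab`` drawn from a Beta(alpha, beta) mixing distribution fitted by maximum
likelihood.  Then

* ``S`` is the coefficient of variation of the fitted Beta,
  ``sqrt(beta / (alpha * (alpha + beta + 1)))`` - near 0 for homogeneous
  societies, near or above 1 for well-differentiated ones;
* ``r`` is the correlation between true and estimated association indices
  under the fitted model, obtained by Monte-Carlo integration over the
  empirical distribution of the per-dyad sample sizes ``d_ab``.

Standard errors come from bootstrapping sampling occasions (days are the
independent unit, dyads are not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .association import AssociationCounts
from .matrices import upper_indices
from .permutations import OccasionIncidence, _counts

__all__ = ["PrecisionEstimate", "fit_beta_binomial", "estimate_social_differentiation"]


@dataclass
class PrecisionEstimate:
    S: float
    r: float
    se_S: float | None
    se_r: float | None
    alpha: float
    beta: float
    loglik: float
    n_boot: int
    converged: bool


def _dyad_xd(counts: AssociationCounts) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = upper_indices(counts.n)
    x = counts.x[iu, ju]
    d = counts.sampling_denominator()[iu, ju]
    keep = d >= 1
    return x[keep].astype(np.int64), d[keep].astype(np.int64)


def _negloglik(logab: np.ndarray, x: np.ndarray, d: np.ndarray) -> float:
    a, b = np.exp(logab)
    if not (np.isfinite(a) and np.isfinite(b)):
        return np.inf
    ll = stats.betabinom.logpmf(x, d, a, b)
    return -float(ll.sum())


def fit_beta_binomial(
    x: np.ndarray,
    d: np.ndarray,
    n_starts: int = 5,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> tuple[float, float, float, bool]:
    """ML fit of Beta(alpha, beta) mixing over binomial dyad counts.

    Bounded quasi-Newton on (log alpha, log beta) from several random starts;
    returns (alpha, beta, loglik, converged).
    """
    rng = np.random.default_rng(seed)
    starts = [np.array([0.0, 1.0])]
    if x0 is not None:
        starts = [np.log(np.asarray(x0, dtype=float))] + starts
    while len(starts) < n_starts:
        starts.append(rng.uniform(-3, 3, size=2))
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _negloglik,
            s0,
            args=(x, d),
            method="L-BFGS-B",
            bounds=[(-12, 12), (-12, 12)],
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    converged = bool(best.success) or np.isfinite(best.fun)
    if not np.isfinite(best.fun):
        raise RuntimeError(f"beta-binomial fit failed: {best.message}")
    return float(a), float(b), -float(best.fun), converged


def _cv_of_beta(a: float, b: float) -> float:
    return float(np.sqrt(b / (a * (a + b + 1.0))))


def _mc_correlation(
    a: float, b: float, d_pool: np.ndarray, n_mc: int, rng: np.random.Generator
) -> float:
    """corr(true p, x/d) under the fitted model and the observed d mix."""
    d = rng.choice(d_pool, size=n_mc, replace=True)
    p = rng.beta(a, b, size=n_mc)
    xs = rng.binomial(d, p)
    est = xs / d
    sd_p, sd_e = p.std(), est.std()
    if sd_p == 0 or sd_e == 0 or not (np.isfinite(sd_p) and np.isfinite(sd_e)):
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(np.corrcoef(p, est)[0, 1])


def estimate_social_differentiation(
    counts: AssociationCounts,
    incidence: OccasionIncidence | None = None,
    n_boot: int = 0,
    n_mc: int = 20_000,
    seed: int = 0,
) -> PrecisionEstimate:
    """Estimate S and r (with optional occasion-bootstrap standard errors).

    ``incidence`` (the per-occasion group structure) is required when
    ``n_boot > 0``, because the bootstrap resamples whole sampling occasions
    and re-tallies the dyadic counts from them.
    """
    rng = np.random.default_rng(seed)
    x, d = _dyad_xd(counts)
    if x.size == 0:
        raise ValueError("no dyads with d >= 1")
    a, b, ll, conv = fit_beta_binomial(x, d, seed=seed)
    S = _cv_of_beta(a, b)
    if a >= np.exp(11.9) or b <= np.exp(-11.9):
        warnings.warn("degenerate fit (S -> 0); reporting boundary value",
                      stacklevel=2)
        S = 0.0
    r = _mc_correlation(a, b, d, n_mc, rng)

    se_S = se_r = None
    if n_boot > 0:
        if incidence is None:
            raise ValueError("occasion bootstrap needs the incidence structure")
        Ss, rs = _bootstrap(incidence, (a, b), n_boot, n_mc, rng)
        se_S = float(np.std(Ss, ddof=1))
        se_r = float(np.std(rs, ddof=1))
    return PrecisionEstimate(S, r, se_S, se_r, a, b, ll, n_boot, conv)


def _bootstrap(
    incidence: OccasionIncidence,
    ab0: tuple[float, float],
    n_boot: int,
    n_mc: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n_occ = incidence.n_occasions
    Ss = np.empty(n_boot)
    rs = np.empty(n_boot)
    starts = incidence.occ_start
    for bi in range(n_boot):
        pick = rng.integers(0, n_occ, size=n_occ)
        rows = [np.arange(starts[t], starts[t + 1]) for t in pick]
        occ_start = np.zeros(n_occ + 1, dtype=np.int64)
        occ_start[1:] = np.cumsum([len(r) for r in rows])
        inc = incidence.inc[np.concatenate(rows)] if rows else incidence.inc[:0]
        xm, both, seen, _, _ = _counts(inc, occ_start)
        iu, ju = upper_indices(incidence.n)
        xv = xm[iu, ju]
        dv = (seen[:, None] + seen[None, :] - both)[iu, ju]
        keep = dv >= 1
        a, b, _, _ = fit_beta_binomial(
            xv[keep], dv[keep], n_starts=1, x0=np.array(ab0)
        )
        Ss[bi] = _cv_of_beta(a, b)
        rs[bi] = _mc_correlation(a, b, dv[keep], max(2000, n_mc // 10), rng)
    return Ss, rs
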