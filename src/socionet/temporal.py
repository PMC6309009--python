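"""Temporal stability of associations: SLAR, SNAR and decay models.

The standardized lagged association rate g(tau) estimates the probability
that an associate of a focal animal, re-examined tau days later, is still an
associate - standardised so that incomplete identification of group members
does not bias the estimate.  For every ordered pair of occasions (t, t') and
every focal individual identified at both:

* the numerator accumulates the associates shared between t and t',
* the denominator accumulates (associates at t) x (associates at t'),

so the ratio is a weighted conditional probability; for a stable group of
size k it equals 1/(k-1), and for daily random re-association it falls to
the null rate.  The null (SNAR) is obtained empirically by relabelling the
identities of each occasion's individuals at the later time, which preserves
group sizes and identification effort while destroying identity persistence.

Four decay models are fitted to the pair-persistence events by maximum
binomial pseudo-likelihood and ranked by QAIC (the quasi-likelihood AIC,
with the overdispersion factor c-hat taken from the most general model):

* preferred companions            g(tau) = a2
* casual acquaintances            g(tau) = a2 * exp(-a1 tau)
* both                            g(tau) = a3 + a2 * exp(-a1 tau)
* two levels of casual            g(tau) = a3 * exp(-a1 tau) + a2 * exp(-a4 tau)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LagCurve",
    "DecayModelFit",
    "pair_events",
    "slar",
    "snar",
    "jackknife_se",
    "fit_decay_models",
]


# ---------------------------------------------------------------------------
# occasion structures
# ---------------------------------------------------------------------------

def _occasion_structures(
    records: pd.DataFrame, ids: list[str] | None = None, subset: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-occasion day numbers, adjacency stacks and identification masks.

    ``subset`` restricts both focal and associate individuals (within-unit
    rates).  Returns (days, adj, ident) with adj boolean (n_occ, n, n).
    """
    if ids is None:
        ids = sorted(records["individual_id"].astype(str).unique())
    if subset is not None:
        keep = set(map(str, subset))
        records = records[records["individual_id"].astype(str).isin(keep)]
        ids = [i for i in ids if i in keep]
    idx = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    dates = pd.to_datetime(records["occasion_id"])
    day0 = dates.min()
    occ_groups = records.assign(_day=(dates - day0).dt.days).groupby("occasion_id", sort=True)
    n_occ = occ_groups.ngroups
    days = np.empty(n_occ, dtype=np.int64)
    adj = np.zeros((n_occ, n, n), dtype=bool)
    ident = np.zeros((n_occ, n), dtype=bool)
    for t, (_, occ) in enumerate(occ_groups):
        days[t] = occ["_day"].iloc[0]
        for _, grp in occ.groupby("group_id", sort=True):
            members = [idx[i] for i in grp["individual_id"].astype(str) if i in idx]
            for a in members:
                ident[t, a] = True
            for ai in range(len(members)):
                for bi in range(ai + 1, len(members)):
                    adj[t, members[ai], members[bi]] = True
                    adj[t, members[bi], members[ai]] = True
    return days, adj, ident


def pair_events(
    records: pd.DataFrame,
    ids: list[str] | None = None,
    subset: list[str] | None = None,
    occasion_keep: np.ndarray | None = None,
) -> pd.DataFrame:
    """Numerator/denominator persistence events aggregated per exact lag.

    ``occasion_keep`` (boolean over occasions, in sorted occasion order)
    supports the jackknife's block deletion.  Returns a frame with columns
    ``lag``, ``num``, ``den`` sorted by lag.
    """
    days, adj, ident = _occasion_structures(records, ids, subset)
    return _events_from_structures(days, adj, ident, occasion_keep)


def _events_from_structures(
    days: np.ndarray,
    adj: np.ndarray,
    ident: np.ndarray,
    occasion_keep: np.ndarray | None = None,
) -> pd.DataFrame:
    n_occ = len(days)
    use = np.arange(n_occ) if occasion_keep is None else np.where(occasion_keep)[0]
    acc: dict[int, list[float]] = {}
    deg = adj.sum(axis=2)  # associates identified per focal per occasion
    for a_i in range(len(use)):
        t = use[a_i]
        for b_i in range(a_i + 1, len(use)):
            u = use[b_i]
            lag = int(days[u] - days[t])
            if lag <= 0:
                continue
            focal = ident[t] & ident[u]
            if not focal.any():
                continue
            shared = (adj[t] & adj[u]).sum(axis=1)
            num = float(shared[focal].sum())
            den = float((deg[t] * deg[u])[focal].sum())
            if den == 0:
                continue
            ent = acc.setdefault(lag, [0.0, 0.0])
            ent[0] += num
            ent[1] += den
    rows = [(lag, v[0], v[1]) for lag, v in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["lag", "num", "den"])


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass
class LagCurve:
    """Association rate vs. time lag (days)."""

    lag: np.ndarray          # representative lag per bin (den-weighted mean)
    rate: np.ndarray
    den: np.ndarray          # denominator mass per bin
    se: np.ndarray | None = None
    null_rate: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"lag": self.lag, "slar": self.rate, "den": self.den})
        if self.null_rate is not None:
            out["snar"] = self.null_rate
        if self.se is not None:
            out["se"] = self.se
        return out


def _smooth(events: pd.DataFrame, window: float | None) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
    """Aggregate exact-lag events into smoothing windows.

    Consecutive lags are pooled until the accumulated denominator reaches
    ``window`` association records (the moving-average convention for these
    curves).  ``window=None`` or <= the smallest denominator keeps every lag
    separate, so a unit window reproduces the unsmoothed curve.
    """
    lags = events["lag"].to_numpy(float)
    num = events["num"].to_numpy(float)
    den = events["den"].to_numpy(float)
    if window is None:
        window = 0.0
    bins: list[np.ndarray] = []
    cur: list[int] = []
    d_acc = 0.0
    for i in range(len(lags)):
        cur.append(i)
        d_acc += den[i]
        if d_acc >= window:
            bins.append(np.array(cur))
            cur = []
            d_acc = 0.0
    if cur:
        bins.append(np.array(cur))
    lag_out = np.array([np.average(lags[b], weights=den[b]) for b in bins])
    num_out = np.array([num[b].sum() for b in bins])
    den_out = np.array([den[b].sum() for b in bins])
    return lag_out, num_out / den_out, den_out, bins


def slar(
    records: pd.DataFrame,
    ids: list[str] | None = None,
    subset: list[str] | None = None,
    window: float | None = None,
) -> LagCurve:
    """Standardized lagged association rate curve.

    ``window`` is the moving-average width in association records (the
    denominator mass pooled per plotted point); the study-scale conventions
    are 8,000 for the whole population and 5,000 within units.
    """
    ev = pair_events(records, ids, subset)
    if ev.empty:
        raise ValueError("need at least two sampling occasions with overlap")
    lag, rate, den, _ = _smooth(ev, window)
    return LagCurve(lag, rate, den)


def snar(
    records: pd.DataFrame,
    ids: list[str] | None = None,
    subset: list[str] | None = None,
    window: float | None = None,
    n_rand: int = 100,
    seed: int = 0,
) -> LagCurve:
    """Standardized NULL association rate by identity randomisation.

    Identities of the individuals identified on the later occasion are
    relabelled uniformly at random within that occasion (preserving group
    sizes, gregariousness and identification effort), and the SLAR machinery
    is re-run; the returned curve averages ``n_rand`` randomisations on the
    binning of the observed curve.
    """
    days, adj, ident = _occasion_structures(records, ids, subset)
    obs = _events_from_structures(days, adj, ident)
    lag_out, _, _, bins = _smooth(obs, window)
    rng = np.random.default_rng(seed)
    n = adj.shape[1]
    totals = np.zeros((n_rand, len(obs)))
    dens = np.zeros((n_rand, len(obs)))
    for r in range(n_rand):
        adj_r = np.empty_like(adj)
        ident_r = ident  # identified set is label-invariant per occasion
        for t in range(len(days)):
            pres = np.where(ident[t])[0]
            perm = np.arange(n)
            perm[pres] = rng.permutation(pres)
            inv = np.argsort(perm)
            adj_r[t] = adj[t][np.ix_(inv, inv)]
        ev = _events_from_structures(days, adj_r, ident_r)
        merged = obs[["lag"]].merge(ev, on="lag", how="left").fillna(0.0)
        totals[r] = merged["num"].to_numpy()
        dens[r] = merged["den"].to_numpy()
    num_mean = totals.mean(axis=0)
    den_mean = dens.mean(axis=0)
    rate = np.array(
        [
            num_mean[b].sum() / den_mean[b].sum() if den_mean[b].sum() > 0 else np.nan
            for b in bins
        ]
    )
    return LagCurve(lag_out, rate, np.array([den_mean[b].sum() for b in bins]))


def jackknife_se(
    records: pd.DataFrame,
    ids: list[str] | None = None,
    subset: list[str] | None = None,
    window: float | None = None,
    block: int = 10,
    reps: int = 1000,
) -> LagCurve:
    """Delete-block jackknife standard errors for the SLAR curve.

    Each replicate omits one contiguous block of ``block`` sampling
    occasions; with fewer distinct blocks than requested replicates the
    count truncates (every block used once - further cycling adds nothing).
    """
    days, adj, ident = _occasion_structures(records, ids, subset)
    n_occ = len(days)
    if n_occ < 2 * block:
        raise ValueError("need at least two blocks of occasions")
    obs = _events_from_structures(days, adj, ident)
    lag_out, rate, den_out, bins = _smooth(obs, window)
    starts = list(range(0, n_occ - block + 1, block))
    if reps < len(starts):
        starts = starts[:reps]
    elif reps > len(starts):
        warnings.warn(
            f"only {len(starts)} distinct blocks; truncating replicates",
            stacklevel=2,
        )
    g = len(starts)
    reps_rates = np.full((g, len(bins)), np.nan)
    for k, s in enumerate(starts):
        keep = np.ones(n_occ, dtype=bool)
        keep[s : s + block] = False
        ev = _events_from_structures(days, adj, ident, occasion_keep=keep)
        merged = obs[["lag"]].merge(ev, on="lag", how="left").fillna(0.0)
        num_k = merged["num"].to_numpy()
        den_k = merged["den"].to_numpy()
        reps_rates[k] = [
            num_k[b].sum() / den_k[b].sum() if den_k[b].sum() > 0 else np.nan
            for b in bins
        ]
    mean_rep = np.nanmean(reps_rates, axis=0)
    se = np.sqrt((g - 1) / g * np.nansum((reps_rates - mean_rep) ** 2, axis=0))
    return LagCurve(lag_out, rate, den_out, se=se)


# ---------------------------------------------------------------------------
# decay models
# ---------------------------------------------------------------------------

MODELS = ("CONSTANT", "EXPONENTIAL", "CONSTANT_PLUS_EXPONENTIAL", "DOUBLE_EXPONENTIAL")

_N_PARAMS = {
    "CONSTANT": 1,
    "EXPONENTIAL": 2,
    "CONSTANT_PLUS_EXPONENTIAL": 3,
    "DOUBLE_EXPONENTIAL": 4,
}


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-z))


def _model_rate(model: str, theta: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Rate g(tau); parameters live on unconstrained scales.

    Levels are logit-transformed (total level in (0,1), composite models
    split it by a logit fraction) and rates are log-transformed, keeping
    every parameter vector feasible.
    """
    if model == "CONSTANT":
        return np.full_like(tau, _sigmoid(theta[0]), dtype=float)
    if model == "EXPONENTIAL":
        return _sigmoid(theta[0]) * np.exp(-np.exp(theta[1]) * tau)
    if model == "CONSTANT_PLUS_EXPONENTIAL":
        level = _sigmoid(theta[0])
        f = _sigmoid(theta[1])
        return level * f + level * (1 - f) * np.exp(-np.exp(theta[2]) * tau)
    if model == "DOUBLE_EXPONENTIAL":
        level = _sigmoid(theta[0])
        f = _sigmoid(theta[1])
        return level * f * np.exp(-np.exp(theta[2]) * tau) + level * (1 - f) * np.exp(
            -np.exp(theta[3]) * tau
        )
    raise ValueError(model)


def natural_parameters(model: str, theta: np.ndarray) -> dict[str, float]:
    """Translate the unconstrained parameters into the a1..a4 convention."""
    if model == "CONSTANT":
        return {"a2": float(_sigmoid(theta[0]))}
    if model == "EXPONENTIAL":
        return {"a2": float(_sigmoid(theta[0])), "a1": float(np.exp(theta[1]))}
    if model == "CONSTANT_PLUS_EXPONENTIAL":
        level, f = _sigmoid(theta[0]), _sigmoid(theta[1])
        return {
            "a3": float(level * f),
            "a2": float(level * (1 - f)),
            "a1": float(np.exp(theta[2])),
        }
    level, f = _sigmoid(theta[0]), _sigmoid(theta[1])
    return {
        "a3": float(level * f),
        "a1": float(np.exp(theta[2])),
        "a2": float(level * (1 - f)),
        "a4": float(np.exp(theta[3])),
    }


@dataclass
class DecayModelFit:
    model: str
    theta: np.ndarray
    parameters: dict[str, float]
    loglik: float
    k: int
    qaic: float = np.nan
    delta_qaic: float = np.nan
    weight: float = np.nan
    c_hat: float = np.nan
    converged: bool = True


def _fit_one(model: str, tau: np.ndarray, num: np.ndarray, den: np.ndarray, seed: int) -> DecayModelFit:
    eps = 1e-10

    def nll(theta):
        g = np.clip(_model_rate(model, np.asarray(theta), tau), eps, 1 - eps)
        return -float(np.sum(num * np.log(g) + (den - num) * np.log(1 - g)))

    rng = np.random.default_rng(seed)
    p0_level = np.log(max(num.sum() / den.sum(), 1e-6) / max(1 - num.sum() / den.sum(), 1e-6))
    base = {
        "CONSTANT": np.array([p0_level]),
        "EXPONENTIAL": np.array([p0_level, np.log(1.0 / max(tau.max(), 1.0))]),
        "CONSTANT_PLUS_EXPONENTIAL": np.array([p0_level, 0.0, np.log(1.0 / max(tau.max(), 1.0))]),
        "DOUBLE_EXPONENTIAL": np.array(
            [p0_level, 0.0, np.log(5.0 / max(tau.max(), 1.0)), np.log(0.2 / max(tau.max(), 1.0))]
        ),
    }[model]
    best = None
    for trial in range(6):
        x0 = base if trial == 0 else base + rng.normal(0, 1.0, size=base.size)
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    ok = np.isfinite(best.fun)
    theta = np.asarray(best.x)
    return DecayModelFit(
        model=model,
        theta=theta,
        parameters=natural_parameters(model, theta),
        loglik=-float(best.fun),
        k=_N_PARAMS[model],
        converged=ok,
    )


def fit_decay_models(
    events: pd.DataFrame, seed: int = 0, c_hat: float | None = None
) -> list[DecayModelFit]:
    """Fit and QAIC-rank the four decay models on exact-lag events.

    The overdispersion factor c-hat defaults to the Pearson statistic of the
    most general (double-exponential) model divided by its residual degrees
    of freedom, floored at 1.  QAIC = -2 logL / c_hat + 2k; weights are the
    usual Akaike weights over the converged models.
    """
    tau = events["lag"].to_numpy(float)
    num = events["num"].to_numpy(float)
    den = events["den"].to_numpy(float)
    if len(tau) < 5:
        raise ValueError("too few distinct lags to fit decay models")
    fits = [_fit_one(m, tau, num, den, seed) for m in MODELS]
    general = fits[-1]
    if c_hat is None:
        g = np.clip(_model_rate(general.model, general.theta, tau), 1e-10, 1 - 1e-10)
        pearson = float(np.sum((num - den * g) ** 2 / (den * g * (1 - g))))
        dof = max(len(tau) - general.k, 1)
        c_hat = max(pearson / dof, 1.0)
    usable = [f for f in fits if f.converged]
    for f in fits:
        f.c_hat = c_hat
        f.qaic = -2.0 * f.loglik / c_hat + 2.0 * f.k
    best = min(f.qaic for f in usable)
    wsum = 0.0
    for f in usable:
        f.delta_qaic = f.qaic - best
        wsum += np.exp(-0.5 * f.delta_qaic)
    for f in usable:
        f.weight = float(np.exp(-0.5 * f.delta_qaic) / wsum)
    return sorted(fits, key=lambda f: (not f.converged, f.qaic))
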