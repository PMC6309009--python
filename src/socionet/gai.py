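"""Generalized affiliation indices (GAIs).

Association indices confound social preference with structural opportunity:
two gregarious animals sharing a home range will show a high half-weight
index with no affiliation at all.  A GAI is the residual of a dyadic binomial
regression of the association counts on structural predictor matrices - what
remains of an association once gregariousness, spatial overlap and the other
structural factors are accounted for.

Workflow (one call each):

1. :func:`mrqap_dsp` - significance of each predictor by the multiple
   regression quadratic assignment procedure with Dekker's double
   semi-partialing: the focal predictor is residualised on the others and
   permuted by simultaneous row/column relabelling.
2. :func:`stepwise_select` - backward elimination keeping predictors that are
   both significant and carry a non-trivial partial correlation.
3. :func:`fit_dyadic_binomial` - logit-link binomial GLM over dyads; its
   deviance residuals are the GAIs, and the variance-stabilised Anscombe
   residuals flag exceptional dyads (|residual| > 2.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import AssociationCounts
from .matrices import DyadMatrix, upper_indices

__all__ = [
    "GaiModel",
    "AffiliationCalls",
    "fit_dyadic_binomial",
    "mrqap_dsp",
    "stepwise_select",
    "call_affiliations",
]


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _dyad_design(
    counts: AssociationCounts, predictors: dict[str, DyadMatrix]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Vectorise counts and predictors over dyads.

    Returns (X, successes, trials, valid_mask, (iu, ju)).  Trials are the
    half-weight denominator rounded half-up to an integer; successes are
    clamped to the trials.  Dyads with zero trials or any undefined predictor
    are excluded from the fit (and masked in the residual matrices).
    """
    ids = counts.ids
    n = counts.n
    iu, ju = upper_indices(n)
    for name, p in predictors.items():
        if p.ids != ids:
            raise ValueError(f"predictor {name!r} has mismatched id order")
    denom = counts.hwi_denominator()[iu, ju]
    trials = np.floor(denom + 0.5).astype(np.int64)  # round half-up
    succ = np.minimum(counts.x[iu, ju], trials)
    X = np.column_stack([p.values[iu, ju] for p in predictors.values()]) if predictors else np.empty((len(iu), 0))
    valid = trials >= 1
    if X.size:
        valid &= ~np.isnan(X).any(axis=1)
    return X, succ, trials, valid, (iu, ju)


def _to_matrix(ids: list[str], iu, ju, vec: np.ndarray, valid: np.ndarray, kind: str) -> DyadMatrix:
    n = len(ids)
    m = np.full((n, n), np.nan)
    vals = np.full(valid.shape, np.nan)
    vals[valid] = vec
    m[iu, ju] = vals
    m[ju, iu] = vals
    return DyadMatrix(ids, m, kind=kind)


# ---------------------------------------------------------------------------
# binomial GLM -> GAIs
# ---------------------------------------------------------------------------

@dataclass
class GaiModel:
    """Fitted dyadic binomial model and its residual matrices."""

    predictor_names: list[str]
    coefficients: pd.Series
    deviance_residuals: DyadMatrix
    anscombe_residuals: DyadMatrix
    partial_correlations: pd.Series | None = None
    mrqap_p: pd.Series | None = None
    n_dyads: int = 0
    deviance: float = np.nan


def fit_dyadic_binomial(
    counts: AssociationCounts, predictors: dict[str, DyadMatrix]
) -> GaiModel:
    """Logit-link binomial regression of dyadic association on predictors.

    Each dyad is one observation with ``x_ab`` successes out of the rounded
    half-weight denominator.  The deviance-residual matrix is the GAI matrix;
    Anscombe residuals are computed alongside for the +/-2.5 affiliation
    calls.  Raises on non-convergence, reporting the predictor correlation
    structure to help diagnose collinearity.
    """
    X, succ, trials, valid, (iu, ju) = _dyad_design(counts, predictors)
    if valid.sum() < X.shape[1] + 1:
        raise ValueError("not enough valid dyads to fit the model")
    exog = sm.add_constant(X[valid], has_constant="add")
    endog = np.column_stack([succ[valid], trials[valid] - succ[valid]])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as err:  # pragma: no cover - diagnostic path
        corr = np.corrcoef(X[valid], rowvar=False) if X.shape[1] > 1 else None
        raise RuntimeError(
            f"binomial GLM failed to converge; predictor correlations:\n{corr}"
        ) from err
    names = ["intercept"] + list(predictors)
    coef = pd.Series(res.params, index=names)
    dev = _to_matrix(counts.ids, iu, ju, res.resid_deviance, valid, "GAI")
    ans = _to_matrix(counts.ids, iu, ju, res.resid_anscombe, valid, "GAI")
    return GaiModel(
        predictor_names=list(predictors),
        coefficients=coef,
        deviance_residuals=dev,
        anscombe_residuals=ans,
        n_dyads=int(valid.sum()),
        deviance=float(res.deviance),
    )


# ---------------------------------------------------------------------------
# MRQAP with double semi-partialing
# ---------------------------------------------------------------------------

def _ols_beta_t(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and t statistics (X already includes the intercept)."""
    beta, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = len(y) - rank
    resid = y - X @ beta
    s2 = float(resid @ resid) / max(dof, 1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 1e-300))
    return beta, beta / se


def mrqap_dsp(
    response: DyadMatrix,
    predictors: dict[str, DyadMatrix],
    n_perm: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """MRQAP significance of each predictor via double semi-partialing.

    For each predictor the procedure residualises it on the remaining
    predictors, permutes the residual *matrix* by simultaneous row/column
    relabelling of individuals (preserving its dyadic dependence structure),
    and compares the regression t statistic of the permuted residual against
    the observed one.  Two-sided permutation p-values use (k+1)/(N+1).

    Returns a frame indexed by predictor with columns ``coefficient``,
    ``partial_correlation`` and ``p``.
    """
    if not predictors:
        raise ValueError("at least one predictor required")
    ids = response.ids
    n = response.n
    iu, ju = upper_indices(n)
    y = response.values[iu, ju]
    names = list(predictors)
    cols = {}
    for name in names:
        p = predictors[name]
        if p.ids != ids:
            raise ValueError(f"predictor {name!r} has mismatched id order")
        cols[name] = p.values[iu, ju]
    Xfull = np.column_stack([cols[nm] for nm in names])
    valid = ~np.isnan(y) & ~np.isnan(Xfull).any(axis=1)
    y = y[valid]
    Xfull = Xfull[valid]
    # collinearity guard
    if Xfull.shape[1] > 1:
        cc = np.corrcoef(Xfull, rowvar=False)
        pair = np.unravel_index(np.nanargmax(np.abs(cc - np.eye(len(names)))), cc.shape)
        if abs(cc[pair]) > 0.999:
            raise ValueError(
                f"predictors {names[pair[0]]!r} and {names[pair[1]]!r} are collinear"
            )

    rng = np.random.default_rng(seed)
    rows = []
    intercept = np.ones(len(y))
    for k, name in enumerate(names):
        others = np.column_stack(
            [intercept] + [Xfull[:, j] for j in range(len(names)) if j != k]
        )
        pinv_o = np.linalg.pinv(others)
        xk = Xfull[:, k]
        ek = xk - others @ (pinv_o @ xk)  # residualised focal predictor
        yres = y - others @ (pinv_o @ y)
        # observed stats: regress y on [others, ek]
        Xo = np.column_stack([others, ek])
        beta, tstat = _ols_beta_t(y, Xo)
        t_obs = tstat[-1]
        denom = np.sqrt((ek @ ek) * (yres @ yres))
        pc = float(ek @ yres / denom) if denom > 0 else 0.0
        # permutation: relabel individuals of the residualised matrix
        e_mat = np.zeros((n, n))
        ev = np.full(valid.shape, 0.0)
        ev[valid] = ek
        e_mat[iu, ju] = ev
        e_mat[ju, iu] = ev
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pe = e_mat[np.ix_(perm, perm)][iu, ju][valid]
            pe_res = pe - others @ (pinv_o @ pe)
            Xp = np.column_stack([others, pe_res])
            _, tp = _ols_beta_t(y, Xp)
            if abs(tp[-1]) >= abs(t_obs):
                count += 1
        rows.append(
            {
                "predictor": name,
                "coefficient": float(beta[-1]),
                "partial_correlation": pc,
                "p": (count + 1) / (n_perm + 1),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def stepwise_select(
    response: DyadMatrix,
    predictors: dict[str, DyadMatrix],
    n_perm: int = 20_000,
    seed: int = 0,
    alpha: float = 0.05,
    pc_threshold: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination of weak predictors.

    A predictor fails when its MRQAP p-value is >= ``alpha`` *or* its partial
    correlation is below ``pc_threshold`` in magnitude (a significant but
    negligible predictor is still dropped).  One predictor - the failing one
    with the smallest |partial correlation|, ties broken lexically - is
    removed per round until all survivors pass.  Returns the retained names
    and the final MRQAP table (of the last non-empty round).
    """
    current = dict(predictors)
    table = None
    while current:
        table = mrqap_dsp(response, current, n_perm=n_perm, seed=seed)
        failing = table[
            (table["p"] >= alpha)
            | (table["partial_correlation"].abs() < pc_threshold)
        ]
        if failing.empty:
            break
        weakest = failing.assign(a=failing["partial_correlation"].abs()).sort_values(
            ["a", "predictor"]
        ).index[0]
        del current[weakest]
    if not current:
        warnings.warn(
            "all predictors eliminated; GAIs fall back to null-model residuals",
            stacklevel=2,
        )
    return list(current), table


# ---------------------------------------------------------------------------
# affiliation calls
# ---------------------------------------------------------------------------

@dataclass
class AffiliationCalls:
    """Dyads with exceptionally large positive/negative residuals."""

    strong_affiliations: list[tuple[str, str, float]] = field(default_factory=list)
    strong_avoidances: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_affiliations(self) -> int:
        return len(self.strong_affiliations)

    @property
    def n_avoidances(self) -> int:
        return len(self.strong_avoidances)


def call_affiliations(
    anscombe: DyadMatrix, threshold: float = 2.5
) -> AffiliationCalls:
    """Partition dyads by the +/- threshold on Anscombe residuals."""
    calls = AffiliationCalls()
    for a, b, v in anscombe.dyads():
        if np.isnan(v):
            continue
        if v > threshold:
            calls.strong_affiliations.append((a, b, v))
        elif v < -threshold:
            calls.strong_avoidances.append((a, b, v))
    return calls
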