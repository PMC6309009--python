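"""Lagged association rates, their null, jackknife errors and decay models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from socionet.temporal import (
    MODELS,
    fit_decay_models,
    jackknife_se,
    pair_events,
    slar,
    snar,
)

from conftest import day, make_records


def brute_force_slar(records: pd.DataFrame) -> dict[int, float]:
    """Conditional-probability oracle for fully observed data.

    For each occasion pair and focal individual, enumerate associates
    directly from the group lists; accumulate shared associates over the
    product of associate counts, per exact lag.
    """
    occ = {}
    for o, sub in records.groupby("occasion_id"):
        groups = [set(g["individual_id"]) for _, g in sub.groupby("group_id")]
        day_no = (pd.Timestamp(o) - pd.Timestamp("2006-01-01")).days
        occ[day_no] = groups
    days = sorted(occ)
    num = {}
    den = {}
    for t, u in itertools.combinations(days, 2):
        lag = u - t
        inds = set().union(*occ[t]) & set().union(*occ[u])
        for a in inds:
            assoc_t = set().union(*(g for g in occ[t] if a in g)) - {a}
            assoc_u = set().union(*(g for g in occ[u] if a in g)) - {a}
            num[lag] = num.get(lag, 0) + len(assoc_t & assoc_u)
            den[lag] = den.get(lag, 0) + len(assoc_t) * len(assoc_u)
    return {lag: num[lag] / den[lag] for lag in num if den[lag] > 0}


class TestSlar:
    def test_stable_pairs_give_rate_one(self):
        rows = []
        for occ in range(6):
            rows += [(day(occ), "g1", "A"), (day(occ), "g1", "B")]
            rows += [(day(occ), "g2", "C"), (day(occ), "g2", "D")]
        curve = slar(make_records(rows))
        np.testing.assert_allclose(curve.rate, 1.0)

    def test_matches_enumeration_oracle_exactly(self):
        """Fully observed 4-individual, 6-occasion dataset vs. brute force."""
        rng = np.random.default_rng(0)
        rows = []
        for occ in range(6):
            perm = rng.permutation(["A", "B", "C", "D"])
            split = rng.integers(1, 4)
            for ind in perm[:split]:
                rows.append((day(occ * 3), "g1", ind))
            for ind in perm[split:]:
                rows.append((day(occ * 3), "g2", ind))
        records = make_records(rows)
        curve = slar(records)  # unsmoothed: one point per exact lag
        oracle = brute_force_slar(records)
        got = dict(zip(curve.lag.astype(int), curve.rate))
        assert got.keys() == oracle.keys()
        for lag in oracle:
            assert got[lag] == pytest.approx(oracle[lag], abs=1e-12)

    def test_stable_triads_rate_is_half(self):
        # groups of 3 forever: two associates, one of two "chosen" -> 1/2
        rows = []
        for occ in range(5):
            for g, members in enumerate((("A", "B", "C"), ("D", "E", "F"))):
                for ind in members:
                    rows.append((day(occ), f"g{g}", ind))
        curve = slar(make_records(rows))
        np.testing.assert_allclose(curve.rate, 0.5)

    def test_invariant_to_occasion_order(self):
        rng = np.random.default_rng(1)
        rows = []
        for occ in range(8):
            for k, ind in enumerate("ABCDE"):
                if rng.random() < 0.8:
                    rows.append((day(occ * 2), f"g{k % 2}", ind))
        records = make_records(rows)
        c1 = slar(records)
        c2 = slar(records.sample(frac=1, random_state=3))
        np.testing.assert_allclose(c1.rate, c2.rate)
        np.testing.assert_allclose(c1.lag, c2.lag)

    def test_unit_window_equals_unsmoothed(self):
        rng = np.random.default_rng(2)
        rows = []
        for occ in range(10):
            for k, ind in enumerate("ABCDEF"):
                if rng.random() < 0.7:
                    rows.append((day(occ * 5), f"g{k % 2}", ind))
        records = make_records(rows)
        c1 = slar(records, window=None)
        c2 = slar(records, window=1)
        np.testing.assert_allclose(c1.rate, c2.rate)

    def test_smoothing_pools_denominator_mass(self):
        rng = np.random.default_rng(3)
        rows = []
        for occ in range(12):
            for k, ind in enumerate("ABCDEFGH"):
                if rng.random() < 0.8:
                    rows.append((day(occ * 7), f"g{k % 3}", ind))
        records = make_records(rows)
        coarse = slar(records, window=200)
        fine = slar(records)
        assert len(coarse.lag) < len(fine.lag)
        # all but possibly the trailing window carry >= the requested mass
        assert (coarse.den[:-1] >= 200).all()


class TestSnar:
    def test_two_individuals_always_seen(self):
        rows = []
        for occ in range(4):
            rows += [(day(occ), "g", "A"), (day(occ), "g", "B")]
        nullc = snar(make_records(rows), n_rand=10, seed=0)
        np.testing.assert_allclose(nullc.rate, 1.0)

    def test_random_regrouping_snar_matches_slar(self):
        """Daily random re-association: the null equals the observed rate."""
        rng = np.random.default_rng(4)
        ids = [f"I{k}" for k in range(10)]
        rows = []
        for occ in range(30):
            perm = rng.permutation(ids)
            for k, ind in enumerate(perm):
                rows.append((day(occ), f"g{k // 2}", ind))
        records = make_records(rows)
        obs = slar(records, window=3000)
        nullc = snar(records, window=3000, n_rand=60, seed=1)
        np.testing.assert_allclose(obs.rate, nullc.rate, atol=0.03)

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(5)
        rows = []
        for occ in range(8):
            for k, ind in enumerate("ABCDE"):
                if rng.random() < 0.8:
                    rows.append((day(occ), f"g{k % 2}", ind))
        records = make_records(rows)
        n1 = snar(records, n_rand=30, seed=2)
        mapping = dict(zip("ABCDE", "VWXYZ"))
        n2 = snar(
            records.assign(individual_id=records["individual_id"].map(mapping)),
            n_rand=30, seed=2,
        )
        np.testing.assert_allclose(n1.rate, n2.rate)


class TestJackknife:
    def _records(self, n_occ, rng=None, stable=True):
        rows = []
        rng = rng or np.random.default_rng(0)
        for occ in range(n_occ):
            if stable:
                rows += [(day(occ), "g1", "A"), (day(occ), "g1", "B"),
                         (day(occ), "g2", "C"), (day(occ), "g2", "D")]
            else:
                perm = rng.permutation(["A", "B", "C", "D"])
                rows += [(day(occ), "g1", perm[0]), (day(occ), "g1", perm[1]),
                         (day(occ), "g2", perm[2]), (day(occ), "g2", perm[3])]
        return make_records(rows)

    def test_constant_estimator_gives_zero_se(self):
        curve = jackknife_se(self._records(30), window=1e9, block=10, reps=3)
        np.testing.assert_allclose(curve.se, 0.0, atol=1e-12)

    def test_truncates_when_blocks_run_out(self):
        records = self._records(25, stable=False)
        with pytest.warns(UserWarning, match="truncating"):
            jackknife_se(records, window=1e9, block=10, reps=100)

    def test_needs_enough_occasions(self):
        with pytest.raises(ValueError):
            jackknife_se(self._records(12), block=10)

    def test_deterministic(self):
        records = self._records(40, stable=False)
        c1 = jackknife_se(records, window=1e9, block=10, reps=4)
        c2 = jackknife_se(records, window=1e9, block=10, reps=4)
        np.testing.assert_allclose(c1.se, c2.se)


def simulate_pair_events(kind: str, seed: int, n_lags=60, den=400,
                         level=0.35, rate=1 / 50.0):
    """Binomial persistence events from a known decay law."""
    rng = np.random.default_rng(seed)
    lags = np.arange(1, n_lags + 1) * 5.0
    if kind == "CONSTANT":
        g = np.full_like(lags, level)
    else:
        g = level * np.exp(-rate * lags)
    num = rng.binomial(den, g)
    return pd.DataFrame({"lag": lags, "num": num, "den": den})


class TestDecayModels:
    def test_nested_models_dominate_in_likelihood(self):
        ev = simulate_pair_events("EXPONENTIAL", 0)
        fits = {f.model: f for f in fit_decay_models(ev, seed=0)}
        assert set(fits) == set(MODELS)
        assert fits["CONSTANT_PLUS_EXPONENTIAL"].loglik >= fits["CONSTANT"].loglik - 1e-6
        assert fits["CONSTANT_PLUS_EXPONENTIAL"].loglik >= fits["EXPONENTIAL"].loglik - 1e-6

    def test_qaic_weights_sum_to_one_and_best_has_zero_delta(self):
        ev = simulate_pair_events("CONSTANT", 1)
        fits = fit_decay_models(ev, seed=1)
        assert np.isclose(sum(f.weight for f in fits if np.isfinite(f.weight)), 1.0)
        assert fits[0].delta_qaic == 0.0

    @pytest.mark.parametrize("kind", ["CONSTANT", "EXPONENTIAL"])
    def test_generating_regime_identified(self, kind):
        """Constant vs. decaying data: QAIC picks the generating form."""
        wins = 0
        for seed in range(10):
            ev = simulate_pair_events(kind, seed)
            fits = fit_decay_models(ev, seed=seed)
            two = [f for f in fits if f.model in ("CONSTANT", "EXPONENTIAL")]
            best = min(two, key=lambda f: f.qaic)
            wins += best.model == kind
        assert wins >= 9

    def test_exponential_rate_recovered(self):
        """Half-life 50 days over a 300-day span: rate within 25%."""
        true_rate = np.log(2) / 50.0
        ests = []
        for seed in range(8):
            ev = simulate_pair_events("EXPONENTIAL", seed, n_lags=60,
                                      den=2000, rate=true_rate)
            fits = {f.model: f for f in fit_decay_models(ev, seed=seed)}
            ests.append(fits["EXPONENTIAL"].parameters["a1"])
        assert np.mean(ests) == pytest.approx(true_rate, rel=0.25)
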