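import numpy as np
import pandas as pd
import pytest

from spo2delta import (
    bland_altman,
    cox_fit,
    ph_check,
    roc_auc,
    survivor_table,
    two_group_t,
    zscore,
)
from spo2delta.exceptions import (
    DegenerateInputError,
    NonIdentifiableError,
    SchemaError,
)

from _oracles import auc_pairwise, cox_grid_mle, pooled_t


class TestZscore:
    def test_basic(self):
        z, mu, sd = zscore([1, 2, 3])
        np.testing.assert_allclose(z, [-1, 0, 1])
        assert (mu, sd) == (2.0, 1.0)

    def test_idempotent(self, rng):
        z, _, _ = zscore(rng.normal(5, 3, 40))
        z2, mu, sd = zscore(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)
        assert mu == pytest.approx(0, abs=1e-12) and sd == pytest.approx(1)

    def test_constant_raises(self):
        with pytest.raises(NonIdentifiableError):
            zscore([4, 4, 4])


class TestTwoGroupT:
    def test_identical_groups(self):
        res = two_group_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p == pytest.approx(1.0)

    def test_matches_pooled_oracle(self):
        res = two_group_t([1, 2, 3], [4, 5, 6])
        t, df = pooled_t(np.array([1, 2, 3.0]), np.array([4, 5, 6.0]))
        assert res.t == pytest.approx(t, abs=5e-4)
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == df == 4

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        r1, r2 = two_group_t(a, b), two_group_t(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_welch_switch(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 40)
        w = two_group_t(a, b, welch=True)
        assert w.welch and w.df != len(a) + len(b) - 2

    def test_tiny_group_raises(self):
        with pytest.raises(DegenerateInputError):
            two_group_t([1.0], [2.0, 3.0])


def _toy_survival(n=6, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    while x.std() == 0:
        x = rng.integers(0, 2, n).astype(float)
    time = rng.permutation(np.arange(1.0, n + 1))  # distinct times
    event = np.ones(n, dtype=int)
    return x, time, event


class TestCoxFit:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_oracle_small_n(self, seed, ties):
        # distinct event times: Efron and Breslow coincide with the plain
        # partial likelihood, maximised here by brute-force grid search
        x, time, event = _toy_survival(seed=seed)
        fit = cox_fit(pd.DataFrame({"x": x}), time, event, ties=ties)
        beta_star = cox_grid_mle(x, time, event)
        assert fit.effect("x").beta == pytest.approx(beta_star, abs=1e-4)

    def test_effect_fields_consistent(self):
        x, time, event = _toy_survival(n=8, seed=3)
        fit = cox_fit(pd.DataFrame({"x": x}), time, event)
        e = fit.effect("x")
        assert e.hazard_ratio == pytest.approx(np.exp(e.beta))
        assert e.ci95_low == pytest.approx(np.exp(e.beta - 1.96 * e.se))
        assert e.ci95_high == pytest.approx(np.exp(e.beta + 1.96 * e.se))
        assert fit.n == 8 and fit.n_events == 8 and fit.converged

    def test_null_covariate_small_effect(self, rng):
        n = 300
        x = rng.normal(size=n)
        time = rng.exponential(20, n)
        event = (time <= 30).astype(int)
        time = np.minimum(time, 30.0)
        fit = cox_fit(pd.DataFrame({"x": x}), time, event)
        assert abs(fit.effect("x").beta) < 3.5 * fit.effect("x").se

    def test_identical_columns_rank_deficient(self):
        x, time, event = _toy_survival(n=8, seed=1)
        with pytest.raises(NonIdentifiableError):
            cox_fit(pd.DataFrame({"a": x, "b": x}), time, event)

    def test_constant_covariate_rejected(self):
        _, time, event = _toy_survival(n=6)
        with pytest.raises(NonIdentifiableError):
            cox_fit(pd.DataFrame({"a": np.ones(6)}), time, event)

    def test_no_events_rejected(self):
        x, time, _ = _toy_survival(n=6)
        with pytest.raises(DegenerateInputError):
            cox_fit(pd.DataFrame({"x": x}), time, np.zeros(6, dtype=int))


class TestPHCheck:
    def test_few_events_undefined(self):
        x, time, event = _toy_survival(n=6)
        event = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(DegenerateInputError):
            ph_check(pd.DataFrame({"x": x}), time, event)

    def test_null_flag_rate_near_alpha(self):
        # data simulated under proportional hazards: ~5% spurious flags
        flags = 0
        reps = 100
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(15 / np.exp(0.5 * x))
            event = (t <= 30).astype(int)
            t = np.minimum(t, 30.0)
            if event.sum() < 3:
                continue
            rows = ph_check(pd.DataFrame({"x": x}), t, event)
            flags += rows[0].flagged
        assert 0.0 <= flags / reps <= 0.12

    def test_time_varying_effect_flagged(self):
        # effect reverses sign at the median time: strong PH violation
        rng = np.random.default_rng(42)
        n = 500
        x = rng.normal(size=n)
        # piecewise hazard: rate depends on +x early, -x late
        t_early = rng.exponential(8 / np.exp(1.2 * x))
        t_late = 8 + rng.exponential(8 / np.exp(-1.2 * x))
        t = np.where(t_early < 8, t_early, t_late)
        event = (t <= 30).astype(int)
        t = np.minimum(t, 30.0)
        rows = ph_check(pd.DataFrame({"x": x}), t, event)
        assert rows[0].flagged


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_all_tied_scores(self):
        res = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == 0.5

    def test_matches_pairwise_oracle_with_ties(self, rng):
        scores = rng.integers(0, 5, 30).astype(float)
        outcome = rng.integers(0, 2, 30)
        outcome[0], outcome[1] = 0, 1  # both classes present
        res = roc_auc(scores, outcome)
        assert res.auc == pytest.approx(auc_pairwise(scores, outcome), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        outcome = (rng.random(50) < 0.4).astype(int)
        outcome[:2] = [0, 1]
        a = roc_auc(scores, outcome).auc
        b = roc_auc(np.exp(3 * scores) + 7, outcome).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([0.1, 0.2], [1, 1])


class TestBlandAltman:
    def test_identical_vectors(self):
        rep = bland_altman([1, 2, 3.0], [1, 2, 3.0])
        assert rep.bias == 0 and rep.loa_low == rep.loa_high == 0
        assert rep.n_outside == 0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = bland_altman(a, a + 0.5)
        assert rep.bias == pytest.approx(-0.5)
        assert rep.sd_diff == 0
        assert rep.loa_low == rep.loa_high == pytest.approx(-0.5)

    def test_outside_count_matches_recount(self, rng):
        a = rng.normal(0, 1, 164)
        b = a + rng.normal(0, 0.1, 164)
        rep = bland_altman(a, b)
        d = a - b
        manual = int(np.sum((d < rep.loa_low) | (d > rep.loa_high)))
        assert rep.n_outside == manual <= 164
        # ~5% expected outside the 1.96 SD band for gaussian differences
        assert rep.n_outside <= 20

    def test_length_mismatch(self):
        with pytest.raises(SchemaError):
            bland_altman([1, 2, 3.0], [1, 2.0])


class TestSurvivorTable:
    @staticmethod
    def _cohort(rng, shift=0.0, n=60):
        event = np.repeat([0, 1], n // 2)
        delta = rng.normal(0.05 + shift * event, 0.1)
        return pd.DataFrame({
            "group": "sepsis", "event": event, "delta": delta,
            "mean_spo2": rng.normal(97, 3, n), "sampen": rng.uniform(0, 0.4, n),
            "sofa": rng.integers(0, 15, n),
        })

    def test_values_match_direct_recomputation(self, rng):
        co = self._cohort(rng)
        tab = survivor_table(co)
        row = tab[(tab.group == "sepsis") & (tab.feature == "delta")].iloc[0]
        surv = co[co.event == 0]["delta"]
        assert row.survivor_mean == pytest.approx(surv.mean())
        assert row.survivor_sd == pytest.approx(surv.std(ddof=1))
        assert row.p_value == pytest.approx(
            two_group_t(surv, co[co.event == 1]["delta"]).p)

    def test_null_shift_not_significant(self):
        co = self._cohort(np.random.default_rng(0), shift=0.0, n=80)
        tab = survivor_table(co)
        assert tab[tab.feature == "delta"].iloc[0].p_value > 0.05

    def test_small_stratum_reported_nan(self):
        co = pd.DataFrame({"group": "alf", "event": [0, 0, 0, 1],
                           "delta": [0.1, 0.2, 0.3, 0.4]})
        tab = survivor_table(co, features=("delta",))
        assert np.isnan(tab.iloc[0].p_value)
        assert np.isnan(tab.iloc[0].nonsurvivor_sd)

    def test_missing_columns(self):
        with pytest.raises(SchemaError):
            survivor_table(pd.DataFrame({"delta": [1.0]}))
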