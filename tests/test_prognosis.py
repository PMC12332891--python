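"""Survival screening, Cox fits, signature, risk score and AUC contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from fatestrat import prognosis as pg
from fatestrat.containers import RiskSignature, SurvivalTable
from fatestrat.synth import SimulationConfig, simulate_cohort

from conftest import expression_from_array


def _surv(times, events, index=None):
    index = index or [f"p{i}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame({"time": times, "event": events}, index=index)
    )


def _oracle_partial_loglik(x, times, events, beta):
    """Hand-written Efron partial log-likelihood for a single covariate."""
    eta = beta * np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        d = dead.sum()
        tie = np.exp(eta[dead]).sum()
        risk = np.exp(eta[at_risk]).sum()
        ll += eta[dead].sum()
        for ell in range(d):
            ll -= np.log(risk - ell / d * tie)
    return ll


class TestSplitCohort:
    def test_sizes_and_disjointness(self):
        surv = _surv(np.arange(1, 11, dtype=float), [1] * 10)
        train, test = pg.split_cohort(surv, ratio=0.7, seed=0)
        assert len(train) == 7 and len(test) == 3
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(surv.samples)

    def test_seed_reproducibility(self):
        surv = _surv(np.arange(1, 41, dtype=float), [1, 0] * 20)
        assert pg.split_cohort(surv, seed=5) == pg.split_cohort(surv, seed=5)

    def test_event_rate_stratified(self):
        rng = np.random.default_rng(0)
        n = 200
        surv = _surv(rng.exponential(5, n) + 0.01, rng.binomial(1, 0.37, n))
        train, test = pg.split_cohort(surv, seed=1)
        r_train = surv.event[train].mean()
        r_test = surv.event[test].mean()
        assert abs(r_train - r_test) <= 1 / min(len(train), len(test))

    def test_all_censored_rejected(self):
        surv = _surv(np.arange(1, 11, dtype=float), [0] * 10)
        with pytest.raises(ValueError, match="censored"):
            pg.split_cohort(surv)


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2, 3, 4, 1, 2, 3, 4]
        surv = _surv(times, [1] * 8)
        values = pd.Series([0, 0, 0, 0, 1, 1, 1, 1.0], index=surv.samples)
        res = pg.km_logrank(values, surv, cutoff=0.5)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["pvalue"] == pytest.approx(1.0)

    def test_statistic_matches_hand_computation(self):
        """O-E accumulation per event time, written out longhand."""
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.array([1, 1, 1, 1, 1, 1])
        group = np.array([1, 0, 1, 0, 1, 0])  # group 1 dies earlier on average
        o_minus_e = 0.0
        var = 0.0
        for t in times[events == 1]:
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & (group == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d1 = ((times == t) & (events == 1) & (group == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / var
        surv = _surv(times, events)
        values = pd.Series(group.astype(float), index=surv.samples)
        res = pg.km_logrank(values, surv, cutoff=0.5)
        assert res["statistic"] == pytest.approx(expected, rel=1e-9)

    def test_planted_hazard_highly_significant(self):
        cfg = SimulationConfig(
            seed=11, n_genes=5, n_samples=400, n_informative=1,
            hazard_beta=np.log(2.0), subtype_loghr=[0.0] * 4, effect_size=0.0,
        )
        expr, surv, truth = simulate_cohort(cfg)
        gene = next(iter(truth.informative_genes))
        res = pg.km_logrank(expr.values.loc[gene], surv)
        assert res["pvalue"] < 1e-3

    def test_constant_values_rejected(self):
        surv = _surv([1.0, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            pg.km_logrank(pd.Series(1.0, index=surv.samples), surv)


class TestUnicox:
    def test_matches_grid_search_oracle_small_fixtures(self):
        """beta-hat equals the maximiser of the written partial likelihood."""
        fixtures = [
            ([1.0, 0, 1, 0], [1.0, 2, 3, 4], [1, 1, 1, 1]),
            ([0.5, -1, 2, 0, 1], [2.0, 1, 4, 3, 5], [1, 0, 1, 1, 1]),
            ([1.0, 2, 0, -1, 3, 0.5, 2, 1], [3.0, 1, 4, 2, 8, 6, 5, 7],
             [1, 1, 0, 1, 1, 0, 1, 1]),
        ]
        for x, times, events in fixtures:
            surv = _surv(times, events)
            res = pg.unicox(pd.Series(x, index=surv.samples), surv)
            oracle = minimize_scalar(
                lambda b: -_oracle_partial_loglik(x, times, events, b),
                bounds=(-5, 5), method="bounded",
                options={"xatol": 1e-10},
            ).x
            assert res["beta"] == pytest.approx(oracle, abs=1e-3)

    def test_independent_covariate_beta_near_zero(self):
        cfg = SimulationConfig(
            seed=21, n_genes=5, n_samples=1000, n_informative=1,
            hazard_beta=0.5, subtype_loghr=[0.0] * 4, effect_size=0.0,
        )
        expr, surv, _ = simulate_cohort(cfg)
        res = pg.unicox(expr.values.loc["G0003"], surv)  # not informative
        assert abs(res["beta"]) < 0.1

    def test_constant_covariate_rejected(self):
        surv = _surv([1.0, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            pg.unicox(pd.Series(2.0, index=surv.samples), surv)


class TestFitSignature:
    def test_lambda_zero_limit_equals_multivariate_cox(self):
        cfg = SimulationConfig(
            seed=7, n_genes=10, n_samples=300, n_informative=3,
            hazard_beta=0.5, subtype_loghr=[0.0] * 4,
        )
        expr, surv, _ = simulate_cohort(cfg)
        sig = pg.fit_signature(expr, surv, screen_p=1.1, alpha_override=1e-9)
        direct = pg._multivariate_cox(expr, surv, list(expr.genes))
        for gene, beta in sig.coefficients:
            assert beta == pytest.approx(direct[gene], abs=1e-4)

    def test_huge_lambda_empty_signature(self):
        cfg = SimulationConfig(
            seed=8, n_genes=10, n_samples=200, subtype_loghr=[0.0] * 4
        )
        expr, surv, _ = simulate_cohort(cfg)
        with pytest.warns(UserWarning, match="shrinkage"):
            sig = pg.fit_signature(expr, surv, screen_p=1.1, alpha_override=1e6)
        assert sig.coefficients == []

    def test_planted_genes_recovered(self):
        cfg = SimulationConfig(
            seed=11, n_genes=53, n_samples=600, n_informative=3,
            hazard_beta=0.6, subtype_loghr=[0.0] * 4, effect_size=0.0,
        )
        expr, surv, truth = simulate_cohort(cfg)
        sig = pg.fit_signature(expr, surv, screen_p=0.05, cv_folds=5, seed=0)
        planted = set(truth.informative_genes)
        assert planted <= set(sig.genes)
        assert len(set(sig.genes) - planted) <= 2


class TestRiskScore:
    def test_linear_contract(self):
        sig = RiskSignature([("g0", 2.0)])
        expr = expression_from_array([[3.0, 0.0]])
        scores = pg.risk_score(expr, sig)
        assert scores.tolist() == [6.0, 0.0]

    def test_packaged_signature_all_ones(self):
        sig = pg.load_packaged_signature()
        expr = expression_from_array(
            np.ones((15, 1)), genes=sig.genes, samples=["s"]
        )
        assert pg.risk_score(expr, sig)["s"] == pytest.approx(-0.4154)

    def test_missing_gene_listed_in_error(self):
        sig = RiskSignature([("absent", 1.0), ("g0", 1.0)])
        expr = expression_from_array(np.ones((1, 2)))
        with pytest.raises(ValueError, match="absent"):
            pg.risk_score(expr, sig)

    def test_affine_equivariance_in_beta(self):
        rng = np.random.default_rng(0)
        expr = expression_from_array(rng.normal(size=(4, 6)))
        sig = RiskSignature([(f"g{i}", float(b)) for i, b in enumerate([0.5, -1, 2, 0.1])])
        scaled = RiskSignature([(g, 3.0 * b) for g, b in sig.coefficients])
        np.testing.assert_allclose(
            pg.risk_score(expr, scaled), 3.0 * pg.risk_score(expr, sig)
        )


class TestTimeDependentAuc:
    def test_perfect_ranking_auc_one(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(0.5, 8, 60)
        surv = _surv(times, [1] * 60)
        score = pd.Series(-times, index=surv.samples)
        aucs = pg.time_dependent_auc(score, surv, horizons=[1, 2, 3])
        for v in aucs.values():
            assert v == pytest.approx(1.0)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(4, 100) + 0.05
        surv = _surv(times, rng.binomial(1, 0.8, 100))
        score = pd.Series(rng.normal(size=100), index=surv.samples)
        a = pg.time_dependent_auc(score, surv, horizons=[2.0])
        b = pg.time_dependent_auc(-score, surv, horizons=[2.0])
        assert a[2.0] == pytest.approx(1.0 - b[2.0], abs=1e-9)

    def test_no_event_before_horizon_reported_missing(self):
        surv = _surv([5.0, 6, 7, 8], [1, 1, 1, 1])
        score = pd.Series([1.0, 2, 3, 4], index=surv.samples)
        aucs = pg.time_dependent_auc(score, surv, horizons=[1.0])
        assert np.isnan(aucs[1.0])


class TestCovariateCox:
    @staticmethod
    def _cohort(seed=31):
        cfg = SimulationConfig(
            seed=seed, n_genes=5, n_samples=400, n_informative=1,
            hazard_beta=0.7, subtype_loghr=[0.0] * 4, effect_size=0.0,
        )
        expr, surv, truth = simulate_cohort(cfg)
        gene = next(iter(truth.informative_genes))
        score = expr.values.loc[gene].rename("risk_score")
        rng = np.random.default_rng(seed)
        covars = pd.DataFrame(
            {"age": rng.normal(60, 8, 400), "stage": rng.integers(1, 5, 400)},
            index=surv.samples,
        )
        return score, covars, surv

    def test_score_independent_factor(self):
        score, covars, surv = self._cohort()
        tables = pg.covariate_cox(score, covars, surv)
        assert tables["multivariate"].loc["risk_score", "pvalue"] < 0.05
        assert tables["multivariate"].loc["age", "pvalue"] > 0.01

    def test_univariate_matches_unicox(self):
        score, covars, surv = self._cohort(seed=32)
        tables = pg.covariate_cox(score, covars, surv)
        direct = pg.unicox(score, surv)
        assert tables["univariate"].loc["risk_score", "beta"] == pytest.approx(
            direct["beta"], rel=1e-9
        )

    def test_collinear_covariate_dropped(self):
        score, covars, surv = self._cohort(seed=33)
        covars["age_copy"] = covars["age"]
        with pytest.warns(UserWarning, match="collinear"):
            tables = pg.covariate_cox(score, covars, surv)
        assert "age_copy" not in tables["multivariate"].index
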