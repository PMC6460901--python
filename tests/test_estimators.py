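"""Estimation: person-period expansion, component fits, ab and ACME."""

import numpy as np
import pytest

from dtsmed.estimators import (
    acme_mediation_formula,
    expand_person_period,
    fit_dtsm,
    fit_hazard_model,
    fit_mediator_model,
    newton_logistic,
    product_of_coefficients,
)
from dtsmed.simulator import (
    MISSING,
    MediationParams,
    SimulatedDataset,
    baseline_logit,
    simulate_dataset,
)

from conftest import make_params


def dataset_from_rows(rows, x=None, m=None):
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0]
    return SimulatedDataset(
        x=np.zeros(n, np.int8) if x is None else np.asarray(x, np.int8),
        m=np.zeros(n) if m is None else np.asarray(m, float),
        events=rows,
    )


class TestExpandPersonPeriod:
    def test_event_row(self):
        data = dataset_from_rows([[0, 1, MISSING, MISSING]])
        t = expand_person_period(data)
        assert t["event"].tolist() == [0, 1]
        assert t["j"].tolist() == [1, 2]

    def test_censored_row(self):
        t = expand_person_period(dataset_from_rows([[0, 0, 0, 0]]))
        assert len(t) == 4 and t["event"].sum() == 0

    def test_total_row_count(self):
        rows = [
            [1, MISSING, MISSING, MISSING],
            [0, 0, 1, MISSING],
            [0, 0, 0, 0],
        ]
        t = expand_person_period(dataset_from_rows(rows))
        assert len(t) == 1 + 3 + 4
        # event = 1 only in each subject's final row
        last = t.groupby("id").tail(1)
        assert last["event"].tolist() == [1, 1, 0]
        assert t.groupby("id")["event"].sum().tolist() == [1, 1, 0]

    def test_malformed_matrix_rejected(self):
        with pytest.raises(ValueError):
            expand_person_period(dataset_from_rows([[MISSING, 0, 0, 0]]))


class TestMediatorModel:
    def test_exact_interpolation(self):
        x = np.array([0, 0, 1, 1])
        m = 0.39 * x
        a, b0, sigma = fit_mediator_model((x, m))
        assert a == pytest.approx(0.39)
        assert b0 == pytest.approx(0.0)
        assert sigma == pytest.approx(0.0)

    def test_null_large_sample(self, rng):
        x = rng.integers(0, 2, 100_000)
        m = rng.standard_normal(100_000)
        a, _, sigma = fit_mediator_model((x, m))
        assert abs(a) < 0.02
        assert sigma == pytest.approx(1.0, abs=0.02)

    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError):
            fit_mediator_model((np.zeros(10), np.arange(10.0)))


@pytest.fixture(scope="module")
def recovery_data():
    p = make_params(a=0.0, b_or=2.0, c_or=1.0, h0=0.2, J=8)
    return simulate_dataset(p, np.random.SeedSequence(31), n=50_000)


class TestHazardModel:
    def test_parameter_recovery(self, recovery_data):
        fit = fit_hazard_model(expand_person_period(recovery_data))
        assert fit["converged"]
        assert fit["b_hat"] == pytest.approx(np.log(2), abs=0.03)

    def test_null_recovery(self):
        p = make_params(a=0.0, b_or=1.0, c_or=1.0, h0=0.2, J=8)
        data = simulate_dataset(p, np.random.SeedSequence(32), n=50_000)
        fit = fit_hazard_model(expand_person_period(data))
        assert abs(fit["b_hat"]) < 0.05
        assert abs(fit["cprime_hat"]) < 0.05

    def test_agrees_with_statsmodels(self, recovery_data):
        sm = pytest.importorskip("statsmodels.api")
        small = SimulatedDataset(
            x=recovery_data.x[:2000],
            m=recovery_data.m[:2000],
            events=recovery_data.events[:2000],
        )
        table = expand_person_period(small)
        ours = fit_hazard_model(table)
        X = np.column_stack(
            [np.ones(len(table)), table["x"].to_numpy(float), table["m"].to_numpy(float)]
        )
        ref = sm.Logit(table["event"].to_numpy(float), X).fit(disp=0)
        assert ours["beta02_hat"][0] == pytest.approx(ref.params[0], abs=1e-6)
        assert ours["cprime_hat"] == pytest.approx(ref.params[1], abs=1e-6)
        assert ours["b_hat"] == pytest.approx(ref.params[2], abs=1e-6)

    def test_per_interval_agrees_with_statsmodels(self, recovery_data):
        sm = pytest.importorskip("statsmodels.api")
        small = SimulatedDataset(
            x=recovery_data.x[:2000],
            m=recovery_data.m[:2000],
            events=recovery_data.events[:2000],
        )
        table = expand_person_period(small)
        ours = fit_hazard_model(table, baseline="per-interval")
        js = np.sort(table["j"].unique())
        dummies = (table["j"].to_numpy()[:, None] == js[None, :]).astype(float)
        X = np.column_stack(
            [dummies, table["x"].to_numpy(float), table["m"].to_numpy(float)]
        )
        ref = sm.Logit(table["event"].to_numpy(float), X).fit(disp=0)
        np.testing.assert_allclose(ours["beta02_hat"], ref.params[: len(js)], atol=1e-6)
        assert ours["b_hat"] == pytest.approx(ref.params[-1], abs=1e-6)

    def test_separation_flagged(self):
        # events occur exactly when x = 1: the x coefficient diverges
        rows = [[1] + [MISSING] * 3] * 5 + [[0, 0, 0, 0]] * 5
        x = [1] * 5 + [0] * 5
        m = [0.1, -0.2, 0.3, 0.0, 0.2, -0.1, 0.1, 0.0, -0.3, 0.2]
        table = expand_person_period(dataset_from_rows(rows, x=x, m=m))
        fit = fit_hazard_model(table)
        assert not fit["converged"]
        assert fit["separated"]

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            fit_hazard_model(expand_person_period(dataset_from_rows([[0, 0, 0, 0]])))

    def test_likelihood_monotone(self, medium_dataset):
        fit = fit_dtsm(medium_dataset)
        path = fit.loglik_path
        assert np.all(np.diff(path) >= -1e-10)


class TestMediatedEffects:
    def test_product_of_coefficients(self):
        assert product_of_coefficients(0.39, np.log(2)) == pytest.approx(0.2703, abs=1e-4)
        assert product_of_coefficients(0.0, 3.2) == 0.0
        assert product_of_coefficients(1.7, 0.0) == 0.0
        with pytest.raises(ValueError):
            product_of_coefficients(np.nan, 1.0)

    def test_acme_equals_ab_and_is_exposure_invariant(self, medium_dataset):
        fit = fit_dtsm(medium_dataset)
        acme1 = acme_mediation_formula(fit, t=1)
        acme0 = acme_mediation_formula(fit, t=0)
        assert abs(acme1 - acme0) < 1e-8
        assert abs(acme1 - fit.ab_hat) < 1e-6

    def test_acme_zero_when_a_zero(self, medium_dataset):
        fit = fit_dtsm(medium_dataset)
        fit.a_hat = 0.0
        assert acme_mediation_formula(fit, t=1) == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_matches_monte_carlo(self, medium_dataset):
        fit = fit_dtsm(medium_dataset)
        quad = acme_mediation_formula(fit, t=1)
        rng = np.random.default_rng(8)
        n_draws = 200_000
        mc = acme_mediation_formula(
            fit, t=1, integration="monte-carlo", n_draws=n_draws, rng=rng
        )
        mc_se = abs(fit.b_hat) * fit.sigma_hat * np.sqrt(2.0 / n_draws)
        assert abs(quad - mc) < 3 * mc_se

    def test_acme_requires_convergence(self, medium_dataset):
        fit = fit_dtsm(medium_dataset)
        fit.converged = False
        with pytest.raises(ValueError):
            acme_mediation_formula(fit)


class TestFitDtsm:
    def test_large_sample_recovery(self):
        p = make_params(a=0.59, b_or=4.0, c_or=1.0, h0=0.2, J=8)
        data = simulate_dataset(p, np.random.SeedSequence(33), n=50_000)
        fit = fit_dtsm(data)
        assert fit.converged
        assert fit.ab_hat == pytest.approx(0.59 * np.log(4), abs=0.05)

    def test_null_recovery(self):
        p = make_params(a=0.39, b_or=1.0, c_or=1.5, h0=0.05, J=4)
        data = simulate_dataset(p, np.random.SeedSequence(34), n=50_000)
        fit = fit_dtsm(data)
        assert abs(fit.ab_hat) < 0.05

    def test_ab_identity_and_counts(self, medium_dataset):
        fit = fit_dtsm(medium_dataset)
        assert fit.ab_hat == fit.a_hat * fit.b_hat
        assert fit.n_subjects == 500
        trials = (np.asarray(medium_dataset.events) != MISSING).sum()
        assert fit.n_person_periods == trials

    def test_constant_and_per_interval_paths_agree_on_b(self, medium_dataset):
        const = fit_dtsm(medium_dataset, baseline="constant")
        per = fit_dtsm(medium_dataset, baseline="per-interval")
        # same data, nested baselines: coefficients close but not identical
        assert per.b_hat == pytest.approx(const.b_hat, abs=0.05)
        assert per.beta02_hat.shape == (medium_dataset.J,)


class TestNewtonLogistic:
    def test_binomial_aggregation_equals_row_level(self, medium_dataset):
        # the collapsed binomial likelihood gives the same MLE as the
        # person-period rows it summarizes
        table = expand_person_period(medium_dataset)
        X_rows = np.column_stack(
            [np.ones(len(table)), table["x"].to_numpy(float), table["m"].to_numpy(float)]
        )
        row_fit = newton_logistic(
            X_rows, table["event"].to_numpy(float), np.ones(len(table))
        )
        agg_fit = fit_dtsm(medium_dataset)
        assert agg_fit.b_hat == pytest.approx(row_fit["beta"][2], abs=1e-7)
        assert agg_fit.cprime_hat == pytest.approx(row_fit["beta"][1], abs=1e-7)
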