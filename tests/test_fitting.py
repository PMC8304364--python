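import numpy as np
import pytest

import panelmarkov as pm
from panelmarkov.fitting import (
    FitConfig,
    FitResult,
    fit_mle,
    fitted_summary_table,
    hazard_ratio_report,
    interval_probability_table,
)
from panelmarkov.likelihood import (
    CovariateModel,
    ParamLayout,
    extract_pairs,
    loglik_from_params,
    pack_params,
)
from panelmarkov.markov import IntensityMatrix, TRANSITIONS
from panelmarkov.simulate import CohortConfig, simulate_cohort

#: A generator with all six rates well identified under 3-visit panel data
#: (comparable magnitudes, no rare direct transition swamped by a two-step
#: pathway). Used for recovery checks that exercise the optimizer itself.
BALANCED_Q = IntensityMatrix.from_rates(np.array([0.05, 0.04, 0.10, 0.06, 0.08, 0.09]))


class TestFitMle:
    def test_recovers_balanced_truth(self):
        # 6-visit schedule at n=3000 keeps every SE(log rate) near 0.04, so a
        # single replicate lands within 15% on all six rates with margin
        model = CovariateModel.from_intensity(BALANCED_Q)
        data, _ = simulate_cohort(
            CohortConfig(n_subjects=3000, model=model, seed=42,
                         schedule=(6.0, 10.0, 14.0, 18.0, 22.0, 26.0),
                         initial_distribution=(1 / 3, 1 / 3, 1 / 3))
        )
        fit = fit_mle(data, config=FitConfig(n_starts=1, seed=0))
        assert fit.converged
        rel = np.abs(fit.model.baseline_intensity().rates / BALANCED_Q.rates - 1)
        assert np.all(rel < 0.15)

    def test_one_free_parameter_matches_grid_search(self, reference_q):
        data, _ = simulate_cohort(CohortConfig(n_subjects=500, seed=3))
        truth = pack_params(CovariateModel.from_intensity(reference_q))
        fixed = {k: truth[k] for k in range(1, 6)}
        fit = fit_mle(data, fixed=fixed, config=FitConfig(n_starts=1, seed=0))

        layout = ParamLayout(allowed=tuple(range(6)), covariates=(), centering=np.zeros(0))
        pairs = extract_pairs(data, layout)

        def profile(v):
            x = truth.copy()
            x[0] = v
            return float(np.real(loglik_from_params(x, layout, pairs)))

        # grid search oracle, progressively refined around the best point
        lo, hi = -10.0, 0.0
        for _ in range(6):
            grid = np.linspace(lo, hi, 101)
            vals = [profile(g) for g in grid]
            best = grid[int(np.argmax(vals))]
            span = (hi - lo) / 10
            lo, hi = best - span, best + span
        assert fit.model.log_baseline[0] == pytest.approx(best, abs=1e-4)

    def test_zero_support_flagged(self):
        rows = []
        for k, path in enumerate([(1, 1, 2), (2, 1, 1), (2, 3, 2), (3, 2, 1), (1, 2, 1)] * 8):
            for t, s in zip((6.0, 13.0, 26.0), path):
                rows.append(pm.Observation(f"s{k}", t, state=s))
        data = pm.PanelDataset(rows)
        fit = fit_mle(data, config=FitConfig(n_starts=1, seed=0, maxiter=200))
        assert any("1->3" in f for f in fit.flags)

    def test_disallowed_transition_excluded(self):
        # no direct 1->3 observed and 1->3 disallowed: five free rates
        rows = []
        for k, path in enumerate([(1, 2, 3), (3, 2, 1), (2, 1, 2), (3, 1, 2), (2, 3, 2)] * 10):
            for t, s in zip((6.0, 13.0, 26.0), path):
                rows.append(pm.Observation(f"s{k}", t, state=s))
        data = pm.PanelDataset(rows)
        allowed = tuple(k for k, tr in enumerate(TRANSITIONS) if tr != (0, 2))
        fit = fit_mle(data, allowed=allowed, config=FitConfig(n_starts=1, seed=0))
        assert fit.converged
        assert fit.model.baseline_intensity().q[0, 2] == 0.0

    def test_empty_dataset_rejected(self):
        data = pm.PanelDataset([pm.Observation("a", 6.0, state=1)])
        with pytest.raises(ValueError, match="no consecutive-visit pairs"):
            fit_mle(data)

    def test_deterministic_given_seed(self):
        data, _ = simulate_cohort(CohortConfig(n_subjects=200, seed=9))
        f1 = fit_mle(data, config=FitConfig(seed=4))
        f2 = fit_mle(data, config=FitConfig(seed=4))
        assert np.array_equal(f1.params, f2.params)


class TestHazardRatioReport:
    def _fit_with(self, beta, se):
        model = CovariateModel.from_intensity(
            BALANCED_Q, covariates=("x",), betas=np.full((6, 1), beta)
        )
        cov = np.zeros((12, 12))
        cov[6:, 6:] = np.eye(6) * se**2
        return FitResult(
            model=model, loglik=0.0, covariance=cov, converged=True,
            n_iter=1, n_subjects=1, n_pairs=1,
        )

    def test_null_beta_closed_form(self):
        report = hazard_ratio_report(self._fit_with(0.0, 0.1))
        e = report.entries[0]
        assert e.hr == pytest.approx(1.0)
        assert e.lo == pytest.approx(np.exp(-1.959963984540054 * 0.1), abs=1e-6)
        assert (round(e.lo, 2), round(e.hi, 2)) == (0.82, 1.22)

    def test_zero_se_collapses_ci(self):
        report = hazard_ratio_report(self._fit_with(np.log(2.0), 0.0))
        e = report.entries[0]
        assert (e.lo, e.hr, e.hi) == pytest.approx((2.0, 2.0, 2.0))

    def test_missing_covariance_rejected(self):
        fit = self._fit_with(0.0, 0.1)
        broken = FitResult(
            model=fit.model, loglik=0.0, covariance=None, converged=True,
            n_iter=1, n_subjects=1, n_pairs=1,
        )
        with pytest.raises(ValueError, match="covariance"):
            hazard_ratio_report(broken)

    def test_significance_filter(self):
        report = hazard_ratio_report(self._fit_with(0.0, 0.1))
        assert report.significant().entries == ()

    def test_recovers_simulated_hazard_ratio(self):
        betas = np.zeros((6, 1))
        betas[1, 0] = np.log(0.5)  # HR 0.5 on transition 1->3
        model = CovariateModel.from_intensity(
            pm.IntensityMatrix.from_rates(BALANCED_Q.rates), covariates=("x",),
            betas=betas, centering=np.zeros(1),
        )
        data, _ = simulate_cohort(
            CohortConfig(n_subjects=1200, model=model, seed=77,
                         covariate_specs={"x": (0.0, 1.0, -np.inf, np.inf)},
                         initial_distribution=(1 / 3, 1 / 3, 1 / 3))
        )
        fit = fit_mle(data, covariates=("x",), config=FitConfig(n_starts=1, seed=0))
        entry = next(
            e for e in hazard_ratio_report(fit).entries
            if e.transition == "1->3" and e.covariate == "x"
        )
        assert entry.lo <= 0.5 <= entry.hi
        assert 0.3 < entry.hr < 0.8


class TestFittedSummaryTable:
    def test_equal_rates_give_uniform_jumps(self):
        model = CovariateModel.from_intensity(IntensityMatrix.from_rates(np.full(6, 0.1)))
        fit = FitResult(model=model, loglik=0.0, covariance=None, converged=True,
                        n_iter=1, n_subjects=1, n_pairs=1)
        table = fitted_summary_table(fit)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(table.jump.values[off], 0.5)
        assert np.allclose(table.sojourn.weeks, 5.0)

    def test_deterministic(self):
        data, _ = simulate_cohort(CohortConfig(n_subjects=200, seed=21))
        fit = fit_mle(data, config=FitConfig(n_starts=1, seed=0))
        t1 = fitted_summary_table(fit)
        t2 = fitted_summary_table(fit)
        assert np.array_equal(t1.jump.values, t2.jump.values)
        assert np.array_equal(t1.sojourn.weeks, t2.sojourn.weeks)

    def test_unconverged_fit_rejected(self):
        model = CovariateModel.from_intensity(BALANCED_Q)
        fit = FitResult(model=model, loglik=0.0, covariance=None, converged=False,
                        n_iter=1, n_subjects=1, n_pairs=1)
        with pytest.raises(ValueError, match="converge"):
            fitted_summary_table(fit)

    def test_simulation_round_trip_against_published_summaries(self, reference_q):
        data, _ = simulate_cohort(
            CohortConfig(n_subjects=5000, seed=13,
                         schedule=tuple(np.arange(6.0, 27.0, 1.0)))
        )
        fit = fit_mle(data, config=FitConfig(n_starts=1, seed=0))
        table = fitted_summary_table(fit)
        true_jump = pm.jump_chain_probabilities(reference_q).values
        true_soj = pm.mean_sojourn_times(reference_q).weeks
        off = ~np.eye(3, dtype=bool)
        assert np.max(np.abs(table.jump.values[off] - true_jump[off])) < 0.05
        assert np.all(np.abs(table.sojourn.weeks / true_soj - 1) < 0.15)


class TestIntervalProbabilityTable:
    def test_nine_month_recovery_cell(self, reference_q):
        table = interval_probability_table(reference_q, ci=False)
        assert table.cell("9m", (3, 1)) == pytest.approx(0.769, abs=0.01)

    def test_short_horizon_offdiagonals_vanish(self, reference_q):
        table = interval_probability_table(
            reference_q, horizons=("0.0001m",), ci=False
        )
        assert np.all(table.point < 1e-4)

    def test_zero_covariance_collapses_ci(self):
        model = CovariateModel.from_intensity(BALANCED_Q)
        n = model.n_params
        fit = FitResult(model=model, loglik=0.0, covariance=np.zeros((n, n)),
                        converged=True, n_iter=1, n_subjects=1, n_pairs=1)
        table = interval_probability_table(fit, horizons=("3m",), bootstrap_reps=50)
        assert np.allclose(table.lo, table.point, atol=1e-12)
        assert np.allclose(table.hi, table.point, atol=1e-12)

    def test_plateau_between_two_and_three_years(self, reference_q):
        table = interval_probability_table(reference_q, horizons=("2y", "3y"), ci=False)
        assert np.max(np.abs(table.point[0] - table.point[1])) < 0.005

    def test_ci_contains_point(self):
        data, _ = simulate_cohort(CohortConfig(n_subjects=500, seed=31))
        fit = fit_mle(data, config=FitConfig(n_starts=1, seed=0))
        table = interval_probability_table(fit, horizons=("3m", "1y"),
                                           bootstrap_reps=300, seed=1)
        assert np.all(table.lo <= table.point + 1e-9)
        assert np.all(table.hi >= table.point - 1e-9)

    def test_points_only_without_covariance(self):
        model = CovariateModel.from_intensity(BALANCED_Q)
        fit = FitResult(model=model, loglik=0.0, covariance=None, converged=True,
                        n_iter=1, n_subjects=1, n_pairs=1)
        table = interval_probability_table(fit, horizons=("3m",))
        assert table.lo is None and table.hi is None


class TestInvariances:
    def test_affine_covariate_rescaling(self):
        betas = np.zeros((6, 1))
        betas[1, 0] = np.log(0.7)
        model = CovariateModel.from_intensity(
            BALANCED_Q, covariates=("x",), betas=betas, centering=np.zeros(1)
        )
        data, _ = simulate_cohort(
            CohortConfig(n_subjects=300, model=model, seed=55,
                         covariate_specs={"x": (0.0, 1.0, -np.inf, np.inf)})
        )
        a, b = 2.5, -1.0
        rows = []
        for s in data.subjects:
            covs = {"x": s.covariates["x"], "xs": a * s.covariates["x"] + b}
            for t, st in zip(s.times, s.states):
                rows.append(pm.Observation(s.subject_id, t, state=int(st), covariates=covs))
        both = pm.PanelDataset(rows)
        f1 = fit_mle(both, covariates=("x",), config=FitConfig(n_starts=1, seed=0))
        f2 = fit_mle(both, covariates=("xs",), config=FitConfig(n_starts=1, seed=0))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)
        assert np.allclose(f2.model.betas * a, f1.model.betas, rtol=1e-2, atol=1e-4)

    def test_consistency_error_decreases_with_n(self):
        model = CovariateModel.from_intensity(BALANCED_Q)
        med = []
        for n in (304, 1000, 5000):
            errs = []
            for rep in range(8):
                data, _ = simulate_cohort(
                    CohortConfig(n_subjects=n, model=model, seed=600 + rep,
                                 initial_distribution=(1 / 3, 1 / 3, 1 / 3))
                )
                fit = fit_mle(data, config=FitConfig(n_starts=1, seed=rep))
                errs.append(
                    np.abs(fit.model.baseline_intensity().rates / BALANCED_Q.rates - 1).sum()
                )
            med.append(np.median(errs))
        assert med[0] > med[1] > med[2]
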