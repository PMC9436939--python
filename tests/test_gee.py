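"""GEE engine: oracle equivalence, limits, moment estimators, sandwich."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from mvgee import (
    ModelSpec,
    PanelDataset,
    fit_gee,
    generate_panel,
    recovery_config,
    sandwich_covariance,
    stack_responses,
)
from mvgee.gee import (
    GEEError,
    RankDeficientError,
    WorkingCorrelation,
    estimate_exchangeable_alpha,
)


def brute_force_gee(design, alpha: float):
    """Independent oracle: solve the estimating equations by explicit
    matrix algebra at fixed exchangeable alpha.

    Builds every cluster's correlation matrix explicitly, inverts it with
    a dense solver, and solves (sum X_i' R_i^-1 X_i) beta = sum X_i' R_i^-1 y_i.
    Also returns the sandwich covariance assembled the same way.
    """
    X, y = design.X, design.y
    p = X.shape[1]
    B = np.zeros((p, p))
    u = np.zeros(p)
    parts = []
    for sl in design.cluster_slices():
        m = sl.stop - sl.start
        R = np.full((m, m), alpha)
        np.fill_diagonal(R, 1.0)
        Rinv = scipy.linalg.inv(R)
        B += X[sl].T @ Rinv @ X[sl]
        u += X[sl].T @ Rinv @ y[sl]
        parts.append((sl, Rinv))
    beta = scipy.linalg.solve(B, u)
    M = np.zeros((p, p))
    for sl, Rinv in parts:
        e = y[sl] - X[sl] @ beta
        g = X[sl].T @ Rinv @ e
        M += np.outer(g, g)
    Binv = scipy.linalg.inv(B)
    return beta, Binv @ M @ Binv


class TestLimitsAndOracles:
    def test_independence_equals_ols(self, tiny_panel, tiny_spec):
        design = stack_responses(tiny_panel, tiny_spec)
        fit = fit_gee(design, corstr="independence")
        ols, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        np.testing.assert_allclose(fit.params.to_numpy(), ols, atol=1e-8)

    def test_singleton_clusters_make_exchangeable_equal_independence(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "visit_time": (np.arange(n) % 5).astype(float),
                "response": "A",
                "value": rng.normal(size=n),
                "x": rng.normal(size=n),
            }
        )
        panel = PanelDataset(df)
        spec = ModelSpec(responses=("A",), covariates=("x",))
        design = stack_responses(panel, spec)
        f_ind = fit_gee(design, corstr="independence")
        f_exc = fit_gee(design, corstr="exchangeable")
        np.testing.assert_array_equal(
            f_ind.params.to_numpy(), f_exc.params.to_numpy()
        )

    def test_matches_brute_force_solve_at_fitted_alpha(self, tiny_panel, tiny_spec):
        design = stack_responses(tiny_panel, tiny_spec)
        fit = fit_gee(design, corstr="exchangeable", tol=1e-12)
        beta, cov = brute_force_gee(design, fit.working.alpha)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-8)
        np.testing.assert_allclose(fit.cov_robust.to_numpy(), cov, rtol=1e-8)

    @pytest.mark.parametrize("corstr", ["independence", "exchangeable"])
    def test_matches_statsmodels_reference(self, tiny_panel, tiny_spec, corstr):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.genmod.cov_struct import Exchangeable, Independence

        design = stack_responses(tiny_panel, tiny_spec)
        fit = fit_gee(design, corstr=corstr, tol=1e-12)
        cs = Independence() if corstr == "independence" else Exchangeable()
        ref = sm.GEE(
            design.y,
            pd.DataFrame(design.X, columns=design.columns),
            groups=pd.Series(design.cluster),
            cov_struct=cs,
            family=sm.families.Gaussian(),
        ).fit(maxiter=200, ctol=1e-12)
        np.testing.assert_allclose(
            fit.params.to_numpy(), ref.params.to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(
            fit.se_robust.to_numpy(), ref.bse.to_numpy(), rtol=1e-6
        )

    def test_ar1_fits_stacked_panel(self, tiny_panel, tiny_spec):
        design = stack_responses(tiny_panel, tiny_spec)
        fit = fit_gee(design, corstr="ar1")
        assert fit.converged
        assert np.isfinite(fit.params.to_numpy()).all()
        assert -1 < fit.working.alpha < 1

    def test_unstructured_fits_univariate_balanced_panel(self):
        # a 14x14 correlation matrix needs many more clusters than entries
        cfg = recovery_config(n_subjects=200, seed=29)
        panel = generate_panel(cfg).subset_response("FBS")
        spec = ModelSpec(responses=("FBS",), covariates=("systolic_bp",))
        fit = fit_gee(stack_responses(panel, spec), corstr="unstructured")
        assert fit.converged
        R = fit.working.matrix
        assert R.shape == (14, 14)
        # off-diagonals concentrate near the generating alpha
        off = R[np.triu_indices(14, k=1)]
        assert abs(off.mean() - 0.5) < 0.1

    def test_unstructured_rejects_unbalanced(self, tiny_panel, tiny_spec):
        df = tiny_panel.data.drop(index=0).reset_index(drop=True)
        design = stack_responses(PanelDataset(df), tiny_spec)
        with pytest.raises(GEEError, match="balanced"):
            fit_gee(design, corstr="unstructured")


class TestAlphaEstimator:
    def test_iid_residuals_give_near_zero_alpha(self):
        rng = np.random.default_rng(4)
        n_clusters, m = 600, 6
        resid = rng.normal(size=n_clusters * m)
        slices = [slice(i * m, (i + 1) * m) for i in range(n_clusters)]
        alpha, clamped = estimate_exchangeable_alpha(resid, slices, 1.0, 2)
        assert not clamped
        assert abs(alpha) < 0.03

    def test_identical_residuals_clamp_at_upper_boundary(self):
        resid = np.repeat([1.0, -2.0, 0.5, 1.5], 4)
        slices = [slice(i * 4, (i + 1) * 4) for i in range(4)]
        scale = float(resid @ resid / len(resid))
        with pytest.warns(UserWarning, match="clamped"):
            alpha, clamped = estimate_exchangeable_alpha(resid, slices, scale, 0)
        assert clamped
        assert alpha == pytest.approx(1.0, abs=1e-5)

    def test_all_singleton_clusters_raise(self):
        resid = np.ones(5)
        slices = [slice(i, i + 1) for i in range(5)]
        with pytest.raises(GEEError, match="independence"):
            estimate_exchangeable_alpha(resid, slices, 1.0, 1)

    def test_generator_alpha_recovered_after_fit(self):
        # responses on a common scale: the single-scale stacked model can
        # then recover the generating alpha (heteroscedastic responses
        # attenuate it; see the methods note)
        from mvgee import CovariateSpec, SimulationConfig

        cfg = SimulationConfig(
            n_subjects=1000,
            visit_times=(0.0, 3.0, 6.0, 9.0, 12.0),
            covariates=(CovariateSpec("x", "continuous", mean=0.0, sd=1.0),),
            true_beta={
                "A": {"intercept": 2.0, "time": -0.3, "x": 1.0},
                "B": {"intercept": -1.0, "time": 0.2, "x": -0.5},
            },
            residual_sd={"A": 2.0, "B": 2.0},
            within_corr=0.5,
            seed=17,
        )
        panel = generate_panel(cfg)
        spec = ModelSpec(
            responses=("A", "B"),
            covariates=("x",),
            interaction_set=frozenset({"intercept", "time", "x"}),
        )
        fit = fit_gee(stack_responses(panel, spec), corstr="exchangeable")
        assert fit.converged
        assert fit.working.alpha == pytest.approx(0.5, abs=0.05)


class TestSandwich:
    def test_closed_form_robust_variance_of_mean(self):
        # intercept-only model on singleton clusters: the sandwich equals
        # the heteroskedasticity-robust variance of the sample mean
        from mvgee import StackedDesign

        rng = np.random.default_rng(8)
        n = 200
        y = rng.normal(scale=np.sqrt(np.arange(1, n + 1)), size=n)
        design = StackedDesign(
            y=y,
            X=np.ones((n, 1)),
            columns=["intercept"],
            cluster=np.array([f"S{i}" for i in range(n)]),
            visit_time=np.zeros(n),
            visit_index=np.zeros(n, dtype=int),
            response_index=np.zeros(n, dtype=int),
            response_names=("A",),
            spec=ModelSpec(responses=("A",)),
        )
        fit = fit_gee(design, corstr="independence")
        e = y - y.mean()
        expected = float(e @ e) / n**2
        assert fit.cov_robust.iloc[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_robust_neq_naive_under_misspecification(self):
        # independence working structure on strongly exchangeable data:
        # the sandwich must disagree with the naive covariance for time
        cfg = recovery_config(n_subjects=500, seed=23)
        import dataclasses

        cfg = dataclasses.replace(cfg, within_corr=0.8)
        panel = generate_panel(cfg)
        spec = ModelSpec(
            responses=("FBS", "HbA1c"), interaction_set=frozenset({"intercept", "time"})
        )
        fit = fit_gee(stack_responses(panel, spec), corstr="independence")
        rel = abs(fit.se_robust["time"] - fit.se_naive["time"]) / fit.se_naive["time"]
        assert rel > 0.10

    def test_standalone_matches_fit_internal(self, tiny_panel, tiny_spec):
        design = stack_responses(tiny_panel, tiny_spec)
        fit = fit_gee(design, corstr="exchangeable", tol=1e-12)
        V = sandwich_covariance(design, fit.working, fit.params.to_numpy())
        np.testing.assert_allclose(fit.cov_robust.to_numpy(), V, rtol=1e-10)


class TestContractsAndInvariances:
    def test_rank_deficient_design_names_columns(self, tiny_panel):
        spec = ModelSpec(
            responses=("FBS", "HbA1c"), covariates=("systolic_bp", "systolic_bp2")
        )
        df = tiny_panel.data.copy()
        df["systolic_bp2"] = df["systolic_bp"]
        with pytest.raises(RankDeficientError, match="systolic_bp"):
            fit_gee(stack_responses(PanelDataset(df), spec))

    def test_scale_equivariance_identity_link(self, tiny_panel, tiny_spec):
        design = stack_responses(tiny_panel, tiny_spec)
        fit1 = fit_gee(design, corstr="exchangeable", tol=1e-12)
        import copy

        design2 = copy.deepcopy(design)
        design2.y = design.y * 3.0
        fit2 = fit_gee(design2, corstr="exchangeable", tol=1e-12)
        np.testing.assert_allclose(
            fit2.params.to_numpy(), 3.0 * fit1.params.to_numpy(), rtol=1e-8
        )

    def test_cluster_permutation_invariance(self, tiny_config, tiny_spec):
        panel = generate_panel(tiny_config)
        design = stack_responses(panel, tiny_spec)
        fit1 = fit_gee(design, corstr="exchangeable", tol=1e-12)
        shuffled = panel.data.sort_values(
            "subject_id", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
        design2 = stack_responses(PanelDataset(shuffled), tiny_spec)
        fit2 = fit_gee(design2, corstr="exchangeable", tol=1e-12)
        np.testing.assert_allclose(
            fit1.params.to_numpy(), fit2.params.to_numpy(), atol=1e-10
        )

    def test_nonconvergence_reported_not_raised(self, tiny_panel, tiny_spec):
        design = stack_responses(tiny_panel, tiny_spec)
        with pytest.warns(UserWarning, match="did not converge"):
            fit = fit_gee(design, corstr="exchangeable", tol=1e-16, max_iter=1)
        assert not fit.converged
        assert fit.iterations == 1
        assert np.isfinite(fit.max_rel_change)

    def test_fewer_than_two_clusters_rejected(self, tiny_panel, tiny_spec):
        one = tiny_panel.data[
            tiny_panel.data["subject_id"] == tiny_panel.subject_ids[0]
        ].reset_index(drop=True)
        design = stack_responses(PanelDataset(one), tiny_spec)
        with pytest.raises(GEEError, match="clusters"):
            fit_gee(design)

    def test_fixed_alpha_is_honoured(self, tiny_panel, tiny_spec):
        design = stack_responses(tiny_panel, tiny_spec)
        fit = fit_gee(design, corstr="exchangeable", fixed_alpha=0.25)
        assert fit.working.alpha == 0.25
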