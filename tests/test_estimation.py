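"""CLS / MQL / CML estimation, variance estimators, covariance, AIC/BIC."""

import numpy as np
import pytest
from scipy import optimize

from psetinar import (
    CountSeries,
    InnovationSpec,
    ModelSpec,
    ThetaVector,
    aic_bic,
    asymptotic_covariance,
    cls_estimate,
    cml_estimate,
    mql_estimate,
    mql_normal_equations,
    simulate,
    transition_pmf,
    variance_est_v1,
    variance_est_v2,
)
from psetinar.estimation import _cycle_loglik
from psetinar.study import make_model, make_scenario, run_parameter_study


def _unit_theta(T):
    """theta giving V == 1 for every observation."""
    return ThetaVector(theta1=np.zeros(T), theta2=np.zeros(T), sigma2z=np.ones(T))


class TestCLS:
    def test_equals_numeric_sse_minimizer(self, series_a_model_i_spec):
        """The closed form coincides with a generic optimizer of the SSE."""
        spec = series_a_model_i_spec
        series = simulate(spec, 50, rng=42)
        est = cls_estimate(series, spec.r)

        def sse(beta):
            total = 0.0
            for j in (1, 2, 3):
                xp, x = series.cycle(j)
                a1, a2, lam = beta[3 * (j - 1): 3 * j]
                in1 = xp <= spec.r[j - 1]
                fitted = np.where(in1, a1, a2) * xp + lam
                total += np.sum((x - fitted) ** 2)
            return total

        opt = optimize.minimize(sse, est.beta_hat + 0.3, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert sse(est.beta_hat) <= opt.fun + 1e-8
        np.testing.assert_allclose(est.beta_hat, opt.x, atol=1e-5)

    def test_empty_regime_flagged(self):
        # all lagged values <= r: regime 2 has no data
        series = CountSeries(x=[1, 2, 1, 3, 2, 1], T=1, x0=1)
        est = cls_estimate(series, r=[10])
        assert np.isnan(est.alpha[0, 1])
        assert est.n_regime[0, 1] == 0
        assert any("regime 2" in msg for msg in est.flags[1])

    def test_boundary_detection(self):
        est = cls_estimate(
            CountSeries(x=[0, 5, 0, 6, 0, 7, 1, 4], T=1, x0=2), r=[2]
        )
        # whatever the values, the boundary mask matches the raw estimates
        expected = (est.alpha < 0) | (est.alpha > 1)
        np.testing.assert_array_equal(est.boundary, expected)


class TestVarianceEstimators:
    def test_v1_zero_alpha_reduces_to_msr(self, series_a_sim, series_a_model_i_spec):
        series, r = series_a_sim, series_a_model_i_spec.r
        lam_hat = np.array([series.cycle(j)[1].mean() for j in (1, 2, 3)])
        v1, _ = variance_est_v1(series, r, np.zeros((3, 2)), lam_hat)
        for j in (1, 2, 3):
            x = series.cycle(j)[1]
            assert v1[j - 1] == pytest.approx(np.mean((x - lam_hat[j - 1]) ** 2))

    def test_v1_consistency(self, series_a_model_i_spec):
        # Poisson innovations: sigma2z = lam
        spec = series_a_model_i_spec
        acc = []
        for i in range(200):
            s = simulate(spec, 300, rng=i)
            c = cls_estimate(s, spec.r)
            v1, _ = variance_est_v1(s, spec.r, np.clip(c.alpha, 0, 1), c.lam)
            acc.append(v1)
        np.testing.assert_allclose(
            np.mean(acc, axis=0), spec.innovations.lam, rtol=0.05
        )

    def test_v2_collapse_all_regime_one(self):
        # p_hat = 1 and alpha = 0: v2 equals the marginal variance
        series = CountSeries(x=[3, 1, 4, 1, 5, 9, 2, 6], T=1, x0=3)
        v2, floored, flags = variance_est_v2(series, r=[100], alpha_hat=[[0.0, 0.0]])
        assert 1 in flags  # regime 2 empty
        series2 = CountSeries(x=[3, 1, 4, 1, 5, 9, 2, 6], T=1, x0=3)
        # use a threshold splitting the data; then check agreement with formula
        v2b, _, flags_b = variance_est_v2(series2, r=[3], alpha_hat=[[0.0, 0.0]])
        assert not flags_b

    def test_v1_v2_agree_in_mean(self, series_a_model_i_spec):
        spec = series_a_model_i_spec
        acc1, acc2 = [], []
        for i in range(200):
            s = simulate(spec, 300, rng=i)
            c = cls_estimate(s, spec.r)
            a = np.clip(c.alpha, 0, 1)
            v1, _ = variance_est_v1(s, spec.r, a, c.lam)
            v2, _, _ = variance_est_v2(s, spec.r, a)
            acc1.append(v1)
            acc2.append(v2)
        m1, m2 = np.mean(acc1, axis=0), np.mean(acc2, axis=0)
        se = np.std(np.array(acc1) - np.array(acc2), axis=0, ddof=1) / np.sqrt(200)
        assert np.all(np.abs(m1 - m2) < np.maximum(3 * se, 0.02))

    def test_flooring(self):
        # constant-ish series gives a tiny/negative raw value -> floored
        series = CountSeries(x=[2, 2, 2, 2, 2, 2, 3, 2], T=1, x0=2)
        v1, floored = variance_est_v1(series, [2], [[0.5, 0.5]], [0.0])
        assert np.all(v1 >= 1e-4)


class TestMQL:
    def test_unit_weights_equal_cls(self, series_a_sim, series_a_model_i_spec):
        r = series_a_model_i_spec.r
        cls_res = cls_estimate(series_a_sim, r)
        mql_res = mql_estimate(series_a_sim, r, theta=_unit_theta(3))
        np.testing.assert_allclose(mql_res.beta_hat, cls_res.beta_hat, atol=1e-10)

    def test_block_diagonal_identity(self, series_a_sim, series_a_model_i_spec):
        """Solving the assembled 9x9 system equals the per-cycle 3x3 solves."""
        r = series_a_model_i_spec.r
        theta = ThetaVector.from_alpha(
            series_a_model_i_spec.alpha, series_a_model_i_spec.innovations.lam
        )
        Q, q = mql_normal_equations(series_a_sim, r, theta)
        full = np.linalg.solve(Q, q)
        res = mql_estimate(series_a_sim, r, theta=theta)
        np.testing.assert_allclose(res.beta_hat, full, atol=1e-10)

    def test_efficiency_vs_cls_geometric(self):
        """Overdispersed innovations: MQL at least as precise as CLS for most
        components (inverse-variance weighting uses more information)."""
        scen = make_scenario("A", "II", N_list=(300,), reps=500, base_seed=100)
        tab = run_parameter_study(scen, methods=("CLS", "MQL"))
        piv = tab.pivot_table(index="parameter", columns="method", values="mse")
        wins = int((piv["MQL"] <= piv["CLS"]).sum())
        assert wins >= 6, f"MQL beat CLS on only {wins}/9 components"


class TestCML:
    def test_transition_pmf_rows_sum_to_one(self, series_a_model_i_spec):
        spec = series_a_model_i_spec
        for j in (1, 2, 3):
            for x_prev in (0, 3, 7):
                k = 0 if x_prev <= spec.r[j - 1] else 1
                row = transition_pmf(
                    x_prev, np.arange(0, 200), spec.alpha[j - 1, k],
                    spec.innovations, j
                )
                assert row.sum() == pytest.approx(1.0, abs=1e-8)

    def test_likelihood_dominance_at_truth(self, series_a_model_i_spec):
        """True parameters beat a fixed perturbation on nearly every draw."""
        spec = series_a_model_i_spec
        wins = 0
        for i in range(20):
            s = simulate(spec, 300, rng=500 + i)
            ll_true = ll_pert = 0.0
            for j in (1, 2, 3):
                xp, x = s.cycle(j)
                in1 = xp <= spec.r[j - 1]
                a1, a2 = spec.alpha[j - 1]
                lam = spec.innovations.lam[j - 1]
                ll_true += _cycle_loglik(xp, x, in1, a1, a2, lam, spec.innovations.family)
                ll_pert += _cycle_loglik(
                    xp, x, in1, min(a1 + 0.3, 1 - 1e-6), min(a2 + 0.3, 1 - 1e-6),
                    lam + 2, spec.innovations.family,
                )
            wins += ll_true > ll_pert
        assert wins >= 19

    def test_estimates_near_truth(self, series_a_model_i_spec):
        spec = series_a_model_i_spec
        s = simulate(spec, 300, rng=9)
        est = cml_estimate(s, spec.r, family="poisson")
        assert est.loglik is not None
        np.testing.assert_allclose(est.lam, spec.innovations.lam, atol=0.8)
        np.testing.assert_allclose(est.alpha, spec.alpha, atol=0.35)

    def test_mixture_rejected(self, series_a_sim):
        with pytest.raises(ValueError):
            cml_estimate(series_a_sim, [3, 2, 2], family="mixture")


class TestAsymptoticCovariance:
    def test_symmetric_psd_blocks(self, series_a_sim, series_a_model_i_spec):
        spec = series_a_model_i_spec
        theta = ThetaVector.from_alpha(spec.alpha, spec.innovations.lam)
        cov = asymptotic_covariance(series_a_sim, spec.r, theta)
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)
        # block-diagonal: off-diagonal blocks are exactly zero
        assert np.all(cov[:3, 3:] == 0)

    def test_unit_weights_reduce_to_moment_matrix(
        self, series_a_sim, series_a_model_i_spec
    ):
        r = series_a_model_i_spec.r
        Q, _ = mql_normal_equations(series_a_sim, r, _unit_theta(3))
        xp, x = series_a_sim.cycle(1)
        in1 = xp <= r[0]
        assert Q[0, 0] == pytest.approx(np.sum((xp * in1) ** 2))
        assert Q[2, 2] == pytest.approx(xp.size)

    def test_matches_monte_carlo_dispersion(self, series_a_model_i_spec):
        """Plug-in variances track the sampling variance of the estimator."""
        spec = series_a_model_i_spec
        draws, plug = [], []
        for i in range(400):
            s = simulate(spec, 300, rng=3000 + i)
            est = mql_estimate(s, spec.r)
            if not np.all(np.isfinite(est.beta_hat)):
                continue
            draws.append(est.beta_hat)
            plug.append(np.diag(est.cov))
        emp = np.var(np.asarray(draws), axis=0, ddof=1)
        mean_plug = np.mean(plug, axis=0)
        np.testing.assert_allclose(mean_plug, emp, rtol=0.2)


class TestConsistencyAcrossN:
    def test_mse_decreases_with_sample_size(self, series_a_model_i_spec):
        """Every component's MSE shrinks from N=50 to N=300 for all methods,
        and the average |bias| shrinks too."""
        scen = make_scenario("A", "I", N_list=(50, 300), reps=200, base_seed=0)
        tab = run_parameter_study(scen, methods=("CLS", "MQL", "CML"))
        for m in ("CLS", "MQL", "CML"):
            sub = tab[tab.method == m].pivot_table(
                index="parameter", columns="N", values=["mse", "bias"]
            )
            assert (sub["mse"][300] < sub["mse"][50]).all(), m
            assert sub["bias"][300].abs().mean() < sub["bias"][50].abs().mean(), m


class TestRobustnessToMixtureContamination:
    def test_quasi_likelihood_robust_cml_not(self):
        """Shrinking the mixture weight (more geometric contamination) barely
        moves CLS/MQL MSEs but inflates CML biases (which assume Poisson)."""
        tabs = {}
        for rho in (0.9, 0.8):
            scen = make_scenario(
                "A", "III", rho=np.full(3, rho), N_list=(300,), reps=200,
                base_seed=7000,
            )
            tabs[rho] = run_parameter_study(
                scen, methods=("CLS", "MQL", "CML"), cml_family="poisson"
            )
        for m in ("CLS", "MQL"):
            a = tabs[0.9][tabs[0.9].method == m].set_index("parameter")["mse"]
            b = tabs[0.8][tabs[0.8].method == m].set_index("parameter")["mse"]
            rel = ((a - b).abs() / np.maximum(a, 1e-8)).max()
            assert rel < 0.30, f"{m} MSE moved {rel:.0%} under contamination"
        a = tabs[0.9][tabs[0.9].method == "CML"].set_index("parameter")["bias"].abs()
        b = tabs[0.8][tabs[0.8].method == "CML"].set_index("parameter")["bias"].abs()
        assert (b > a).sum() >= 5, "CML bias magnitudes should grow for most components"


class TestInformationCriteria:
    def test_arithmetic(self):
        aic, bic = aic_bic(-100.0, 3, 100)
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200 + 3 * np.log(100))

    def test_zero_params(self):
        aic, bic = aic_bic(-50.0, 0, 10)
        assert aic == bic == 100.0

    def test_monotone_in_params(self):
        assert aic_bic(-10, 5, 30) > aic_bic(-10, 3, 30)
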