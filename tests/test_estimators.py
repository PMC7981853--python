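import numpy as np
import pandas as pd
import pytest
from sksurv.linear_model import CoxPHSurvivalAnalysis

from ivhr import (
    DegenerateDataError,
    HazardRatioModel,
    SimulationConfig,
    SurvivalSample,
    bootstrap_ci,
    breslow_baseline,
    build_risk_sets,
    fit_piecewise,
    generate_dataset,
    iv_estimating_function,
    solve_iv,
    solve_partial_likelihood,
)
from tests.conftest import make_random_sample


def brute_force_equations(theta, sample, model, z):
    """Literal double loop over events and risk sets (the oracle)."""
    model = model.with_theta(theta)
    G = np.zeros(model.K)
    for i in np.flatnonzero(sample.event == 1):
        v = sample.time[i]
        risk = sample.time >= v
        wgt = np.exp(model.log_hazard_ratio(v) * sample.exposure[risk])
        zbar = np.sum(z[risk] * wgt) / np.sum(wgt)
        G += model.gradient(v) * (z[i] - zbar)
    return G


def cox_fit(sample: SurvivalSample) -> float:
    """Independent maximum-partial-likelihood oracle (Breslow ties)."""
    y = np.empty(sample.n, dtype=[("event", bool), ("time", float)])
    y["event"], y["time"] = sample.event.astype(bool), sample.time
    cox = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200).fit(
        pd.DataFrame({"x": sample.exposure}), y
    )
    return float(cox.coef_[0])


class TestEstimatingFunction:
    @pytest.mark.parametrize(
        "model, theta",
        [
            (HazardRatioModel.constant(), [0.0]),
            (HazardRatioModel.constant(), [0.7]),
            (HazardRatioModel.loglinear(), [0.2, -0.3]),
            (HazardRatioModel.piecewise((0.3, 0.8)), [0.5, -0.2, 0.1]),
        ],
    )
    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_brute_force(self, model, theta, seed):
        sample = make_random_sample(seed=seed, n=90)
        fast = iv_estimating_function(theta, sample, model)
        slow = brute_force_equations(np.asarray(theta), sample, model, sample.instrument)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_hand_enumeration(self, tiny_sample):
        # risk sets {0,1,2}, {1,2}, {2}; X=(1,0,1), W=(1,0,0); at theta=0 the
        # weighted means of W are 1/3, 0, 0 so G = (1-1/3)+(0-0)+(0-0) = 2/3
        g = iv_estimating_function([0.0], tiny_sample, HazardRatioModel.constant())
        assert g[0] == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("theta", [[0.0], [1.3], [-2.0]])
    def test_constant_instrument_gives_zero(self, theta):
        sample = make_random_sample(seed=4, n=50)
        flat = SurvivalSample(
            time=sample.time, event=sample.event, exposure=sample.exposure,
            instrument=np.full(sample.n, 3.7),
        )
        g = iv_estimating_function(theta, flat, HazardRatioModel.constant())
        np.testing.assert_allclose(g, 0.0, atol=1e-10)

    def test_with_ties_matches_brute_force(self):
        # Breslow tie handling: tied events share one risk set
        rng = np.random.default_rng(8)
        n = 60
        sample = SurvivalSample(
            time=rng.integers(1, 8, n).astype(float),
            event=(rng.uniform(size=n) < 0.7).astype(float),
            exposure=rng.integers(0, 2, n).astype(float),
            instrument=rng.standard_normal(n),
        )
        model = HazardRatioModel.loglinear()
        theta = [0.3, -0.1]
        np.testing.assert_allclose(
            iv_estimating_function(theta, sample, model),
            brute_force_equations(np.asarray(theta), sample, model, sample.instrument),
            atol=1e-10,
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_iv_with_w_equals_x_matches_cox(self, seed):
        """Substituting W ≡ X turns the IV equations into the Cox score."""
        sample = make_random_sample(seed=seed, n=250)
        degenerate_iv = SurvivalSample(
            time=sample.time, event=sample.event,
            exposure=sample.exposure, instrument=sample.exposure,
        )
        res = solve_iv(degenerate_iv, HazardRatioModel.constant())
        assert res.converged
        assert res.theta_hat[0] == pytest.approx(cox_fit(sample), abs=1e-6)

    def test_partial_likelihood_matches_cox(self, random_sample):
        res = solve_partial_likelihood(random_sample, HazardRatioModel.constant())
        assert res.converged
        assert res.theta_hat[0] == pytest.approx(cox_fit(random_sample), abs=1e-6)

    def test_piecewise_pl_matches_per_window_cox(self):
        sample = make_random_sample(seed=21, n=400)
        cuts = (0.0, 0.4, 1.0)
        res = fit_piecewise(sample, cuts, method="partial_likelihood")
        assert res.converged
        for w in res.window_results:
            keep = sample.time >= w.lower
            t = np.minimum(sample.time[keep], w.upper)
            e = np.where(sample.time[keep] < w.upper, sample.event[keep], 0.0)
            truncated = SurvivalSample(
                time=t, event=e, exposure=sample.exposure[keep],
                instrument=sample.instrument[keep],
            )
            assert w.theta == pytest.approx(cox_fit(truncated), abs=1e-6)


class TestBreslow:
    def test_null_model_is_nelson_aalen(self, random_sample):
        bh = breslow_baseline([0.0], random_sample, HazardRatioModel.constant())
        idx = build_risk_sets(random_sample)
        na = np.array(
            [len(e) / len(r) for e, r in zip(idx.event_ids, idx.at_risk_ids)]
        )
        np.testing.assert_allclose(bh.increments, na, rtol=1e-12)

    def test_hand_arithmetic(self):
        s = SurvivalSample(time=[1, 2], event=[1, 1], exposure=[1, 0], instrument=[0, 1])
        bh = breslow_baseline([np.log(2.0)], s, HazardRatioModel.constant())
        np.testing.assert_allclose(bh.increments, [1.0 / 3.0, 1.0])
        np.testing.assert_allclose(bh.cumulative, [1.0 / 3.0, 4.0 / 3.0])

    def test_solves_baseline_equation_at_event_times(self, random_sample):
        """Plugging the increments back in leaves zero residual at every event time:
        Σ_i N_i(t) = Σ_i ∫₀ᵗ R_i(v) exp{β_X(v)X_i} dΛ̂₀(v)."""
        model = HazardRatioModel.loglinear(0.4, -0.2)
        theta = [0.4, -0.2]
        bh = breslow_baseline(theta, random_sample, model)
        beta_v = model.log_hazard_ratio(bh.event_times)
        lhs = rhs = 0.0
        for k, v in enumerate(bh.event_times):
            risk = random_sample.time >= v
            lhs += np.sum((random_sample.time == v) & (random_sample.event == 1))
            rhs += bh.increments[k] * np.sum(
                np.exp(beta_v[k] * random_sample.exposure[risk])
            )
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_increments_positive_cumulative_monotone(self, random_sample):
        bh = breslow_baseline([0.6], random_sample, HazardRatioModel.constant())
        assert np.all(bh.increments > 0)
        assert np.all(np.diff(bh.cumulative) > 0)


class TestSolver:
    def test_root_is_verified(self, random_sample):
        res = solve_iv(random_sample, HazardRatioModel.constant())
        assert res.converged
        assert res.residual_norm <= 1e-8
        g = iv_estimating_function(res.theta_hat, random_sample, HazardRatioModel.constant())
        assert np.max(np.abs(g)) <= 1e-8

    def test_loglinear_root_is_verified(self, random_sample):
        res = solve_iv(random_sample, HazardRatioModel.loglinear())
        assert res.converged
        g = iv_estimating_function(res.theta_hat, random_sample, HazardRatioModel.loglinear())
        assert np.max(np.abs(g)) <= 1e-8

    def test_constant_exposure_degenerate(self):
        rng = np.random.default_rng(0)
        s = SurvivalSample(time=rng.exponential(size=20), event=np.ones(20),
                           exposure=np.ones(20), instrument=rng.standard_normal(20))
        with pytest.raises(DegenerateDataError, match="exposure"):
            solve_iv(s, HazardRatioModel.constant())

    def test_constant_instrument_degenerate(self, random_sample):
        flat = SurvivalSample(time=random_sample.time, event=random_sample.event,
                              exposure=random_sample.exposure,
                              instrument=np.zeros(random_sample.n))
        with pytest.raises(DegenerateDataError, match="instrument"):
            solve_iv(flat, HazardRatioModel.constant())

    def test_nonconvergence_is_reported_not_raised(self, random_sample):
        res = solve_iv(random_sample, HazardRatioModel.constant(), max_iter=1)
        assert not res.converged  # one Newton step cannot reach 1e-8 here
        assert np.isfinite(res.theta_hat).all()

    def test_scale_equivariance(self, random_sample):
        """Multiplying all times by c leaves constant/piecewise θ̂ unchanged
        (with cutpoints scaled) and divides the loglinear slope by c."""
        c = 37.0
        scaled = SurvivalSample(time=random_sample.time * c, event=random_sample.event,
                                exposure=random_sample.exposure,
                                instrument=random_sample.instrument)
        r1 = solve_iv(random_sample, HazardRatioModel.constant())
        r2 = solve_iv(scaled, HazardRatioModel.constant())
        assert r2.theta_hat[0] == pytest.approx(r1.theta_hat[0], abs=1e-7)

        p1 = fit_piecewise(random_sample, (0.3, 0.9), method="iv")
        p2 = fit_piecewise(scaled, (0.3 * c, 0.9 * c), method="iv")
        np.testing.assert_allclose(p1.theta_hat, p2.theta_hat, atol=1e-7)

        l1 = solve_iv(random_sample, HazardRatioModel.loglinear())
        l2 = solve_iv(scaled, HazardRatioModel.loglinear())
        assert l2.theta_hat[0] == pytest.approx(l1.theta_hat[0], abs=1e-6)
        assert l2.theta_hat[1] == pytest.approx(l1.theta_hat[1] / c, abs=1e-6)

    def test_instrument_affine_invariance(self, random_sample):
        shifted = SurvivalSample(time=random_sample.time, event=random_sample.event,
                                 exposure=random_sample.exposure,
                                 instrument=5.0 - 2.0 * random_sample.instrument)
        r1 = solve_iv(random_sample, HazardRatioModel.loglinear())
        r2 = solve_iv(shifted, HazardRatioModel.loglinear())
        np.testing.assert_allclose(r1.theta_hat, r2.theta_hat, atol=1e-6)

    def test_recovers_constant_log_hr_without_confounding(self):
        """Median IV estimate over replicates approaches the true marginal
        log HR of 0.5 when treatment is exogenous."""
        true = HazardRatioModel.constant(0.5)
        estimates = []
        for i in range(200):
            ds = generate_dataset(SimulationConfig(
                true_model=true, alpha_ux=0.0, alpha_wx=np.log(10.0),
                n=1000, censor_rate=0.5, seed=9000 + i,
            ))
            res = solve_iv(ds.sample, HazardRatioModel.constant())
            if res.converged:
                estimates.append(res.theta_hat[0])
        estimates = np.asarray(estimates)
        assert len(estimates) >= 190
        med = np.median(estimates)
        mc_err = 1.2533 * estimates.std() / np.sqrt(len(estimates))
        assert abs(med - 0.5) < 4 * mc_err + 0.01


class TestPiecewiseFitting:
    def test_single_window_equals_constant(self, random_sample):
        pw = fit_piecewise(random_sample, (0.0,), method="iv")
        const = solve_iv(random_sample, HazardRatioModel.constant())
        assert pw.theta_hat[0] == pytest.approx(const.theta_hat[0], abs=1e-8)

    @pytest.mark.parametrize("method", ["iv", "partial_likelihood"])
    def test_joint_solve_decouples(self, method):
        """The K-dimensional system with indicator weights equals the
        window-by-window constant solves."""
        sample = make_random_sample(seed=31, n=300)
        cuts = (0.0, 0.3, 0.8)
        per_window = fit_piecewise(sample, cuts, method=method)
        model = HazardRatioModel.piecewise(cuts)
        if method == "iv":
            joint = solve_iv(sample, model)
        else:
            joint = solve_partial_likelihood(sample, model)
        assert per_window.converged and joint.converged
        np.testing.assert_allclose(per_window.theta_hat, joint.theta_hat, atol=1e-6)

    def test_empty_window_reported_others_returned(self):
        rng = np.random.default_rng(2)
        n = 80
        # all events before t=2; the (2, inf) window has censorings only
        t = rng.uniform(0.1, 1.9, n)
        e = np.ones(n)
        e[t > 1.5] = 0
        t[e == 0] = 2.5
        s = SurvivalSample(time=t, event=e, exposure=rng.integers(0, 2, n).astype(float),
                           instrument=rng.standard_normal(n))
        res = fit_piecewise(s, (0.0, 1.0, 2.0), method="iv")
        assert not res.converged
        assert res.window_results[2].error is not None
        assert "window 2" in res.window_results[2].error
        assert np.isnan(res.theta_hat[2])
        assert np.isfinite(res.theta_hat[:2]).all()


class TestBootstrap:
    def test_seed_reproducibility(self, random_sample):
        a = bootstrap_ci(random_sample, HazardRatioModel.constant(), B=50, seed=5)
        b = bootstrap_ci(random_sample, HazardRatioModel.constant(), B=50, seed=5)
        np.testing.assert_array_equal(a.ci_lower, b.ci_lower)
        np.testing.assert_array_equal(a.ci_upper, b.ci_upper)

    def test_interval_nesting(self, random_sample):
        wide = bootstrap_ci(random_sample, HazardRatioModel.constant(), B=200,
                            level=0.95, seed=3)
        narrow = bootstrap_ci(random_sample, HazardRatioModel.constant(), B=200,
                              level=0.50, seed=3)
        assert np.all(wide.ci_lower <= narrow.ci_lower)
        assert np.all(narrow.ci_upper <= wide.ci_upper)

    def test_interval_brackets_estimate(self, random_sample):
        res = bootstrap_ci(random_sample, HazardRatioModel.constant(), B=200, seed=1)
        assert np.all(res.ci_lower <= res.theta_hat)
        assert np.all(res.theta_hat <= res.ci_upper)

    def test_coverage_without_confounding(self):
        """95% percentile intervals cover the true log HR in roughly 95% of
        replications (checked at reduced replication, ±5 points)."""
        true_theta = 0.5
        covered = 0
        outer = 60
        for i in range(outer):
            ds = generate_dataset(SimulationConfig(
                true_model=HazardRatioModel.constant(true_theta),
                alpha_ux=0.0, alpha_wx=np.log(10.0), n=200, censor_rate=0.5,
                seed=5000 + i,
            ))
            res = bootstrap_ci(ds.sample, HazardRatioModel.constant(),
                               B=120, level=0.95, seed=i)
            if res.ci_lower[0] <= true_theta <= res.ci_upper[0]:
                covered += 1
        assert covered / outer == pytest.approx(0.95, abs=0.05)

    def test_validation(self, random_sample):
        with pytest.raises(ValueError):
            bootstrap_ci(random_sample, HazardRatioModel.constant(), B=1)
        with pytest.raises(ValueError):
            bootstrap_ci(random_sample, HazardRatioModel.constant(), level=1.5)
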