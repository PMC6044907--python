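"""FIML likelihood, fitting, tests (Wald/LRT), multigroup models, shares."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iced import (Dataset, Design, ICEDModel, MultigroupICEDModel,
                  SimulationSpec, VarianceComponents, fiml_loglik, fit_fiml,
                  interaction_lrt, simulate_dataset, standardize,
                  two_day_design)


def dense_loglik(values: pd.DataFrame, mean: np.ndarray, sigma: np.ndarray) -> float:
    """Independent oracle: complete-data MVN log-likelihood via scipy."""
    return float(sum(stats.multivariate_normal.logpdf(row, mean=mean, cov=sigma)
                     for row in values.to_numpy()))


def oneway_ml(values: np.ndarray):
    """Closed-form ML for the balanced one-way random-effects model.

    For n persons x k occasions under compound symmetry the ML
    estimates are mu = grand mean, sigma_W^2 = SSW / (n(k-1)) and
    sigma_B^2 = SSB/n - sigma_W^2/k with SSB the person-mean sum of
    squares (ML divisors, no Bessel correction).
    """
    n, k = values.shape
    mu = values.mean()
    person_means = values.mean(axis=1)
    ssw = ((values - person_means[:, None]) ** 2).sum()
    sigma_w2 = ssw / (n * (k - 1))
    sigma_b2 = ((person_means - mu) ** 2).sum() / n - sigma_w2 / k
    return mu, max(sigma_b2, 0.0), sigma_w2


class TestFimlLoglik:
    def test_single_standard_normal_observation(self):
        """One person, one observed cell at the mean, total variance 1:
        the density is the standard normal at 0."""
        d = Design(["a", "b"], [], {})
        frame = pd.DataFrame({"a": [5.0], "b": [np.nan]}, index=["p1"])
        theta = VarianceComponents(0.6, {}, 0.4, mu=5.0)
        ll = fiml_loglik(Dataset(frame), d, theta)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_complete_data_matches_dense_oracle(self, design4, theta4):
        data = simulate_dataset(SimulationSpec(design4, theta4, 40, seed=3))
        from iced import model_implied_covariance
        sigma = model_implied_covariance(design4, theta4)
        expected = dense_loglik(data.values, np.full(4, theta4.mu), sigma)
        assert fiml_loglik(data, design4, theta4) == pytest.approx(expected, rel=1e-10)

    def test_missing_data_matches_personwise_oracle(self, design4, theta4):
        """With missing cells, FIML equals a slow person-by-person loop
        over observed subvectors and submatrices."""
        spec = SimulationSpec(
            design4, theta4, 30, seed=9,
            missing_pattern=lambda rng, n, p: rng.random((n, p)) < 0.7)
        data = simulate_dataset(spec)
        from iced import model_implied_covariance
        sigma = model_implied_covariance(design4, theta4)
        mean = np.full(4, theta4.mu)
        expected = 0.0
        for _, row in data.values.iterrows():
            obs = row.notna().to_numpy()
            expected += stats.multivariate_normal.logpdf(
                row[obs], mean=mean[obs], cov=sigma[np.ix_(obs, obs)])
        assert fiml_loglik(data, design4, theta4) == pytest.approx(expected, rel=1e-10)

    def test_duplicating_persons_doubles_loglik(self, design4, theta4):
        data = simulate_dataset(SimulationSpec(design4, theta4, 25, seed=4))
        doubled = Dataset(pd.concat([
            data.values.rename(index=lambda s: "a" + s),
            data.values.rename(index=lambda s: "b" + s)]))
        assert fiml_loglik(doubled, design4, theta4) == pytest.approx(
            2 * fiml_loglik(data, design4, theta4), rel=1e-12)

    def test_empty_dataset_rejected(self, design4):
        with pytest.raises(ValueError, match="empty"):
            Dataset(pd.DataFrame(columns=list(design4.occasions)))


class TestFit:
    def test_balanced_compound_symmetry_matches_closed_form(self):
        """No facets, complete balanced data: the FIML optimum must agree
        with the analytic one-way ML solution."""
        d = Design([f"t{i}" for i in range(4)], [], {})
        theta = VarianceComponents(2.0, {}, 1.0, mu=5.0)
        data = simulate_dataset(SimulationSpec(d, theta, 80, seed=12))
        fit = ICEDModel(data, d).fit(restarts=2, seed=0, compute_se=False)
        mu, b2, w2 = oneway_ml(data.values.to_numpy())
        assert fit.converged
        assert fit.params["mu"] == pytest.approx(mu, abs=1e-5)
        assert fit.params["sigma_T2"] == pytest.approx(b2, rel=1e-4)
        assert fit.params["sigma_E2"] == pytest.approx(w2, rel=1e-4)

    def test_no_between_person_differences_hits_zero_bound(self):
        d = Design([f"t{i}" for i in range(3)], [], {})
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(10.0 + rng.normal(0, 1, size=(300, 3)),
                             index=[f"p{i}" for i in range(300)],
                             columns=list(d.occasions))
        fit = ICEDModel(Dataset(frame), d).fit(restarts=2, seed=1,
                                               compute_se=False)
        assert fit.params["sigma_T2"] < 0.05
        # with zero shared variance in truth the estimate often sits on
        # the bound; when it does, it must be flagged
        if fit.params["sigma_T2"] <= 1e-8:
            assert "sigma_T2" in fit.boundary_flags

    def test_fit_is_invariant_to_person_order(self, design4, small_dataset):
        shuffled = Dataset(small_dataset.values.sample(frac=1, random_state=8))
        fit_a = ICEDModel(small_dataset, design4).fit(restarts=1, seed=0)
        fit_b = ICEDModel(shuffled, design4).fit(restarts=1, seed=0)
        for name in fit_a.params:
            assert fit_a.params[name] == fit_b.params[name]  # bitwise

    def test_two_persons_minimum(self, design4):
        frame = pd.DataFrame([[1.0, 2, 3, 4]], index=["p1"],
                             columns=list(design4.occasions))
        with pytest.raises(ValueError, match="at least 2 persons"):
            ICEDModel(Dataset(frame), design4).fit()


class TestWald:
    def test_statistic_is_squared_z_on_chi2_1(self, design4, small_dataset):
        fit = ICEDModel(small_dataset, design4).fit(restarts=1, seed=0)
        fit.params["session"] = 2.0
        fit.se["session"] = 1.0
        fit.boundary_flags = frozenset()
        res = fit.wald_test("session")
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-6)
        assert res.p_value == pytest.approx(0.0455, abs=5e-4)

    def test_boundary_estimate_warns_and_returns_p_one(self, design4, small_dataset):
        fit = ICEDModel(small_dataset, design4).fit(restarts=1, seed=0)
        fit.params["day"] = 0.0
        fit.boundary_flags = frozenset({"day"})
        with pytest.warns(UserWarning, match="zero bound"):
            res = fit.wald_test("day")
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestLRT:
    def test_null_component_gives_small_statistic(self, design4):
        """When the tested component is truly (and estimated) ~0, the
        restricted fit nearly coincides with the full fit."""
        theta = VarianceComponents(4.0, {"day": 1.0, "session": 0.0}, 1.0, mu=10)
        data = simulate_dataset(SimulationSpec(design4, theta, 300, seed=30))
        fit = ICEDModel(data, design4).fit(restarts=1, seed=0, compute_se=False)
        res = fit.lrt("session", restarts=1, seed=0)
        assert res.statistic >= 0.0
        assert res.statistic < 4.0
        assert res.kind == "LRT" and res.df == 1

    def test_full_loglik_dominates_restricted(self, design4, small_dataset):
        fit = ICEDModel(small_dataset, design4).fit(restarts=2, seed=0,
                                                    compute_se=False)
        for comp in ("day", "session", "true_score"):
            res = fit.lrt(comp, restarts=2, seed=0)
            assert res.statistic >= 0.0

    def test_residual_cannot_be_dropped(self, design4, small_dataset):
        fit = ICEDModel(small_dataset, design4).fit(restarts=1, seed=0)
        with pytest.raises(ValueError, match="wald_test"):
            fit.lrt("residual")

    def test_mixture_reference_halves_p(self, design4, small_dataset):
        fit = ICEDModel(small_dataset, design4).fit(restarts=1, seed=0,
                                                    compute_se=False)
        plain = fit.lrt("day", restarts=1, seed=0)
        mixed = fit.lrt("day", mixture=True, restarts=1, seed=0)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)

    def test_equality_constraint_near_nominal_when_true(self, design4):
        """H0: session and residual variances equal (true here) — the
        1-df equality LRT should reject at ~nominal rate."""
        theta = VarianceComponents(4.0, {"day": 0.5, "session": 1.0}, 1.0, mu=10)
        rng = np.random.default_rng(77)
        rejections = 0
        n_reps = 40
        for _ in range(n_reps):
            s = int(rng.integers(0, 2**31 - 1))
            data = simulate_dataset(SimulationSpec(design4, theta, 150, seed=s))
            fit = ICEDModel(data, design4).fit(restarts=1, seed=s,
                                               compute_se=False)
            res = fit.lrt_equal("session", "residual", restarts=1, seed=s)
            rejections += res.p_value < 0.10
        # nominal 10%; allow wide MC band for 40 replicates
        assert rejections / n_reps <= 0.25

    def test_session_lrt_has_power(self, design4):
        """A real session effect (sigma_S2 = 1 at n=300) should be
        detected essentially always."""
        theta = VarianceComponents(4.0, {"day": 1.0, "session": 1.0}, 1.0, mu=10)
        data = simulate_dataset(SimulationSpec(design4, theta, 300, seed=2))
        fit = ICEDModel(data, design4).fit(restarts=1, seed=0, compute_se=False)
        res = fit.lrt("session", restarts=1, seed=0)
        assert res.p_value < 0.01


class TestMultigroup:
    def test_unconstrained_joint_equals_sum_of_separate_fits(self, design4, theta4):
        d1 = simulate_dataset(SimulationSpec(design4, theta4, 100, seed=1))
        d2 = simulate_dataset(SimulationSpec(design4, theta4, 100, seed=2))
        joint = MultigroupICEDModel([d1, d2], design4).fit(restarts=2, seed=0)
        f1 = ICEDModel(d1, design4).fit(restarts=2, seed=0, compute_se=False)
        f2 = ICEDModel(d2, design4).fit(restarts=2, seed=0, compute_se=False)
        assert joint.df_model == f1.df_model + f2.df_model
        assert joint.loglik == pytest.approx(f1.loglik + f2.loglik, abs=1e-4)

    def test_fully_constrained_matches_pooled_single_group(self, design4, theta4):
        d1 = simulate_dataset(SimulationSpec(design4, theta4, 80, seed=5))
        d2 = simulate_dataset(SimulationSpec(design4, theta4, 80, seed=6))
        cons = MultigroupICEDModel([d1, d2], design4).fit(
            equal=["mu", "true_score", "day", "session", "residual"],
            restarts=2, seed=0)
        pooled = Dataset(pd.concat([
            d1.values.rename(index=lambda s: "a" + s),
            d2.values.rename(index=lambda s: "b" + s)]))
        single = ICEDModel(pooled, design4).fit(restarts=2, seed=0,
                                                compute_se=False)
        assert cons.loglik == pytest.approx(single.loglik, abs=1e-4)
        for name in single.params:
            assert cons.group_results[0].params[name] == pytest.approx(
                single.params[name], abs=1e-4)

    def test_unknown_constraint_rejected(self, design4, theta4):
        d1 = simulate_dataset(SimulationSpec(design4, theta4, 30, seed=1))
        d2 = simulate_dataset(SimulationSpec(design4, theta4, 30, seed=2))
        with pytest.raises(KeyError):
            MultigroupICEDModel([d1, d2], design4).fit(equal=["scanner"])

    def test_interaction_lrt_identical_groups_near_zero(self, design4, theta4):
        data = simulate_dataset(SimulationSpec(design4, theta4, 150, seed=9))
        m = MultigroupICEDModel([data, data], design4)
        free = m.fit(restarts=2, seed=0)
        cons = m.fit(equal=["session"], restarts=2, seed=0)
        res = interaction_lrt(free, cons)
        assert res.statistic == pytest.approx(0.0, abs=1e-3)
        assert res.df == 1

    def test_interaction_lrt_detects_mirrored_session_difference(self):
        """Mirrored designs (sessions 2+1 vs 1+2 across days) with a 4:1
        session-variance ratio: the cross-group equality LRT rejects."""
        d_a = two_day_design()
        d_b = Design(("scan1", "scan2", "scan3", "scan4"), ("day", "session"), {
            "day": {"scan1": "d1", "scan2": "d1", "scan3": "d2", "scan4": "d2"},
            "session": {"scan1": "s1", "scan2": "s2", "scan3": "s3", "scan4": "s3"},
        })
        th_a = VarianceComponents(4.0, {"day": 1.0, "session": 2.0}, 1.0, mu=10)
        th_b = VarianceComponents(4.0, {"day": 1.0, "session": 0.5}, 1.0, mu=10)
        da = simulate_dataset(SimulationSpec(d_a, th_a, 400, seed=21))
        db = simulate_dataset(SimulationSpec(d_b, th_b, 400, seed=22))
        m = MultigroupICEDModel([da, db], [d_a, d_b])
        free = m.fit(restarts=1, seed=0)
        cons = m.fit(equal=["session"], restarts=1, seed=0)
        res = interaction_lrt(free, cons)
        assert res.p_value < 0.01

    def test_non_nested_inputs_rejected(self, design4, theta4):
        d1 = simulate_dataset(SimulationSpec(design4, theta4, 50, seed=1))
        d2 = simulate_dataset(SimulationSpec(design4, theta4, 50, seed=2))
        m = MultigroupICEDModel([d1, d2], design4)
        free = m.fit(restarts=1, seed=0)
        with pytest.raises(ValueError, match="not nested"):
            interaction_lrt(free, free)


class TestStandardize:
    def test_worked_example_shares(self, design3, mwf_theta):
        data = simulate_dataset(SimulationSpec(design3, mwf_theta, 50, seed=1))
        fit = ICEDModel(data, design3).fit(restarts=1, seed=0, compute_se=False)
        # shares are a pure function of the components; check on the
        # known parameter point rather than the noisy estimate
        from iced import standardized_shares
        shares = standardized_shares(mwf_theta)
        assert round(100 * shares["sigma_T2"]) == 86
        assert round(100 * shares["sigma_E2"]) == 6
        assert sum(shares.values()) == pytest.approx(1.0)
        assert set(standardize(fit)) == set(shares)

    def test_equal_components_get_equal_shares(self):
        theta = VarianceComponents(1.0, {"day": 1.0, "session": 1.0}, 1.0)
        from iced import standardized_shares
        shares = standardized_shares(theta)
        assert all(v == pytest.approx(0.25) for v in shares.values())
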