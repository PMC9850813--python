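"""BYM Poisson spatial model: likelihood, sampler correctness, recovery."""

import numpy as np
import pandas as pd
import pytest

import naspatial as ns
from naspatial.exceptions import InputError, ParameterError


class TestPoissonLoglik:
    @pytest.mark.parametrize(
        "y, e, eta, expected",
        [
            ([0], [1.0], [0.0], -1.0),  # -E * e^0
            ([1], [1.0], [0.0], -1.0),  # log(1 * e^-1)
        ],
    )
    def test_closed_form_values(self, y, e, eta, expected):
        assert ns.poisson_loglik(y, e, eta) == pytest.approx(expected)

    def test_zero_count_limit_as_eta_decreases(self):
        assert ns.poisson_loglik([0], [1.0], [-40.0]) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("bad_y", [[-1], [1.5]])
    def test_invalid_counts(self, bad_y):
        with pytest.raises(InputError):
            ns.poisson_loglik(bad_y, [1.0], [0.0])

    def test_nonpositive_expected(self):
        with pytest.raises(InputError):
            ns.poisson_loglik([1], [0.0], [0.0])


class TestLinearPredictor:
    def test_all_zero_parameters(self):
        data = pd.DataFrame({"exposure": [1.0, 2.0]})
        np.testing.assert_array_equal(
            ns.linear_predictor({"beta0": 0.0, "beta_x": 0.0}, data), [0.0, 0.0]
        )

    def test_single_covariate(self):
        data = pd.DataFrame({"z_a": [3.0, 3.0]})
        np.testing.assert_allclose(
            ns.linear_predictor({"gamma_z_a": 2.0}, data), [6.0, 6.0]
        )

    def test_consistency_with_poisson_loglik(self):
        data = pd.DataFrame({"exposure": [0.5, 1.5], "z_a": [1.0, -1.0]})
        draw = {"beta0": 0.1, "beta_x": -0.2, "gamma_z_a": 0.3,
                "theta": np.array([0.05, -0.05])}
        eta = ns.linear_predictor(draw, data)
        e = np.array([2.0, 3.0])
        direct = float(
            np.sum([y * (np.log(ei) + et) - ei * np.exp(et) for y, ei, et in
                    zip([1, 2], e, eta)])
        ) - np.sum(np.log([1.0, 2.0]))
        assert ns.poisson_loglik([1, 2], e, eta) == pytest.approx(direct)


def _flat_data(n, rng, e=5.0):
    x = rng.normal(size=n)
    return pd.DataFrame(
        {
            "area_id": [f"a{i}" for i in range(n)],
            "y_late": rng.poisson(e, n),
            "expected": np.full(n, e),
            "exposure": x,
        }
    )


class TestFitBym:
    def test_determinism(self, small_study):
        spec = ns.BymSpec(iterations=150, burn_in=50, seed=7)
        a = ns.fit_bym(small_study.areas, small_study.graph, spec)
        b = ns.fit_bym(small_study.areas, small_study.graph, spec)
        pd.testing.assert_frame_equal(a.params, b.params)
        np.testing.assert_array_equal(a.random_effects["phi"], b.random_effects["phi"])

    def test_structured_effect_sums_to_zero_each_iteration(self, small_study):
        spec = ns.BymSpec(iterations=120, burn_in=20, seed=3)
        draws = ns.fit_bym(small_study.areas, small_study.graph, spec)
        phi = draws.random_effects["phi"]
        labels = small_study.graph.component_labels
        for c in np.unique(labels):
            np.testing.assert_allclose(phi[:, labels == c].sum(axis=1), 0.0, atol=1e-10)

    def test_acceptance_rates_recorded_per_block(self, small_study):
        spec = ns.BymSpec(iterations=200, burn_in=50, seed=5)
        draws = ns.fit_bym(small_study.areas, small_study.graph, spec)
        assert {"beta", "theta", "phi"} <= set(draws.acceptance)
        for rate in draws.acceptance.values():
            assert 0.0 < rate < 1.0

    def test_gaussian_hook_matches_conjugate_posterior(self):
        """With Gaussian likelihood and no random effects the beta draws must
        match the closed-form Normal-Normal conjugate posterior."""
        rng = np.random.default_rng(10)
        n, sigma, prior_sd = 30, 0.7, 2.0
        data = _flat_data(n, rng)
        data["y_late"] = np.log(data["expected"]) + rng.normal(0.1, sigma, n)
        graph = ns.build_graph(
            [(f"a{i}", f"a{i+1}") for i in range(n - 1)], list(data["area_id"])
        )
        spec = ns.BymSpec(
            iterations=4000, burn_in=500, seed=1, likelihood="gaussian",
            gaussian_sigma=sigma, coef_prior_sd=prior_sd,
            include_structured=False, include_unstructured=False,
        )
        draws = ns.fit_bym(data, graph, spec)
        A = np.column_stack([np.ones(n), data["exposure"]])
        prec = A.T @ A / sigma**2 + np.eye(2) / prior_sd**2
        cov = np.linalg.inv(prec)
        mean = cov @ (A.T @ (data["y_late"] - np.log(data["expected"])) / sigma**2)
        sampled = draws.params[["beta0", "beta_x"]].to_numpy()
        mcse = sampled.std(axis=0) / np.sqrt(len(sampled))
        np.testing.assert_array_less(np.abs(sampled.mean(axis=0) - mean), 3.5 * mcse)
        np.testing.assert_allclose(sampled.std(axis=0), np.sqrt(np.diag(cov)), rtol=0.1)

    def test_forward_backward_moment_matching(self):
        """Marginal-conditional check of the Poisson kernel: pooling posterior
        draws over data replicates simulated from the prior must reproduce
        the prior moments of beta_x."""
        rng = np.random.default_rng(20)
        n, n_rep = 20, 40
        prior_sd = 0.3
        a0, b0 = 3.0, 0.5  # inverse-gamma(3, 0.5) on sigma_theta^2
        x = rng.normal(size=n)
        e = np.full(n, 5.0)
        ids = [f"a{i}" for i in range(n)]
        graph = ns.build_graph([(ids[i], ids[i + 1]) for i in range(n - 1)], ids)
        rep_means = []
        rep_second = []
        for r in range(n_rep):
            beta = rng.normal(0.0, prior_sd, 2)
            sigma2 = 1.0 / rng.gamma(a0, 1.0 / b0)
            theta = rng.normal(0.0, np.sqrt(sigma2), n)
            y = rng.poisson(e * np.exp(beta[0] + beta[1] * x + theta))
            data = pd.DataFrame(
                {"area_id": ids, "y_late": y, "expected": e, "exposure": x}
            )
            spec = ns.BymSpec(
                iterations=700, burn_in=200, seed=1000 + r,
                coef_prior_sd=prior_sd, variance_prior_shape=a0,
                variance_prior_rate=b0, include_structured=False,
                save_random_effects=False,
            )
            bx = ns.fit_bym(data, graph, spec).get("beta_x")
            rep_means.append(bx.mean())
            rep_second.append(np.mean(bx**2))
        rep_means = np.asarray(rep_means)
        rep_second = np.asarray(rep_second)
        se_mean = rep_means.std(ddof=1) / np.sqrt(n_rep)
        se_second = rep_second.std(ddof=1) / np.sqrt(n_rep)
        assert abs(rep_means.mean() - 0.0) < 3 * se_mean
        assert abs(rep_second.mean() - prior_sd**2) < 3 * se_second

    def test_posterior_contraction_with_sample_size(self):
        sds = {}
        for n in (100, 200):
            cfg = ns.GeneratorConfig(n_areas=n, confounder_delta=0.0, confounder_sd=0.05)
            study = ns.generate_study(cfg, seed=5)
            spec = ns.BymSpec(iterations=1500, burn_in=300, seed=2,
                              save_random_effects=False)
            sds[n] = ns.fit_bym(study.areas, study.graph, spec).get("beta_x").std()
        assert sds[200] < sds[100]

    def test_mismatched_ordering_is_error(self, small_study):
        shuffled = small_study.areas.iloc[::-1].reset_index(drop=True)
        with pytest.raises(InputError, match="ordering"):
            ns.fit_bym(shuffled, small_study.graph, ns.BymSpec(iterations=10, burn_in=1))

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            ns.BymSpec(iterations=100, burn_in=100).validate()
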