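import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import invgamma

import gazemix as gm
from gazemix import GibbsConfig, Hyperparams, ModelParams
from gazemix.inference import (
    SaccadeData,
    b_conditional,
    gamma_probabilities,
    hmc_transition,
    run_gibbs,
    s_o_conditional,
    sample_rho_fixed,
)
from gazemix.polya import sample_pg


def quadratic_fit_moments(logp, points):
    """Independent completion-of-squares oracle: the log of a Gaussian
    density is an exact quadratic, so fitting one through three points
    recovers the mean and variance without any algebra shared with the
    implementation."""
    pts = np.asarray(points, dtype=float)
    vals = np.array([logp(p) for p in pts])
    coeffs = np.polyfit(pts, vals, 2)  # alpha b^2 + beta b + c
    alpha, beta = coeffs[0], coeffs[1]
    var = -1.0 / (2.0 * alpha)
    mean = beta * var
    return mean, np.sqrt(var)


class TestGammaConditional:
    def test_endpoints(self, rng):
        assert gamma_probabilities(1.0, [0.3], [0.5])[0] == 1.0
        assert gamma_probabilities(0.0, [0.3], [0.5])[0] == 0.0

    def test_zero_weight_component(self, rng):
        assert gamma_probabilities(0.5, [0.0], [0.2])[0] == 0.0
        assert gamma_probabilities(0.5, [0.2], [0.0])[0] == 1.0

    def test_bayes_toy(self):
        # rho=0.5, p_local=0.02, p_global=0.01 -> P(gamma=1) = 2/3
        assert gamma_probabilities(0.5, [0.02], [0.01])[0] == pytest.approx(2.0 / 3.0)

    def test_both_components_zero_raises(self):
        with pytest.raises(ValueError, match="inconsistent"):
            gamma_probabilities(0.5, [0.0], [0.0])


class TestLinkConditionals:
    def test_b_prior_when_no_saccades(self):
        h = Hyperparams(mu_b=1.5, sigma_b=2.0)
        mean, sd = b_conditional([], [], [], h)
        assert mean == pytest.approx(1.5) and sd == pytest.approx(2.0)

    def test_b_concentrates_at_prior_mean_for_tiny_sigma(self):
        h = Hyperparams(mu_b=-0.7, sigma_b=1e-6)
        mean, sd = b_conditional([2.0], [1], [0.3], h)
        assert mean == pytest.approx(-0.7, abs=1e-9)
        assert sd < 2e-6

    def test_b_single_saccade_matches_quadratic_oracle(self):
        h = Hyperparams(mu_b=0.4, sigma_b=2.5)
        x, gamma, w = 1.7, 1, 0.36

        def logp(b):
            f = b * x
            return (
                -0.5 * ((b - h.mu_b) / h.sigma_b) ** 2
                + (gamma - 0.5) * f
                - 0.5 * w * f**2
            )

        mean_o, sd_o = quadratic_fit_moments(logp, [-1.0, 0.0, 1.0])
        mean, sd = b_conditional([x], [gamma], [w], h)
        assert mean == pytest.approx(mean_o, abs=1e-10)
        assert sd == pytest.approx(sd_o, abs=1e-10)

    def test_s_o_prior_when_slope_zero(self):
        h = Hyperparams(mu_so=2.2, sigma_so=0.8)
        mean, sd = s_o_conditional([1.0, 3.0], [1, 0], [0.2, 0.4], 0.0, h)
        assert mean == pytest.approx(2.2) and sd == pytest.approx(0.8)

    def test_s_o_single_saccade_matches_quadratic_oracle(self):
        h = Hyperparams(mu_so=0.9, sigma_so=3.0)
        r, gamma, w, b = 2.4, 0, 0.5, 1.3

        def logp(so):
            f = b * (r - so)
            return (
                -0.5 * ((so - h.mu_so) / h.sigma_so) ** 2
                + (gamma - 0.5) * f
                - 0.5 * w * f**2
            )

        mean_o, sd_o = quadratic_fit_moments(logp, [-1.0, 0.0, 1.0])
        mean, sd = s_o_conditional([r], [gamma], [w], b, h)
        assert mean == pytest.approx(mean_o, abs=1e-10)
        assert sd == pytest.approx(sd_o, abs=1e-10)

    def test_s_o_symmetric_toy_prior_weighted(self):
        # ratios symmetric about s_o with balanced tags and equal w: the
        # likelihood contribution to the mean collapses onto b^2 w mean(r)
        h = Hyperparams(mu_so=1.0, sigma_so=2.0)
        r = [0.5, 1.5]
        mean, _ = s_o_conditional(r, [1, 0], [0.3, 0.3], 2.0, h)
        prec = 1 / 4.0 + 4.0 * 0.6
        expected = (1.0 / 4.0 + 4.0 * 0.3 * 2.0) / prec
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_gibbs_b_marginal_matches_grid_posterior(self):
        """Two-block Gibbs over (w, b) on a one-saccade toy reproduces the
        exact marginal p(b) obtained by numerically normalizing
        prior x logistic likelihood (the PG identity marginalizes w)."""
        h = Hyperparams(mu_b=0.0, sigma_b=2.0)
        x, gamma = 1.5, 1
        rng = np.random.default_rng(77)
        n = 60_000
        draws = np.empty(n)
        b = 0.0
        for i in range(n):
            w = sample_pg(np.array([b * x]), rng)[0]
            mean, sd = b_conditional([x], [gamma], [w], h)
            b = rng.normal(mean, sd)
            draws[i] = b
        grid = np.linspace(-8, 8, 4001)
        dens = np.exp(-0.5 * (grid / 2.0) ** 2) * expit(grid * x)
        dens /= np.trapezoid(dens, grid)
        edges = np.linspace(-8, 8, 33)
        p_hat, _ = np.histogram(draws[2000:], bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p_exact = np.interp(centers, grid, dens)
        width = edges[1] - edges[0]
        tv = 0.5 * np.sum(np.abs(p_hat - p_exact)) * width
        assert tv < 0.02


class TestRhoFixedConditional:
    def test_prior_draw_without_data(self, rng):
        h = Hyperparams(beta_a=3.0, beta_b=7.0)
        draws = [sample_rho_fixed([], h, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(0.3, abs=0.02)

    def test_posterior_beta_moments(self, rng):
        h = Hyperparams(beta_a=1.0, beta_b=1.0)
        gamma = [1] * 7 + [0] * 3
        draws = [sample_rho_fixed(gamma, h, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(8.0 / 12.0, abs=0.02)

    def test_all_local_large_n_tends_to_one(self, rng):
        h = Hyperparams()
        draws = [sample_rho_fixed([1] * 5000, h, rng) for _ in range(100)]
        assert min(draws) > 0.995


class TestHMC:
    @staticmethod
    def _gauss_target(u):
        return -0.5 * float(u @ u), -u

    def test_tiny_step_always_accepts(self, rng):
        u = np.array([0.3, -0.5])
        n_acc = 0
        for _ in range(50):
            _, acc, aprob, _, _ = hmc_transition(
                self_target := self._gauss_target, u, 1e-5, 3, rng
            )
            n_acc += acc
            assert aprob > 0.999999
        assert n_acc == 50

    def test_preserves_gaussian_target(self, rng):
        u = np.zeros(2)
        draws = []
        for i in range(4000):
            u, _, _, _, _ = hmc_transition(self._gauss_target, u, 0.5, 8, rng)
            draws.append(u.copy())
        draws = np.asarray(draws[500:])
        assert abs(draws.mean()) < 0.08
        assert draws.var() == pytest.approx(1.0, abs=0.1)

    def test_zero_density_start_raises(self, rng):
        def target(u):
            return -np.inf, None

        with pytest.raises(ValueError):
            hmc_transition(target, np.zeros(1), 0.1, 2, rng)


class TestMarginalizationIdentity:
    def test_augmented_factors_marginalize_to_mixture(self, small_map, rng):
        """Summing the gamma-augmented factor over gamma in {0, 1} gives
        exactly the mixture step probability."""
        p = ModelParams(eps_x=3.0, eps_y=4.0, xi_x=50.0, xi_y=60.0, b=1.2, s_o=0.8)
        for _ in range(25):
            z_prev = tuple(rng.integers(2, 22, 2))
            z_prev2 = tuple(rng.integers(2, 22, 2))
            z_t = tuple(rng.integers(0, 24, 2))
            sb = gm.step_probability(z_t, z_prev, z_prev2, p, small_map)
            marg = sb.rho * sb.p_local + (1.0 - sb.rho) * sb.p_global
            assert sb.prob == pytest.approx(marg, abs=1e-15)


@pytest.fixture(scope="module")
def tiny_fit_dataset():
    truth = ModelParams(eps_x=9.0, eps_y=9.0, xi_x=250.0, xi_y=250.0, b=2.5, s_o=1.0)
    return truth, gm.synthetic_dataset(
        truth, n_subjects=1, n_images=8, n_fix=14, shape=(32, 32), n_modes=2,
        seed=42, px_per_degree=2.0,
    )


class TestRunGibbs:
    def test_local_saliency_updates_only_xi(self, tiny_fit_dataset):
        _, ds = tiny_fit_dataset
        cfg = GibbsConfig(n_iter=60, n_burn=20, n_chains=1, hmc_steps=3, seed=0)
        post = run_gibbs(ds.table, ds.saliency_maps, "local_saliency", None, cfg)
        assert set(post.param_names) == {"xi_x", "xi_y"}

    def test_constraint_preserved_in_every_draw(self, tiny_fit_dataset):
        _, ds = tiny_fit_dataset
        cfg = GibbsConfig(n_iter=80, n_burn=20, n_chains=2, hmc_steps=3, seed=1)
        with pytest.warns(RuntimeWarning):
            post = run_gibbs(ds.table, ds.saliency_maps, "full", None, cfg)
        assert np.all(post.draws["xi_x"] > post.draws["eps_x"])
        assert np.all(post.draws["xi_y"] > post.draws["eps_y"])
        assert np.all(post.draws["eps_x"] > 0)

    def test_fixed_choice_gate_recovered(self):
        truth = ModelParams(
            eps_x=4.0, eps_y=4.0, xi_x=120.0, xi_y=120.0,
            variant="fixed_choice", rho_fixed=0.7,
        )
        ds = gm.synthetic_dataset(
            truth, n_subjects=1, n_images=10, n_fix=15, shape=(32, 32),
            n_modes=2, seed=7,
        )
        cfg = GibbsConfig(n_iter=250, n_burn=100, n_chains=2, hmc_steps=5, seed=3)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = run_gibbs(ds.table, ds.saliency_maps, "fixed_choice", None, cfg)
        lo, hi = post.credible_interval(0.95)["rho_fixed"]
        assert lo < 0.7 < hi

    def test_saliency_baseline_has_nothing_to_infer(self, tiny_fit_dataset):
        _, ds = tiny_fit_dataset
        with pytest.raises(ValueError, match="no parameters to infer"):
            run_gibbs(ds.table, ds.saliency_maps, "saliency_baseline")

    def test_posterior_samples_roundtrip(self, tiny_fit_dataset):
        _, ds = tiny_fit_dataset
        cfg = GibbsConfig(n_iter=60, n_burn=20, n_chains=2, hmc_steps=3, seed=5)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = run_gibbs(ds.table, ds.saliency_maps, "full", None, cfg)
        df = post.to_dataframe()
        assert {"chain", "iteration", "log_posterior"} <= set(df.columns)
        assert len(df) == 2 * 40
        summ = post.summary()
        assert set(summ["parameter"]) == set(post.param_names)
        mp = post.mean_params()
        assert mp.xi_x > mp.eps_x and mp.xi_y > mp.eps_y


class TestConjugateLimit:
    def test_all_local_eps_posterior_matches_inverse_gamma(self):
        """With every saccade tagged local on a large uniform map, the
        scale target reduces to a conjugate Inverse-Gamma posterior for
        eps; a short HMC run must land on its closed form (posterior-mean
        check here; the full Q-Q agreement runs in the acceptance suite)."""
        from gazemix.inference import _GibbsEngine

        rng = np.random.default_rng(0)
        h, w_ = 64, 64
        sal = gm.SaliencyMap(np.full((h, w_), 1.0 / (h * w_)))
        truth_eps = 9.0
        rows = []
        for trial in range(10):
            x = [32.0, 32.0]
            y = [32.0, 32.0]
            for t in range(19):
                x.append(np.clip(x[-1] + rng.normal(0, 3.0), 0, 63))
                y.append(np.clip(y[-1] + rng.normal(0, 3.0), 0, 63))
            for i, (xi_, yi_) in enumerate(zip(x, y), start=1):
                rows.append(("s", 0, trial + 1, i, xi_, yi_))
        import pandas as pd

        table = pd.DataFrame(
            rows, columns=["subject_id", "image_id", "trial_id", "fixation_index", "x", "y"]
        )
        data = SaccadeData(table, {0: sal}, "full")
        hyper = Hyperparams(alpha_eps=2.0, beta_eps=25.0, alpha_xi=2.0, beta_xi=2500.0)
        eng = _GibbsEngine(data, "full", hyper, GibbsConfig())
        gamma = np.ones(data.n, dtype=int)
        target = eng._scale_target(gamma)
        u = np.log([9.0, 9.0, 2500.0, 2500.0])
        draws = []
        step = 0.08
        for i in range(3000):
            u, _, _, _, _ = hmc_transition(target, u, step, 5, rng)
            draws.append(np.exp(u[0]))
        draws = np.asarray(draws[500:])
        n = data.n
        a_post = 2.0 + n / 2.0
        b_post = 25.0 + float((data.dx**2).sum()) / 2.0
        expected_mean = b_post / (a_post - 1.0)
        assert draws.mean() == pytest.approx(expected_mean, rel=0.05)


def test_prior_only_chain_empty_dataset():
    """run_gibbs with no data draws b and s_o from their exact priors."""
    cfg = GibbsConfig(n_iter=600, n_burn=100, n_chains=1, hmc_steps=5, seed=9)
    hyper = Hyperparams(mu_b=1.0, sigma_b=2.0, mu_so=-0.5, sigma_so=1.5)
    post = run_gibbs(None, {}, "full", hyper, cfg)
    b = post.draws["b"].ravel()
    so = post.draws["s_o"].ravel()
    assert b.mean() == pytest.approx(1.0, abs=4 * 2.0 / np.sqrt(len(b)))
    assert so.std() == pytest.approx(1.5, rel=0.15)
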