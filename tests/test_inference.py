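"""Model density, sampler, fit contracts, diagnostics and LOO."""

import warnings

import numpy as np
import pytest

from sliderirt.design import make_design, ResponseTable
from sliderirt.inference import (
    McmcConfig,
    ModelConfig,
    SliderModel,
    compute_loo,
    diagnose,
    fit_model,
)
from sliderirt.inference.nuts import NutsConfig, sample_nuts
from sliderirt.simulate import draw_true_params, simulate_study


class TestGradient:
    def test_matches_finite_differences(self, tiny_study, rng):
        _, _, table = tiny_study
        model = SliderModel(table, "strict")
        vec = model.initial_value(rng)
        _, g = model.logp_grad(vec)
        eps = 1e-6
        idx = rng.choice(model.n_params, 50, replace=False)
        for name in ("mu_free", "log_sigma_free", "y_chol"):
            s = model.slices[name]
            idx = np.concatenate([idx, np.arange(s.start, min(s.stop, s.start + 5))])
        for i in np.unique(idx):
            v1, v2 = vec.copy(), vec.copy()
            v1[i] += eps
            v2[i] -= eps
            fd = (model.logp(v1) - model.logp(v2)) / (2 * eps)
            assert abs(fd - g[i]) / max(1.0, abs(fd)) < 1e-5

    def test_configural_gradient(self, tiny_study, rng):
        _, _, table = tiny_study
        model = SliderModel(table, "configural")
        vec = model.initial_value(rng)
        _, g = model.logp_grad(vec)
        eps = 1e-6
        for i in rng.choice(model.n_params, 30, replace=False):
            v1, v2 = vec.copy(), vec.copy()
            v1[i] += eps
            v2[i] -= eps
            fd = (model.logp(v1) - model.logp(v2)) / (2 * eps)
            assert abs(fd - g[i]) / max(1.0, abs(fd)) < 1e-5

    def test_numba_and_numpy_paths_agree(self, tiny_study, rng):
        _, _, table = tiny_study
        fast = SliderModel(table, "strict", use_numba=True)
        slow = SliderModel(table, "strict", use_numba=False)
        if not fast._use_numba:
            pytest.skip("numba unavailable")
        for _ in range(5):
            vec = fast.initial_value(rng)
            lp1, g1 = fast.logp_grad(vec)
            lp2, g2 = slow.logp_grad(vec)
            assert lp1 == pytest.approx(lp2, rel=1e-10, abs=1e-7)
            np.testing.assert_allclose(g1, g2, rtol=1e-8, atol=1e-7)

    def test_nonfinite_region_flagged(self, tiny_study):
        _, _, table = tiny_study
        model = SliderModel(table, "strict")
        vec = np.full(model.n_params, 80.0)  # saturates links / overflows tau
        lp, g = model.logp_grad(vec)
        assert lp == -np.inf
        assert np.all(g == 0)


class TestModelStructure:
    def test_strict_one_parameter_set_per_item(self, tiny_study):
        design, _, table = tiny_study
        model = SliderModel(table, "strict")
        n_items = len(design.all_item_ids)
        # every item appears in both formats across persons
        assert len(model.brm_alpha_keys) == n_items
        assert len(model.ddrm_tau_keys) == n_items
        assert all(not isinstance(k, tuple) for k in model.brm_alpha_keys)

    def test_configural_doubles_groups(self, tiny_study):
        _, _, table = tiny_study
        strict = SliderModel(table, "strict")
        conf = SliderModel(table, "configural")
        assert len(conf.brm_alpha_keys) == 2 * len(strict.brm_alpha_keys)
        assert len(conf.ddrm_delta_keys) == 2 * len(strict.ddrm_delta_keys)

    def test_metric_shares_only_alpha(self, tiny_study):
        _, _, table = tiny_study
        m = SliderModel(table, "metric")
        assert all(not isinstance(k, tuple) for k in m.brm_alpha_keys)
        assert all(isinstance(k, tuple) for k in m.brm_delta_keys)
        assert all(isinstance(k, tuple) for k in m.brm_tau_keys)

    def test_missing_occasion_names_person(self, tiny_study):
        _, _, table = tiny_study
        df = table.df
        drop = (df["person_id"] == "P003") & (df["occasion"] == 2)
        with pytest.raises(ValueError, match="P003"):
            SliderModel(table.subset(~drop))

    def test_single_person_rejected(self, tiny_study):
        _, _, table = tiny_study
        sub = table.subset(table.df["person_id"] == "P001")
        with pytest.raises(ValueError, match="two persons"):
            SliderModel(sub)

    def test_pointwise_loglik_bookkeeping(self, tiny_study, rng):
        _, _, table = tiny_study
        model = SliderModel(table, "strict")
        ll = model.pointwise_loglik(model.initial_value(rng))
        assert ll.shape == (len(table),)
        assert np.all(np.isfinite(ll))


class TestNuts:
    def test_standard_normal_moments(self):
        def lg(q):
            return -0.5 * float(q @ q), -q

        cfg = NutsConfig(warmup=300, draws=800, target_accept=0.9)
        draws, stats = sample_nuts(lg, np.zeros(3), cfg, np.random.default_rng(0))
        assert abs(draws.mean()) < 0.1
        assert abs(draws.std() - 1.0) < 0.1
        assert stats["diverging"].sum() == 0

    def test_scaled_gaussian_via_metric(self):
        scales = np.array([0.01, 1.0, 100.0])

        def lg(q):
            return -0.5 * float(np.sum((q / scales) ** 2)), -q / scales**2

        cfg = NutsConfig(warmup=400, draws=600, target_accept=0.9)
        draws, _ = sample_nuts(lg, np.zeros(3), cfg, np.random.default_rng(1))
        assert np.allclose(draws.std(axis=0) / scales, 1.0, atol=0.15)

    def test_determinism(self):
        def lg(q):
            return -0.5 * float(q @ q), -q

        cfg = NutsConfig(warmup=100, draws=100)
        a, _ = sample_nuts(lg, np.zeros(2), cfg, np.random.default_rng(5))
        b, _ = sample_nuts(lg, np.zeros(2), cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestFitContracts:
    def test_identification_constraints_exact(self, small_fit):
        _, _, draws = small_fit
        # first-occasion means exactly 0 and SDs exactly 1 in every draw
        first = [i for i, l in enumerate(draws.dim_labels) if l.endswith("_1")]
        assert np.all(draws.mu[..., first] == 0.0)
        assert np.all(draws.sigma[..., first] == 1.0)

    def test_correlation_draws_valid(self, small_fit):
        _, _, draws = small_fit
        C = draws.corr
        assert np.allclose(C, np.swapaxes(C, -1, -2))
        assert np.allclose(C[..., range(C.shape[-1]), range(C.shape[-1])], 1.0)
        flat = C.reshape(-1, C.shape[-1], C.shape[-1])
        for M in flat[:: max(1, len(flat) // 20)]:
            assert np.linalg.eigvalsh(M).min() > -1e-10

    def test_loglik_count_matches_records(self, small_fit):
        table, _, draws = small_fit
        assert draws.log_lik.shape[-1] == len(table)

    def test_strict_item_draws_shared(self, small_fit):
        _, _, draws = small_fit
        assert all(not isinstance(k, tuple) for k in draws.item_keys["brm_alpha"])

    def test_determinism_same_seed(self, tiny_study):
        _, _, table = tiny_study
        cfg = ModelConfig(mcmc=McmcConfig(chains=2, warmup=50, draws=30, seed=3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_model(table, cfg, store_loglik=False, check_convergence=False)
            b = fit_model(table, cfg, store_loglik=False, check_convergence=False)
        np.testing.assert_array_equal(a.corr, b.corr)
        np.testing.assert_array_equal(a.person, b.person)


class TestDiagnose:
    @staticmethod
    def _fake_draws(chains):
        from sliderirt.inference.fit import PosteriorDraws
        import pandas as pd

        C, S = chains.shape[0], chains.shape[1]
        d = 2
        return PosteriorDraws(
            person=chains[..., None, None] * np.ones((C, S, 1, d)),
            corr=np.tile(np.eye(d), (C, S, 1, 1)),
            mu=np.zeros((C, S, d)),
            sigma=np.ones((C, S, d)),
            items={}, item_keys={}, dim_labels=["a_1", "b_1"],
            person_ids=["P1"], sample_stats={}, record_meta=pd.DataFrame(),
            invariance_level="strict",
        )

    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 10_000))
        diag = diagnose(self._fake_draws(chains))
        assert 0.999 <= diag.rhat_max < 1.01
        assert diag.ess_bulk_min >= 400
        assert diag.passed

    def test_non_mixing_chains_fail(self):
        chains = np.stack([np.zeros(500), np.ones(500)])
        chains += np.random.default_rng(1).normal(0, 1e-3, chains.shape)
        diag = diagnose(self._fake_draws(chains))
        assert diag.rhat_max > 1.5
        assert not diag.passed

    def test_chain_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 1000))
        a = diagnose(self._fake_draws(chains))
        b = diagnose(self._fake_draws(chains[::-1]))
        assert a.rhat_max == pytest.approx(b.rhat_max)
        assert a.ess_bulk_min == pytest.approx(b.ess_bulk_min)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            diagnose(self._fake_draws(np.zeros((1, 100))))


class TestLoo:
    def test_degenerate_posterior(self):
        # all draws identical: elpd_loo equals the summed log-likelihood
        ll = np.tile(np.array([-1.2, -0.7, -2.0]), (2, 100, 1))
        res = compute_loo(ll)
        assert res.elpd_loo == pytest.approx(ll[0, 0].sum(), abs=1e-6)
        assert res.p_loo == pytest.approx(0.0, abs=1e-6)

    def test_penalization_direction(self, rng):
        # elpd_loo never exceeds the in-sample log predictive density
        ll = rng.normal(-1.0, 0.4, size=(2, 400, 20))
        res = compute_loo(ll)
        from scipy.special import logsumexp

        lpd = np.sum(
            logsumexp(ll.reshape(-1, 20), axis=0) - np.log(ll.shape[0] * ll.shape[1])
        )
        assert res.elpd_loo <= lpd + 1e-9

    def test_conjugate_normal_exact_loo_oracle(self, rng):
        # Normal(mu, 1) with Normal(0, 1) prior on mu: exact LOO predictive
        # density available in closed form via posterior-predictive algebra.
        y = rng.normal(0.7, 1.0, size=6)
        S = 4000

        def posterior(data):
            n = len(data)
            var = 1.0 / (n + 1.0)
            return var * data.sum(), var

        exact = []
        for i in range(len(y)):
            rest = np.delete(y, i)
            m, v = posterior(rest)
            # predictive: Normal(m, v + 1)
            from scipy.stats import norm

            exact.append(norm.logpdf(y[i], m, np.sqrt(v + 1.0)))
        m, v = posterior(y)
        mus = rng.normal(m, np.sqrt(v), size=(2, S))
        from scipy.stats import norm

        ll = norm.logpdf(y[None, None, :], mus[..., None], 1.0)
        res = compute_loo(ll)
        assert res.elpd_loo == pytest.approx(np.sum(exact), abs=3 * res.se)

    def test_missing_loglik_errors(self, tiny_study):
        _, _, table = tiny_study
        cfg = ModelConfig(mcmc=McmcConfig(chains=2, warmup=30, draws=20, seed=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_model(table, cfg, store_loglik=False, check_convergence=False)
        with pytest.raises(ValueError):
            compute_loo(draws)
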