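"""Variational conv layers: concrete gates, local reparameterization, KL."""

import numpy as np
import pytest
from scipy import integrate, stats

import spikeseg as ss
from spikeseg.layers import (
    FilterGeometry, LayerPosterior, conv3d, softplus_inv,
)


def _posterior(mu, sigma, geom=None, c_in=1, f=1, bias=None):
    """Build a LayerPosterior with explicit mu/sigma arrays."""
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    f = mu.shape[-1]
    return LayerPosterior(
        p_logit=np.zeros(f),
        mu=mu,
        rho=softplus_inv(np.maximum(sigma, 1e-12)) if (sigma > 0).all()
        else np.full_like(mu, -1e3),
        bias=np.zeros(f) if bias is None else np.asarray(bias, dtype=float),
    )


class TestSampleConcrete:
    def test_symmetry_at_half(self):
        assert ss.sample_concrete(0.5, ss.ConcreteSpec(), u=0.5) == pytest.approx(0.5)

    def test_saturation_at_low_temperature(self):
        val = ss.sample_concrete(0.9, ss.ConcreteSpec(0.02), u=0.5)
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_mean_converges_to_p(self):
        rng = np.random.default_rng(0)
        p = 0.7
        draws = ss.sample_concrete(np.full(100_000, p), ss.ConcreteSpec(0.02),
                                   u=rng.random(100_000))
        assert np.mean(draws) == pytest.approx(p, abs=0.01)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_gate_exceedance_matches_bernoulli(self, p):
        """At t = 0.02 the gates behave as Bernoulli(p): the fraction > 0.5
        matches p within 3 binomial standard errors over 1e5 draws."""
        n = 100_000
        rng = np.random.default_rng(42)
        draws = ss.sample_concrete(np.full(n, p), ss.ConcreteSpec(0.02),
                                   u=rng.random(n))
        frac = np.mean(draws > 0.5)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se
        assert abs(np.mean(draws) - p) <= 3 * se + 0.01

    def test_endpoint_u_clamped_not_nan(self):
        out = ss.sample_concrete(np.array([0.5, 0.5]), ss.ConcreteSpec(0.02),
                                 u=np.array([0.0, 1.0]))
        assert np.isfinite(out).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.sample_concrete(0.0, ss.ConcreteSpec(), u=0.5)


class TestFFGDilatedConv:
    def test_zero_variance_unit_gate_equals_deterministic_conv(self):
        rng = np.random.default_rng(1)
        h = rng.standard_normal((7, 7, 7, 2))
        mu = rng.standard_normal((3, 3, 3, 2, 4))
        post = _posterior(mu, np.full_like(mu, 1e-9))
        geom = FilterGeometry(1, 1, 1, 1)
        noise = rng.standard_normal((7, 7, 7, 4))
        out = ss.ffg_dilated_conv(h, post, geom, noise=noise)
        det = conv3d(h[None], mu, 1)[0]
        assert np.allclose(out, det, atol=1e-4)

    def test_one_hot_input_reduces_to_centre_tap(self):
        h = np.zeros((5, 5, 5, 1))
        h[2, 2, 2, 0] = 1.0
        rng = np.random.default_rng(2)
        mu = rng.standard_normal((3, 3, 3, 1, 1))
        sigma = rng.random((3, 3, 3, 1, 1)) + 0.1
        post = _posterior(mu, sigma)
        geom = FilterGeometry(1, 1, 1, 1)
        m, v = ss.ffg_moments(h, post, geom)
        assert m[2, 2, 2, 0] == pytest.approx(mu[1, 1, 1, 0, 0])
        assert v[2, 2, 2, 0] == pytest.approx(sigma[1, 1, 1, 0, 0] ** 2)

    def test_moments_match_explicit_weight_sampling(self):
        """Central local-reparameterization contract: the analytic
        pre-activation moments equal those of brute-force sampling of the
        factorized Gaussian weights (1e5 draws, 4 SE tolerance)."""
        rng = np.random.default_rng(3)
        h = rng.standard_normal((5, 5, 5, 1))
        mu = rng.standard_normal((3, 3, 3, 1, 1))
        sigma = rng.random((3, 3, 3, 1, 1)) * 0.5 + 0.05
        post = _posterior(mu, sigma)
        geom = FilterGeometry(1, 1, 1, 1)
        m_star, v_star = ss.ffg_moments(h, post, geom)

        n_draws = 100_000
        w = (mu.ravel()[None, :]
             + sigma.ravel()[None, :] * rng.standard_normal((n_draws, 27)))
        # explicit convolution at a few voxels via patch extraction
        hp = np.pad(h[..., 0], 1)
        for vox in [(2, 2, 2), (0, 0, 0), (4, 1, 3)]:
            i, j, k = vox
            patch = hp[i:i + 3, j:j + 3, k:k + 3].ravel()
            samples = w @ patch
            se_mean = samples.std() / np.sqrt(n_draws)
            assert abs(samples.mean() - m_star[vox + (0,)]) < 4 * se_mean
            var = samples.var()
            se_var = var * np.sqrt(2.0 / (n_draws - 1))
            assert abs(var - v_star[vox + (0,)]) < 4 * se_var

    def test_dilated_moments_match_sampling(self):
        """Same contract with dilation 2 (taps two voxels apart)."""
        rng = np.random.default_rng(4)
        h = rng.standard_normal((5, 5, 5, 1))
        mu = rng.standard_normal((3, 3, 3, 1, 1))
        sigma = rng.random((3, 3, 3, 1, 1)) * 0.3 + 0.05
        post = _posterior(mu, sigma)
        geom = FilterGeometry(1, 1, 1, 2)
        m_star, v_star = ss.ffg_moments(h, post, geom)
        n_draws = 100_000
        w = (mu.ravel()[None, :]
             + sigma.ravel()[None, :] * rng.standard_normal((n_draws, 27)))
        hp = np.pad(h[..., 0], 2)
        i, j, k = 2, 2, 2
        patch = hp[i:i + 5:2, j:j + 5:2, k:k + 5:2].ravel()
        samples = w @ patch
        assert abs(samples.mean() - m_star[2, 2, 2, 0]) \
            < 4 * samples.std() / np.sqrt(n_draws)
        var = samples.var()
        assert abs(var - v_star[2, 2, 2, 0]) < 4 * var * np.sqrt(2 / (n_draws - 1))

    def test_gates_scale_output(self):
        rng = np.random.default_rng(5)
        h = rng.standard_normal((4, 4, 4, 1))
        mu = rng.standard_normal((1, 1, 1, 1, 2))
        post = _posterior(mu, np.full_like(mu, 1e-9))
        geom = FilterGeometry(0, 0, 0, 1)
        full = ss.ffg_dilated_conv(h, post, geom)
        gated = ss.ffg_dilated_conv(h, post, geom, gates=np.array([0.5, 1.0]))
        assert np.allclose(gated[..., 0], 0.5 * full[..., 0], atol=1e-5)
        assert np.allclose(gated[..., 1], full[..., 1], atol=1e-6)


class TestBernoulliDropoutConv:
    def test_keep_prob_one_is_deterministic_conv(self):
        rng = np.random.default_rng(6)
        h = rng.standard_normal((6, 6, 6, 2))
        w = rng.standard_normal((3, 3, 3, 2, 3))
        geom = FilterGeometry(1, 1, 1, 1)
        out = ss.bernoulli_dropout_conv(h, w, 1.0, geom, rng=rng)
        det = conv3d(h[None].astype(np.float64), w, 1)[0]
        assert np.allclose(out, det, atol=1e-5)

    def test_mask_expectation_scales_output(self):
        """Mean over many masked passes approximates keep_prob times the
        deterministic output (no inverted-dropout rescaling)."""
        rng = np.random.default_rng(7)
        h = np.abs(rng.standard_normal((4, 4, 4, 1))) + 0.5
        w = np.abs(rng.standard_normal((3, 3, 3, 1, 1))) + 0.2
        geom = FilterGeometry(1, 1, 1, 1)
        det = conv3d(h[None].astype(np.float64), w, 1)[0]
        keep = 0.8
        acc = np.zeros_like(det)
        n = 10_000
        for _ in range(n):
            acc += ss.bernoulli_dropout_conv(h, w, keep, geom, rng=rng)
        acc /= n
        interior = (slice(1, 3),) * 3
        assert np.allclose(acc[interior], keep * det[interior], rtol=0.05)

    def test_default_keep_prob_is_09(self):
        assert ss.ArchitectureSpec().keep_prob == 0.9

    def test_keep_prob_zero_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.bernoulli_dropout_conv(np.zeros((3, 3, 3, 1)),
                                      np.zeros((1, 1, 1, 1, 1)), 0.0,
                                      FilterGeometry(0, 0, 0, 1))


class TestKL:
    def test_bernoulli_zero_at_prior(self):
        assert ss.kl_bernoulli(0.5, 0.5) == pytest.approx(0.0)

    @pytest.mark.parametrize("p,expected", [(0.9, 0.3680642), (0.25, 0.1308123)])
    def test_bernoulli_known_values(self, p, expected):
        # oracle: explicit two-outcome sum q log(q/p)
        oracle = (p * np.log(p / 0.5) + (1 - p) * np.log((1 - p) / 0.5))
        assert ss.kl_bernoulli(p, 0.5) == pytest.approx(oracle, abs=1e-12)
        assert ss.kl_bernoulli(p, 0.5) == pytest.approx(expected, abs=1e-6)

    def test_bernoulli_open_interval_enforced(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ss.ValidationError):
                ss.kl_bernoulli(bad, 0.5)
            with pytest.raises(ss.ValidationError):
                ss.kl_bernoulli(0.5, bad)

    def test_gaussian_zero_at_prior(self):
        assert ss.kl_gaussian(0.0, 0.1) == pytest.approx(0.0)

    @pytest.mark.parametrize("mu,sigma,expected", [
        (1.0, 0.1, 50.0),
        (0.0, 0.2, 0.8068528),
    ])
    def test_gaussian_known_values(self, mu, sigma, expected):
        assert ss.kl_gaussian(mu, sigma) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("mu,sigma", [(0.3, 0.05), (-0.7, 0.25), (1.2, 0.4)])
    def test_gaussian_matches_numerical_integration(self, mu, sigma):
        """KL(q||p) cross-checked by quadrature of q log(q/p)."""
        prior = ss.PriorSpec()
        q = stats.norm(mu, sigma)
        p = stats.norm(prior.mu_prior, prior.sigma_prior)
        val, _ = integrate.quad(
            lambda x: q.pdf(x) * (q.logpdf(x) - p.logpdf(x)),
            mu - 12 * sigma, mu + 12 * sigma, limit=200)
        assert ss.kl_gaussian(mu, sigma, prior) == pytest.approx(val, abs=1e-6)

    def test_gaussian_nonpositive_sigma_rejected(self):
        with pytest.raises(ss.ValidationError):
            ss.kl_gaussian(0.0, 0.0)

    def test_kl_nonnegative_on_grid(self):
        mus = np.linspace(-2, 2, 9)
        sigmas = np.linspace(0.02, 1.0, 9)
        grid = ss.kl_gaussian(mus[:, None], sigmas[None, :])
        assert (grid >= -1e-12).all()
        ps = np.linspace(0.05, 0.95, 19)
        assert (ss.kl_bernoulli(ps, 0.5) >= -1e-12).all()


class TestLayerKL:
    def test_zero_when_posterior_equals_prior(self):
        prior = ss.PriorSpec()
        mu = np.zeros((3, 3, 3, 1, 2))
        post = _posterior(mu, np.full_like(mu, prior.sigma_prior))
        post.p_logit[:] = 0.0  # p = 0.5 = prior
        assert ss.layer_kl(post, prior) == pytest.approx(0.0, abs=1e-9)

    def test_single_filter_single_tap_value(self):
        """1 filter, 1 tap, (p=0.9, mu=1, sigma=0.1) vs default prior:
        0.36806... + 50.0."""
        from spikeseg.layers import logit
        mu = np.full((1, 1, 1, 1, 1), 1.0)
        post = _posterior(mu, np.full_like(mu, 0.1))
        post.p_logit[:] = logit(0.9)
        total = ss.layer_kl(post, ss.PriorSpec())
        assert total == pytest.approx(50.0 + 0.3680642, abs=1e-4)

    def test_additive_over_filters(self):
        from spikeseg.layers import logit
        mu1 = np.full((1, 1, 1, 1, 1), 0.4)
        one = _posterior(mu1, np.full_like(mu1, 0.2))
        one.p_logit[:] = logit(0.8)
        mu2 = np.concatenate([mu1, mu1], axis=-1)
        two = _posterior(mu2, np.full_like(mu2, 0.2))
        two.p_logit[:] = logit(0.8)
        assert ss.layer_kl(two) == pytest.approx(2 * ss.layer_kl(one), rel=1e-10)


class TestMapPenalty:
    def test_zero_weights(self):
        assert ss.map_penalty(np.zeros(10)) == 0.0

    def test_single_weight(self):
        assert ss.map_penalty(np.array([2.0])) == pytest.approx(2.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(8)
        w = rng.standard_normal(20)
        assert ss.map_penalty(3.0 * w) == pytest.approx(9.0 * ss.map_penalty(w))


class TestLayerGradients:
    """Finite-difference validation of the hand-derived backward passes.

    Biases are moved off zero first: with ReLU-dead patches the
    pre-activation otherwise sits exactly at the ReLU kink (z ~ +-1e-6)
    where finite differences are invalid.
    """

    @pytest.mark.parametrize("variant", ["map", "bd", "ssd"])
    def test_full_network_gradients(self, variant):
        from spikeseg.training import _nll_and_grad

        arch = ss.ArchitectureSpec(
            n_filters=2, n_classes=2, variant=variant, dtype="float64",
            layer_table=(ss.LayerSpec(3, 1), ss.LayerSpec(3, 2),
                         ss.LayerSpec(1, 1, relu=False)))
        net = ss.build_model(arch, seed=3)
        rngb = np.random.default_rng(11)
        for lay in net.layers:
            lay.params["b"][:] = rngb.uniform(0.2, 0.5, lay.params["b"].shape)
        rng0 = np.random.default_rng(0)
        x = rng0.standard_normal((2, 5, 5, 5, 1))
        y = rng0.integers(0, 2, (2, 5, 5, 5))

        def loss_fn(seed=7, scale=3.0):
            s = net.forward(x, rng=np.random.default_rng(seed), sample=True)
            nll, d = _nll_and_grad(s, y, scale)
            return scale * float(nll.sum()) + net.regularizer(), d

        net.zero_grads()
        _, d = loss_fn()
        net.backward(d)
        net.add_regularizer_grads(1.0)
        grads = {k: v.copy() for k, v in net.gradients().items()}
        rng_pick = np.random.default_rng(5)
        for k, p in net.parameters().items():
            flat = p.ravel()
            for _ in range(min(4, flat.size)):
                i = rng_pick.integers(0, flat.size)
                h = 1e-6 * max(1.0, abs(flat[i]))
                old = flat[i]
                flat[i] = old + h
                lp, _ = loss_fn()
                flat[i] = old - h
                lm, _ = loss_fn()
                flat[i] = old
                fd = (lp - lm) / (2 * h)
                an = grads[k].ravel()[i]
                rel = abs(fd - an) / max(abs(fd), abs(an), 1e-8)
                assert rel < 1e-4, f"{k}[{i}]: fd={fd}, analytic={an}"

    def test_ssd_input_gradient(self):
        from spikeseg.layers import SpikeSlabConvLayer

        geom = FilterGeometry(1, 1, 1, 1)
        lay = SpikeSlabConvLayer(geom, 2, 2, relu=False,
                                 rng=np.random.default_rng(0), dtype=np.float64)
        x = np.random.default_rng(1).standard_normal((1, 4, 4, 4, 2))

        def run(xx):
            return lay.forward(xx, rng=np.random.default_rng(7), sample=True)

        y0 = run(x)
        lay.zero_grads()
        dx = lay.backward(np.ones_like(y0))
        rng = np.random.default_rng(2)
        for _ in range(6):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (run(xp).sum() - run(xm).sum()) / (2 * h)
            assert abs(fd - dx[idx]) / max(abs(fd), abs(dx[idx]), 1e-8) < 1e-5
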