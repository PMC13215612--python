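"""The flow oracle suite: exact invertibility and agreement of every analytic
log-determinant with a numerically assembled Jacobian, for each elementary
layer and for full compositions; actnorm initialization statistics; density
normalization and push-forward consistency."""

import numpy as np
import pytest
from scipy import stats

from helpers import numeric_jacobian
from pepflow.flow import (
    COUPLING_PATTERNS,
    ActNorm,
    AffineCoupling,
    MultiHeadInvertibleLinear,
    PriorFlow,
)
from pepflow.nn import Tensor, no_grad

D_MODEL, HEADS, FFN, MAXLEN = 8, 2, 2, 16


def make_x(rng, B=1, N=5):
    return Tensor(rng.standard_normal((B, N, D_MODEL))), np.ones((B, N), bool)


def full_mask(B, T):
    return np.ones((B, T), dtype=bool)


def make_flow(rng, d_z, n_steps, clamp=2.0):
    return PriorFlow(
        d_z, n_steps, n_heads_flow=2, d_model=D_MODEL, n_heads_attn=HEADS,
        ffn_mult=FFN, cond_layers=1, max_len=MAXLEN, rng=rng, clamp=clamp,
    )


def jacobian_logdet(fwd, z0):
    """log|det| of the numerically assembled Jacobian of a flat map."""
    J = numeric_jacobian(fwd, z0.ravel())
    sign, logdet = np.linalg.slogdet(J)
    assert sign != 0
    return logdet


class TestActNorm:
    def test_identity_when_unit_scale_zero_shift(self, rng):
        an = ActNorm(4)
        an.initialized = True
        z = Tensor(rng.standard_normal((1, 3, 4)))
        out, ld = an.forward(z, full_mask(1, 3))
        np.testing.assert_allclose(out.data, z.data)
        assert float(ld.data[0]) == pytest.approx(0.0, abs=1e-12)

    def test_scale_two_logdet_matches_brute_jacobian(self, rng):
        an = ActNorm(2)
        an.scale.data[:] = 2.0
        an.initialized = True
        T = 3
        z0 = rng.standard_normal((1, T, 2))

        def fwd(flat):
            out, _ = an.forward(Tensor(flat.reshape(1, T, 2)), full_mask(1, T))
            return out.data.ravel()

        _, ld = an.forward(Tensor(z0), full_mask(1, T))
        assert float(ld.data[0]) == pytest.approx(T * 2 * np.log(2), abs=1e-9)
        assert float(ld.data[0]) == pytest.approx(jacobian_logdet(fwd, z0), abs=1e-6)

    def test_data_dependent_init_normalizes_batch(self, rng):
        an = ActNorm(6)
        z = Tensor(rng.standard_normal((8, 10, 6)) * 3.0 + 1.5)
        out, _ = an.forward(z, full_mask(8, 10), training=True)
        assert an.initialized
        mean = out.data.mean(axis=(0, 1))
        var = out.data.var(axis=(0, 1))
        assert np.all(np.abs(mean) < 1e-3)
        assert np.all((var > 0.999) & (var < 1.001))

    def test_zero_scale_rejected(self, rng):
        an = ActNorm(2)
        an.scale.data[0] = 0.0
        an.initialized = True
        with pytest.raises(ValueError):
            an.forward(Tensor(rng.standard_normal((1, 2, 2))), full_mask(1, 2))


class TestMultiHeadLinear:
    def test_identity_weight_is_identity_map(self, rng):
        lin = MultiHeadInvertibleLinear(4, 1, rng)
        lin.weight.data[0] = np.eye(4)
        z = Tensor(rng.standard_normal((1, 3, 4)))
        out, ld = lin.forward(z, full_mask(1, 3))
        np.testing.assert_allclose(out.data, z.data)
        assert float(ld.data[0]) == pytest.approx(0.0, abs=1e-12)

    def test_single_head_equals_dense_layer(self, rng):
        d, T = 4, 3
        lin = MultiHeadInvertibleLinear(d, 1, rng)
        W = lin.weight.data[0]
        z0 = rng.standard_normal((1, T, d))
        out, ld = lin.forward(Tensor(z0), full_mask(1, T))
        np.testing.assert_allclose(out.data, z0 @ W, atol=1e-12)
        expected = T * np.linalg.slogdet(W)[1]
        assert float(ld.data[0]) == pytest.approx(expected, abs=1e-6)

    def test_orthogonal_heads_have_zero_logdet(self, rng):
        lin = MultiHeadInvertibleLinear(4, 2, rng)  # init is orthogonal
        z0 = rng.standard_normal((1, 5, 4))
        _, ld = lin.forward(Tensor(z0), full_mask(1, 5))
        assert float(ld.data[0]) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("scheme", ["contiguous", "strided"])
    def test_logdet_matches_brute_jacobian(self, scheme, rng):
        d, T = 4, 2
        lin = MultiHeadInvertibleLinear(d, 2, rng, scheme)
        lin.weight.data += 0.3 * rng.standard_normal(lin.weight.shape)
        z0 = rng.standard_normal((1, T, d))

        def fwd(flat):
            out, _ = lin.forward(Tensor(flat.reshape(1, T, d)), full_mask(1, T))
            return out.data.ravel()

        _, ld = lin.forward(Tensor(z0), full_mask(1, T))
        assert float(ld.data[0]) == pytest.approx(
            jacobian_logdet(fwd, z0), abs=1e-5
        )

    def test_inverse_roundtrip(self, rng):
        lin = MultiHeadInvertibleLinear(6, 3, rng, "strided")
        z = Tensor(rng.standard_normal((2, 4, 6)))
        out, _ = lin.forward(z, full_mask(2, 4))
        back = lin.inverse(out, full_mask(2, 4))
        np.testing.assert_allclose(back.data, z.data, atol=1e-10)

    def test_singular_head_rejected(self, rng):
        lin = MultiHeadInvertibleLinear(4, 2, rng)
        lin.weight.data[0] = 0.0
        with pytest.raises(ValueError):
            lin.forward(Tensor(rng.standard_normal((1, 2, 4))), full_mask(1, 2))


class TestAffineCoupling:
    def make_coupling(self, rng, pattern, swap=False, d_z=4):
        return AffineCoupling(
            d_z, pattern, swap, D_MODEL, HEADS, FFN, 1, MAXLEN, rng
        )

    @pytest.mark.parametrize("pattern", COUPLING_PATTERNS)
    def test_fresh_coupling_is_identity(self, pattern, rng):
        c = self.make_coupling(rng, pattern)
        x, xm = make_x(rng)
        z = Tensor(rng.standard_normal((1, 4, 4)))
        out, ld = c.forward(z, full_mask(1, 4), x, xm)
        np.testing.assert_allclose(out.data, z.data, atol=1e-12)
        np.testing.assert_allclose(ld.data, 0.0, atol=1e-12)

    @pytest.mark.parametrize("pattern", COUPLING_PATTERNS)
    @pytest.mark.parametrize("swap", [False, True])
    def test_untouched_partition_bitwise_unchanged(self, pattern, swap, rng):
        c = self.make_coupling(rng, pattern, swap)
        self._randomize(c, rng)
        x, xm = make_x(rng)
        T = 5
        z0 = rng.standard_normal((1, T, 4))
        out, _ = c.forward(Tensor(z0), full_mask(1, T), x, xm)
        if pattern == "time":
            a_idx, _ = c._time_split_idx(T)
            np.testing.assert_array_equal(out.data[:, a_idx, :], z0[:, a_idx, :])
        else:
            np.testing.assert_array_equal(
                out.data[..., c.feat_a], z0[..., c.feat_a]
            )

    @staticmethod
    def _randomize(c, rng):
        c.net.out_proj.weight.data = 0.5 * rng.standard_normal(
            c.net.out_proj.weight.shape
        )
        c.net.out_proj.bias.data = 0.3 * rng.standard_normal(
            c.net.out_proj.bias.shape
        )

    @pytest.mark.parametrize("pattern", COUPLING_PATTERNS)
    @pytest.mark.parametrize("swap", [False, True])
    def test_logdet_matches_brute_jacobian(self, pattern, swap, rng):
        c = self.make_coupling(rng, pattern, swap)
        self._randomize(c, rng)
        x, xm = make_x(rng)
        T, d = 4, 4
        z0 = rng.standard_normal((1, T, d))

        def fwd(flat):
            with no_grad():
                out, _ = c.forward(
                    Tensor(flat.reshape(1, T, d)), full_mask(1, T), x, xm
                )
            return out.data.ravel()

        _, ld = c.forward(Tensor(z0), full_mask(1, T), x, xm)
        assert float(ld.data[0]) == pytest.approx(
            jacobian_logdet(fwd, z0), abs=1e-4
        )

    @pytest.mark.parametrize("pattern", COUPLING_PATTERNS)
    def test_inverse_roundtrip(self, pattern, rng):
        c = self.make_coupling(rng, pattern)
        self._randomize(c, rng)
        x, xm = make_x(rng, B=2)
        z = Tensor(rng.standard_normal((2, 5, 4)))
        out, _ = c.forward(z, full_mask(2, 5), x, xm)
        back = c.inverse(out, full_mask(2, 5), x, xm)
        np.testing.assert_allclose(back.data, z.data, atol=1e-9)


class TestFullFlow:
    def _randomize(self, flow, rng):
        for step in flow.steps:
            step.actnorm.scale.data = rng.uniform(0.5, 1.5, step.actnorm.scale.shape)
            step.actnorm.shift.data = 0.3 * rng.standard_normal(
                step.actnorm.shift.shape
            )
            step.actnorm.initialized = True
            step.coupling.net.out_proj.weight.data = 0.4 * rng.standard_normal(
                step.coupling.net.out_proj.weight.shape
            )

    def test_roundtrip_many_random_parameterizations(self):
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            flow = make_flow(rng, d_z=4, n_steps=3)
            self._randomize(flow, rng)
            x, xm = make_x(rng)
            for _ in range(5):
                z = Tensor(rng.standard_normal((1, 4, 4)))
                u, _ = flow.forward(z, full_mask(1, 4), x, xm)
                back = flow.inverse(u, full_mask(1, 4), x, xm)
                worst = max(worst, np.abs(back.data - z.data).max())
        assert worst < 1e-5

    def test_zero_step_flow_is_standard_normal(self, rng):
        flow = make_flow(rng, d_z=3, n_steps=0)
        x, xm = make_x(rng)
        z = rng.standard_normal((2, 4, 3))
        lp = flow.log_prob(Tensor(z), full_mask(2, 4), x, xm)
        expected = stats.norm.logpdf(z).sum(axis=(1, 2))
        np.testing.assert_allclose(lp.data, expected, atol=1e-8)

    def test_composition_logdet_matches_brute_jacobian(self, rng):
        T, d = 3, 4
        flow = make_flow(rng, d_z=d, n_steps=2)
        self._randomize(flow, rng)
        x, xm = make_x(rng)
        z0 = rng.standard_normal((1, T, d))

        def fwd(flat):
            with no_grad():
                u, _ = flow.forward(
                    Tensor(flat.reshape(1, T, d)), full_mask(1, T), x, xm
                )
            return u.data.ravel()

        _, ld = flow.forward(Tensor(z0), full_mask(1, T), x, xm)
        assert float(ld.data[0]) == pytest.approx(
            jacobian_logdet(fwd, z0), abs=1e-4
        )

    def test_density_integrates_to_one_on_toy_grid(self, rng):
        """T=1, d_z=2: numerically integrate exp(log p(z|x)) over a grid."""
        flow = make_flow(rng, d_z=2, n_steps=2, clamp=1.0)
        self._randomize(flow, rng)
        x, xm = make_x(rng)
        lim, n = 14.0, 281
        grid = np.linspace(-lim, lim, n)
        h = grid[1] - grid[0]
        za, zb = np.meshgrid(grid, grid, indexing="ij")
        pts = np.stack([za.ravel(), zb.ravel()], axis=1)[:, None, :]  # (n^2,1,2)
        with no_grad():
            xx = Tensor(np.repeat(x.data, pts.shape[0], axis=0))
            xxm = np.repeat(xm, pts.shape[0], axis=0)
            lp = flow.log_prob(
                Tensor(pts), full_mask(pts.shape[0], 1), xx, xxm
            )
        integral = np.exp(lp.data).sum() * h * h
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_pushforward_of_samples_matches_base(self, rng):
        """forward(sample()) must reproduce the base distribution."""
        flow = make_flow(rng, d_z=2, n_steps=3)
        self._randomize(flow, rng)
        x, xm = make_x(rng, B=1)
        B = 2500  # scalar draws: B * T * d_z = 10^4
        token_mask = full_mask(B, 2)
        xx = Tensor(np.repeat(x.data, B, axis=0))
        xxm = np.repeat(xm, B, axis=0)
        z = flow.sample(xx, xxm, token_mask, np.random.default_rng(0))
        with no_grad():
            u, _ = flow.forward(z, token_mask, xx, xxm)
        ks = stats.kstest(u.data.ravel(), "norm")
        assert ks.pvalue > 0.01

    def test_same_seed_same_sample(self, rng):
        flow = make_flow(rng, d_z=4, n_steps=2)
        x, xm = make_x(rng)
        tm = full_mask(1, 5)
        z1 = flow.sample(x, xm, tm, np.random.default_rng(7))
        z2 = flow.sample(x, xm, tm, np.random.default_rng(7))
        np.testing.assert_array_equal(z1.data, z2.data)

    def test_noise_scale_zero_limit_collapses_to_mode(self, rng):
        flow = make_flow(rng, d_z=4, n_steps=1)
        x, xm = make_x(rng)
        tm = full_mask(1, 3)
        z1 = flow.sample(x, xm, tm, np.random.default_rng(0), noise_scale=1e-9)
        z2 = flow.sample(x, xm, tm, np.random.default_rng(1), noise_scale=1e-9)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-7)

    def test_unknown_family_rejected(self, rng):
        flow = make_flow(rng, d_z=2, n_steps=1)
        x, xm = make_x(rng)
        with pytest.raises(ValueError):
            flow.sample(x, xm, full_mask(1, 2), rng, family="cauchy")

    def test_uniform_family_bounded_support(self, rng):
        flow = make_flow(rng, d_z=2, n_steps=0)
        x, xm = make_x(rng)
        z = flow.sample(
            x, xm, full_mask(1, 8), np.random.default_rng(0),
            noise_scale=0.5, family="uniform",
        )
        assert np.all(np.abs(z.data) <= np.sqrt(3) * 0.5 + 1e-12)
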