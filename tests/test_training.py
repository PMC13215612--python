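"""ELBO assembly: closed-form KL agreement, uniform-decoder reconstruction,
optimization smoke test, exact resume, and the IWAE lower-bound property."""

import numpy as np
import pytest

from pepflow import (
    AminoAcidVocabulary,
    ModelConfig,
    PepFlowModel,
    SimulationConfig,
    preprocess,
    simulate_dataset,
)
from pepflow.encoder import SpectrumBatch
from pepflow.model import make_target_batch
from pepflow.nn import no_grad
from pepflow.posterior import PosteriorNetwork, sample_diagonal_gaussian
from pepflow.training import Trainer, TrainingConfig, elbo_step


@pytest.fixture(scope="module")
def flowless_model(vocab):
    """Tiny model whose prior is the standard normal (0 flow steps)."""
    cfg = ModelConfig(
        d_model=16, d_z=4, n_enc_layers=1, n_post_layers=1, n_dec_layers=1,
        n_heads=2, ffn_mult=2, n_flow_steps=0, n_flow_heads=1, n_cond_layers=1,
    )
    return PepFlowModel(cfg, vocab, np.random.default_rng(3))


@pytest.fixture(scope="module")
def small_batch():
    return [
        preprocess(sp)
        for sp in simulate_dataset(SimulationConfig(n_peptides=8, seed=9))
    ]


def closed_form_gaussian_kl(mu, sigma):
    """KL(N(mu, sigma^2) || N(0, 1)), summed."""
    return 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma))


class TestKlAgainstClosedForm:
    def test_single_sample_estimate_unbiased(self, flowless_model, small_batch):
        """With a standard-normal prior the Monte-Carlo KL estimate must agree
        with the analytic Gaussian KL within 3 standard errors."""
        model = flowless_model
        sb = SpectrumBatch(small_batch)
        tb = make_target_batch([s.annotation for s in small_batch], model.vocab)
        with no_grad():
            x, xm = model.encode_spectra(sb)
            mu, sigma = model.posterior(tb.token_ids, tb.token_mask, x, xm)
            m = tb.token_mask[..., None]
            analytic = 0.5 * np.sum(
                (mu.data**2 + sigma.data**2 - 1.0 - 2.0 * np.log(sigma.data)) * m
            )
            rng = np.random.default_rng(0)
            n = 3000
            estimates = np.empty(n)
            for i in range(n):
                z = sample_diagonal_gaussian(mu, sigma, rng)
                logq = PosteriorNetwork.log_q(z, mu, sigma, tb.token_mask)
                logp = model.flow.log_prob(z, tb.token_mask, x, xm)
                estimates[i] = float((logq.data - logp.data).sum())
        se = estimates.std(ddof=1) / np.sqrt(n)
        assert abs(estimates.mean() - analytic) < 3 * se


class TestReconstruction:
    def test_uniform_decoder_gives_log_inverse_vocab(self, flowless_model, small_batch):
        model = flowless_model
        model.decoder.vocab_proj.weight.data[:] = 0.0
        model.decoder.vocab_proj.bias.data[:] = 0.0
        bd = elbo_step(model, small_batch, np.random.default_rng(0), training=False)
        V = len(model.vocab)
        T = 24  # minimum model length; all sampled peptides are shorter
        assert bd.reconstruction == pytest.approx(T * np.log(1.0 / V), abs=1e-9)


class TestOptimization:
    def test_loss_halves_within_200_steps(self):
        vocab = AminoAcidVocabulary.default()
        cfg = ModelConfig(
            d_model=32, d_z=8, n_enc_layers=1, n_post_layers=1,
            n_dec_layers=1, n_heads=2, ffn_mult=2, n_flow_steps=2,
            n_flow_heads=2, n_cond_layers=1,
        )
        model = PepFlowModel(cfg, vocab, np.random.default_rng(0))
        spectra = [
            preprocess(sp)
            for sp in simulate_dataset(SimulationConfig(n_peptides=50, seed=3))
        ]
        trainer = Trainer(model, TrainingConfig(batch_size=25, seed=0), total_steps=200)
        order = np.random.default_rng(1)
        first = last = None
        for _ in range(200):
            idx = order.choice(50, 25, replace=False)
            bd = trainer.train_step([spectra[i] for i in idx])
            first = first if first is not None else bd.total
            last = bd.total
        assert last < 0.5 * first

    def test_joint_update_of_length_head_and_decoder(self, small_batch, vocab):
        cfg = ModelConfig(
            d_model=16, d_z=4, n_enc_layers=1, n_post_layers=1, n_dec_layers=1,
            n_heads=2, ffn_mult=2, n_flow_steps=1, n_flow_heads=1, n_cond_layers=1,
        )
        model = PepFlowModel(cfg, vocab, np.random.default_rng(0))
        before_len = model.length_head.proj.weight.data.copy()
        before_dec = model.decoder.vocab_proj.weight.data.copy()
        trainer = Trainer(model, TrainingConfig(), total_steps=10)
        trainer.train_step(small_batch)
        assert np.any(model.length_head.proj.weight.data != before_len)
        assert np.any(model.decoder.vocab_proj.weight.data != before_dec)

    def test_non_finite_loss_aborts(self, small_batch, vocab):
        cfg = ModelConfig(
            d_model=16, d_z=4, n_enc_layers=1, n_post_layers=1, n_dec_layers=1,
            n_heads=2, ffn_mult=2, n_flow_steps=0, n_flow_heads=1, n_cond_layers=1,
        )
        model = PepFlowModel(cfg, vocab, np.random.default_rng(0))
        model.decoder.vocab_proj.bias.data[0] = np.nan
        trainer = Trainer(model, TrainingConfig(), total_steps=10)
        with pytest.raises(FloatingPointError):
            trainer.train_step(small_batch)

    def test_unannotated_batch_rejected(self, small_batch, vocab, tiny_config):
        model = PepFlowModel(tiny_config, vocab, np.random.default_rng(0))
        stripped = [sp.copy(annotation=None) for sp in small_batch]
        with pytest.raises(ValueError):
            elbo_step(model, stripped, np.random.default_rng(0))


class TestResume:
    def test_resume_reproduces_next_step_loss(self, tmp_path, small_batch, vocab):
        cfg = ModelConfig(
            d_model=16, d_z=4, n_enc_layers=1, n_post_layers=1, n_dec_layers=1,
            n_heads=2, ffn_mult=2, n_flow_steps=1, n_flow_heads=1, n_cond_layers=1,
        )

        def fresh():
            model = PepFlowModel(cfg, vocab, np.random.default_rng(5))
            return Trainer(model, TrainingConfig(seed=3), total_steps=20)

        uninterrupted = fresh()
        for _ in range(5):
            uninterrupted.train_step(small_batch)
        reference = uninterrupted.train_step(small_batch).total

        resumed = fresh()
        for _ in range(5):
            resumed.train_step(small_batch)
        ckpt = tmp_path / "mid.npz"
        resumed.save(ckpt)
        restored = Trainer.resume(ckpt)
        assert restored.step_count == 5
        assert restored.train_step(small_batch).total == pytest.approx(
            reference, abs=1e-4
        )


class TestIwaeBound:
    def test_elbo_below_importance_weighted_estimate(self, memorized):
        """E_q[log p(y|z,x)] - KL must lower-bound the 64-sample IWAE
        log-likelihood estimate on a trained model."""
        model, spectra = memorized
        batch = spectra[:4]
        sb = SpectrumBatch(batch)
        tb = make_target_batch([s.annotation for s in batch], model.vocab)
        rng = np.random.default_rng(0)
        with no_grad():
            x, xm = model.encode_spectra(sb)
            mu, sigma = model.posterior(tb.token_ids, tb.token_mask, x, xm)
            B, T = tb.token_ids.shape
            sel = (np.arange(B)[:, None], np.arange(T)[None, :], tb.token_ids)
            elbo_terms, iwae_terms = [], []
            log_ws = []
            for _ in range(64):
                z = sample_diagonal_gaussian(mu, sigma, rng)
                logq = PosteriorNetwork.log_q(z, mu, sigma, tb.token_mask).data
                logp = model.flow.log_prob(z, tb.token_mask, x, xm).data
                logits = model.decode_logits(z, tb.token_mask, x, xm, sb).data
                recon = (logits[sel] * tb.token_mask).sum(axis=-1)
                log_ws.append(recon + logp - logq)
            log_ws = np.stack(log_ws)  # (64, B)
        elbo = log_ws.mean(axis=0)
        iwae = np.log(np.exp(log_ws - log_ws.max(0)).mean(axis=0)) + log_ws.max(0)
        assert np.all(elbo <= iwae + 1e-9)
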