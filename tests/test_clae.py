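"""Encoder behaviour, penalty formulas, training, metrics, PCA, ablation."""

import dataclasses

import numpy as np
import pytest

from cgmed import autodiff as ad
from cgmed.autodiff import Tensor
from cgmed.clae import (CLAEConfig, balancing_penalty, cond_indep_penalty,
                        fit_pca, linearizability_penalty, load_model,
                        reconstruction_losses, save_model, stability_penalty,
                        train_clae, validate_embeddings, ablation_harness)
from cgmed.preprocessing import standardize_pre_matrices
from cgmed.synthetic import ValidationError

RNG = np.random.default_rng(7)


class TestEncoder:
    def test_output_shape_and_eval_determinism(self, mini_model, split_windows):
        model, _ = mini_model
        spec, train, *_ = split_windows
        x = standardize_pre_matrices(train[:10], spec)
        phi1 = model.encode_np(x)
        phi2 = model.encode_np(x)
        assert phi1.shape == (10, 8)
        np.testing.assert_array_equal(phi1, phi2)

    def test_wrong_channel_count_raises(self, mini_model):
        model, _ = mini_model
        with pytest.raises(ValidationError, match="channels"):
            model.encode(np.zeros((4, 24, 3)))

    def test_training_mode_passes_differ(self, mini_model, split_windows):
        model, _ = mini_model
        spec, train, *_ = split_windows
        x = standardize_pre_matrices(train[:10], spec)
        model.train_mode()
        rng = np.random.default_rng(0)
        a = model.encode(x, rng).data
        b = model.encode(x, rng).data
        model.eval_mode()
        assert not np.allclose(a, b)

    def test_basis_expansion_matches_dim_and_residual_form(self, mini_model):
        model, _ = mini_model
        phi = Tensor(RNG.standard_normal((6, 8)))
        psi = model.basis_expansion(phi)
        assert psi.shape == (6, 8)
        # zeroed g-branch output weights turn the expansion into identity
        saved = model.params["g2_w"].data.copy()
        saved_b = model.params["g2_b"].data.copy()
        model.params["g2_w"].data = np.zeros_like(saved)
        model.params["g2_b"].data = np.zeros_like(saved_b)
        np.testing.assert_allclose(model.basis_expansion(phi).data, phi.data)
        model.params["g2_w"].data = saved
        model.params["g2_b"].data = saved_b


class TestPenalties:
    def test_reconstruction_losses_zero_when_perfect(self):
        targets = {"mediator": RNG.standard_normal((8, 1)),
                   "outcome": RNG.standard_normal((8, 6))}
        heads = {k: Tensor(v.copy()) for k, v in targets.items()}
        losses = reconstruction_losses(heads, targets)
        for v in losses.values():
            assert float(v.data) == pytest.approx(0.0)

    def test_constant_head_loss_equals_target_variance(self):
        y = RNG.standard_normal((200, 1))
        heads = {"outcome": Tensor(np.full_like(y, y.mean()))}
        loss = reconstruction_losses(heads, {"outcome": y})["outcome"]
        assert float(loss.data) == pytest.approx(float(y.var()), rel=1e-9)

    def test_total_loss_uses_configured_head_weights(self):
        cfg = CLAEConfig()
        fake = {"pre_treatment": 1.0, "mediator": 2.0, "outcome": 3.0,
                "treatment": 100.0}
        total = sum(cfg.head_weights[k] * fake[k] for k in fake)
        assert total == pytest.approx(0.5 * 1 + 0.5 * 2 + 2.0 * 3 + 0.0 * 100)

    def test_balancing_zero_for_identical_groups(self):
        phi_half = RNG.standard_normal((16, 8))
        phi = Tensor(np.vstack([phi_half, phi_half]))
        hi = np.array([True] * 16 + [False] * 16)
        assert float(balancing_penalty(phi, hi, 2.0).data) == pytest.approx(0.0)

    def test_balancing_mean_gap_formula(self):
        # two large groups with near-identical covariance, means differing
        # by the first basis vector -> penalty ~ gamma * 1
        base = RNG.standard_normal((4000, 8))
        shift = base.copy()
        shift[:, 0] += 1.0
        phi = Tensor(np.vstack([shift, base]))
        hi = np.array([True] * 4000 + [False] * 4000)
        assert float(balancing_penalty(phi, hi, 2.0).data) == pytest.approx(
            2.0, abs=0.1)

    def test_balancing_vanishes_for_independent_embeddings(self):
        vals = []
        for n in (50, 500, 8000):
            phi = Tensor(RNG.standard_normal((n, 8)))
            hi = RNG.random(n) > 0.5
            vals.append(float(balancing_penalty(phi, hi, 2.0).data))
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.15

    def test_balancing_single_group_warns_and_zeroes(self, caplog):
        phi = Tensor(RNG.standard_normal((8, 8)))
        with caplog.at_level("WARNING"):
            val = balancing_penalty(phi, np.ones(8, dtype=bool), 2.0)
        assert float(val.data) == 0.0
        assert "single treatment group" in caplog.text

    def test_cond_indep_detects_shared_signal(self):
        n = 400
        psi = Tensor(RNG.standard_normal((n, 8)))
        z = RNG.standard_normal(n)
        # M identical to Z, psi uninformative -> residual corr ~ 1
        val = cond_indep_penalty(psi, z, z.copy(), lam=0.05)
        assert float(val.data) == pytest.approx(0.05, rel=0.05)
        # M a deterministic function of psi -> residual corr ~ 0
        m_from_psi = psi.data @ RNG.standard_normal(8)
        val2 = cond_indep_penalty(psi, z, m_from_psi, lam=0.05)
        assert float(val2.data) < 1e-3
        # degenerate constant mediator -> exactly zero
        val3 = cond_indep_penalty(psi, z, np.zeros(n), lam=0.05)
        assert float(val3.data) == 0.0

    def test_linearizability_zero_for_linear_head(self):
        n = 300
        phi = Tensor(RNG.standard_normal((n, 8)))
        beta = RNG.standard_normal((8, 6))
        y = phi.data @ beta
        pred = ad.matmul(phi, Tensor(beta))
        val = linearizability_penalty(phi, pred, y, lam=0.1)
        assert float(val.data) < 1e-6

    def test_stability_zero_for_identical_views(self):
        phi = Tensor(RNG.standard_normal((64, 8)))
        assert float(stability_penalty(phi, phi, 0.01).data) == 0.0

    def test_penalties_nonnegative(self):
        phi = Tensor(RNG.standard_normal((64, 8)))
        phi2 = Tensor(RNG.standard_normal((64, 8)))
        hi = RNG.random(64) > 0.4
        z = RNG.standard_normal(64)
        m = RNG.standard_normal(64)
        assert float(balancing_penalty(phi, hi, 2.0).data) >= 0
        assert float(cond_indep_penalty(phi, z, m, 0.05).data) >= 0
        assert float(stability_penalty(phi, phi2, 0.01).data) >= 0


class TestTraining:
    def test_loss_decreases_and_history_complete(self, mini_model):
        _, history = mini_model
        assert history.total.iloc[-1] < history.total.iloc[0]
        for col in ("loss_outcome", "loss_mediator", "loss_pre_treatment",
                    "loss_treatment", "pen_balancing",
                    "pen_conditional_independence", "pen_linearizability",
                    "pen_stability"):
            assert col in history.columns

    def test_seed_reproducibility(self, split_windows):
        spec, train, *_ = split_windows
        cfg = CLAEConfig(epochs=2, seed=9)
        _, h1 = train_clae(train, cfg, spec)
        _, h2 = train_clae(train, cfg, spec)
        np.testing.assert_array_equal(h1.total, h2.total)

    def test_rnn_encoder_stub_trains(self, split_windows):
        spec, train, *_ = split_windows
        cfg = CLAEConfig(epochs=1, encoder="rnn", seed=0)
        model, history = train_clae(train[:64], cfg, spec)
        x = standardize_pre_matrices(train[:4], spec)
        assert model.encode_np(x).shape == (4, 8)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            CLAEConfig(encoder="transformer").validate()
        bad = CLAEConfig()
        bad.penalty_weights["balancing"] = -1.0
        with pytest.raises(ValidationError):
            bad.validate()


class TestValidationMetrics:
    def test_metric_ranges(self, mini_model, split_windows):
        model, _ = mini_model
        _, _, test, _ = split_windows
        m = validate_embeddings(model, test)
        assert set(m) == {"outcome_r2", "mediator_r2", "balance_score",
                          "in_range_auc"}
        assert 0.0 <= m["balance_score"] <= 1.0
        assert m["outcome_r2"] <= 1.0
        assert np.isnan(m["in_range_auc"]) or 0.0 <= m["in_range_auc"] <= 1.0

    def test_balance_score_near_one_for_unrelated_embeddings(self, mini_model,
                                                             split_windows):
        model, _ = mini_model
        _, _, test, _ = split_windows
        rng = np.random.default_rng(1)
        n = len(test)
        # embeddings unrelated to Z: balance score close to its noise ceiling
        corrs = [abs(np.corrcoef(rng.standard_normal(n),
                                 [w.Z for w in test])[0, 1])
                 for _ in range(8)]
        assert 1 - np.mean(corrs) > 0.85


class TestPCA:
    def test_presets_and_orthogonality(self, mini_model, split_windows):
        model, _ = mini_model
        spec, train, *_ = split_windows
        phi = model.encode_np(standardize_pre_matrices(train, spec))
        pca3 = fit_pca(phi, "mediation")
        pca6 = fit_pca(phi, "balancing")
        assert pca3.n_components_ == 3 and pca6.n_components_ == 6
        scores = pca6.transform(phi)
        cov = np.cov(scores.T)
        off = np.abs(cov - np.diag(np.diag(cov))).max()
        assert off < 1e-8 * np.trace(cov)
        assert np.all(np.diff(pca6.explained_variance_) <= 1e-12)

    def test_k_above_latent_dim_rejected(self, mini_model, split_windows):
        model, _ = mini_model
        spec, train, *_ = split_windows
        phi = model.encode_np(standardize_pre_matrices(train[:20], spec))
        with pytest.raises(ValidationError):
            fit_pca(phi, 9)


def test_checkpoint_round_trip(tmp_path, mini_model, split_windows):
    model, _ = mini_model
    spec, train, *_ = split_windows
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    x = standardize_pre_matrices(train[:6], spec)
    np.testing.assert_array_equal(model.encode_np(x), back.encode_np(x))
    assert back.cfg == model.cfg
    assert back.meal_medians == model.meal_medians


def test_ablation_bookkeeping_and_determinism(split_windows):
    spec, train, test, _ = split_windows
    base = CLAEConfig(epochs=2)
    grid = [{"penalty_weights": {"balancing": 0.0}}, {}]
    t1 = ablation_harness(base, grid, [0, 1], train[:96], test[:48], spec)
    t2 = ablation_harness(base, grid, [0, 1], train[:96], test[:48], spec)
    assert len(t1) == 2
    assert len(t1.attrs["runs"]) == 4
    assert t1.selected.sum() == 1
    np.testing.assert_allclose(t1.balance_mean, t2.balance_mean)
    np.testing.assert_allclose(t1.outcome_r2_mean, t2.outcome_r2_mean)
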