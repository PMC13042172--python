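"""Causally-constrained autoencoder for pre-treatment CGM embeddings.

A small 1-D CNN compresses each standardized 24x5 pre-meal matrix into an
8-dimensional embedding phi.  Training combines four reconstruction heads
(pre-meal matrix, bolus mediator, post-meal glucose trajectory, and a
zero-weighted treatment head kept for ablations) with four causal penalties:

* **balancing** -- matches the first two moments of phi between higher- and
  lower-carbohydrate meals (split at the per-meal-type training median), so
  the representation does not encode treatment information;
* **conditional independence** -- penalizes the squared correlation between
  the residuals of treatment and mediator after regressing both on a
  nonlinear basis expansion of phi;
* **linearizability** -- penalizes the gap between the nonlinear outcome
  head and the best in-batch linear map of phi onto the outcome;
* **stability** -- penalizes the Frobenius distance between the embedding
  covariance matrices of two stochastic forward passes.

All penalties are differentiable and exactly zero in their degenerate case.
Downstream, PCA (fit on training embeddings only) provides the covariates
for the mediation (k=3) and balancing (k=6) models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score

from . import HORIZONS
from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .preprocessing import (CHANNELS, PRE_ROWS, MealWindow, SplitSpec,
                            standardize_pre_matrices)
from .synthetic import ValidationError

log = logging.getLogger(__name__)

__all__ = ["CLAEConfig", "CLAEModel", "Embedding", "TrainingDivergedError",
           "train_clae", "validate_embeddings", "fit_pca", "ablation_harness",
           "save_model", "load_model", "make_embedding",
           "balancing_penalty", "cond_indep_penalty", "linearizability_penalty",
           "stability_penalty"]

IN_RANGE = (70.0, 180.0)  # clinically relevant glucose band, mg/dL


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries the last finite-loss parameters."""

    def __init__(self, epoch: int, checkpoint: dict):
        super().__init__(f"training diverged at epoch {epoch}")
        self.checkpoint = checkpoint


@dataclass
class CLAEConfig:
    encoder: str = "cnn"                 # "cnn" or "rnn" (recurrent stub)
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    kernel_size: int = 3
    latent_dim: int = 8
    weight_decay_l2: float = 1e-4        # explicit L2 regularization in the loss
    dropout: float = 0.2
    input_noise_sd: float = 0.05
    head_weights: dict[str, float] = field(default_factory=lambda: {
        "pre_treatment": 0.5, "mediator": 0.5, "outcome": 2.0, "treatment": 0.0})
    penalty_weights: dict[str, float] = field(default_factory=lambda: {
        "balancing": 2.0, "linearizability": 0.1,
        "conditional_independence": 0.05, "stability": 0.01})
    optimizer: str = "adamw"             # "adamw" or "rmsprop"
    learning_rate: float = 1e-3
    optimizer_weight_decay: float = 1e-5
    epochs: int = 100
    batch_size: int = 32
    grad_clip_norm: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.encoder not in ("cnn", "rnn"):
            raise ValidationError(f"unknown encoder {self.encoder!r}")
        if any(v < 0 for v in self.head_weights.values()):
            raise ValidationError("head weights must be >= 0")
        if any(v < 0 for v in self.penalty_weights.values()):
            raise ValidationError("penalty weights must be >= 0")


@dataclass
class Embedding:
    """Learned embeddings and their retained principal components."""

    phi: np.ndarray                  # (n, 8)
    pcs: np.ndarray                  # (n, k)
    pca_model: PCA


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _linear_init(rng, n_in, n_out, scale=None):
    s = scale if scale is not None else np.sqrt(2.0 / n_in)
    return Parameter(s * rng.standard_normal((n_in, n_out))), \
        Parameter(np.zeros(n_out))


class CLAEModel:
    """Encoder, basis expansion, and the four prediction heads."""

    N_POST = len(HORIZONS)

    def __init__(self, cfg: CLAEConfig, split: SplitSpec,
                 target_stats: dict[str, tuple[float, float]],
                 meal_medians: dict[str, float]):
        cfg.validate()
        self.cfg = cfg
        self.split = split
        self.target_stats = target_stats      # mediator/outcome mean & sd (train)
        self.meal_medians = meal_medians      # per-meal-type training Z median
        self.training = False
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
        self.params: dict[str, Parameter] = {}
        p = self.params
        c = len(CHANNELS)
        d = cfg.latent_dim
        if cfg.encoder == "cnn":
            f1, f2, f3 = cfg.conv_filters
            k = cfg.kernel_size
            for name, (fo, fi) in {"c1": (f1, c), "c2": (f2, f1),
                                   "c3": (f3, f2)}.items():
                p[f"{name}_w"] = Parameter(
                    np.sqrt(2.0 / (fi * k)) * rng.standard_normal((fo, fi, k)))
                p[f"{name}_b"] = Parameter(np.zeros(fo))
            enc_out = f3
        else:
            # minimal single-layer 64-unit tanh recurrent encoder: a
            # simplified stub standing on the architecture-ablation axis
            h = 64
            p["r_wx"] = Parameter(np.sqrt(1.0 / c) * rng.standard_normal((c, h)))
            p["r_wh"] = Parameter(np.sqrt(1.0 / h) * rng.standard_normal((h, h)))
            p["r_b"] = Parameter(np.zeros(h))
            enc_out = h
        # final projection consumes pooled features + per-channel means
        p["proj_w"], p["proj_b"] = _linear_init(rng, enc_out + c, d)
        # basis expansion g: two-layer residual map of matching dimension
        p["g1_w"], p["g1_b"] = _linear_init(rng, d, 16)
        p["g2_w"], p["g2_b"] = _linear_init(rng, 16, d, scale=0.1)
        # heads
        p["pre_w"], p["pre_b"] = _linear_init(rng, d, PRE_ROWS * c)
        p["med1_w"], p["med1_b"] = _linear_init(rng, d, 16)
        p["med2_w"], p["med2_b"] = _linear_init(rng, 16, 1)
        p["out1_w"], p["out1_b"] = _linear_init(rng, d, 32)
        p["out2_w"], p["out2_b"] = _linear_init(rng, 32, self.N_POST)
        p["trt_w"], p["trt_b"] = _linear_init(rng, d, 1)

    # -- modes ----------------------------------------------------------
    def train_mode(self):
        self.training = True

    def eval_mode(self):
        self.training = False

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    # -- forward --------------------------------------------------------
    def encode(self, x: np.ndarray, rng: np.random.Generator | None = None
               ) -> Tensor:
        """Standardized (n, 24, 5) pre-meal matrices -> (n, 8) embeddings.

        Deterministic in evaluation mode; in training mode adds input noise
        and applies dropout (requires an rng).
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (PRE_ROWS, len(CHANNELS)):
            raise ValidationError(
                f"expected (n, {PRE_ROWS}, {len(CHANNELS)}) with channels "
                f"{CHANNELS}, got {x.shape}")
        if self.training:
            if rng is None:
                raise ValidationError("training-mode encode requires an rng")
            x = x + self.cfg.input_noise_sd * rng.standard_normal(x.shape)
        xt = Tensor(x.transpose(0, 2, 1))            # (n, C, 24)
        chan_means = Tensor(x.mean(axis=1))          # (n, C)
        p = self.params
        if self.cfg.encoder == "cnn":
            h = xt
            for name in ("c1", "c2", "c3"):
                h = ad.relu(ad.conv1d(h, p[f"{name}_w"], p[f"{name}_b"]))
                h = ad.maxpool1d(h, 2, 2)
            feats = h.mean(axis=2)                   # global average pooling
        else:
            n, c, L = xt.shape
            hprev = Tensor(np.zeros((n, p["r_wh"].shape[0])))
            for t in range(L):
                step = ad.matmul(xt[:, :, t], p["r_wx"]) \
                    + ad.matmul(hprev, p["r_wh"]) + p["r_b"]
                hprev = ad.tanh(step)
            feats = hprev
        if self.training and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(feats.shape) < keep) / keep
            feats = feats * Tensor(mask)
        z = ad.concat([feats, chan_means], axis=1)
        return ad.matmul(z, p["proj_w"]) + p["proj_b"]

    def encode_np(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode embeddings as a plain array."""
        was = self.training
        self.eval_mode()
        out = self.encode(x).data
        self.training = was
        return out

    def basis_expansion(self, phi: Tensor) -> Tensor:
        """psi(phi) = phi + g(phi), g a small two-layer map (residual)."""
        p = self.params
        g = ad.matmul(ad.tanh(ad.matmul(phi, p["g1_w"]) + p["g1_b"]),
                      p["g2_w"]) + p["g2_b"]
        return phi + g

    def heads(self, phi: Tensor) -> dict[str, Tensor]:
        p = self.params
        med = ad.matmul(ad.relu(ad.matmul(phi, p["med1_w"]) + p["med1_b"]),
                        p["med2_w"]) + p["med2_b"]
        out = ad.matmul(ad.relu(ad.matmul(phi, p["out1_w"]) + p["out1_b"]),
                        p["out2_w"]) + p["out2_b"]
        return {
            "pre_treatment": ad.matmul(phi, p["pre_w"]) + p["pre_b"],
            "mediator": med,
            "outcome": out,
            "treatment": ad.matmul(phi, p["trt_w"]) + p["trt_b"],
        }

    # -- convenience predictions (evaluation scale) ----------------------
    def predict_outcome(self, x_std: np.ndarray) -> np.ndarray:
        """Predicted glucose excursions (mg/dL) at the six horizons."""
        phi = Tensor(self.encode_np(x_std))
        raw = self.heads(phi)["outcome"].data
        mu, sd = self.target_stats["outcome"]
        return raw * sd + mu

    def predict_mediator(self, x_std: np.ndarray) -> np.ndarray:
        phi = Tensor(self.encode_np(x_std))
        raw = self.heads(phi)["mediator"].data[:, 0]
        mu, sd = self.target_stats["mediator"]
        return raw * sd + mu


# ---------------------------------------------------------------------------
# losses and penalties
# ---------------------------------------------------------------------------

def reconstruction_losses(heads: dict[str, Tensor], targets: dict[str, np.ndarray]
                          ) -> dict[str, Tensor]:
    """Per-head mean-squared errors (targets already standardized)."""
    return {name: ((heads[name] - Tensor(targets[name])) ** 2).mean()
            for name in heads}


def balancing_penalty(phi: Tensor, hi_group: np.ndarray, gamma: float) -> Tensor:
    """gamma * (||mean gap||^2 + ||covariance gap||_F^2) between the
    embeddings of higher- and lower-carbohydrate meals."""
    hi_idx = np.flatnonzero(hi_group)
    lo_idx = np.flatnonzero(~hi_group)
    if len(hi_idx) < 2 or len(lo_idx) < 2:
        log.warning("balancing penalty: batch contains a single treatment "
                    "group; penalty set to 0")
        return Tensor(0.0)
    gaps = []
    means = []
    for idx in (hi_idx, lo_idx):
        grp = phi[idx]
        mu = grp.mean(axis=0, keepdims=True)
        centered = grp - mu
        cov = ad.matmul(centered.T, centered) * (1.0 / (len(idx) - 1))
        means.append(mu)
        gaps.append(cov)
    mean_gap = ((means[0] - means[1]) ** 2).sum()
    cov_gap = ((gaps[0] - gaps[1]) ** 2).sum()
    return gamma * (mean_gap + cov_gap)


def _residualize(y: Tensor, psi_aug: Tensor, gram_inv: Tensor) -> Tensor:
    beta = ad.matmul(gram_inv, ad.matmul(psi_aug.T, y))
    return y - ad.matmul(psi_aug, beta)


def cond_indep_penalty(psi: Tensor, Z: np.ndarray, M: np.ndarray,
                       lam: float, ridge: float = 1e-6) -> Tensor:
    """lam * squared correlation of the residuals of Z and M on psi(phi)."""
    n = psi.shape[0]
    ones = Tensor(np.ones((n, 1)))
    psi_aug = ad.concat([ones, psi], axis=1)
    k = psi_aug.shape[1]
    gram = ad.matmul(psi_aug.T, psi_aug) + Tensor(ridge * n * np.eye(k))
    gram_inv = ad.inv(gram)
    rz = _residualize(Tensor(Z.reshape(-1, 1)), psi_aug, gram_inv)
    rm = _residualize(Tensor(M.reshape(-1, 1)), psi_aug, gram_inv)
    var_z = (rz ** 2).mean()
    var_m = (rm ** 2).mean()
    if float(var_z.data) < 1e-12 or float(var_m.data) < 1e-12:
        return Tensor(0.0)
    cov = (rz * rm).mean()
    return lam * (cov ** 2) / (var_z * var_m)


def linearizability_penalty(phi: Tensor, outcome_pred: Tensor, Y: np.ndarray,
                            lam: float, ridge: float = 1e-6) -> Tensor:
    """lam * MSE between the nonlinear outcome head and the best in-batch
    linear map of phi onto the outcome targets."""
    n = phi.shape[0]
    ones = Tensor(np.ones((n, 1)))
    phi_aug = ad.concat([ones, phi], axis=1)
    k = phi_aug.shape[1]
    gram = ad.matmul(phi_aug.T, phi_aug) + Tensor(ridge * n * np.eye(k))
    beta = ad.matmul(ad.inv(gram), ad.matmul(phi_aug.T, Tensor(Y)))
    linear_fit = ad.matmul(phi_aug, beta)
    return lam * ((outcome_pred - linear_fit) ** 2).mean()


def stability_penalty(phi_view1: Tensor, phi_view2: Tensor, lam: float) -> Tensor:
    """lam * Frobenius norm of the difference of the two views' embedding
    covariance matrices."""
    covs = []
    for phi in (phi_view1, phi_view2):
        mu = phi.mean(axis=0, keepdims=True)
        c = phi - mu
        covs.append(ad.matmul(c.T, c) * (1.0 / max(phi.shape[0] - 1, 1)))
    return lam * ((covs[0] - covs[1]) ** 2).sum() ** 0.5


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_standardize(phi: Tensor) -> Tensor:
    """Per-dimension z-scoring within the batch (differentiable)."""
    centered = phi - phi.mean(axis=0, keepdims=True)
    var = (centered ** 2).mean(axis=0, keepdims=True)
    return centered / (var + 1e-8) ** 0.5


def _targets(windows: Sequence[MealWindow], model_stats=None):
    """Standardized training targets; stats computed here on first call."""
    M = np.array([w.M for w in windows])
    Y = np.array([[w.delta_g[t] for t in HORIZONS] for w in windows])
    Z = np.array([w.Z for w in windows])
    if model_stats is None:
        model_stats = {
            "mediator": (float(M.mean()), float(M.std() + 1e-12)),
            "outcome": (float(Y.mean()), float(Y.std() + 1e-12)),
            "treatment": (float(Z.mean()), float(Z.std() + 1e-12)),
        }
    ms, os_, ts = model_stats["mediator"], model_stats["outcome"], \
        model_stats["treatment"]
    return model_stats, (M - ms[0]) / ms[1], (Y - os_[0]) / os_[1], \
        (Z - ts[0]) / ts[1]


def train_clae(windows_train: Sequence[MealWindow], cfg: CLAEConfig,
               split: SplitSpec | None = None
               ) -> tuple[CLAEModel, pd.DataFrame]:
    """Train the autoencoder; returns the model and a per-epoch history of
    every loss component.  Deterministic given ``cfg.seed``."""
    cfg.validate()
    if split is None:
        # stats from the provided windows (they are the training partition)
        stack = np.stack([w.pre_matrix for w in windows_train])
        mean = stack.mean(axis=(0, 1))
        sd = np.where(stack.std(axis=(0, 1)) < 1e-12, 1.0, stack.std(axis=(0, 1)))
        split = SplitSpec(train_fraction_days=1.0, day_boundary={},
                          channel_mean=mean, channel_sd=sd)
    X = standardize_pre_matrices(windows_train, split)
    stats, M_std, Y_std, Z_std = _targets(windows_train)
    pre_flat = X.transpose(0, 2, 1).reshape(len(X), -1)
    Z = np.array([w.Z for w in windows_train])
    types = np.array([w.meal_type for w in windows_train])
    medians = {mt: float(np.median(Z[types == mt])) for mt in np.unique(types)}
    hi_group = np.array([w.Z > medians[w.meal_type] for w in windows_train])

    model = CLAEModel(cfg, split, stats, medians)
    params = model.parameters()
    if cfg.optimizer == "adamw":
        opt = ad.AdamW(params, lr=cfg.learning_rate,
                       weight_decay=cfg.optimizer_weight_decay)
    elif cfg.optimizer == "rmsprop":
        opt = ad.RMSprop(params, lr=cfg.learning_rate,
                         weight_decay=cfg.optimizer_weight_decay)
    else:
        raise ValidationError(f"unknown optimizer {cfg.optimizer!r}")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]))
    n = len(windows_train)
    hw, pw = cfg.head_weights, cfg.penalty_weights
    history = []
    last_good = model.state_dict()
    model.train_mode()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        comp_sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 4:
                continue
            xb = X[idx]
            phi = model.encode(xb, rng)
            heads = model.heads(phi)
            targets = {"pre_treatment": pre_flat[idx],
                       "mediator": M_std[idx, None],
                       "outcome": Y_std[idx],
                       "treatment": Z_std[idx, None]}
            losses = reconstruction_losses(heads, targets)
            psi = model.basis_expansion(phi)
            # penalties on batch-standardized embeddings: the moment-gap
            # forms are not scale-invariant, and without this the encoder
            # can shrink phi instead of decorrelating it
            phi_std = _batch_standardize(phi)
            pen = {
                "balancing": balancing_penalty(phi_std, hi_group[idx],
                                               pw["balancing"]),
                "conditional_independence": cond_indep_penalty(
                    psi, Z_std[idx], M_std[idx],
                    pw["conditional_independence"]),
                "linearizability": linearizability_penalty(
                    phi, heads["outcome"], Y_std[idx],
                    pw["linearizability"]),
            }
            if pw["stability"] > 0:
                phi2 = model.encode(xb, rng)
                pen["stability"] = stability_penalty(
                    phi_std, _batch_standardize(phi2), pw["stability"])
            else:
                pen["stability"] = Tensor(0.0)
            total = sum((hw[k] * losses[k] for k in losses), Tensor(0.0))
            total = sum(pen.values(), total)
            if cfg.weight_decay_l2 > 0:
                l2 = sum(((p ** 2).sum() for p in params), Tensor(0.0))
                total = total + cfg.weight_decay_l2 * l2
            if not np.isfinite(total.data):
                model.load_state_dict(last_good)
                raise TrainingDivergedError(epoch, last_good)
            opt.zero_grad()
            total.backward()
            ad.clip_global_norm(params, cfg.grad_clip_norm)
            opt.step()
            for k, v in losses.items():
                comp_sums[f"loss_{k}"] = comp_sums.get(f"loss_{k}", 0) + float(v.data)
            for k, v in pen.items():
                comp_sums[f"pen_{k}"] = comp_sums.get(f"pen_{k}", 0) + float(v.data)
            comp_sums["total"] = comp_sums.get("total", 0) + float(total.data)
            n_batches += 1
        row = {k: v / max(n_batches, 1) for k, v in comp_sums.items()}
        row["epoch"] = epoch
        history.append(row)
        last_good = model.state_dict()
    model.eval_mode()
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# validation metrics and PCA
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot < 1e-12:
        log.warning("constant target; R^2 floored at 0")
        return 0.0
    r2 = 1 - ss_res / ss_tot
    if not np.isfinite(r2):
        return 0.0
    return max(r2, 0.0) if np.allclose(pred, pred.ravel()[0]) else r2


def validate_embeddings(model: CLAEModel, windows_test: Sequence[MealWindow]
                        ) -> dict[str, float]:
    """Held-out embedding quality: outcome/mediator R^2, balance score
    (1 - mean |corr(phi_d, Z)|), and in-range AUC for the 70-180 mg/dL band.

    The in-range score for a horizon is the negative distance of the
    predicted glucose value from the band (zero inside it)."""
    X = standardize_pre_matrices(windows_test, model.split)
    phi = model.encode_np(X)
    Z = np.array([w.Z for w in windows_test])
    M = np.array([w.M for w in windows_test])
    Y = np.array([[w.delta_g[t] for t in HORIZONS] for w in windows_test])
    G0 = np.array([w.G0 for w in windows_test])

    pred_y = model.predict_outcome(X)
    pred_m = model.predict_mediator(X)
    out_r2 = _r2(Y.ravel(), pred_y.ravel())
    med_r2 = _r2(M, pred_m)

    corrs = np.array([abs(np.corrcoef(phi[:, d], Z)[0, 1])
                      for d in range(phi.shape[1])])
    corrs = np.nan_to_num(corrs)
    balance = 1.0 - float(corrs.mean())

    glucose_obs = G0[:, None] + Y
    glucose_pred = G0[:, None] + pred_y
    labels = ((glucose_obs >= IN_RANGE[0]) & (glucose_obs <= IN_RANGE[1])).ravel()
    dist = np.maximum.reduce([IN_RANGE[0] - glucose_pred,
                              glucose_pred - IN_RANGE[1],
                              np.zeros_like(glucose_pred)])
    scores = -dist.ravel()
    if labels.all() or not labels.any():
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
    return {"outcome_r2": out_r2, "mediator_r2": med_r2,
            "balance_score": balance, "in_range_auc": auc}


def save_model(model: CLAEModel, path) -> None:
    """Persist parameters + config + standardization state in one archive."""
    import dataclasses as dc
    import json
    meta = {
        "cfg": dc.asdict(model.cfg),
        "target_stats": model.target_stats,
        "meal_medians": model.meal_medians,
        "split": {"train_fraction_days": model.split.train_fraction_days,
                  "day_boundary": model.split.day_boundary},
    }
    arrays = {f"param_{k}": v.data for k, v in model.params.items()}
    np.savez(path, __meta__=json.dumps(meta),
             split_mean=model.split.channel_mean,
             split_sd=model.split.channel_sd, **arrays)


def load_model(path) -> CLAEModel:
    import json
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        cfg_d = meta["cfg"]
        for key in ("conv_filters",):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = CLAEConfig(**cfg_d)
        split = SplitSpec(
            train_fraction_days=meta["split"]["train_fraction_days"],
            day_boundary=meta["split"]["day_boundary"],
            channel_mean=archive["split_mean"],
            channel_sd=archive["split_sd"])
        stats = {k: tuple(v) for k, v in meta["target_stats"].items()}
        model = CLAEModel(cfg, split, stats, meta["meal_medians"])
        for k in model.params:
            model.params[k].data = archive[f"param_{k}"].copy()
    return model


PCA_PRESETS = {"mediation": 3, "balancing": 6}


def fit_pca(phi_train: np.ndarray, k: int | str = "mediation") -> PCA:
    """PCA loadings fit on training embeddings only.

    ``k`` may be an integer or a named preset ('mediation' -> 3 components
    used as covariates in the mediation models; 'balancing' -> 6 components
    used in the weight model)."""
    if isinstance(k, str):
        k = PCA_PRESETS[k]
    if k > phi_train.shape[1]:
        raise ValidationError(f"k={k} exceeds latent dimension "
                              f"{phi_train.shape[1]}")
    return PCA(n_components=k, svd_solver="full").fit(phi_train)


def make_embedding(model: CLAEModel, windows_train, windows_other=None,
                   k: int | str = "mediation"):
    """Fit PCA on training phi; return Embeddings for train (and other)."""
    X_tr = standardize_pre_matrices(windows_train, model.split)
    phi_tr = model.encode_np(X_tr)
    pca = fit_pca(phi_tr, k)
    emb_tr = Embedding(phi=phi_tr, pcs=pca.transform(phi_tr), pca_model=pca)
    if windows_other is None:
        return emb_tr
    X_o = standardize_pre_matrices(windows_other, model.split)
    phi_o = model.encode_np(X_o)
    return emb_tr, Embedding(phi=phi_o, pcs=pca.transform(phi_o), pca_model=pca)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def ablation_harness(base_cfg: CLAEConfig, grid: Sequence[dict], seeds: Sequence[int],
                     windows_train: Sequence[MealWindow],
                     windows_test: Sequence[MealWindow],
                     split: SplitSpec | None = None,
                     adequacy_margin: float = 0.1) -> pd.DataFrame:
    """Train every (configuration, seed) pair; summarize mean +/- SD of
    outcome R^2 and balance score per configuration.

    ``grid`` entries are dicts of CLAEConfig field overrides (nested dicts
    for head/penalty weights are merged).  The selection rule prioritizes
    covariate balance subject to adequate outcome prediction: among
    configurations whose mean outcome R^2 is within ``adequacy_margin`` of
    the best mean R^2, the one with the highest mean balance score is
    marked selected.
    """
    rows = []
    for gi, overrides in enumerate(grid):
        for seed in seeds:
            cfg = _merge_cfg(base_cfg, overrides, seed)
            model, _ = train_clae(windows_train, cfg, split)
            metrics = validate_embeddings(model, windows_test)
            rows.append({"config": gi, "seed": seed, **overrides_label(overrides),
                         **metrics})
    runs = pd.DataFrame(rows)
    summary = runs.groupby("config").agg(
        label=("label", "first"),
        outcome_r2_mean=("outcome_r2", "mean"),
        outcome_r2_sd=("outcome_r2", "std"),
        balance_mean=("balance_score", "mean"),
        balance_sd=("balance_score", "std"),
    ).reset_index()
    best_r2 = summary.outcome_r2_mean.max()
    adequate = summary.outcome_r2_mean >= best_r2 - adequacy_margin
    summary["selected"] = False
    if adequate.any():
        pick = summary.loc[adequate, "balance_mean"].idxmax()
        summary.loc[pick, "selected"] = True
    summary.attrs["runs"] = runs
    return summary


def _merge_cfg(base: CLAEConfig, overrides: dict, seed: int) -> CLAEConfig:
    kwargs = {}
    for key, val in overrides.items():
        if key in ("head_weights", "penalty_weights"):
            merged = dict(getattr(base, key))
            merged.update(val)
            kwargs[key] = merged
        else:
            kwargs[key] = val
    return replace(base, seed=seed, **kwargs)


def overrides_label(overrides: dict) -> dict:
    parts = []
    for key, val in overrides.items():
        if isinstance(val, dict):
            parts += [f"{k}={v}" for k, v in val.items()]
        else:
            parts.append(f"{key}={val}")
    return {"label": ",".join(parts) if parts else "default"}
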