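"""Covariate-balancing weights for a continuous treatment.

Implements the exponential-tilting (entropy-balancing) member of the
non-parametric covariate balancing propensity score family: weights maximize
entropy subject to mean-one normalization and linear decorrelation
constraints — the weighted means of every covariate, of the treatment, and
of every treatment-by-covariate product are zero (treatment and covariates
standardized).  The dual is an unconstrained convex problem in one
multiplier per constraint, solved with a Newton trust-region method; the
weighted treatment–covariate correlations are then zero up to solver
tolerance.

The weight model deliberately includes meal-time glucose and the cohort
indicator alongside the embedding PCs, while the mediation formulas exclude
them (collider avoidance); that composition happens in the pipeline layer,
not here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import ValidationError

log = logging.getLogger(__name__)

__all__ = ["BalanceResult", "InfeasibleBalanceError", "estimate_weights",
           "balance_report", "effective_sample_size", "weighted_corr"]


class InfeasibleBalanceError(RuntimeError):
    """No positive reweighting can satisfy the balance constraints."""


@dataclass
class BalanceResult:
    weights: np.ndarray               # positive, mean 1
    pre_corr: np.ndarray              # |corr(Z, X_j)| before weighting
    post_corr: np.ndarray             # weighted |corr| after
    covariate_names: list[str]
    ess: float                        # (sum w)^2 / sum w^2
    dual: np.ndarray
    constraint_residual: float        # max |weighted constraint|

    @property
    def weight_summary(self) -> dict[str, float]:
        w = self.weights
        q1, med, q3 = np.percentile(w, [25, 50, 75])
        return {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3),
                "frac_above_2": float(np.mean(w > 2.0))}


def weighted_corr(z: np.ndarray, x: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation (weights need not be normalized)."""
    w = w / w.sum()
    zc = z - np.sum(w * z)
    xc = x - np.sum(w * x)
    cov = np.sum(w * zc * xc)
    vz = np.sum(w * zc ** 2)
    vx = np.sum(w * xc ** 2)
    if vz < 1e-15 or vx < 1e-15:
        return 0.0
    return float(cov / np.sqrt(vz * vx))


def effective_sample_size(w: np.ndarray) -> float:
    return float(w.sum() ** 2 / np.sum(w ** 2))


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0)
    if np.any(sd < 1e-12):
        raise ValidationError("constant covariate cannot be balanced; remove it")
    return (a - a.mean(axis=0)) / sd


def estimate_weights(Z: np.ndarray, covariates: pd.DataFrame | np.ndarray,
                     *, trim_cap: float | None = None,
                     tol: float = 1e-9) -> BalanceResult:
    """Entropy-balancing weights decorrelating a continuous treatment from
    covariates.

    Parameters
    ----------
    Z : treatment values (will be standardized internally).
    covariates : columns are the balancing covariates (embedding PCs,
        meal-time glucose, centered cohort indicator, ...).
    trim_cap : optional cap applied to the fitted weights (then
        renormalized to mean one); off by default.

    Raises
    ------
    InfeasibleBalanceError
        if the treatment is perfectly collinear with a covariate (no
        positive reweighting can break an exact linear tie) or the dual
        solver fails to reduce the constraint residuals.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(float)
    else:
        X = np.asarray(covariates, float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    Z = np.asarray(Z, float)
    n, k = X.shape
    if n < 20:
        raise ValidationError("need at least 20 observations to balance")

    z = _standardize(Z[:, None])[:, 0]
    Xs = _standardize(X)

    # perfect collinearity check: |corr(Z, X_j)| == 1 is infeasible
    pre_corr = np.array([abs(np.corrcoef(z, Xs[:, j])[0, 1]) for j in range(k)])
    if np.any(pre_corr > 1 - 1e-10):
        j = int(np.argmax(pre_corr))
        raise InfeasibleBalanceError(
            f"treatment is perfectly collinear with covariate {names[j]!r}; "
            "remove it from the balance model")

    # constraint features: E_w[X]=0, E_w[Z]=0, E_w[Z*X]=0 on the
    # standardized scale; the last block is the decorrelation constraint
    C = np.column_stack([Xs, z, z[:, None] * Xs])       # (n, 2k+1)

    # dual: minimize log mean exp(C lam); gradient = weighted constraint
    # means, which the optimum drives to zero
    def fgh(lam):
        eta = C @ lam
        m = eta.max()
        e = np.exp(eta - m)
        s = e.sum()
        w = e / s
        f = m + np.log(s / len(eta))
        g = C.T @ w
        H = (C * w[:, None]).T @ C - np.outer(g, g)
        return f, g, H

    lam0 = np.zeros(C.shape[1])
    res = optimize.minimize(
        lambda l: fgh(l)[0], lam0, jac=lambda l: fgh(l)[1],
        hess=lambda l: fgh(l)[2], method="trust-ncg",
        options={"gtol": tol, "maxiter": 500})
    lam = res.x
    _, grad, _ = fgh(lam)
    residual = float(np.abs(grad).max())
    if residual > 1e-6:
        raise InfeasibleBalanceError(
            f"balance constraints not satisfied (max dual residual "
            f"{residual:.2e}); covariates may be nearly collinear with "
            "treatment")

    eta = C @ lam
    w = np.exp(eta - eta.max())
    w = w / w.mean()
    if trim_cap is not None:
        capped = np.minimum(w, trim_cap)
        n_capped = int(np.sum(w > trim_cap))
        if n_capped:
            log.info("weight trimming active: %d weights capped at %.1f",
                     n_capped, trim_cap)
        w = capped / capped.mean()

    post_corr = np.array([abs(weighted_corr(z, Xs[:, j], w)) for j in range(k)])
    return BalanceResult(weights=w, pre_corr=pre_corr, post_corr=post_corr,
                         covariate_names=names, ess=effective_sample_size(w),
                         dual=lam, constraint_residual=residual)


def balance_report(result: BalanceResult) -> pd.DataFrame:
    """Per-covariate pre/post correlation table, most imbalanced first,
    with ESS and weight-distribution summary in ``attrs``."""
    df = pd.DataFrame({
        "covariate": result.covariate_names,
        "pre_abs_corr": result.pre_corr,
        "post_abs_corr": result.post_corr,
    }).sort_values("pre_abs_corr", ascending=False).reset_index(drop=True)
    df["reduction"] = 1.0 - df.post_abs_corr / df.pre_abs_corr.clip(lower=1e-12)
    df.attrs["ess"] = result.ess
    df.attrs["n"] = len(result.weights)
    df.attrs["weight_summary"] = result.weight_summary
    df.attrs["mean_abs_corr_reduction"] = float(
        1.0 - result.post_corr.mean() / max(result.pre_corr.mean(), 1e-12))
    return df
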