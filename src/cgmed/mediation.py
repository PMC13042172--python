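"""Mediation models and the quasi-Bayesian ACME/ADE engine.

The mediator model is a left-censored (at zero) Tobit regression of the
bolus dose on treatment and embedding PCs, fit by weighted censored-normal
maximum likelihood.  The outcome model is either a weighted random-intercept
linear mixed model (population mean) or weighted quantile regression at
tau in {0.25, 0.50, 0.75} (solved exactly as a linear program, with
subject-level bootstrap covariance).  Effects are propagated by the
quasi-Bayesian algorithm: parameters are drawn from normal approximations
centered at the estimates, potential mediators are simulated with the Tobit
censoring applied, and the average causal mediation effect (ACME), average
direct effect (ADE) and total effect are computed from model-implied
counterfactual outcomes, with percentile intervals and Monte-Carlo p-values
across draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from . import HORIZONS, MEAL_TYPES
from .synthetic import ValidationError

log = logging.getLogger(__name__)

__all__ = ["TobitFit", "OutcomeFit", "MediationEstimate", "MediationSpec",
           "fit_tobit", "fit_outcome", "quasi_bayes_mediate", "run_suite",
           "report_tables"]


# ---------------------------------------------------------------------------
# Tobit mediator model
# ---------------------------------------------------------------------------

@dataclass
class TobitFit:
    """Left-censored (at 0) Gaussian regression fit."""

    beta: np.ndarray                  # (p,), intercept first
    sigma: float
    cov: np.ndarray                   # (p+1, p+1) for (beta, sigma)
    loglike: float
    names: list[str]
    weights: np.ndarray
    censored_fraction: float
    gaussian_fallback: bool = False

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, [self.sigma]])


def _tobit_loglike(params, X, y, w, censored):
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    xb = X @ beta
    r = (y - xb) / sigma
    ll = np.where(censored,
                  stats.norm.logcdf(-xb / sigma),
                  stats.norm.logpdf(r) - log_sigma)
    return float(np.sum(w * ll))


def _tobit_grad(params, X, y, w, censored):
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    xb = X @ beta
    r = (y - xb) / sigma
    s = -xb / sigma
    mills = np.exp(stats.norm.logpdf(s) - stats.norm.logcdf(s))
    gb_unc = r / sigma
    gb_cen = -mills / sigma
    gbeta_terms = np.where(censored, gb_cen, gb_unc)
    gbeta = X.T @ (w * gbeta_terms)
    gs = np.where(censored, -s * mills, r ** 2 - 1)
    return np.concatenate([gbeta, [np.sum(w * gs)]])


def fit_tobit(M: np.ndarray, design: pd.DataFrame | np.ndarray,
              weights: np.ndarray | None = None) -> TobitFit:
    """Weighted censored-normal MLE of the bolus mediator.

    ``design`` should NOT contain an intercept column (one is added).
    All-censored samples are rejected; a sample with no zeros falls back to
    weighted Gaussian regression (the uncensored limit) with a logged note.
    """
    if isinstance(design, pd.DataFrame):
        names = ["intercept"] + list(design.columns)
        X0 = design.to_numpy(float)
    else:
        X0 = np.asarray(design, float)
        if X0.ndim == 1:
            X0 = X0[:, None]
        names = ["intercept"] + [f"x{j}" for j in range(X0.shape[1])]
    y = np.asarray(M, float)
    n = len(y)
    X = np.column_stack([np.ones(n), X0])
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    if np.any(y < 0):
        raise ValidationError("mediator values must be >= 0")
    censored = y <= 0
    frac = float(censored.mean())
    if censored.all():
        raise ValidationError("all mediator values are censored at 0; "
                              "Tobit model is unidentified")
    gaussian = not censored.any()
    if gaussian:
        log.info("no censored mediator values; falling back to weighted "
                 "Gaussian regression")

    # start at weighted LS on uncensored observations
    obs = ~censored
    Wo = w[obs]
    Xo, yo = X[obs], y[obs]
    beta0 = np.linalg.lstsq(Xo * np.sqrt(Wo)[:, None],
                            yo * np.sqrt(Wo), rcond=None)[0]
    resid = yo - Xo @ beta0
    sigma0 = max(np.sqrt(np.sum(Wo * resid ** 2) / Wo.sum()), 1e-3)
    x0 = np.concatenate([beta0, [np.log(sigma0)]])

    def nll(p):
        return -_tobit_loglike(p, X, y, w, censored)

    def grad(p):
        return -_tobit_grad(p, X, y, w, censored)

    res = optimize.minimize(nll, x0, jac=grad, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))

    # observed information in (beta, sigma) coordinates
    def nll_sigma(p):
        q = np.concatenate([p[:-1], [np.log(max(p[-1], 1e-8))]])
        return -_tobit_loglike(q, X, y, w, censored)

    H = approx_hess(np.concatenate([beta, [sigma]]), nll_sigma)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return TobitFit(beta=beta, sigma=sigma, cov=cov, loglike=-res.fun,
                    names=names, weights=w, censored_fraction=frac,
                    gaussian_fallback=gaussian)


# ---------------------------------------------------------------------------
# outcome models
# ---------------------------------------------------------------------------

@dataclass
class OutcomeFit:
    """Weighted outcome model for one horizon.

    ``kind`` is 'mixed' (random-intercept mean model) or 'quantile'.
    ``beta`` covers intercept, Z, M, then PCs.
    """

    kind: str
    beta: np.ndarray
    cov: np.ndarray
    names: list[str]
    tau: float | None = None
    sigma_b: float | None = None      # random-intercept SD (mixed)
    sigma_e: float | None = None      # residual SD (mixed)
    n_boot: int | None = None
    subjects: np.ndarray | None = None


def _wls(X, y, w):
    sw = np.sqrt(w)
    return np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]


def _mixed_profile(X, y, w, groups):
    """Weighted random-intercept ML: marginal covariance per subject is
    sigma_e^2 diag(1/w) + sigma_b^2 J."""
    labels, idx = np.unique(groups, return_inverse=True)
    by = [np.flatnonzero(idx == g) for g in range(len(labels))]
    n, p = X.shape

    def neg_ll(theta):
        sb2, se2 = np.exp(2 * theta[0]), np.exp(2 * theta[1])
        XtSiX = np.zeros((p, p))
        XtSiy = np.zeros(p)
        quad_y = 0.0
        logdet = 0.0
        for rows in by:
            Xi, yi, wi = X[rows], y[rows], w[rows]
            # Woodbury: Si_inv = W/se2 - (W1)(W1)'/se2^2 / (1/sb2 + sum(w)/se2)
            denom = 1.0 / sb2 + wi.sum() / se2
            Wy = wi * yi
            WX = wi[:, None] * Xi
            XtSiX += (WX.T @ Xi) / se2 - np.outer(WX.sum(0), WX.sum(0)) \
                / (se2 ** 2 * denom)
            XtSiy += (WX.T @ yi) / se2 - WX.sum(0) * Wy.sum() \
                / (se2 ** 2 * denom)
            quad_y += (Wy @ yi) / se2 - Wy.sum() ** 2 / (se2 ** 2 * denom)
            # determinant lemma: det(Si) = prod(se2/wi) * (1 + sb2*sum(wi)/se2)
            logdet += np.sum(np.log(se2 / wi)) + np.log(sb2 * denom)
        beta = np.linalg.solve(XtSiX, XtSiy)
        quad = quad_y - XtSiy @ beta
        ll = -0.5 * (logdet + quad + n * np.log(2 * np.pi))
        return -ll, beta, XtSiX

    def obj(theta):
        return neg_ll(theta)[0]

    y_sd = max(float(np.std(y)), 1e-6)
    res = optimize.minimize(obj, np.log([0.3 * y_sd, 0.8 * y_sd]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 400})
    _, beta, XtSiX = neg_ll(res.x)
    cov = np.linalg.inv(XtSiX)
    sb, se = np.exp(res.x)
    return beta, cov, float(sb), float(se)


def _quantile_lp(X, y, w, tau):
    """Exact weighted quantile regression via the standard LP formulation."""
    n, p = X.shape
    c = np.concatenate([np.zeros(p), tau * w, (1 - tau) * w])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds,
                           method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:p]


def fit_outcome(delta_g: np.ndarray, design: pd.DataFrame,
                weights: np.ndarray | None = None, kind: str = "mixed",
                *, subjects: Sequence[str] | None = None,
                tau: float = 0.5, n_boot: int = 200,
                seed: int = 0) -> OutcomeFit:
    """Fit the weighted outcome model for one horizon.

    ``design`` columns must start with Z and M, followed by covariates; an
    intercept is added.  ``kind='mixed'`` fits the random-intercept mean
    model (subject labels required); ``kind='quantile'`` fits weighted
    quantile regression at ``tau`` with subject-bootstrap covariance.
    """
    names = ["intercept"] + list(design.columns)
    X = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    y = np.asarray(delta_g, float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    if kind == "mixed":
        if subjects is None:
            raise ValidationError("mixed outcome model requires subject labels")
        subjects = np.asarray(subjects)
        if len(np.unique(subjects)) < 2:
            raise ValidationError("mixed model needs at least two subjects")
        beta, cov, sb, se = _mixed_profile(X, y, w, subjects)
        return OutcomeFit(kind="mixed", beta=beta, cov=cov, names=names,
                          sigma_b=sb, sigma_e=se, subjects=subjects)
    if kind == "quantile":
        if not 0 < tau < 1:
            raise ValidationError("tau must be in (0, 1)")
        beta = _quantile_lp(X, y, w, tau)
        subjects = np.asarray(subjects) if subjects is not None \
            else np.arange(len(y)).astype(str)
        labels = np.unique(subjects)
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            take = rng.choice(labels, size=len(labels), replace=True)
            rows = np.concatenate([np.flatnonzero(subjects == s) for s in take])
            try:
                boots.append(_quantile_lp(X[rows], y[rows], w[rows], tau))
            except RuntimeError:
                continue
        if len(boots) < max(10, n_boot // 4):
            log.warning("quantile bootstrap unstable: only %d/%d resamples "
                        "converged", len(boots), n_boot)
        cov = np.cov(np.array(boots).T) if len(boots) > 1 else \
            np.full((X.shape[1], X.shape[1]), np.nan)
        return OutcomeFit(kind="quantile", beta=beta, cov=cov, names=names,
                          tau=tau, n_boot=n_boot, subjects=subjects)
    raise ValidationError(f"unknown outcome kind {kind!r}")


# ---------------------------------------------------------------------------
# quasi-Bayesian mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationEstimate:
    stratum: str                       # 'pooled' or a meal type
    horizon: int
    dose: float
    model: str                         # 'mean' or 'q25'/'q50'/'q75'
    acme: float
    acme_ci: tuple[float, float]
    acme_p: float
    ade: float
    ade_ci: tuple[float, float]
    ade_p: float
    total: float
    total_ci: tuple[float, float]
    total_p: float
    n: int
    n_sims: int
    seed: int
    z0: float = np.nan                 # mean anchor across units
    z1: float = np.nan

    def as_row(self) -> dict:
        return {
            "stratum": self.stratum, "model": self.model,
            "horizon": self.horizon, "dose": self.dose,
            "acme": self.acme, "acme_lo": self.acme_ci[0],
            "acme_hi": self.acme_ci[1], "acme_p": self.acme_p,
            "ade": self.ade, "ade_lo": self.ade_ci[0],
            "ade_hi": self.ade_ci[1], "ade_p": self.ade_p,
            "total": self.total, "total_lo": self.total_ci[0],
            "total_hi": self.total_ci[1], "total_p": self.total_p,
            "n": self.n, "n_sims": self.n_sims, "seed": self.seed,
            "z0": self.z0, "z1": self.z1,
        }


def _draw_params(mean: np.ndarray, cov: np.ndarray,
                 rng: np.random.Generator, n_sims: int) -> np.ndarray:
    cov = np.asarray(cov, float)
    cov = 0.5 * (cov + cov.T)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        log.warning("singular parameter covariance; ridge-stabilized draws")
        ridge = 1e-8 * max(np.trace(cov) / len(cov), 1e-12)
        chol = np.linalg.cholesky(cov + ridge * np.eye(len(cov)))
    return mean + rng.standard_normal((n_sims, len(mean))) @ chol.T


def _mc_p(draws: np.ndarray) -> float:
    n = len(draws)
    p = 2 * min(np.mean(draws <= 0), np.mean(draws >= 0))
    return float(min(max(p, 1.0 / n), 1.0))


def quasi_bayes_mediate(tobit: TobitFit, outcome: OutcomeFit,
                        z0: float | np.ndarray, z1: float | np.ndarray,
                        covariate_rows: pd.DataFrame | np.ndarray,
                        n_sims: int = 1000, seed: int = 0,
                        stratum: str = "pooled", horizon: int = 120,
                        model_label: str | None = None) -> MediationEstimate:
    """Quasi-Bayesian decomposition of the z0 -> z1 carbohydrate contrast.

    Per Monte-Carlo draw, mediator and outcome parameters are sampled from
    normal approximations at the fitted estimates; potential bolus doses
    ``M(z)`` are simulated per unit with fresh latent noise and censoring at
    zero; counterfactual outcomes are the model-implied means at the four
    (z, M(z')) combinations (random intercepts integrated out).  ACME and
    ADE average their two z-specific versions; Total = ACME + ADE holds
    exactly per draw.
    """
    if n_sims < 100:
        log.warning("n_sims=%d is small; intervals will be unstable", n_sims)
    Xc = covariate_rows.to_numpy(float) if isinstance(covariate_rows, pd.DataFrame) \
        else np.asarray(covariate_rows, float)
    if Xc.ndim == 1:
        Xc = Xc[:, None]
    n_units = len(Xc)
    z0 = np.broadcast_to(np.asarray(z0, float), (n_units,))
    z1 = np.broadcast_to(np.asarray(z1, float), (n_units,))

    rng = np.random.default_rng(seed)
    med_draws = _draw_params(tobit.params, tobit.cov, rng, n_sims)
    out_draws = _draw_params(outcome.beta, outcome.cov, rng, n_sims)

    # mediator design: intercept, Z, PCs; outcome: intercept, Z, M, PCs
    acme = np.empty(n_sims)
    ade = np.empty(n_sims)
    for s in range(n_sims):
        bm = med_draws[s]
        beta_m, sigma_m = bm[:-1], max(bm[-1], 1e-3)
        mu0 = beta_m[0] + beta_m[1] * z0 + Xc @ beta_m[2:]
        mu1 = beta_m[0] + beta_m[1] * z1 + Xc @ beta_m[2:]
        m0 = np.maximum(0.0, mu0 + sigma_m * rng.standard_normal(n_units))
        m1 = np.maximum(0.0, mu1 + sigma_m * rng.standard_normal(n_units))
        bo = out_draws[s]

        def y_mean(z, m):
            return bo[0] + bo[1] * z + bo[2] * m + Xc @ bo[3:]

        # z-specific effects, then their average
        acme_z1 = np.mean(y_mean(z1, m1) - y_mean(z1, m0))
        acme_z0 = np.mean(y_mean(z0, m1) - y_mean(z0, m0))
        ade_m1 = np.mean(y_mean(z1, m1) - y_mean(z0, m1))
        ade_m0 = np.mean(y_mean(z1, m0) - y_mean(z0, m0))
        acme[s] = 0.5 * (acme_z1 + acme_z0)
        ade[s] = 0.5 * (ade_m1 + ade_m0)
    total = acme + ade

    def summarize(d):
        return (float(d.mean()),
                (float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5))),
                _mc_p(d))

    a, a_ci, a_p = summarize(acme)
    d, d_ci, d_p = summarize(ade)
    t, t_ci, t_p = summarize(total)
    label = model_label or ("mean" if outcome.kind == "mixed"
                            else f"q{int(round((outcome.tau or 0.5) * 100))}")
    return MediationEstimate(
        stratum=stratum, horizon=horizon, dose=float(np.mean(z1 - z0)),
        model=label,
        acme=a, acme_ci=a_ci, acme_p=a_p,
        ade=d, ade_ci=d_ci, ade_p=d_p,
        total=t, total_ci=t_ci, total_p=t_p,
        n=n_units, n_sims=n_sims, seed=seed,
        z0=float(np.mean(z0)), z1=float(np.mean(z1)))


# ---------------------------------------------------------------------------
# suite over strata x horizons x doses x models
# ---------------------------------------------------------------------------

@dataclass
class MediationSpec:
    doses: tuple[float, ...] = (15.0, 30.0, 45.0)
    horizons: tuple[int, ...] = HORIZONS
    taus: tuple[float, ...] = (0.25, 0.5, 0.75)
    include_mean: bool = True
    n_sims: int = 1000
    n_boot: int = 200
    seed: int = 0
    min_stratum_n: int = 20
    weight_mediator: bool = True       # fit the Tobit with balance weights


def run_suite(analysis: pd.DataFrame, spec: MediationSpec | None = None
              ) -> pd.DataFrame:
    """Full mediation grid over {pooled, meal types} x horizons x doses x
    {mean model, quantile taus}.

    ``analysis`` must contain columns: subject_id, meal_type, Z, M,
    delta_g_<t> for each horizon, weight, and PC columns named pc1..pck.
    Treatment anchors z0 are per-meal-type medians computed from this
    analysis sample; the pooled stratum uses each window's own meal-type
    median.  Strata below ``min_stratum_n`` are skipped and logged.
    """
    spec = spec or MediationSpec()
    pc_cols = [c for c in analysis.columns if c.startswith("pc")]
    medians = analysis.groupby("meal_type")["Z"].median()
    rows = []
    strata = ["pooled"] + [m for m in MEAL_TYPES
                           if m in set(analysis.meal_type)]
    root = np.random.SeedSequence(spec.seed)
    for si, stratum in enumerate(strata):
        sub = analysis if stratum == "pooled" \
            else analysis[analysis.meal_type == stratum]
        if len(sub) < spec.min_stratum_n:
            log.info("stratum %s skipped: n=%d below floor %d", stratum,
                     len(sub), spec.min_stratum_n)
            continue
        w = sub["weight"].to_numpy(float)
        med_design = sub[["Z"] + pc_cols]
        try:
            tobit = fit_tobit(sub["M"].to_numpy(float), med_design,
                              w if spec.weight_mediator else None)
        except ValidationError as err:
            log.warning("stratum %s: Tobit fit failed (%s); skipped",
                        stratum, err)
            continue
        z0 = sub["meal_type"].map(medians).to_numpy(float)
        covs = sub[pc_cols]
        models: list[tuple[str, float | None]] = []
        if spec.include_mean:
            models.append(("mean", None))
        models += [(f"q{int(round(t * 100))}", t) for t in spec.taus]
        for t_idx, horizon in enumerate(spec.horizons):
            y = sub[f"delta_g_{horizon}"].to_numpy(float)
            out_design = sub[["Z", "M"] + pc_cols]
            for label, tau in models:
                child = np.random.SeedSequence(
                    [spec.seed, si, t_idx, int((tau or 0) * 100)])
                sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
                try:
                    if tau is None:
                        fit = fit_outcome(y, out_design, w, "mixed",
                                          subjects=sub["subject_id"])
                    else:
                        fit = fit_outcome(y, out_design, w, "quantile",
                                          subjects=sub["subject_id"], tau=tau,
                                          n_boot=spec.n_boot, seed=sub_seed)
                except (ValidationError, RuntimeError) as err:
                    log.warning("stratum %s h=%d %s: outcome fit failed (%s)",
                                stratum, horizon, label, err)
                    continue
                for dose in spec.doses:
                    est = quasi_bayes_mediate(
                        tobit, fit, z0, z0 + dose, covs,
                        n_sims=spec.n_sims, seed=sub_seed,
                        stratum=stratum, horizon=horizon, model_label=label)
                    rows.append(est.as_row())
    return pd.DataFrame(rows)


def report_tables(estimates: pd.DataFrame, *, table4_horizon: int = 120,
                  table4_dose: float = 30.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dose-by-horizon and meal-by-model summary tables.

    The first table lists, per stratum and model, each (horizon, dose) cell
    with ACME/ADE/Total, CIs and p-values, significance flagged at p<0.05.
    The second compares strata and outcome models at one (horizon, dose).
    """
    if estimates.empty:
        return pd.DataFrame(), pd.DataFrame()
    t3 = estimates.copy().sort_values(["stratum", "model", "horizon", "dose"])
    for eff in ("acme", "ade", "total"):
        t3[f"{eff}_sig"] = t3[f"{eff}_p"] < 0.05
    cols3 = ["stratum", "model", "horizon", "dose"] + [
        f"{e}{s}" for e in ("acme", "ade", "total")
        for s in ("", "_lo", "_hi", "_p", "_sig")]
    t4 = estimates[(estimates.horizon == table4_horizon)
                   & (np.isclose(estimates.dose, table4_dose))]
    cols4 = ["stratum", "model"] + [f"{e}{s}" for e in ("ade", "acme", "total")
                                    for s in ("", "_p")]
    t4 = t4.copy()
    return t3[cols3].reset_index(drop=True), \
        t4[[c for c in cols4 if c in t4.columns]].reset_index(drop=True)
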