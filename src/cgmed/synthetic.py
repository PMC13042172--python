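"""Synthetic meal-centered CGM event logs with known mediation structure.

The generator emulates the statistical structure of pump/CGM study data
(5-minute interstitial glucose, self-reported carbohydrate meals, bolus
events, basal rates, wrist-band heart rate and steps) under an explicit
structural model, so that every downstream stage of the pipeline can be
checked against analytic ground truth:

* a per-meal latent state ``U`` (standard normal) confounds everything: it
  shifts the pre-meal glucose level, the carbohydrate dose, the bolus, and
  the outcome;
* the treatment ``Z`` is the meal-type median carbohydrate dose plus noise
  correlated with ``U`` (confounding strength ``rho``);
* the mediator is a left-censored bolus: ``M = max(0, alpha0 + a*Z + gamma'U
  + eps_M)``, materialized as bolus events inside the mediator window;
* the glucose excursion at horizon ``t`` is
  ``dG(t) = c(t)*Z + b(t)*M + kappa'U + eps_Y(t)``,
  built into the post-meal CGM trace so that window extraction recovers it.

The closed-form ACME/ADE implied by these equations (:func:`true_acme`,
:func:`true_ade`) are the oracles for the mediation engine.  This is a
statistical emulator, not a physiological insulin PK/PD simulator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import interpolate, stats

from . import GRID_MINUTES, HORIZONS, MEAL_TYPES

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "MealEventLog",
    "ValidationError",
    "simulate_cohort",
    "simulate_flat_mediation_table",
    "true_acme",
    "true_ade",
    "true_total",
    "censored_normal_mean",
    "alpha0_for_zero_fraction",
    "write_logs",
    "read_logs",
]

DOSES = (15.0, 30.0, 45.0)

#: minute-of-day slots for up to four meals; spaced 360 min so each meal's
#: [-120, +210] analysis neighbourhood is free of the previous meal's response
#: (responses wash out by +240).
MEAL_SLOTS = (240, 600, 960, 1320)
SLOT_TYPES = ("breakfast", "lunch", "dinner", "snack")
WASHOUT_MIN = 240  # minutes after a meal by which its response has decayed to 0

DAY_MIN = 1440


class ValidationError(ValueError):
    """A configuration or input failed a named validation rule."""


def _default_medians() -> dict[str, float]:
    # approximate pooled medians of typical T1DM study meals
    return {"breakfast": 47.0, "lunch": 65.0, "dinner": 63.0, "snack": 27.0}


def _default_direct() -> dict[int, float]:
    # mg/dL per gram, peaking near 120 min
    return {60: 0.23, 90: 0.43, 120: 0.49, 150: 0.38, 180: 0.39, 210: 0.39}


def _default_mediated() -> dict[int, float]:
    # mg/dL per unit of insulin (negative: insulin lowers glucose)
    return {60: -1.4, 90: -2.7, 120: -3.2, 150: -2.5, 180: -2.4, 210: -1.9}


def _default_alpha0() -> dict[str, float]:
    # per-stratum mediator intercepts (U) targeting realistic zero-bolus
    # rates: ~8% breakfast/lunch, ~11% dinner, ~20% snack
    return {"breakfast": -0.55, "lunch": -2.45, "dinner": -2.65,
            "snack": -0.3}


def _default_modifiers() -> dict[str, dict[str, float]]:
    # multiplicative meal-type modifiers on (a, b, c): amplified but nearly
    # cancelling pathways in the morning, under-compensated evening meals,
    # weak coupling at lunch/snack
    return {
        "breakfast": {"a": 1.0, "b": 1.5, "c": 1.5},
        "lunch": {"a": 1.0, "b": 0.6, "c": 0.6},
        "dinner": {"a": 1.0, "b": 1.0, "c": 2.0},
        "snack": {"a": 0.8, "b": 0.4, "c": 0.4},
    }


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults define the study conditions.

    Units: carbohydrates in grams, insulin in units (U), glucose in mg/dL,
    time in minutes on a 5-minute grid.
    """

    n_subjects: int = 12
    days_per_subject: int = 56
    meals_per_day: int = 4
    meal_type_carb_medians: dict[str, float] = field(default_factory=_default_medians)
    carb_sd: float = 20.0
    mediator_intercept: float = 0.8      # alpha0 fallback, units
    #: per-stratum alpha0 overrides (censoring knobs); a meal type absent
    #: from this map falls back to mediator_intercept
    meal_type_alpha0: dict[str, float] = field(default_factory=_default_alpha0)
    mediator_slope: float = 0.1          # a, units per gram (1:10 insulin:carb)
    mediator_confound: tuple[float, ...] = (0.6, 0.3)   # gamma, U per latent unit
    mediator_noise_sd: float = 2.0       # sigma_M, units
    direct_slope: dict[int, float] = field(default_factory=_default_direct)     # c(t)
    mediated_slope: dict[int, float] = field(default_factory=_default_mediated)  # b(t)
    outcome_confound: tuple[float, ...] = (8.0, 4.0)    # kappa, mg/dL per latent unit
    outcome_noise_sd: float = 22.0       # sigma_Y, mg/dL
    latent_dim: int = 2
    meal_type_modifiers: dict[str, dict[str, float]] = field(default_factory=_default_modifiers)
    seed: int = 0

    # treatment confounding: corr(Z, U1) target; 0.4 makes balancing
    # necessary but feasible
    treatment_confound_rho: float = 0.4
    # pre-meal glucose level shift per latent unit (makes U recoverable from
    # the pre-meal window, i.e. an observable confounder)
    premeal_level_confound: tuple[float, ...] = (12.0, 6.0)
    baseline_glucose: float = 145.0
    ar_coef: float = 0.9
    ar_innovation_sd: float = 5.0

    gap_rate: float = 0.003       # per-point probability of starting a CGM gap
    artifact_rate: float = 0.001  # per-point probability of an artifact spike
    meal_time_jitter_min: int = 7  # uniform +/- jitter (minutes, off-grid)

    # location-shift outcome noise by default; scale-shift mode makes the
    # noise SD increase with Z to create genuine quantile heterogeneity
    scale_shift_coef: float = 0.0
    # one bolus event at meal time by default; optionally split across two
    split_bolus_events: bool = False

    def validate(self) -> None:
        if self.carb_sd <= 0 or self.mediator_noise_sd <= 0 or self.outcome_noise_sd <= 0:
            raise ValidationError("all SDs must be > 0")
        if self.ar_innovation_sd <= 0:
            raise ValidationError("ar_innovation_sd must be > 0")
        if set(self.meal_type_carb_medians) != set(MEAL_TYPES):
            raise ValidationError(
                f"meal_type_carb_medians keys must be exactly {set(MEAL_TYPES)}"
            )
        for table, name in ((self.direct_slope, "direct_slope"),
                            (self.mediated_slope, "mediated_slope")):
            if set(table) != set(HORIZONS):
                raise ValidationError(f"{name} must have exactly horizons {HORIZONS}")
        if self.days_per_subject < 2:
            raise ValidationError("days_per_subject must be >= 2 (chronological split)")
        if not 1 <= self.meals_per_day <= len(MEAL_SLOTS):
            raise ValidationError(f"meals_per_day must be in [1, {len(MEAL_SLOTS)}]")
        for mt in self.meal_type_modifiers:
            if mt not in MEAL_TYPES:
                raise ValidationError(f"unknown meal type in modifiers: {mt!r}")
        for mt in self.meal_type_alpha0:
            if mt not in MEAL_TYPES:
                raise ValidationError(
                    f"unknown meal type in meal_type_alpha0: {mt!r}")
        if len(self.mediator_confound) != self.latent_dim:
            raise ValidationError("mediator_confound length must equal latent_dim")
        if len(self.outcome_confound) != self.latent_dim:
            raise ValidationError("outcome_confound length must equal latent_dim")
        if len(self.premeal_level_confound) != self.latent_dim:
            raise ValidationError("premeal_level_confound length must equal latent_dim")

    def modifier(self, meal_type: str, key: str) -> float:
        return self.meal_type_modifiers.get(meal_type, {}).get(key, 1.0)

    def alpha0(self, meal_type: str) -> float:
        return self.meal_type_alpha0.get(meal_type, self.mediator_intercept)


@dataclass
class MealEventLog:
    """Raw per-subject event streams (one study participant)."""

    subject_id: str
    cohort: str                  # "2018" or "2020"
    cgm: pd.DataFrame            # columns: timestamp_min, glucose (NaN = gap)
    boluses: pd.DataFrame        # columns: timestamp_min, units
    basal: pd.DataFrame          # columns: timestamp_min, rate_u_hr (step fn)
    meals: pd.DataFrame          # columns: timestamp_min, carbs_g, meal_type
    heart_rate: pd.DataFrame     # columns: timestamp_min, bpm
    steps: pd.DataFrame          # columns: timestamp_min, count
    #: per-meal latent confounder draws; emitted for oracle adjustment tests
    #: only -- NOT available to the analysis pipeline.
    latent_u: pd.DataFrame | None = None


@dataclass
class SyntheticTruth:
    """Analytic ACME/ADE/Total per (meal type, horizon, dose), plus the
    generator coefficients they were derived from."""

    table: pd.DataFrame          # meal_type, horizon, dose, acme, ade, total
    config: SyntheticConfig

    def lookup(self, meal_type: str, t: int, dose: float) -> dict[str, float]:
        row = self.table[
            (self.table.meal_type == meal_type)
            & (self.table.horizon == t)
            & (np.isclose(self.table.dose, dose))
        ]
        if row.empty:
            raise KeyError((meal_type, t, dose))
        r = row.iloc[0]
        return {"acme": r.acme, "ade": r.ade, "total": r.total}


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def censored_normal_mean(mu: float, sigma: float) -> float:
    """E[max(0, X)] for X ~ N(mu, sigma^2):  mu*Phi(mu/s) + s*phi(mu/s)."""
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    z = mu / sigma
    return float(mu * stats.norm.cdf(z) + sigma * stats.norm.pdf(z))


def true_acme(cfg: SyntheticConfig, meal_type: str, t: int, dose: float) -> float:
    """Analytic insulin-mediated effect of a +dose g contrast at horizon t.

    The latent confounder is integrated out at its mean (0), so the mediator
    mean at carbohydrate level z is ``mu_z = alpha0 + a*z`` and

        ACME = b(t) * (E max(0, N(mu_z1, s^2)) - E max(0, N(mu_z0, s^2)))

    with z0 the meal-type median and z1 = z0 + dose.
    """
    if dose <= 0:
        raise ValidationError("dose must be > 0")
    if t not in HORIZONS:
        raise ValidationError(f"horizon {t} not in {HORIZONS}")
    if meal_type not in MEAL_TYPES:
        raise ValidationError(f"unknown meal type {meal_type!r}")
    a = cfg.mediator_slope * cfg.modifier(meal_type, "a")
    b = cfg.mediated_slope[t] * cfg.modifier(meal_type, "b")
    z0 = cfg.meal_type_carb_medians[meal_type]
    alpha0 = cfg.alpha0(meal_type)
    mu0 = alpha0 + a * z0
    mu1 = alpha0 + a * (z0 + dose)
    s = cfg.mediator_noise_sd
    return b * (censored_normal_mean(mu1, s) - censored_normal_mean(mu0, s))


def true_ade(cfg: SyntheticConfig, meal_type: str, t: int, dose: float) -> float:
    """Analytic direct effect: c(t) * dose (meal-type modified)."""
    if dose <= 0:
        raise ValidationError("dose must be > 0")
    if t not in HORIZONS:
        raise ValidationError(f"horizon {t} not in {HORIZONS}")
    return cfg.direct_slope[t] * cfg.modifier(meal_type, "c") * dose


def true_total(cfg: SyntheticConfig, meal_type: str, t: int, dose: float) -> float:
    return true_acme(cfg, meal_type, t, dose) + true_ade(cfg, meal_type, t, dose)


def _truth_table(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for mt in MEAL_TYPES:
        for t in HORIZONS:
            for d in DOSES:
                acme = true_acme(cfg, mt, t, d)
                ade = true_ade(cfg, mt, t, d)
                rows.append(
                    {"meal_type": mt, "horizon": t, "dose": d,
                     "acme": acme, "ade": ade, "total": acme + ade}
                )
    return pd.DataFrame(rows)


def alpha0_for_zero_fraction(cfg: SyntheticConfig, meal_type: str,
                             target_fraction: float) -> float:
    """Mediator intercept yielding approximately the target zero-bolus rate.

    Uses a marginal normal approximation of the latent bolus, with the
    positivity truncation of the carbohydrate draw accounted for through
    truncated-normal moments:  M* ~ N(alpha0 + a*E[Z], a^2 Var[Z] +
    |gamma|^2 + sigma_M^2), solving P(M* <= 0) = target.  Assign the
    result to ``cfg.meal_type_alpha0[meal_type]``; per-stratum entries take
    precedence over the scalar ``mediator_intercept``.
    """
    if not 0 < target_fraction < 1:
        raise ValidationError("target_fraction must be in (0, 1)")
    a = cfg.mediator_slope * cfg.modifier(meal_type, "a")
    mu_z = cfg.meal_type_carb_medians[meal_type]
    lo = (0.5 - mu_z) / cfg.carb_sd
    mean_z, var_z = stats.truncnorm.stats(lo, np.inf, loc=mu_z,
                                          scale=cfg.carb_sd, moments="mv")
    var = a ** 2 * float(var_z) \
        + float(np.sum(np.square(cfg.mediator_confound))) \
        + cfg.mediator_noise_sd ** 2
    return float(-a * float(mean_z)
                 - np.sqrt(var) * stats.norm.ppf(target_fraction))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _response_curve(delta_at_horizons: np.ndarray) -> np.ndarray:
    """Glucose excursion at +5..+210 min (42 points) passing exactly through
    the configured deltas at the six horizons, monotone-spline interpolated."""
    knots_t = np.concatenate([[0.0], np.array(HORIZONS, dtype=float)])
    knots_v = np.concatenate([[0.0], delta_at_horizons])
    f = interpolate.PchipInterpolator(knots_t, knots_v)
    return f(np.arange(5, 211, GRID_MINUTES, dtype=float))


def _simulate_subject(cfg: SyntheticConfig, subject_id: str, cohort: str,
                      rng: np.random.Generator) -> MealEventLog:
    # extra washout tail so the last meal's full window is observed
    n_pts = (cfg.days_per_subject * DAY_MIN + WASHOUT_MIN) // GRID_MINUTES
    grid = np.arange(n_pts) * GRID_MINUTES

    # --- meal schedule ------------------------------------------------
    meal_rows = []
    for day in range(cfg.days_per_subject):
        for j in range(cfg.meals_per_day):
            slot = day * DAY_MIN + MEAL_SLOTS[j]
            jitter = int(rng.integers(-cfg.meal_time_jitter_min,
                                      cfg.meal_time_jitter_min + 1))
            meal_rows.append({"timestamp_min": slot + jitter,
                              "meal_type": SLOT_TYPES[j]})
    meals = pd.DataFrame(meal_rows)
    n_meals = len(meals)

    # --- structural draws ---------------------------------------------
    U = rng.standard_normal((n_meals, cfg.latent_dim))
    rho = cfg.treatment_confound_rho
    z_noise = rng.standard_normal(n_meals)
    medians = meals.meal_type.map(cfg.meal_type_carb_medians).to_numpy(float)
    z_raw = medians + cfg.carb_sd * (rho * U[:, 0] + np.sqrt(1 - rho ** 2) * z_noise)
    # truncate positive by resampling from the conditional (truncated normal)
    neg = z_raw <= 0.5
    if neg.any():
        lo = (0.5 - medians[neg]) / cfg.carb_sd
        z_raw[neg] = stats.truncnorm.rvs(
            lo, np.inf, loc=medians[neg], scale=cfg.carb_sd, random_state=rng)
    Z = z_raw

    a_mod = meals.meal_type.map(lambda m: cfg.modifier(m, "a")).to_numpy(float)
    alpha0 = meals.meal_type.map(cfg.alpha0).to_numpy(float)
    m_latent = (alpha0 + cfg.mediator_slope * a_mod * Z
                + U @ np.asarray(cfg.mediator_confound)
                + cfg.mediator_noise_sd * rng.standard_normal(n_meals))
    M = np.maximum(0.0, m_latent)

    # --- baseline CGM: AR(1) around a U-shifted level -------------------
    level_shift = U @ np.asarray(cfg.premeal_level_confound)
    meal_idx_snapped = _snap(meals.timestamp_min.to_numpy())
    # level target per grid point: each meal governs the segment up to and
    # including its own snapped time, starting after the previous washout
    level = np.full(n_pts, cfg.baseline_glucose)
    boundaries = meal_idx_snapped // GRID_MINUTES
    prev_end = 0
    for k in range(n_meals):
        seg_end = min(boundaries[k] + 1, n_pts)
        level[prev_end:seg_end] = cfg.baseline_glucose + level_shift[k]
        prev_end = min(boundaries[k] + WASHOUT_MIN // GRID_MINUTES, n_pts)
    glucose = np.empty(n_pts)
    glucose[0] = level[0] + cfg.ar_innovation_sd * rng.standard_normal()
    innov = cfg.ar_innovation_sd * rng.standard_normal(n_pts)
    for i in range(1, n_pts):
        glucose[i] = level[i] + cfg.ar_coef * (glucose[i - 1] - level[i]) + innov[i]

    # --- post-meal response overwrite ----------------------------------
    b_mod = meals.meal_type.map(lambda m: cfg.modifier(m, "b")).to_numpy(float)
    c_mod = meals.meal_type.map(lambda m: cfg.modifier(m, "c")).to_numpy(float)
    b_vec = np.array([cfg.mediated_slope[t] for t in HORIZONS])
    c_vec = np.array([cfg.direct_slope[t] for t in HORIZONS])
    kap = np.asarray(cfg.outcome_confound)
    z_med = medians
    for k in range(n_meals):
        i0 = boundaries[k]
        n_post = 210 // GRID_MINUTES          # 42 points at +5..+210
        n_wash = (WASHOUT_MIN - 210) // GRID_MINUTES  # 6 points at +215..+240
        if i0 + n_post + n_wash >= n_pts:
            continue  # truncated at end of study; window will be incomplete
        sd = cfg.outcome_noise_sd
        if cfg.scale_shift_coef:
            sd = sd * max(0.2, 1.0 + cfg.scale_shift_coef * (Z[k] - z_med[k]) / cfg.carb_sd)
        eps_y = sd * rng.standard_normal(len(HORIZONS))
        deltas = (c_vec * c_mod[k] * Z[k] + b_vec * b_mod[k] * M[k]
                  + float(U[k] @ kap) + eps_y)
        g0 = glucose[i0]
        glucose[i0 + 1:i0 + 1 + n_post] = g0 + _response_curve(deltas)
        # linear washout back to the baseline process
        end_val = glucose[i0 + n_post]
        target = glucose[i0 + n_post + n_wash]
        w = np.linspace(0, 1, n_wash + 1)[1:]
        glucose[i0 + n_post + 1:i0 + n_post + n_wash + 1] = (1 - w) * end_val + w * target
    glucose = np.clip(glucose, 22.0, 498.0)

    # --- gaps and artifacts --------------------------------------------
    gap_starts = np.flatnonzero(rng.random(n_pts) < cfg.gap_rate)
    for s in gap_starts:
        length = min(int(rng.geometric(0.3)), 12)
        glucose[s:s + length] = np.nan
    art = np.flatnonzero(rng.random(n_pts) < cfg.artifact_rate)
    if art.size:
        glucose[art] = rng.choice([10.0, 540.0], size=art.size)

    # --- other streams --------------------------------------------------
    hr = 75 + 8 * _ar1(n_pts, 0.95, rng)
    step_active = rng.random(n_pts) < 0.15
    steps = np.where(step_active, rng.poisson(120, n_pts), rng.poisson(3, n_pts))
    basal_times = np.arange(0, cfg.days_per_subject * DAY_MIN, 360)
    basal_rates = np.clip(1.0 + 0.2 * rng.standard_normal(len(basal_times)), 0.2, 3.0)

    # --- bolus events ----------------------------------------------------
    bolus_rows = []
    for k in range(n_meals):
        if M[k] <= 0:
            continue
        t_meal = int(meals.timestamp_min.iloc[k])
        if cfg.split_bolus_events:
            bolus_rows.append({"timestamp_min": t_meal - 10, "units": 0.6 * M[k]})
            bolus_rows.append({"timestamp_min": t_meal + 30, "units": 0.4 * M[k]})
        else:
            bolus_rows.append({"timestamp_min": t_meal, "units": M[k]})

    meals_out = meals.assign(carbs_g=Z)[["timestamp_min", "carbs_g", "meal_type"]]
    latent = pd.DataFrame(U, columns=[f"u{j + 1}" for j in range(cfg.latent_dim)])
    latent.insert(0, "timestamp_min", meals.timestamp_min.to_numpy())
    latent["mediator_latent"] = m_latent

    return MealEventLog(
        subject_id=subject_id,
        cohort=cohort,
        cgm=pd.DataFrame({"timestamp_min": grid, "glucose": glucose}),
        boluses=pd.DataFrame(bolus_rows, columns=["timestamp_min", "units"]),
        basal=pd.DataFrame({"timestamp_min": basal_times, "rate_u_hr": basal_rates}),
        meals=meals_out,
        heart_rate=pd.DataFrame({"timestamp_min": grid, "bpm": hr}),
        steps=pd.DataFrame({"timestamp_min": grid, "count": steps}),
        latent_u=latent,
    )


def _ar1(n: int, coef: float, rng: np.random.Generator) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.standard_normal()
    e = np.sqrt(1 - coef ** 2) * rng.standard_normal(n)
    for i in range(1, n):
        x[i] = coef * x[i - 1] + e[i]
    return x


def _snap(times: np.ndarray) -> np.ndarray:
    """Snap minute timestamps to the nearest 5-minute grid point, ties down."""
    t = np.asarray(times, dtype=float)
    down = np.floor(t / GRID_MINUTES) * GRID_MINUTES
    frac = t - down
    return np.where(frac > GRID_MINUTES / 2, down + GRID_MINUTES, down).astype(int)


def simulate_cohort(cfg: SyntheticConfig) -> tuple[list[MealEventLog], SyntheticTruth]:
    """Simulate per-subject event logs plus the analytic effect table.

    Deterministic given ``cfg.seed``.  Subjects are split between the two
    cohort labels; subject IDs encode the cohort.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_subjects)
    logs = []
    for i, ss in enumerate(children):
        cohort = "2018" if i < (cfg.n_subjects + 1) // 2 else "2020"
        sid = f"S{cohort}-{i:02d}"
        logs.append(_simulate_subject(cfg, sid, cohort, np.random.default_rng(ss)))
    return logs, SyntheticTruth(table=_truth_table(cfg), config=cfg)


# ---------------------------------------------------------------------------
# flat single-horizon fixture
# ---------------------------------------------------------------------------

def simulate_flat_mediation_table(
    n: int,
    a: float,
    b: float,
    c: float,
    censor: bool = True,
    seed: int = 0,
    *,
    alpha0: float = 1.0,
    sigma_m: float = 2.0,
    sigma_y: float = 10.0,
    rho: float = 0.0,
    gamma: Sequence[float] = (0.0, 0.0, 0.0),
    kappa: Sequence[float] = (0.0, 0.0, 0.0),
    z_center: float = 50.0,
    z_sd: float = 20.0,
    n_subjects: int = 20,
    subject_sd: float = 0.0,
    scale_shift_coef: float = 0.0,
) -> pd.DataFrame:
    """Single-horizon table (Z, M, Y, X1..Xk, subject) from the same
    structural equations as the cohort generator, without the time-series
    layer.  Minimal fixture for the mediation-engine oracle tests.

    Y = c*Z + b*M + kappa'X + subject intercept + noise;
    M = max(0, alpha0 + a*Z + gamma'X + eps) when ``censor`` else uncensored.
    """
    if n < 10:
        raise ValidationError("n must be >= 10")
    gamma = np.asarray(gamma, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if gamma.shape != kappa.shape:
        raise ValidationError("gamma and kappa must have equal length")
    k = len(gamma)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    z_noise = rng.standard_normal(n)
    x1 = X[:, 0] if k else np.zeros(n)
    Z = z_center + z_sd * (rho * x1 + np.sqrt(1 - rho ** 2) * z_noise)
    Z = np.maximum(Z, 1.0)
    m_latent = alpha0 + a * Z + X @ gamma + sigma_m * rng.standard_normal(n)
    M = np.maximum(0.0, m_latent) if censor else m_latent
    subj = rng.integers(0, n_subjects, n)
    intercepts = subject_sd * rng.standard_normal(n_subjects)
    sd = sigma_y * np.maximum(0.2, 1.0 + scale_shift_coef * (Z - z_center) / z_sd)
    Y = c * Z + b * M + X @ kappa + intercepts[subj] + sd * rng.standard_normal(n)
    out = pd.DataFrame({"Z": Z, "M": M, "Y": Y})
    for j in range(k):
        out[f"X{j + 1}"] = X[:, j]
    out["subject"] = pd.Series(subj).map(lambda s: f"S{s:02d}")
    return out


# ---------------------------------------------------------------------------
# I/O: delimited text streams, one file per stream type
# ---------------------------------------------------------------------------

_STREAMS = ("cgm", "boluses", "basal", "meals", "heart_rate", "steps", "latent_u")


def write_logs(logs: Sequence[MealEventLog], outdir: str | Path,
               truth: SyntheticTruth | None = None) -> None:
    """Write event logs as CSV tables (one file per stream, subject column
    prepended) plus subjects.csv and, optionally, the truth table + config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stream in _STREAMS:
        frames = []
        for log in logs:
            df = getattr(log, stream)
            if df is None:
                continue
            frames.append(df.assign(subject_id=log.subject_id))
        if frames:
            combined = pd.concat(frames, ignore_index=True)
            cols = ["subject_id"] + [c for c in combined.columns if c != "subject_id"]
            combined[cols].to_csv(outdir / f"{stream}.csv", index=False)
    pd.DataFrame(
        [{"subject_id": log.subject_id, "cohort": log.cohort} for log in logs]
    ).to_csv(outdir / "subjects.csv", index=False)
    if truth is not None:
        truth.table.to_csv(outdir / "truth.csv", index=False)
        with open(outdir / "truth_config.yaml", "w") as fh:
            yaml.safe_dump(_config_to_dict(truth.config), fh, sort_keys=False)


def _config_to_dict(cfg: SyntheticConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["direct_slope"] = {int(k): float(v) for k, v in d["direct_slope"].items()}
    d["mediated_slope"] = {int(k): float(v) for k, v in d["mediated_slope"].items()}
    for key in ("mediator_confound", "outcome_confound", "premeal_level_confound"):
        d[key] = [float(v) for v in d[key]]
    return d


def config_from_dict(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    for key in ("mediator_confound", "outcome_confound", "premeal_level_confound"):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("direct_slope", "mediated_slope"):
        if key in d:
            d[key] = {int(k): float(v) for k, v in d[key].items()}
    return SyntheticConfig(**d)


def read_logs(indir: str | Path) -> list[MealEventLog]:
    """Read logs previously written by :func:`write_logs`."""
    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.csv", dtype={"cohort": str})
    streams = {}
    for stream in _STREAMS:
        path = indir / f"{stream}.csv"
        streams[stream] = pd.read_csv(path) if path.exists() else None
    logs = []
    for _, row in subjects.iterrows():
        kwargs = {}
        for stream in _STREAMS:
            df = streams[stream]
            if df is None:
                kwargs[stream] = None
                continue
            sub = df[df.subject_id == row.subject_id].drop(columns="subject_id")
            kwargs[stream] = sub.reset_index(drop=True)
        logs.append(MealEventLog(subject_id=row.subject_id, cohort=str(row.cohort),
                                 **kwargs))
    return logs
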