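"""End-to-end composition of the pipeline stages.

Chains event logs -> meal windows -> chronological split -> embeddings ->
balancing weights -> mediation suite, matching the study design: models are
fit on the held-out (test) partition, balance weights are estimated from
the six leading embedding PCs plus meal-time glucose and a centered cohort
indicator, while the mediation formulas use only the three leading PCs
(meal-time glucose and cohort stay out of them to avoid collider paths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import HORIZONS
from .balancing import BalanceResult, estimate_weights
from .clae import CLAEConfig, CLAEModel, fit_pca, train_clae
from .mediation import MediationSpec, run_suite
from .preprocessing import (MealWindow, SplitSpec, apply_exclusions,
                            chronological_split, extract_windows,
                            interpolate_gaps, standardize_pre_matrices)
from .synthetic import MealEventLog

log = logging.getLogger(__name__)

__all__ = ["preprocess_logs", "build_analysis_frame", "run_pipeline",
           "PipelineResult"]


def preprocess_logs(logs: Sequence[MealEventLog]
                    ) -> tuple[list[MealWindow], dict[str, int]]:
    """Interpolate CGM gaps, extract windows, apply exclusions."""
    windows: list[MealWindow] = []
    for lg in logs:
        lg.cgm, _ = interpolate_gaps(lg.cgm)
        windows.extend(extract_windows(lg))
    return apply_exclusions(windows)


def build_analysis_frame(model: CLAEModel,
                         windows_train: Sequence[MealWindow],
                         windows_test: Sequence[MealWindow],
                         *, trim_cap: float | None = None
                         ) -> tuple[pd.DataFrame, BalanceResult]:
    """Analysis-sample table with mediation PCs and balance weights.

    PCA loadings are fit on training embeddings only; weights are estimated
    on the analysis (test) sample from the 6-PC + meal-time glucose +
    cohort balance model.
    """
    phi_train = model.encode_np(standardize_pre_matrices(windows_train,
                                                         model.split))
    phi_test = model.encode_np(standardize_pre_matrices(windows_test,
                                                        model.split))
    pca6 = fit_pca(phi_train, "balancing")
    pca3 = fit_pca(phi_train, "mediation")
    x6 = pca6.transform(phi_test)
    x3 = pca3.transform(phi_test)

    df = pd.DataFrame({
        "subject_id": [w.subject_id for w in windows_test],
        "cohort": [w.cohort for w in windows_test],
        "meal_type": [w.meal_type for w in windows_test],
        "meal_time": [w.meal_time for w in windows_test],
        "Z": [w.Z for w in windows_test],
        "M": [w.M for w in windows_test],
        "G0": [w.G0 for w in windows_test],
    })
    for t in HORIZONS:
        df[f"delta_g_{t}"] = [w.delta_g[t] for w in windows_test]
    for j in range(x3.shape[1]):
        df[f"pc{j + 1}"] = x3[:, j]

    cohorts = sorted(df.cohort.unique())
    indicator = (df.cohort == cohorts[-1]).astype(float)
    balance_covs = pd.DataFrame(
        {f"bpc{j + 1}": x6[:, j] for j in range(x6.shape[1])})
    balance_covs["glucose_0"] = df["G0"].to_numpy()
    if indicator.nunique() > 1:
        balance_covs["cohort"] = (indicator - indicator.mean()).to_numpy()
    result = estimate_weights(df["Z"].to_numpy(), balance_covs,
                              trim_cap=trim_cap)
    df["weight"] = result.weights
    return df, result


@dataclass
class PipelineResult:
    tally: dict[str, int]
    split: SplitSpec
    model: CLAEModel
    history: pd.DataFrame
    analysis: pd.DataFrame
    balance: BalanceResult
    estimates: pd.DataFrame


def run_pipeline(logs: Sequence[MealEventLog],
                 clae_cfg: CLAEConfig | None = None,
                 mediation_spec: MediationSpec | None = None,
                 train_fraction: float = 0.65,
                 trim_cap: float | None = None) -> PipelineResult:
    """Logs in, mediation estimates out; every intermediate kept."""
    retained, tally = preprocess_logs(logs)
    split, train, test = chronological_split(retained, train_fraction)
    log.info("windows: %d retained (%d train / %d test); tally %s",
             len(retained), len(train), len(test), tally)
    clae_cfg = clae_cfg or CLAEConfig()
    model, history = train_clae(train, clae_cfg, split)
    analysis, balance = build_analysis_frame(model, train, test,
                                             trim_cap=trim_cap)
    estimates = run_suite(analysis, mediation_spec)
    return PipelineResult(tally=tally, split=split, model=model,
                          history=history, analysis=analysis,
                          balance=balance, estimates=estimates)
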