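"""Tobit / mixed / quantile fits and the quasi-Bayesian effect engine."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cgmed.mediation import (MediationSpec, fit_outcome, fit_tobit,
                             quasi_bayes_mediate, report_tables, run_suite,
                             _tobit_loglike)
from cgmed.synthetic import (ValidationError, censored_normal_mean,
                             simulate_flat_mediation_table)


class TestTobit:
    def test_uncensored_limit_equals_weighted_least_squares(self):
        tab = simulate_flat_mediation_table(400, 0.1, -3, 0.5, censor=False,
                                            seed=1, alpha0=15.0)
        tab["M"] = tab["M"] - tab["M"].min() + 1.0      # strictly positive
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2.0, len(tab))
        fit = fit_tobit(tab["M"].to_numpy(), tab[["Z"]], w)
        X = np.column_stack([np.ones(len(tab)), tab.Z])
        sw = np.sqrt(w)
        wls = np.linalg.lstsq(X * sw[:, None], tab.M * sw, rcond=None)[0]
        assert fit.gaussian_fallback
        np.testing.assert_allclose(fit.beta, wls, atol=1e-6)

    def test_simulation_recovery_within_three_ses(self):
        tab = simulate_flat_mediation_table(
            2000, 0.1, -3, 0.5, censor=True, seed=2, alpha0=-3.5, sigma_m=2.0)
        assert 0.2 < (tab.M == 0).mean() < 0.4
        fit = fit_tobit(tab["M"].to_numpy(), tab[["Z"]])
        se = np.sqrt(np.diag(fit.cov))
        truth = np.array([-3.5, 0.1, 2.0])
        est = np.concatenate([fit.beta, [fit.sigma]])
        assert np.all(np.abs(est - truth) < 3 * se)

    def test_loglike_at_mle_beats_truth(self):
        tab = simulate_flat_mediation_table(
            1000, 0.1, -3, 0.5, censor=True, seed=3, alpha0=-2.0, sigma_m=2.0)
        fit = fit_tobit(tab["M"].to_numpy(), tab[["Z"]])
        X = np.column_stack([np.ones(len(tab)), tab.Z])
        censored = tab.M.to_numpy() <= 0
        ll_truth = _tobit_loglike(np.array([-2.0, 0.1, np.log(2.0)]), X,
                                  tab.M.to_numpy(), np.ones(len(tab)),
                                  censored)
        assert fit.loglike >= ll_truth

    def test_all_censored_rejected(self):
        with pytest.raises(ValidationError, match="censored"):
            fit_tobit(np.zeros(50), np.ones((50, 1)) * 2.0)

    def test_negative_weights_rejected(self):
        tab = simulate_flat_mediation_table(100, 0.1, -3, 0.5, seed=4)
        with pytest.raises(ValidationError):
            fit_tobit(tab["M"].to_numpy(), tab[["Z"]], -np.ones(len(tab)))


@pytest.fixture(scope="module")
def flat():
    return simulate_flat_mediation_table(
        600, 0.1, -3, 0.5, censor=False, seed=5, alpha0=15.0,
        sigma_y=8.0, subject_sd=4.0, n_subjects=15)


class TestOutcomeModels:
    def test_mixed_matches_statsmodels_unweighted(self, flat):
        fit = fit_outcome(flat["Y"].to_numpy(), flat[["Z", "M"]], None,
                          "mixed", subjects=flat["subject"])
        ref = sm.MixedLM(flat.Y, sm.add_constant(flat[["Z", "M"]]),
                         groups=flat.subject).fit(reml=False)
        np.testing.assert_allclose(fit.beta, ref.fe_params, atol=1e-3)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)), ref.bse_fe,
                                   rtol=1e-2)
        assert fit.sigma_b == pytest.approx(
            np.sqrt(ref.cov_re.iloc[0, 0]), rel=0.02)

    def test_mixed_degenerate_random_intercept_matches_wls(self):
        tab = simulate_flat_mediation_table(
            500, 0.1, -3, 0.5, censor=False, seed=6, alpha0=15.0,
            sigma_y=6.0, subject_sd=0.0)
        fit = fit_outcome(tab["Y"].to_numpy(), tab[["Z", "M"]], None,
                          "mixed", subjects=tab["subject"])
        X = np.column_stack([np.ones(len(tab)), tab.Z, tab.M])
        ols = np.linalg.lstsq(X, tab.Y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=0.02)

    def test_mixed_needs_multiple_subjects(self, flat):
        one = flat[flat.subject == flat.subject.iloc[0]]
        with pytest.raises(ValidationError, match="subject"):
            fit_outcome(one["Y"].to_numpy(), one[["Z", "M"]], None,
                        "mixed", subjects=one["subject"])

    def test_quantile_intercepts_ordered(self, flat):
        fits = {}
        for tau in (0.25, 0.75):
            fits[tau] = fit_outcome(flat["Y"].to_numpy(), flat[["Z", "M"]],
                                    None, "quantile", subjects=flat["subject"],
                                    tau=tau, n_boot=20, seed=0)
        assert fits[0.25].beta[0] < fits[0.75].beta[0]

    def test_median_regression_agrees_with_mean_under_symmetric_noise(self,
                                                                      flat):
        med = fit_outcome(flat["Y"].to_numpy(), flat[["Z", "M"]], None,
                          "quantile", subjects=flat["subject"], tau=0.5,
                          n_boot=60, seed=1)
        mean = fit_outcome(flat["Y"].to_numpy(), flat[["Z", "M"]], None,
                           "mixed", subjects=flat["subject"])
        se = np.sqrt(np.diag(med.cov))
        assert np.all(np.abs(med.beta[1:] - mean.beta[1:]) < 3 * se[1:])

    def test_invalid_tau_rejected(self, flat):
        with pytest.raises(ValidationError):
            fit_outcome(flat["Y"].to_numpy(), flat[["Z", "M"]], None,
                        "quantile", subjects=flat["subject"], tau=1.5)


class TestQuasiBayes:
    @staticmethod
    def _fits(tab):
        tobit = fit_tobit(tab["M"].to_numpy(), tab[["Z"]])
        outcome = fit_outcome(tab["Y"].to_numpy(), tab[["Z", "M"]], None,
                              "mixed", subjects=tab["subject"])
        return tobit, outcome

    def test_uncensored_product_of_coefficients(self):
        tab = simulate_flat_mediation_table(
            2000, 0.1, -3, 0.5, censor=False, seed=7, alpha0=20.0,
            sigma_m=1.5, sigma_y=4.0)
        tobit, outcome = self._fits(tab)
        est = quasi_bayes_mediate(tobit, outcome, 50.0, 80.0, tab[[]],
                                  n_sims=800, seed=3)
        assert est.acme == pytest.approx(-9.0, abs=0.8)
        assert est.ade == pytest.approx(15.0, abs=0.8)
        assert est.acme_ci[0] <= -9.0 <= est.acme_ci[1]
        assert est.total == pytest.approx(est.acme + est.ade)

    def test_null_mediated_path_interval_contains_zero(self):
        tab = simulate_flat_mediation_table(
            1500, 0.1, 0.0, 0.5, censor=False, seed=8, alpha0=20.0,
            sigma_y=5.0)
        tobit, outcome = self._fits(tab)
        est = quasi_bayes_mediate(tobit, outcome, 50.0, 80.0, tab[[]],
                                  n_sims=500, seed=4)
        assert est.acme_ci[0] <= 0.0 <= est.acme_ci[1]

    def test_censored_acme_matches_analytic_oracle(self):
        alpha0, sigma_m = -1.0, 2.0
        tab = simulate_flat_mediation_table(
            8000, 0.1, -3, 0.5, censor=True, seed=9, alpha0=alpha0,
            sigma_m=sigma_m, sigma_y=5.0)
        tobit, outcome = self._fits(tab)
        est = quasi_bayes_mediate(tobit, outcome, 50.0, 80.0, tab[[]],
                                  n_sims=800, seed=5)
        truth = -3 * (censored_normal_mean(alpha0 + 0.1 * 80, sigma_m)
                      - censored_normal_mean(alpha0 + 0.1 * 50, sigma_m))
        assert est.acme == pytest.approx(truth, abs=0.6)

    def test_seed_determinism(self):
        tab = simulate_flat_mediation_table(
            500, 0.1, -3, 0.5, censor=True, seed=10, alpha0=-1.0)
        tobit, outcome = self._fits(tab)
        a = quasi_bayes_mediate(tobit, outcome, 50.0, 80.0, tab[[]],
                                n_sims=300, seed=6)
        b = quasi_bayes_mediate(tobit, outcome, 50.0, 80.0, tab[[]],
                                n_sims=300, seed=6)
        assert a == b

    def test_interval_brackets_point(self):
        tab = simulate_flat_mediation_table(
            600, 0.1, -3, 0.5, censor=True, seed=11, alpha0=-1.0)
        tobit, outcome = self._fits(tab)
        est = quasi_bayes_mediate(tobit, outcome, 50.0, 80.0, tab[[]],
                                  n_sims=300, seed=7)
        for point, ci in [(est.acme, est.acme_ci), (est.ade, est.ade_ci),
                          (est.total, est.total_ci)]:
            assert ci[0] <= point <= ci[1]


def _analysis_frame(n=900, seed=12, n_pcs=3):
    """Synthetic analysis table in the run_suite interchange format."""
    rng = np.random.default_rng(seed)
    tab = simulate_flat_mediation_table(
        n, 0.1, -3, 0.5, censor=True, seed=seed, alpha0=-0.5,
        sigma_m=2.0, sigma_y=8.0, subject_sd=3.0, n_subjects=12,
        gamma=(0.0,) * n_pcs, kappa=(0.0,) * n_pcs)
    frame = pd.DataFrame({
        "subject_id": tab.subject,
        "meal_type": rng.choice(["breakfast", "lunch", "dinner", "snack"], n),
        "Z": tab.Z, "M": tab.M, "weight": 1.0,
    })
    for t in (60, 90, 120, 150, 180, 210):
        frame[f"delta_g_{t}"] = tab.Y + rng.normal(0, 0.5, n)
    for j in range(n_pcs):
        frame[f"pc{j + 1}"] = tab[f"X{j + 1}"]
    return frame


class TestSuite:
    def test_grid_size_and_identities(self):
        frame = _analysis_frame(400)
        spec = MediationSpec(horizons=(60, 120), doses=(15.0, 30.0),
                             taus=(0.5,), n_sims=150, n_boot=15, seed=1)
        out = run_suite(frame, spec)
        # 5 strata x 2 horizons x 2 doses x 2 models
        assert len(out) == 5 * 2 * 2 * 2
        np.testing.assert_allclose(out.total, out.acme + out.ade, atol=1e-9)
        assert (out.total_lo <= out.total).all()
        assert (out.total <= out.total_hi).all()
        assert ((out.acme_p >= 1 / 150) & (out.acme_p <= 1.0)).all()

    def test_small_stratum_skipped(self, caplog):
        frame = _analysis_frame(120)
        frame.loc[frame.meal_type == "snack", "meal_type"] = "dinner"
        frame.loc[frame.index[:5], "meal_type"] = "snack"
        spec = MediationSpec(horizons=(120,), doses=(30.0,), taus=(),
                             n_sims=100, seed=2)
        with caplog.at_level("INFO", logger="cgmed.mediation"):
            out = run_suite(frame, spec)
        assert "snack" not in set(out.stratum)
        assert "skipped" in caplog.text

    def test_dose_linearity_in_uncensored_truth(self):
        frame = _analysis_frame(1200, seed=13)
        # remove censoring for exact dose proportionality
        tab = simulate_flat_mediation_table(
            1200, 0.1, -3, 0.5, censor=False, seed=13, alpha0=25.0,
            sigma_m=1.5, sigma_y=4.0, subject_sd=2.0, n_subjects=12)
        frame["Z"], frame["M"] = tab.Z, tab.M
        for t in (60, 90, 120, 150, 180, 210):
            frame[f"delta_g_{t}"] = tab.Y
        spec = MediationSpec(horizons=(120,), doses=(15.0, 30.0), taus=(),
                             n_sims=400, seed=3)
        out = run_suite(frame[frame.columns], spec)
        pooled = out[out.stratum == "pooled"].set_index("dose")
        assert pooled.loc[30.0, "acme"] == pytest.approx(
            2 * pooled.loc[15.0, "acme"], rel=0.15)
        assert pooled.loc[30.0, "ade"] == pytest.approx(
            2 * pooled.loc[15.0, "ade"], rel=0.15)


class TestReportTables:
    def test_shapes_and_flags(self):
        frame = _analysis_frame(300)
        spec = MediationSpec(horizons=(60, 120), doses=(30.0,), taus=(0.5,),
                             n_sims=120, n_boot=10, seed=4)
        est = run_suite(frame, spec)
        t3, t4 = report_tables(est, table4_horizon=120, table4_dose=30.0)
        assert len(t3) == len(est)
        assert (t3.acme_sig == (t3.acme_p < 0.05)).all()
        assert set(t4.model) <= {"mean", "q50"}
        assert len(t4) == len(est[est.horizon == 120])

    def test_empty_input(self):
        t3, t4 = report_tables(pd.DataFrame())
        assert t3.empty and t4.empty
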