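"""Least-squares estimation of (gamma, lam) and recovery experiments."""

import numpy as np
import pandas as pd
import pytest

from abcog import (
    ABCParams,
    BAYESIAN_NORM,
    ContextProfile,
    ParticipantSpec,
    fit_by,
    fit_gamma,
    fit_gamma_lambda,
    preprocess_cohort,
    recovery_experiment,
    simulate_cohort,
    study_like_cohort,
)
from abcog.bayes import log_likelihood_ratio, to_log_odds


def _noiseless_records(design, params, seed=0):
    profile = ContextProfile.uniform(params, sigma=0.0)
    specs = [ParticipantSpec(p, profile)
             for p in sorted(design["participant_id"].unique())]
    judgments = simulate_cohort(design, specs, seed=seed, round_percent=False)
    return preprocess_cohort(judgments)


def _sse_gamma(records, gamma):
    x = to_log_odds(records["prior"].to_numpy())
    llr = log_likelihood_ratio(records["likelihood"].to_numpy(),
                               records["n_evidence"].to_numpy())
    resid = records["lo_response"].to_numpy() - gamma * x - (1 - gamma) * llr
    return float(resid @ resid)


class TestFitGamma:
    def test_noiseless_recovery_matches_grid_search(self, minimal_design):
        records = _noiseless_records(minimal_design, ABCParams(0.3, 1.0))
        fit = fit_gamma(records)
        assert fit.gamma_hat == pytest.approx(0.3, abs=1e-12)
        # independent oracle: exhaustive search over a fine gamma grid
        grid = np.linspace(0, 1, 1001)
        best = grid[np.argmin([_sse_gamma(records, g) for g in grid])]
        assert fit.gamma_hat == pytest.approx(best, abs=5e-4)

    def test_prior_responders_give_gamma_one(self, minimal_design):
        records = _noiseless_records(minimal_design, ABCParams(1.0, 1.0))
        assert fit_gamma(records).gamma_hat == pytest.approx(1.0, abs=1e-12)

    def test_evidence_responders_give_gamma_zero(self, minimal_design):
        records = _noiseless_records(minimal_design, ABCParams(0.0, 1.0))
        assert fit_gamma(records).gamma_hat == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_predictor_raises(self):
        # prior log-odds equal the evidence term in every record
        records = pd.DataFrame({
            "prior": [0.8, 0.8], "likelihood": [0.8, 0.8],
            "n_evidence": [1, 1], "lo_response": [0.5, 0.7]})
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_gamma(records)

    def test_too_few_observations_raise(self):
        records = pd.DataFrame({"prior": [0.15], "likelihood": [0.8],
                                "n_evidence": [1], "lo_response": [0.0]})
        with pytest.raises(ValueError):
            fit_gamma(records)

    def test_raw_coefficient_retained_when_clipped(self, minimal_design):
        records = _noiseless_records(minimal_design, ABCParams(1.0, 1.0))
        shifted = records.assign(lo_response=lambda d: 1.5 * d["lo_response"]
                                 - 0.5 * log_likelihood_ratio(
                                     d["likelihood"].to_numpy(),
                                     d["n_evidence"].to_numpy()))
        fit = fit_gamma(shifted)  # true slope 1.5, outside [0, 1]
        assert fit.gamma_raw == pytest.approx(1.5, abs=1e-9)
        assert fit.gamma_hat == 1.0
        assert fit.constrained

    def test_shift_sensitivity_matches_regression_algebra(self, minimal_design):
        records = _noiseless_records(minimal_design, ABCParams(0.4, 1.0))
        base = fit_gamma(records).gamma_hat
        c = 0.3
        shifted = records.assign(lo_response=records["lo_response"] + c)
        x = (to_log_odds(records["prior"].to_numpy())
             - log_likelihood_ratio(records["likelihood"].to_numpy(),
                                    records["n_evidence"].to_numpy()))
        predicted = base + c * x.sum() / (x @ x)
        assert fit_gamma(shifted).gamma_hat == pytest.approx(predicted, abs=1e-12)


class TestFitGammaLambda:
    def test_noiseless_recovery_matches_grid_search(self, minimal_design):
        truth = ABCParams(0.9, 1.3)
        records = _noiseless_records(minimal_design, truth)
        fit = fit_gamma_lambda(records)
        assert fit.gamma_hat == pytest.approx(0.9, abs=1e-9)
        assert fit.lam_hat == pytest.approx(1.3, abs=1e-9)
        # 2-D grid-search oracle
        x = to_log_odds(records["prior"].to_numpy())
        llr = log_likelihood_ratio(records["likelihood"].to_numpy(),
                                   records["n_evidence"].to_numpy())
        y = records["lo_response"].to_numpy()
        gs, ls = np.meshgrid(np.linspace(0, 2, 101), np.linspace(1, 2, 51))
        sse = ((y[None, None, :] - gs[..., None] * x[None, None, :]
                - (ls - gs)[..., None] * llr[None, None, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert gs[i, j] == pytest.approx(0.9, abs=0.011)
        assert ls[i, j] == pytest.approx(1.3, abs=0.011)

    def test_bayesian_responder_hits_the_norm(self, minimal_design):
        records = _noiseless_records(minimal_design, BAYESIAN_NORM)
        fit = fit_gamma_lambda(records)
        assert fit.gamma_hat == pytest.approx(1.0, abs=1e-9)
        assert fit.lam_hat == pytest.approx(2.0, abs=1e-9)
        assert not fit.constrained

    def test_rank_deficiency_raises(self):
        records = pd.DataFrame({
            "prior": [0.15] * 4, "likelihood": [0.8] * 4,
            "n_evidence": [1] * 4, "lo_response": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_gamma_lambda(records)

    def test_out_of_bounds_raw_triggers_constrained_refit(self, minimal_design):
        # responses over-weight evidence beyond any admissible lam
        records = _noiseless_records(minimal_design, ABCParams(0.0, 1.0))
        inflated = records.assign(lo_response=records["lo_response"] * 2.5)
        fit = fit_gamma_lambda(inflated)
        assert fit.constrained
        assert fit.lam_raw > 2.0
        assert 1.0 <= fit.lam_hat <= 2.0
        assert 0.0 <= fit.gamma_hat <= fit.lam_hat

    def test_agrees_with_one_parameter_fit_when_lam_is_one(self, minimal_design):
        records = _noiseless_records(minimal_design, ABCParams(0.6, 1.0))
        g1 = fit_gamma(records)
        g2 = fit_gamma_lambda(records)
        assert g2.lam_hat == pytest.approx(1.0, abs=1e-9)
        assert g2.gamma_hat == pytest.approx(g1.gamma_hat, abs=1e-9)


class TestFitBy:
    def test_per_content_fits(self):
        _, judgments = study_like_cohort(seed=3)
        fits = fit_by(preprocess_cohort(judgments), by=("content",))
        assert set(fits["content"]) == {"urn", "cab_standard", "cab_modified"}
        by_content = fits.set_index("content")["gamma_hat"]
        assert by_content["urn"] > by_content["cab_standard"]
        assert by_content["urn"] > by_content["cab_modified"]

    def test_per_participant_fits(self, minimal_design):
        records = _noiseless_records(minimal_design, ABCParams(0.3, 1.0))
        fits = fit_by(records, by=("participant_id",))
        assert len(fits) == 12
        assert np.allclose(fits["gamma_hat"], 0.3, atol=1e-9)


class TestRecovery:
    def test_noiseless_recovery_is_exact(self):
        report = recovery_experiment(ABCParams(0.7, 1.0), sigma=0.0,
                                     n_participants=12, replicates=3, seed=1)
        assert report.bias_gamma == pytest.approx(0.0, abs=1e-9)
        assert report.rmse_gamma == pytest.approx(0.0, abs=1e-9)

    def test_rmse_bounds_bias(self):
        report = recovery_experiment(ABCParams(0.5, 1.0), sigma=0.9,
                                     n_participants=12, replicates=20, seed=1)
        assert report.rmse_gamma >= abs(report.bias_gamma)
        assert 0.0 <= report.coverage_gamma <= 1.0

    def test_two_parameter_noiseless_recovery(self):
        report = recovery_experiment(ABCParams(0.9, 1.3), sigma=0.0,
                                     n_participants=12, replicates=2, seed=1,
                                     model="gamma_lambda")
        assert report.bias_gamma == pytest.approx(0.0, abs=1e-9)
        assert report.bias_lam == pytest.approx(0.0, abs=1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            recovery_experiment(ABCParams(0.5), 0.9, replicates=0)
        with pytest.raises(ValueError):
            recovery_experiment(ABCParams(0.5), 0.9, model="bayes")
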