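"""Parameter estimation for the ABC model and recovery experiments.

The forward model is linear in log-odds space, so estimation is least
squares.  Rearranging the one-parameter model,

    lo_response - LLR = gamma * (lo_prior - LLR),

gives a regression through the origin with closed-form solution
``gamma_hat = sum(x*y) / sum(x^2)``.  The two-parameter model is a rank-2
no-intercept regression of the response log-odds on ``(lo_prior, LLR)``
with ``gamma = b1`` and ``lam = b1 + b2``; estimates outside the model
bounds trigger a bounded quadratic refit.  Identification of lam requires
independent variation of prior and evidence strength, which the balanced
study battery provides.

Noise is assumed homoscedastic in log-odds space (the simulator's
generative assumption), so ordinary least squares is used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .bayes import DEFAULT_EPS, log_likelihood_ratio, to_log_odds
from .design import generate_design
from .model import ABCParams, ContextProfile
from .preprocess import preprocess_cohort
from .simulate import ParticipantSpec, simulate_cohort

logger = logging.getLogger(__name__)

#: Raw coefficients within this distance of a bound are snapped to it
#: rather than triggering a constrained refit (floating-point slack).
_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class FitResult:
    """Result of one least-squares fit of the ABC model.

    ``gamma_hat`` / ``lam_hat`` satisfy the model bounds; ``gamma_raw`` /
    ``lam_raw`` are the unconstrained coefficients (retained because
    exploratory fits may exceed the bounds, e.g. gamma > lam).
    ``constrained`` marks fits where the bounds were active.
    """

    gamma_hat: float
    lam_hat: float
    gamma_raw: float
    lam_raw: float
    residual_sd: float
    gamma_se: float
    n_obs: int
    constrained: bool
    model: str  #: "gamma" (lam fixed at 1) or "gamma_lambda"

    @property
    def params(self) -> ABCParams:
        return ABCParams(self.gamma_hat, self.lam_hat)


def _design_arrays(records: pd.DataFrame, eps: float):
    lo_prior = to_log_odds(records["prior"].to_numpy(dtype=float), eps)
    llr = log_likelihood_ratio(records["likelihood"].to_numpy(dtype=float),
                               records["n_evidence"].to_numpy(), eps)
    y = records["lo_response"].to_numpy(dtype=float)
    keep = np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("excluding %d record(s) with non-finite log-odds", dropped)
    return lo_prior[keep], llr[keep], y[keep]


def fit_gamma(records: pd.DataFrame, eps: float = DEFAULT_EPS) -> FitResult:
    """Fit the one-parameter model (lam = 1) by regression through the origin.

    ``records`` must carry ``lo_response`` (see
    :func:`~abcog.preprocess.preprocess_cohort`) together with the design
    columns ``prior, likelihood, n_evidence``.  The raw coefficient is
    clipped into [0, 1] for ``gamma_hat``.
    """
    lo_prior, llr, y = _design_arrays(records, eps)
    if len(y) < 2:
        raise ValueError("fit_gamma needs at least 2 usable observations")
    x = lo_prior - llr
    sxx = float(x @ x)
    if sxx <= 1e-12:
        raise ValueError(
            "gamma unidentifiable: prior log-odds equal the evidence log "
            "likelihood ratio in every record"
        )
    gamma_raw = float(x @ (y - llr)) / sxx
    resid = (y - llr) - gamma_raw * x
    dof = max(len(y) - 1, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    gamma_hat = min(max(gamma_raw, 0.0), 1.0)
    return FitResult(
        gamma_hat=gamma_hat, lam_hat=1.0, gamma_raw=gamma_raw, lam_raw=1.0,
        residual_sd=residual_sd, gamma_se=residual_sd / np.sqrt(sxx),
        n_obs=len(y), constrained=abs(gamma_hat - gamma_raw) > _BOUND_TOL,
        model="gamma",
    )


def fit_gamma_lambda(records: pd.DataFrame, eps: float = DEFAULT_EPS) -> FitResult:
    """Fit the generalized model by no-intercept least squares.

    Regresses the response log-odds on ``(lo_prior, LLR)``; ``gamma`` is
    the first coefficient and ``lam`` the coefficient sum.  If the raw
    estimates leave the region {0 <= gamma <= lam, 1 <= lam <= 2} the fit
    is repeated as a bounded quadratic program over (gamma, lam).
    """
    lo_prior, llr, y = _design_arrays(records, eps)
    if len(y) < 3:
        raise ValueError("fit_gamma_lambda needs at least 3 usable observations")
    X = np.column_stack([lo_prior, llr])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError(
            "(gamma, lam) unidentifiable: the records lack independent "
            "variation in prior and evidence strength (rank-deficient design)"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    gamma_raw = float(coef[0])
    lam_raw = float(coef[0] + coef[1])

    in_bounds = (gamma_raw >= -_BOUND_TOL and gamma_raw <= lam_raw + _BOUND_TOL
                 and 1.0 - _BOUND_TOL <= lam_raw <= 2.0 + _BOUND_TOL)
    if in_bounds:
        lam_hat = min(max(lam_raw, 1.0), 2.0)
        gamma_hat = min(max(gamma_raw, 0.0), lam_hat)
    else:
        def sse(theta):
            g, lam = theta
            r = y - g * lo_prior - (lam - g) * llr
            return float(r @ r)

        start = (min(max(gamma_raw, 0.0), 2.0), min(max(lam_raw, 1.0), 2.0))
        res = optimize.minimize(
            sse, x0=start, method="SLSQP",
            bounds=[(0.0, 2.0), (1.0, 2.0)],
            constraints=[{"type": "ineq", "fun": lambda t: t[1] - t[0]}],
        )
        gamma_hat, lam_hat = float(res.x[0]), float(res.x[1])

    resid = y - gamma_hat * lo_prior - (lam_hat - gamma_hat) * llr
    dof = max(len(y) - 2, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    # SE of gamma from the unconstrained normal equations
    xtx_inv = np.linalg.inv(X.T @ X)
    gamma_se = float(residual_sd * np.sqrt(xtx_inv[0, 0]))
    return FitResult(
        gamma_hat=gamma_hat, lam_hat=lam_hat, gamma_raw=gamma_raw,
        lam_raw=lam_raw, residual_sd=residual_sd, gamma_se=gamma_se,
        n_obs=len(y), constrained=not in_bounds, model="gamma_lambda",
    )


_FITTERS = {"gamma": fit_gamma, "gamma_lambda": fit_gamma_lambda}


def fit_by(records: pd.DataFrame, by: Sequence[str] = ("content",),
           model: str = "gamma", eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Fit the model separately within groups (e.g. per content, the
    context subscript of the ABC model, or per participant).

    Returns one row per group with the :class:`FitResult` fields.
    """
    fitter = _FITTERS[model]
    rows = []
    for keys, grp in records.groupby(list(by), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        fit = fitter(grp, eps)
        rows.append({**dict(zip(by, keys)),
                     **{k: getattr(fit, k) for k in (
                         "gamma_hat", "lam_hat", "gamma_raw", "lam_raw",
                         "residual_sd", "gamma_se", "n_obs", "constrained",
                         "model")}})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryReport:
    """Bias/RMSE of (gamma, lam) estimates over simulated cohorts."""

    model: str
    true_gamma: float
    true_lam: float
    bias_gamma: float
    rmse_gamma: float
    bias_lam: float
    rmse_lam: float
    coverage_gamma: float  #: fraction of nominal 95% intervals covering gamma
    replicates: int
    n_participants: int
    sigma: float
    seed: int
    estimates: pd.DataFrame  #: per-replicate gamma_hat / lam_hat / gamma_se


def recovery_experiment(true_params: ABCParams, sigma: float,
                        n_participants: int = 48, replicates: int = 200,
                        seed: int = 0, model: str = "gamma",
                        round_percent: bool = False) -> RecoveryReport:
    """Simulate -> preprocess -> fit cycles at known parameters.

    Each replicate generates a fresh balanced design and a clean cohort
    (no missing or non-normalized pairs; percent rounding off by default
    so that noiseless recovery is exact), then fits the requested model on
    the pooled records.  Deterministic given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}")
    profile = ContextProfile.uniform(true_params, sigma)
    rep_seeds = np.random.SeedSequence(seed).generate_state(replicates).astype(np.int64)
    rep_seeds &= 0x7FFFFFFF
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        design = generate_design(n_participants, int(rep_seed))
        specs = [ParticipantSpec(pid, profile)
                 for pid in range(1, n_participants + 1)]
        judgments = simulate_cohort(design, specs, seed=int(rep_seed),
                                    round_percent=round_percent)
        fit = _FITTERS[model](preprocess_cohort(judgments))
        rows.append({"replicate": rep, "gamma_hat": fit.gamma_hat,
                     "lam_hat": fit.lam_hat, "gamma_se": fit.gamma_se})
    est = pd.DataFrame(rows)
    g = est["gamma_hat"].to_numpy()
    l = est["lam_hat"].to_numpy()
    half = 1.959963984540054 * est["gamma_se"].to_numpy()
    covered = np.abs(g - true_params.gamma) <= half
    return RecoveryReport(
        model=model,
        true_gamma=true_params.gamma,
        true_lam=true_params.lam,
        bias_gamma=float(np.mean(g) - true_params.gamma),
        rmse_gamma=float(np.sqrt(np.mean((g - true_params.gamma) ** 2))),
        bias_lam=float(np.mean(l) - true_params.lam),
        rmse_lam=float(np.sqrt(np.mean((l - true_params.lam) ** 2))),
        coverage_gamma=float(np.mean(covered)),
        replicates=replicates,
        n_participants=n_participants,
        sigma=sigma,
        seed=seed,
        estimates=est,
    )
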