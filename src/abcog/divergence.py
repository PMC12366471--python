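"""Kullback-Leibler divergence diagnostics between Bayesian and ABC posteriors.

Each posterior over a binary hypothesis is a Bernoulli distribution, so the
pointwise divergence at a given prior is the Bernoulli KL in nats.  The
default direction is KL(Bayes || ABC), treating the normative posterior as
the reference distribution; the direction is configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .bayes import DEFAULT_EPS, from_log_odds, log_likelihood_ratio, to_log_odds
from .model import ABCParams, abc_log_odds, default_prior_grid


def bernoulli_kl(p, q):
    """KL divergence KL(Bernoulli(p) || Bernoulli(q)) in nats.

    ``p * ln(p/q) + (1-p) * ln((1-p)/(1-q))``; nonnegative, zero iff
    ``p == q``.  A degenerate reference (``q`` in {0, 1}) with ``p != q``
    yields ``+inf``.
    """
    p_arr = np.asarray(p, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)) or np.any((q_arr < 0) | (q_arr > 1)):
        raise ValueError("bernoulli_kl arguments must be probabilities in [0, 1]")
    kl = rel_entr(p_arr, q_arr) + rel_entr(1.0 - p_arr, 1.0 - q_arr)
    if kl.ndim == 0:
        return float(kl)
    return kl


def kl_curve(params: ABCParams, likelihood: float, n_evidence: int = 1,
             prior_grid=None, direction: str = "bayes_to_abc",
             eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Pointwise KL divergence between Bayesian and ABC posteriors on a grid.

    Returns columns ``prior, p_bayes, p_abc, kl``.  ``direction`` is
    ``"bayes_to_abc"`` (default, KL(Bayes || ABC)) or ``"abc_to_bayes"``.
    """
    if direction not in ("bayes_to_abc", "abc_to_bayes"):
        raise ValueError(f"unknown direction {direction!r}")
    grid = default_prior_grid() if prior_grid is None else np.asarray(prior_grid, dtype=float)
    lo_prior = to_log_odds(grid, eps)
    llr = log_likelihood_ratio(likelihood, n_evidence, eps)
    p_bayes = from_log_odds(lo_prior + llr)
    p_abc = from_log_odds(abc_log_odds(lo_prior, llr, params))
    if direction == "bayes_to_abc":
        kl = bernoulli_kl(p_bayes, p_abc)
    else:
        kl = bernoulli_kl(p_abc, p_bayes)
    return pd.DataFrame({"prior": grid, "p_bayes": p_bayes, "p_abc": p_abc, "kl": kl})


def bayes_abc_crossing(params: ABCParams, likelihood: float,
                       n_evidence: int = 1) -> float:
    """Prior log-odds at which the ABC and Bayesian posteriors coincide.

    Solving ``gamma*x + (lam-gamma)*L = x + L`` for ``x`` gives
    ``x = L * (gamma + 1 - lam) / (gamma - 1)``; undefined at gamma = 1
    unless lam = 2 (then the two models agree everywhere).
    """
    llr = log_likelihood_ratio(likelihood, n_evidence)
    if abs(params.gamma - 1.0) < 1e-12:
        if abs(params.lam - 2.0) < 1e-12:
            return float("nan")  # identical lines: every prior is a crossing
        raise ValueError("no finite crossing: gamma = 1 with lam != 2")
    return float(llr * (params.gamma + 1.0 - params.lam) / (params.gamma - 1.0))
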