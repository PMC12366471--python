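"""The Adaptive Bayesian Cognition (ABC) forward model.

Subjective posterior log-odds are a context-weighted combination of the
prior log-odds and the evidence log likelihood ratio:

    LO_hat = gamma * LO_prior + (lam - gamma) * LLR

``gamma`` allocates attention to the prior, ``lam`` caps the total
attentional capacity.  The one-parameter model fixes ``lam = 1`` (fully
competitive weighting: attention to evidence is ``1 - gamma``); the
Bayesian norm is ``gamma = 1, lam = 2``, i.e. unit weight on both terms.
``gamma > lam / 2`` over-weights the prior (conservatism) and
``gamma < lam / 2`` under-weights it (base-rate neglect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bayes import (
    DEFAULT_EPS,
    CONTENTS,
    Scenario,
    bayes_posterior,
    from_log_odds,
    log_likelihood_ratio,
    to_log_odds,
)

#: Tolerance for declaring gamma == lam / 2 (the balanced regime).
BALANCED_TOL = 1e-9


@dataclass(frozen=True)
class ABCParams:
    """Weighting state (gamma, lam) of the ABC model.

    ``strict=True`` (default) enforces the model's bounds
    ``0 <= gamma <= lam`` and ``1 <= lam <= 2``; pass ``strict=False`` for
    exploratory values (e.g. raw regression coefficients, or reduced
    capacity ``lam < 1`` under divided attention).
    """

    gamma: float
    lam: float = 1.0
    strict: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self):
        if self.strict:
            if not 1.0 <= self.lam <= 2.0:
                raise ValueError(
                    f"lam must lie in [1, 2], got {self.lam}; "
                    "pass strict=False for exploratory values"
                )
            if not 0.0 <= self.gamma <= self.lam:
                raise ValueError(
                    f"gamma must lie in [0, lam], got gamma={self.gamma}, lam={self.lam}; "
                    "pass strict=False for exploratory values"
                )

    @property
    def evidence_weight(self) -> float:
        """Weight on the evidence term, ``lam - gamma``."""
        return self.lam - self.gamma


#: The rational Bayesian norm as a point in parameter space.
BAYESIAN_NORM = ABCParams(gamma=1.0, lam=2.0)


def regime(params: ABCParams, tol: float = BALANCED_TOL) -> str:
    """Classify a parameter point into its bias regime.

    ``"conservatism"`` when gamma > lam/2 (prior over-weighted),
    ``"base_rate_neglect"`` when gamma < lam/2, ``"balanced"`` when equal
    within ``tol``.
    """
    delta = params.gamma - params.lam / 2.0
    if abs(delta) <= tol:
        return "balanced"
    return "conservatism" if delta > 0 else "base_rate_neglect"


def abc_log_odds(lo_prior, llr_evidence, params: ABCParams):
    """Subjective posterior log-odds under the ABC model (vectorized)."""
    lo = np.asarray(lo_prior, dtype=float)
    llr = np.asarray(llr_evidence, dtype=float)
    out = params.gamma * lo + (params.lam - params.gamma) * llr
    if out.ndim == 0:
        return float(out)
    return out


def abc_posterior(prior, likelihood=None, n_evidence=1, params: ABCParams = None,
                  eps: float = DEFAULT_EPS):
    """Subjective posterior probability under the ABC model.

    Accepts a :class:`~abcog.bayes.Scenario` or explicit
    ``(prior, likelihood, n_evidence)``.
    """
    if isinstance(prior, Scenario):
        s = prior
        return abc_posterior(s.prior, s.likelihood, s.n_evidence, params, eps)
    if params is None:
        raise TypeError("params is required")
    lo = abc_log_odds(to_log_odds(prior, eps),
                      log_likelihood_ratio(likelihood, n_evidence, eps), params)
    return from_log_odds(lo)


def default_prior_grid() -> np.ndarray:
    """99-point prior grid 0.01..0.99, the resolution used for mapping and
    divergence curves."""
    return np.linspace(0.01, 0.99, 99)


def mapping_curve(params: ABCParams, likelihood: float, n_evidence: int = 1,
                  prior_grid=None, eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Prior-to-posterior mapping of the ABC model across a prior grid.

    Returns one row per grid prior with columns ``prior, lo_prior, abc_lo,
    abc_posterior, bayes_posterior``.  In log-odds coordinates the mapping
    is a straight line with slope ``gamma`` and intercept
    ``(lam - gamma) * LLR``.
    """
    grid = default_prior_grid() if prior_grid is None else np.asarray(prior_grid, dtype=float)
    if np.any((grid <= 0.0) | (grid >= 1.0)):
        raise ValueError("prior grid values must lie in the open interval (0, 1)")
    lo_prior = to_log_odds(grid, eps)
    llr = log_likelihood_ratio(likelihood, n_evidence, eps)
    abc_lo = abc_log_odds(lo_prior, llr, params)
    return pd.DataFrame({
        "prior": grid,
        "lo_prior": lo_prior,
        "abc_lo": abc_lo,
        "abc_posterior": from_log_odds(abc_lo),
        "bayes_posterior": from_log_odds(lo_prior + llr),
    })


@dataclass(frozen=True)
class ContextSettings:
    """ABC parameters plus response-noise SD for one task content."""

    params: ABCParams
    sigma: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ContextProfile:
    """Mapping from task content to :class:`ContextSettings`.

    Every content label appearing in a battery must have an entry.
    """

    contexts: Mapping[str, ContextSettings]

    def for_content(self, content: str) -> ContextSettings:
        try:
            return self.contexts[content]
        except KeyError:
            raise KeyError(
                f"no context settings for content {content!r}; "
                f"profile covers {sorted(self.contexts)}"
            ) from None

    @classmethod
    def uniform(cls, params: ABCParams, sigma: float = 0.0,
                contents=CONTENTS) -> "ContextProfile":
        """Same parameters and noise for every content."""
        return cls({c: ContextSettings(params, sigma) for c in contents})

    @classmethod
    def study_default(cls, gamma_urn: float = 0.9, gamma_cab: float = 0.25,
                      lam: float = 1.0, sigma: float = 0.9) -> "ContextProfile":
        """Context profile emulating the study's qualitative pattern.

        Urn (small-world) content gets a high prior weight, consistent with
        meta-analytic estimates around 0.90-0.95 for urn tasks
        (conservatism); both cab (large-world) contents get a low prior
        weight (base-rate neglect).  The response-noise SD of 0.9 sits in
        the middle of the observed per-scenario log-odds SD range
        (roughly 0.77-0.95).
        """
        urn = ContextSettings(ABCParams(gamma_urn, lam), sigma)
        cab = ContextSettings(ABCParams(gamma_cab, lam), sigma)
        return cls({"urn": urn, "cab_standard": cab, "cab_modified": cab})
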