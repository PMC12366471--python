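"""Exact Bayesian machinery for symmetric binary-evidence problems.

The canonical task is the two-urn problem: a focal hypothesis (e.g. "the
selected urn is blue") holds with prior probability ``prior``; each piece of
evidence confirms the focal hypothesis with probability ``likelihood`` under
the focal hypothesis and with probability ``1 - likelihood`` under the
alternative (symmetric binary evidence).  Updating is additive in natural
log-odds: the posterior log-odds equal the prior log-odds plus ``n`` times
the log likelihood ratio of a single confirming observation.

All transforms use natural logarithms (nats).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Probabilities are clipped to [EPS, 1 - EPS] before log-odds transforms.
#: 0.005 is half of one percentage point, the resolution of percent-scale
#: responses, so clipping never moves a rounded response across a percent.
DEFAULT_EPS = 0.005

#: Numeric design of the study battery: 3 priors x 4 likelihoods give the
#: 12 unique numeric combinations; each appears at both evidence levels.
STUDY_PRIORS = (0.1, 0.15, 0.2)
STUDY_LIKELIHOODS = (0.7, 0.75, 0.8, 0.85)
STUDY_EVIDENCE_LEVELS = (1, 3)

#: Task-content and framing factors of the battery.
CONTENTS = ("urn", "cab_standard", "cab_modified")
FRAMINGS = ("probability", "frequency")


def clip_probability(p, eps: float = DEFAULT_EPS):
    """Clip probabilities into the open interval ``[eps, 1 - eps]``.

    Values outside ``[0, 1]`` raise; boundary values are clipped with a
    logged warning so that log-odds stay finite.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError(f"probability outside [0, 1]: {p!r}")
    clipped = np.clip(arr, eps, 1.0 - eps)
    if np.any(clipped != arr):
        logger.warning(
            "clipped %d boundary probabilit%s to [%g, %g]",
            int(np.sum(clipped != arr)),
            "y" if np.sum(clipped != arr) == 1 else "ies",
            eps,
            1.0 - eps,
        )
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(clipped)
    return clipped


def to_log_odds(p, eps: float = DEFAULT_EPS):
    """Natural log-odds ln(p / (1 - p)) after boundary clipping."""
    q = clip_probability(p, eps)
    out = np.log(np.asarray(q) / (1.0 - np.asarray(q)))
    if np.isscalar(q):
        return float(out)
    return out


def from_log_odds(lo):
    """Inverse of :func:`to_log_odds`: the logistic function."""
    arr = np.asarray(lo, dtype=float)
    # logistic via scipy-free stable form; exact round trip within 1e-12
    out = np.where(arr >= 0, 1.0 / (1.0 + np.exp(-arr)),
                   np.exp(arr) / (1.0 + np.exp(arr)))
    if np.isscalar(lo) or np.ndim(lo) == 0:
        return float(out)
    return out


def log_likelihood_ratio(likelihood, n_evidence=1, eps: float = DEFAULT_EPS):
    """Log likelihood ratio of ``n_evidence`` independent confirming draws.

    For symmetric binary evidence a single confirming observation has
    likelihood ratio ``likelihood / (1 - likelihood)``; independence makes
    ``n`` confirming observations additive in log space:
    ``n * ln(likelihood / (1 - likelihood))``.
    """
    n = np.asarray(n_evidence)
    if np.any(n < 1):
        raise ValueError("n_evidence must be a positive integer")
    return n * to_log_odds(likelihood, eps)


@dataclass(frozen=True)
class Scenario:
    """One Bayesian word problem of the task battery.

    Parameters
    ----------
    content:
        Task cover story: ``"urn"`` (small-world statistical task),
        ``"cab_standard"`` or ``"cab_modified"`` (large-world eyewitness
        scenarios).
    framing:
        ``"probability"`` (single-event) or ``"frequency"`` (relative
        frequency) presentation of the numeric information.
    prior:
        Prior probability (base rate) of the focal hypothesis, in (0, 1).
    likelihood:
        Diagnosticity of one piece of evidence: probability of a confirming
        observation under the focal hypothesis; ``1 - likelihood`` under the
        alternative.  Diagnostic evidence requires 0.5 <= likelihood < 1.
    n_evidence:
        Number of independent confirming observations (>= 1).
    """

    content: str
    framing: str
    prior: float
    likelihood: float
    n_evidence: int = 1

    def __post_init__(self):
        if self.content not in CONTENTS:
            raise ValueError(f"unknown content {self.content!r}; expected one of {CONTENTS}")
        if self.framing not in FRAMINGS:
            raise ValueError(f"unknown framing {self.framing!r}; expected one of {FRAMINGS}")
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must lie in (0, 1), got {self.prior}")
        if not 0.5 <= self.likelihood < 1.0:
            raise ValueError(
                f"likelihood must lie in [0.5, 1) for diagnostic evidence, got {self.likelihood}"
            )
        if self.n_evidence < 1:
            raise ValueError(f"n_evidence must be >= 1, got {self.n_evidence}")

    @property
    def scenario_type(self) -> str:
        """Label of the content x evidence x framing cell, e.g. ``urn_1_pro``."""
        return f"{self.content}_{self.n_evidence}_{self.framing[:3]}"


def bayes_posterior(prior, likelihood=None, n_evidence=1, eps: float = DEFAULT_EPS):
    """Posterior probability of the focal hypothesis under Bayes' theorem.

    Accepts either a :class:`Scenario` as the single argument or explicit
    ``(prior, likelihood, n_evidence)``.  Computed in log-odds space:
    ``logistic(logit(prior) + n * ln(likelihood / (1 - likelihood)))``,
    which is algebraically identical to the ratio form of Bayes' theorem
    and conserves ``posterior(focal) + posterior(complement) = 1``.
    """
    if isinstance(prior, Scenario):
        s = prior
        return bayes_posterior(s.prior, s.likelihood, s.n_evidence, eps)
    if likelihood is None:
        raise TypeError("likelihood required when prior is not a Scenario")
    lo = to_log_odds(prior, eps) + log_likelihood_ratio(likelihood, n_evidence, eps)
    return from_log_odds(lo)


def posterior_grid(priors=STUDY_PRIORS, likelihoods=STUDY_LIKELIHOODS,
                   ns=STUDY_EVIDENCE_LEVELS, round_to: int | None = None) -> pd.DataFrame:
    """Full cross-product table of Bayesian posteriors.

    Returns a tidy frame with columns ``prior, likelihood, n_evidence,
    posterior`` covering every combination.  ``round_to`` applies display
    rounding (the reference tables use 3 decimals); computation is always
    at full precision.
    """
    if not (len(priors) and len(likelihoods) and len(ns)):
        raise ValueError("priors, likelihoods and ns must be nonempty")
    rows = [
        (p, l, n, bayes_posterior(p, l, n))
        for n, p, l in itertools.product(ns, priors, likelihoods)
    ]
    grid = pd.DataFrame(rows, columns=["prior", "likelihood", "n_evidence", "posterior"])
    if round_to is not None:
        grid["posterior"] = grid["posterior"].round(round_to)
    return grid


def grid_pivot(grid: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy posterior grid into the reference-table layout
    (rows: evidence level x prior, columns: likelihood)."""
    return grid.pivot_table(index=["n_evidence", "prior"], columns="likelihood",
                            values="posterior")
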