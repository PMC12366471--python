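"""Preprocessing of subjective probability-judgment pairs.

Raw responses are pairs of percentages (focal, complement) that should sum
to 100.  Preprocessing applies, in order: the scaling correction (divide
both members by their sum so they form a proper Bernoulli distribution),
imputation of missing pairs by the scenario-type mean of the remaining
participants' normalized pairs, the subjective log-odds transform, and
response-mode classification (is the judgment anchored at the prior, the
likelihood, or the Bayesian posterior?).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .bayes import DEFAULT_EPS, Scenario, bayes_posterior, to_log_odds

logger = logging.getLogger(__name__)

#: Half-width of the band around each reference value used to classify a
#: response as prior / posterior / likelihood anchored.
CLASSIFY_TOLERANCE = 0.03

#: Classification categories; the order is the tie-break priority when a
#: response sits at equal distance inside overlapping bands.
CATEGORIES = ("posterior", "prior", "likelihood")


@dataclass(frozen=True)
class NormalizedJudgment:
    """A scaled judgment pair with its subjective log-odds."""

    p1: float
    p2: float
    log_odds: float


def normalize_pair(p1_percent: float, p2_percent: float,
                   eps: float = DEFAULT_EPS) -> NormalizedJudgment:
    """Apply the scaling correction to a percentage pair.

    Both members are multiplied by ``1 / (p1 + p2)`` so that they sum to 1;
    the log-odds ``ln(p1 / p2)`` are computed after epsilon-clipping.
    Pairs that already sum to 100 pass through unchanged (idempotence).
    """
    if p1_percent < 0 or p2_percent < 0:
        raise ValueError(f"negative percentage in pair ({p1_percent}, {p2_percent})")
    total = p1_percent + p2_percent
    if total <= 0:
        raise ValueError("pair sums to zero: scaling correction undefined")
    p1 = p1_percent / total
    p2 = p2_percent / total
    return NormalizedJudgment(p1=p1, p2=p2, log_odds=to_log_odds(p1, eps))


def impute_missing(records: pd.DataFrame) -> pd.DataFrame:
    """Replace missing pairs by the scenario-type mean of the other
    participants' normalized pairs.

    A pair is missing when ``p1_percent`` and ``p2_percent`` are both NaN
    (partial pairs are rejected); an unscalable pair (sum 0) is treated as
    missing and logged.  The donors for a missing pair are all non-missing
    pairs of the same scenario type (content x framing x evidence); their
    normalized pairs are averaged component-wise, renormalized and written
    back as percentages.  Raises when a scenario type has no donors.
    """
    out = records.copy()
    p1 = out["p1_percent"].to_numpy(dtype=float)
    p2 = out["p2_percent"].to_numpy(dtype=float)
    if np.any(np.isnan(p1) != np.isnan(p2)):
        raise ValueError("partial pairs found: p1 and p2 must be missing together")
    unscalable = (~np.isnan(p1)) & (p1 + p2 <= 0)
    if np.any(unscalable):
        logger.warning("treating %d unscalable pair(s) (sum 0) as missing",
                       int(unscalable.sum()))
        p1 = np.where(unscalable, np.nan, p1)
        p2 = np.where(unscalable, np.nan, p2)
    missing = np.isnan(p1)
    if not missing.any():
        return out

    total = np.where(missing, np.nan, p1 + p2)
    norm1 = p1 / total
    out["_norm1"] = norm1
    type_cols = ["content", "framing", "n_evidence"]
    donor_mean = out.groupby(type_cols)["_norm1"].transform("mean")
    if np.any(missing & donor_mean.isna().to_numpy()):
        raise ValueError("a scenario type has no non-missing pair to impute from")
    m1 = donor_mean.to_numpy()
    p1 = np.where(missing, 100.0 * m1, p1)
    p2 = np.where(missing, 100.0 * (1.0 - m1), p2)
    out["p1_percent"] = p1
    out["p2_percent"] = p2
    return out.drop(columns="_norm1")


def preprocess_cohort(records: pd.DataFrame, eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Impute, normalize and log-transform a cohort of judgment pairs.

    Returns the input columns plus ``p1`` and ``p2`` (normalized
    probabilities summing to 1) and ``lo_response`` (subjective log-odds
    after epsilon-clipping).
    """
    out = impute_missing(records)
    total = out["p1_percent"] + out["p2_percent"]
    out["p1"] = out["p1_percent"] / total
    out["p2"] = out["p2_percent"] / total
    clipped = np.clip(out["p1"].to_numpy(dtype=float), eps, 1.0 - eps)
    out["lo_response"] = np.log(clipped / (1.0 - clipped))
    return out


@dataclass(frozen=True)
class ClassificationResult:
    """Response-mode classification of one normalized judgment."""

    category: str                    #: prior / posterior / likelihood / other
    distances: Mapping[str, float]   #: absolute distance to each reference


def classify_response(p1: float, scenario: Scenario,
                      tolerance: float = CLASSIFY_TOLERANCE) -> ClassificationResult:
    """Classify a normalized focal judgment against the scenario references.

    The references are the scenario's prior, its Bayesian posterior, and
    the single-draw likelihood (diagnosticity).  The response is assigned
    to the reference whose ``+-tolerance`` band contains it; if several
    bands overlap at the response, the nearest reference wins, and exact
    distance ties are broken by the fixed priority posterior > prior >
    likelihood.  A response in no band is ``"other"``.
    """
    references = {
        "prior": scenario.prior,
        "posterior": bayes_posterior(scenario),
        "likelihood": scenario.likelihood,
    }
    distances = {name: abs(p1 - ref) for name, ref in references.items()}
    in_band = [name for name in CATEGORIES if distances[name] <= tolerance]
    if not in_band:
        return ClassificationResult("other", distances)
    # CATEGORIES order makes min() break exact ties by priority
    best = min(in_band, key=lambda name: distances[name])
    return ClassificationResult(best, distances)


@dataclass(frozen=True)
class CohortSummary:
    """Scenario-type level summaries of a preprocessed cohort."""

    summary: pd.DataFrame         #: per-type means/SDs with Bayesian references
    classification: pd.DataFrame  #: per-type response-mode proportions (n = 1 only)


def _classification_table(processed: pd.DataFrame,
                          tolerance: float) -> pd.DataFrame:
    rows = []
    type_cols = ["content", "framing", "n_evidence"]
    single = processed[processed["n_evidence"] == 1]
    for (content, framing, n_ev), grp in single.groupby(type_cols, sort=False):
        counts = dict.fromkeys((*CATEGORIES, "other"), 0)
        for rec in grp.itertuples(index=False):
            scenario = Scenario(content, framing, rec.prior, rec.likelihood, n_ev)
            counts[classify_response(rec.p1, scenario, tolerance).category] += 1
        n = len(grp)
        rows.append({"content": content, "framing": framing, "n_evidence": n_ev,
                     **{k: v / n for k, v in counts.items()}})
    return pd.DataFrame(rows)


def summarize_cohort(records: pd.DataFrame, eps: float = DEFAULT_EPS,
                     tolerance: float = CLASSIFY_TOLERANCE) -> CohortSummary:
    """Scenario-type summary and response-mode classification tables.

    The summary has one row per scenario type with the mean subjective
    posterior (probability scale), the mean and SD of the subjective
    log-odds, and two kinds of Bayesian reference: ``p_bayes_design`` /
    ``lo_bayes_design`` evaluate the posterior at the cohort's average
    prior and likelihood (0.15 and 0.775 in the study battery, giving
    0.378 / 0.878 and -0.498 / 1.976), while ``p_bayes_mean`` /
    ``lo_bayes_mean`` average the record-level Bayesian posteriors over the
    numeric combinations actually seen (the benchmark an ideal responder
    attains exactly).

    The classification table covers single-evidence scenario types only,
    where the three references are unambiguous; its four proportions
    partition each scenario type.
    """
    processed = preprocess_cohort(records, eps)
    mean_prior = float(processed["prior"].mean())
    mean_likelihood = float(processed["likelihood"].mean())

    type_cols = ["content", "framing", "n_evidence"]
    p_bayes_records = bayes_posterior(processed["prior"].to_numpy(),
                                      processed["likelihood"].to_numpy(),
                                      processed["n_evidence"].to_numpy(), eps)
    work = processed.assign(_p_bayes=p_bayes_records,
                            _lo_bayes=np.log(p_bayes_records / (1 - p_bayes_records)))
    summary = (
        work.groupby(type_cols, sort=False)
        .agg(m_p_subjective=("p1", "mean"),
             m_log_odds=("lo_response", "mean"),
             sd_log_odds=("lo_response", lambda s: s.std(ddof=1)),
             p_bayes_mean=("_p_bayes", "mean"),
             lo_bayes_mean=("_lo_bayes", "mean"),
             n=("p1", "size"))
        .reset_index()
    )
    p_design = bayes_posterior(mean_prior, mean_likelihood,
                               summary["n_evidence"].to_numpy(), eps)
    summary.insert(3, "p_bayes_design", p_design)
    summary.insert(4, "lo_bayes_design", np.log(p_design / (1 - p_design)))

    classification = _classification_table(work, tolerance)
    return CohortSummary(summary=summary, classification=classification)
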