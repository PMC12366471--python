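"""Synthetic-cohort generator for the task battery.

Each simulated participant answers every battery row with a pair of
complementary percentage judgments.  The response model: the ABC forward
model produces the true subjective log-odds for the row's content; Gaussian
noise with SD ``sigma`` is added in log-odds space (log-odds SDs are
near-constant across conditions in percentage-judgment data, which is why
the noise lives there and not in probability space); the noisy log-odds are
converted back to a probability and emitted as a percent pair.  Optional
imperfections emulate real response sheets: integer-percent rounding,
non-normalized pairs (sum != 100) and missing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import DEFAULT_EPS, from_log_odds, log_likelihood_ratio, to_log_odds
from .design import generate_design
from .model import ContextProfile

JUDGMENT_COLUMNS = ["participant_id", "order", "content", "framing", "n_evidence",
                    "prior", "likelihood", "p1_percent", "p2_percent"]

#: Multiplicative jitter bounds applied to p2 of a non-normalized pair.
NON_NORMALIZED_JITTER = (0.6, 1.4)


@dataclass(frozen=True)
class ParticipantSpec:
    """Generative settings for one simulated participant.

    ``p_non_normalized`` is the probability that a pair is perturbed so the
    two percentages no longer sum to 100 (exercising the downstream scaling
    correction); ``p_missing`` is the probability that a pair is left blank.
    ``framing_shift`` optionally adds a constant to the response log-odds
    per framing level (default none: the model itself is framing-blind).
    """

    participant_id: int
    profile: ContextProfile
    p_non_normalized: float = 0.0
    p_missing: float = 0.0
    framing_shift: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("p_non_normalized", "p_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def simulate_cohort(design: pd.DataFrame, specs: Sequence[ParticipantSpec],
                    seed: int = 0, round_percent: bool = True,
                    eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Simulate percentage-judgment pairs for every row of a design table.

    Every participant in the design must have a spec.  Deterministic given
    ``seed``: each participant draws from an independent substream, so
    adding or removing participants leaves the others' responses unchanged.
    Returns the design columns plus ``p1_percent`` and ``p2_percent``
    (``NaN`` marks a missing pair).
    """
    by_id = {s.participant_id: s for s in specs}
    missing_specs = sorted(set(design["participant_id"]) - set(by_id))
    if missing_specs:
        raise ValueError(f"no ParticipantSpec for participant(s) {missing_specs}")

    chunks = []
    for pid, rows in design.groupby("participant_id", sort=True):
        spec = by_id[pid]
        rng = np.random.default_rng([seed, 7, pid])
        rows = rows.sort_values("order")
        for content in rows["content"].unique():
            spec.profile.for_content(content)  # fail fast on missing context
        gammas = np.array([spec.profile.for_content(c).params.gamma
                           for c in rows["content"]])
        weights = np.array([spec.profile.for_content(c).params.evidence_weight
                            for c in rows["content"]])
        sigmas = np.array([spec.profile.for_content(c).sigma
                           for c in rows["content"]])
        shifts = np.array([spec.framing_shift.get(f, 0.0) for f in rows["framing"]])
        lo_prior = to_log_odds(rows["prior"].to_numpy(), eps)
        llr = log_likelihood_ratio(rows["likelihood"].to_numpy(),
                                   rows["n_evidence"].to_numpy(), eps)
        lo = gammas * lo_prior + weights * llr + shifts
        # draws are taken in a fixed order so toggling one imperfection
        # does not reshuffle the others
        noise = rng.normal(0.0, 1.0, len(rows)) * sigmas
        u_nonnorm = rng.uniform(size=len(rows))
        jitter = rng.uniform(*NON_NORMALIZED_JITTER, size=len(rows))
        u_missing = rng.uniform(size=len(rows))

        p = from_log_odds(lo + noise)
        p1 = p * 100.0
        p2 = (1.0 - p) * 100.0
        perturb = u_nonnorm < spec.p_non_normalized
        p2 = np.where(perturb, p2 * jitter, p2)
        if round_percent:
            p1 = np.rint(p1)
            p2 = np.rint(p2)
        drop = u_missing < spec.p_missing
        p1 = np.where(drop, np.nan, p1)
        p2 = np.where(drop, np.nan, p2)

        chunk = rows.copy()
        chunk["p1_percent"] = p1
        chunk["p2_percent"] = p2
        chunks.append(chunk)
    return pd.concat(chunks, ignore_index=True)[JUDGMENT_COLUMNS]


def study_like_cohort(seed: int = 0, n_participants: int = 48,
                      profile: ContextProfile | None = None,
                      p_non_normalized: float = 0.05,
                      p_missing: float = 1.0 / 576.0,
                      round_percent: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Design plus simulated judgments emulating the study's conditions.

    Defaults: 48 participants; urn content with high prior weight
    (gamma = 0.9), cab contents with low prior weight (gamma = 0.25),
    lam = 1, log-odds noise SD 0.9 (:meth:`ContextProfile.study_default`);
    a roughly one-in-576 missing pair (one blank pair was observed in the
    original 48 x 12 sheets) and an occasional non-normalized pair.
    Reproduces the qualitative content-by-evidence signature: the evidence
    manipulation moves cab judgments far more than urn judgments.
    """
    profile = profile or ContextProfile.study_default()
    design = generate_design(n_participants, seed)
    specs = [
        ParticipantSpec(pid, profile, p_non_normalized=p_non_normalized,
                        p_missing=p_missing)
        for pid in range(1, n_participants + 1)
    ]
    judgments = simulate_cohort(design, specs, seed=seed, round_percent=round_percent)
    return design, judgments
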