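"""Balanced factorial task battery.

The battery crosses 12 scenario types (3 contents x 2 evidence levels x
2 framings) with 12 numeric combinations (3 priors x 4 likelihoods).  Each
participant works through all 12 scenario types and uses each numeric
combination exactly once; across a cohort whose size is divisible by 12,
every scenario-type x combination pair occurs equally often
(48 participants -> 144 unique pairs, 4 occurrences each).  Presentation
order is an independent per-participant shuffle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import (
    CONTENTS,
    FRAMINGS,
    STUDY_EVIDENCE_LEVELS,
    STUDY_LIKELIHOODS,
    STUDY_PRIORS,
)

#: The 12 scenario types in canonical order.
SCENARIO_TYPES: tuple[tuple[str, str, int], ...] = tuple(
    (content, framing, n)
    for content, n, framing in itertools.product(CONTENTS, STUDY_EVIDENCE_LEVELS, FRAMINGS)
)

#: The 12 numeric (prior, likelihood) combinations in canonical order.
NUMERIC_COMBINATIONS: tuple[tuple[float, float], ...] = tuple(
    itertools.product(STUDY_PRIORS, STUDY_LIKELIHOODS)
)

DESIGN_COLUMNS = ["participant_id", "order", "content", "framing",
                  "n_evidence", "prior", "likelihood"]


def _participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    """Deterministic per-participant substream of the shared seed."""
    return np.random.default_rng([seed, participant_id])


def generate_design(n_participants: int, seed: int = 0) -> pd.DataFrame:
    """Generate a balanced battery assignment for a cohort.

    Balance is achieved with a cyclic Latin-square: a seeded random
    bijection pairs scenario types with numeric combinations for the first
    participant, and each subsequent participant shifts the combination
    index by one.  With ``n_participants`` divisible by 12 every
    scenario-type x combination pair therefore occurs exactly
    ``n_participants / 12`` times; otherwise counts differ by at most one
    (a warning is raised).  Presentation order is an independent shuffle
    per participant.

    Returns a frame with one row per participant x scenario type and
    columns ``participant_id, order, content, framing, n_evidence, prior,
    likelihood``.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if n_participants % 12 != 0:
        warnings.warn(
            f"n_participants={n_participants} is not divisible by 12; "
            "scenario-type x combination counts will differ by at most 1",
            stacklevel=2,
        )
    base = np.random.default_rng([seed, 0]).permutation(12)
    rows = []
    for pid in range(1, n_participants + 1):
        order = _participant_rng(seed, pid).permutation(12) + 1
        for j, (content, framing, n_ev) in enumerate(SCENARIO_TYPES):
            prior, likelihood = NUMERIC_COMBINATIONS[(base[j] + pid - 1) % 12]
            rows.append((pid, int(order[j]), content, framing, n_ev, prior, likelihood))
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return design.sort_values(["participant_id", "order"], ignore_index=True)


@dataclass(frozen=True)
class BatterySummary:
    """Balance diagnostics of a design table."""

    scenario_types: pd.DataFrame  #: per-type mean prior/likelihood and row count
    pair_counts: pd.DataFrame     #: scenario-type x numeric-combination counts
    mean_prior: float
    mean_likelihood: float


def battery_statistics(design: pd.DataFrame) -> BatterySummary:
    """Per-scenario-type means and scenario-type x combination pair counts.

    In a fully balanced battery every scenario type has mean prior 0.15 and
    mean likelihood 0.775 (the design-level averages).
    """
    type_cols = ["content", "framing", "n_evidence"]
    scenario_types = (
        design.groupby(type_cols, sort=False)
        .agg(mean_prior=("prior", "mean"), mean_likelihood=("likelihood", "mean"),
             n_rows=("prior", "size"))
        .reset_index()
    )
    pair_counts = (
        design.groupby(type_cols + ["prior", "likelihood"], sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return BatterySummary(
        scenario_types=scenario_types,
        pair_counts=pair_counts,
        mean_prior=float(design["prior"].mean()),
        mean_likelihood=float(design["likelihood"].mean()),
    )
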