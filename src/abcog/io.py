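"""Table readers/writers, run configuration and the end-to-end pipeline.

All interchange tables are comma-separated UTF-8 text with a header row;
writing and re-reading a table reproduces its values exactly (floats are
serialized with round-trip precision).  A pipeline run is reproducible
from its configuration and seed alone; every run writes a manifest
recording the seed, a hash of the canonical configuration and the emitted
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .design import DESIGN_COLUMNS, generate_design
from .estimate import fit_by
from .model import ABCParams, ContextProfile, ContextSettings
from .preprocess import summarize_cohort
from .simulate import JUDGMENT_COLUMNS, ParticipantSpec, simulate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.17g"  # round-trip precision for CSV interchange


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as comma-separated text at round-trip precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    _require_columns(design, DESIGN_COLUMNS, path)
    return design


def read_judgments(path) -> pd.DataFrame:
    judgments = pd.read_csv(path)
    _require_columns(judgments, JUDGMENT_COLUMNS, path)
    return judgments


def _require_columns(df: pd.DataFrame, columns, path):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


@dataclass(frozen=True)
class ContextConfig:
    """Serializable per-content generative settings."""

    gamma: float
    lam: float = 1.0
    sigma: float = 0.9

    def to_settings(self) -> ContextSettings:
        return ContextSettings(ABCParams(self.gamma, self.lam), self.sigma)


def _default_contexts() -> dict:
    return {
        "urn": ContextConfig(gamma=0.9),
        "cab_standard": ContextConfig(gamma=0.25),
        "cab_modified": ContextConfig(gamma=0.25),
    }


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a design -> simulate -> summarize -> fit run."""

    seed: int = 0
    n_participants: int = 48
    contexts: dict = field(default_factory=_default_contexts)
    p_non_normalized: float = 0.05
    p_missing: float = 1.0 / 576.0
    round_percent: bool = True
    fit_model: str = "gamma"
    fit_by: tuple = ("content",)

    def profile(self) -> ContextProfile:
        return ContextProfile({name: cc.to_settings()
                               for name, cc in self.contexts.items()})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_by"] = list(self.fit_by)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "contexts" in d:
            d["contexts"] = {name: ContextConfig(**cc) if isinstance(cc, dict) else cc
                             for name, cc in d["contexts"].items()}
        if "fit_by" in d:
            d["fit_by"] = tuple(d["fit_by"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def digest(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute design -> simulate -> preprocess/summarize -> fit.

    Writes ``design.csv``, ``judgments.csv``, ``summary.csv``,
    ``classification.csv``, ``fits.csv`` and ``manifest.json`` under
    ``outdir`` and returns the artifact paths.  Stages run in order; a
    failing stage logs its error and downstream stages are skipped, with
    the manifest recording what completed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    errors: dict[str, str] = {}

    design = generate_design(config.n_participants, config.seed)
    artifacts["design"] = write_table(design, outdir / "design.csv")

    profile = config.profile()
    specs = [ParticipantSpec(pid, profile,
                             p_non_normalized=config.p_non_normalized,
                             p_missing=config.p_missing)
             for pid in sorted(design["participant_id"].unique())]
    judgments = simulate_cohort(design, specs, seed=config.seed,
                                round_percent=config.round_percent)
    artifacts["judgments"] = write_table(judgments, outdir / "judgments.csv")

    try:
        tables = summarize_cohort(judgments)
        artifacts["summary"] = write_table(tables.summary, outdir / "summary.csv")
        artifacts["classification"] = write_table(tables.classification,
                                                  outdir / "classification.csv")
    except Exception as exc:  # degenerate cohorts (e.g. everything missing)
        logger.error("summarize stage failed: %s", exc)
        errors["summarize"] = str(exc)

    try:
        from .preprocess import preprocess_cohort
        fits = fit_by(preprocess_cohort(judgments), by=config.fit_by,
                      model=config.fit_model)
        artifacts["fits"] = write_table(fits, outdir / "fits.csv")
    except Exception as exc:
        logger.error("fit stage skipped: %s", exc)
        errors["fit"] = str(exc)

    manifest = {
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": config.to_dict(),
        "artifacts": {k: str(v.name) for k, v in artifacts.items()},
        "errors": errors,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest_path
    return artifacts
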