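"""Run configuration: a strict, serializable bundle of all stage parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic import CohortConfig


@dataclass
class RunConfig:
    """Parameters of a full pipeline run, serializable to YAML.

    Unknown keys in a config file are rejected rather than ignored, and every
    run writes its resolved configuration next to its outputs, so artifacts
    are reproducible from config + seed alone.
    """

    # cohort
    n_participants: int = 6
    n_days: int = 14
    seed: int = 0
    gap_minutes_mean: float = 5.59
    gap_minutes_sd: float = 5.33
    n_supplemental_scores: int = 20
    score_noise_sd: float = 0.1
    score_correlation: float = 0.8
    separability: float = 1.0
    # labeling
    use_true_labels: bool = False
    n_trees: int = 100
    filter_cutoff_hz: float = 0.3
    max_train_windows: int = 20000
    # inference
    modality: str = "fusion"  # home | watch | fusion
    stacked: bool = False

    def __post_init__(self) -> None:
        if self.modality not in ("home", "watch", "fusion"):
            raise ValueError(f"modality must be home, watch or fusion, got {self.modality!r}")
        self.cohort()  # validates cohort-level invariants

    def cohort(self) -> CohortConfig:
        return CohortConfig(
            n_participants=self.n_participants,
            n_days=self.n_days,
            seed=self.seed,
            gap_minutes_mean=self.gap_minutes_mean,
            gap_minutes_sd=self.gap_minutes_sd,
            n_supplemental_scores=self.n_supplemental_scores,
            score_noise_sd=self.score_noise_sd,
            score_correlation=self.score_correlation,
            separability=self.separability,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys {unknown}; known keys: {sorted(known)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
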