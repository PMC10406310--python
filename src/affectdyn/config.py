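"""Pipeline configuration: one structured object, YAML round-trip, presets."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .restdecode import TRIM_END, TRIM_START
from .synth import CohortConfig, LatentDynamicsParams

__all__ = ["PipelineConfig", "fixture_preset", "smoke_preset"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs besides paths and data.

    Decoding, simulation and encoding defaults mirror the reference
    analysis: 100 self-task stimuli resampled 30 times with a (5, 10)
    volume trim; up to 6 closed-loop steps averaged over 30 surrogate
    iterations; 500 label permutations with alpha 0.05 and a 20-voxel
    face-wise cluster threshold.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    # resting-state decoding
    n_stimuli: int = 100
    n_iterations: int = 30
    trim: tuple[int, int] = (TRIM_START, TRIM_END)
    outlier_alpha: float = 0.05
    cv_resamples: int = 30
    # dynamics / simulation
    k_max: int = 6
    n_sim_iterations: int = 30
    # encoding
    n_perm: int = 500
    alpha: float = 0.05
    min_cluster: int = 20
    # reproducibility
    master_seed: int = 1
    drift_order: int = 2

    def __post_init__(self):
        counts = (
            self.n_stimuli, self.n_iterations, self.cv_resamples,
            self.k_max, self.n_sim_iterations, self.n_perm, self.min_cluster,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.trim != (TRIM_START, TRIM_END):
            raise ValueError(
                f"trim is fixed at ({TRIM_START}, {TRIM_END}) by the decoding procedure"
            )
        if self.cohort.rest_volumes <= sum(self.trim):
            raise ValueError("trim leaves no decodable window")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["grid_shape"] = list(self.cohort.grid_shape)
        d["cohort"]["iti_range"] = list(self.cohort.iti_range)
        d["cohort"]["dynamics"]["initial_state"] = list(
            self.cohort.dynamics.initial_state
        )
        d["trim"] = list(self.trim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cd = dict(d.pop("cohort"))
        dyn = dict(cd.pop("dynamics"))
        dyn["initial_state"] = tuple(dyn["initial_state"])
        cd["dynamics"] = LatentDynamicsParams(**dyn)
        cd["grid_shape"] = tuple(cd["grid_shape"])
        cd["iti_range"] = tuple(cd["iti_range"])
        d["cohort"] = CohortConfig(**cd)
        d["trim"] = tuple(d["trim"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode("utf8")).hexdigest()[:16]

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def fixture_preset(master_seed: int = 1) -> PipelineConfig:
    """Desk-scale preset: 12 subjects on a 6x6x6 grid, minutes end-to-end."""
    return PipelineConfig(
        cohort=CohortConfig(
            n_subjects=12,
            grid_shape=(6, 6, 6),
            n_trials=40,
            rest_volumes=120,
        ),
        n_perm=99,
        master_seed=master_seed,
    )


def smoke_preset(master_seed: int = 1) -> PipelineConfig:
    """Minimal preset for fast structural checks (not for inference)."""
    return PipelineConfig(
        cohort=CohortConfig(
            n_subjects=3,
            grid_shape=(5, 5, 5),
            n_trials=16,
            rest_volumes=60,
        ),
        n_stimuli=40,
        n_iterations=5,
        cv_resamples=3,
        n_sim_iterations=5,
        n_perm=20,
        master_seed=master_seed,
    )
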