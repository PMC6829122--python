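"""Run configuration: schema-validated YAML in, reproducible runs out.

A run is fully described by a :class:`RunConfig`: where the data come from
(a dataset manifest or a simulation spec), which algorithms to benchmark,
hyperparameter grids, the feature-selection policy, split parameters and a
mandatory master seed.  Unknown keys are rejected.  Every stochastic
component downstream receives a seed derived deterministically from the
master seed and the cell's (algorithm, trait, replicate) coordinates (see
:func:`gpbench.bench.derive_seed`), so a single cell can be re-run in
isolation from the log alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .kernels_trees import KNOWN_ALGORITHMS

__all__ = ["RunConfig", "SimulationSpec", "FeatureSelectionPolicy",
           "parse_and_validate_config"]


class SimulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_lines: int = 500
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbred: bool = False
    n_qtl: int = 50
    h2: float = 0.6
    architecture: str = "additive"
    effect_distribution: str = "normal"
    traits: list[str] = Field(default_factory=lambda: ["trait"])


class FeatureSelectionPolicy(BaseModel):
    model_config = ConfigDict(extra="forbid")

    method: str = "RF"
    k: int = 8000
    exempt: list[str] = Field(default_factory=lambda: ["RF"])

    @field_validator("method")
    @classmethod
    def _known_method(cls, v: str) -> str:
        if v not in ("RF", "EN", "BA"):
            raise ValueError(f"unknown feature-selection method {v!r}")
        return v


class RunConfig(BaseModel):
    """Schema for one benchmark run."""

    model_config = ConfigDict(extra="forbid")

    master_seed: int
    manifest: str | None = None
    simulation: SimulationSpec | None = None
    algorithms: list[str] = Field(
        default_factory=lambda: ["rrBLUP", "BRR", "BA", "BB", "BL"]
    )
    ensembles: list[str] = Field(default_factory=list)
    grids: dict[str, dict[str, list]] = Field(default_factory=dict)
    do_grid_search: bool = False
    feature_selection: FeatureSelectionPolicy | None = None
    test_fraction: float = 0.2
    n_replicates: int = 10
    validation_fraction_of_train: float = 0.2
    folds: int = 5
    sampler_iterations: int = 12000
    sampler_burn_in: int = 2000
    output_dir: str = "results"

    @field_validator("algorithms")
    @classmethod
    def _known_algorithms(cls, v: list[str]) -> list[str]:
        for a in v:
            base = a.split(":")[0]
            if base not in KNOWN_ALGORITHMS:
                raise ValueError(f"unknown algorithm id {a!r}")
        return v

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def parse_and_validate_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, filling defaults and rejecting unknown keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
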