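"""Run configuration: schema-validated YAML in, resolved YAML out.

Every simulation run writes its fully-resolved configuration (plus seeds and
package version) alongside its outputs, so an output directory is always
self-describing.
"""

from __future__ import annotations

import json
import os
from typing import List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .model import Variant
from .pipeline import (
    FREQUENCIES,
    INTERNAL_ALPHAS,
    INTERNAL_SDS,
    MODULATION_SDS,
    ExperimentPlan,
)

__all__ = ["RunConfig", "load_config", "write_resolved_config", "atomic_write_text"]


class RunConfig(BaseModel):
    """Validated simulation plan; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    frequencies: List[float] = Field(default=list(FREQUENCIES))
    modulation_sds: List[float] = Field(default=list(MODULATION_SDS))
    internal_alphas: List[float] = Field(default=list(INTERNAL_ALPHAS))
    internal_sds: List[float] = Field(default=list(INTERNAL_SDS))
    n_reps: int = Field(default=200, ge=2)
    duration: float = Field(default=60.0, gt=0)
    master_seed: int = 0
    variant: Variant = Variant.MAIN
    engine: Literal["fast", "adaptive"] = "fast"
    transient: float = Field(default=2.0, ge=0)
    internal_alpha: float = Field(default=1.0, ge=0)
    internal_sd: float = Field(default=16.0, ge=0)
    tie_policy: Literal["absorb", "separate"] = "absorb"
    histogram_range: Tuple[float, float] = (0.1, 30.0)
    histogram_bins: int = Field(default=30, gt=0)
    output_dir: str = "results"
    verbosity: int = 1

    def plan(self) -> ExperimentPlan:
        return ExperimentPlan(
            frequencies=tuple(self.frequencies),
            modulation_sds=tuple(self.modulation_sds),
            internal_alphas=tuple(self.internal_alphas),
            internal_sds=tuple(self.internal_sds),
            n_reps=self.n_reps,
            duration=self.duration,
            master_seed=self.master_seed,
            variant=self.variant,
            engine=self.engine,
            transient=self.transient,
        )


def load_config(path: Optional[str]) -> RunConfig:
    """Load a YAML config; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def atomic_write_text(path: str, text: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def write_resolved_config(config: RunConfig, out_dir: str) -> str:
    """Record the resolved config and package version next to the outputs."""
    os.makedirs(out_dir, exist_ok=True)
    payload = json.loads(config.model_dump_json())
    payload["package_version"] = __version__
    path = os.path.join(out_dir, "run_config.yaml")
    atomic_write_text(path, yaml.safe_dump(payload, sort_keys=True))
    return path
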