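"""Pipeline configuration: correlation constants, threshold, switches."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .correlation import CorrelationConstants, DEFAULT_CONSTANTS
from .hemolysis import DEFAULT_THRESHOLD_PA


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the screening pipeline.

    ``velocity_first`` selects the interpolation axis order in the
    correction tables (velocity, then shape parameter — the default — or
    the reverse; the difference is <1 % on the tabulated grids and the
    switch exists for sensitivity checks).  ``consistency_tol`` is the
    allowed relative disagreement between a measured velocity and one
    recomputed from the volumetric flow.
    """

    constants: CorrelationConstants = DEFAULT_CONSTANTS
    threshold_pa: float = DEFAULT_THRESHOLD_PA
    velocity_first: bool = True
    consistency_tol: float = 0.02

    def __post_init__(self) -> None:
        if self.threshold_pa <= 0:
            raise ValueError("threshold must be positive")
        if not 0 < self.consistency_tol < 1:
            raise ValueError("consistency tolerance must lie in (0, 1)")


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives the defaults.

    Recognised keys: ``alpha``, ``beta``, ``gamma``, ``threshold_pa``,
    ``velocity_first``, ``consistency_tol``.  Unknown keys are an error so
    typos do not silently fall back to defaults.
    """
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {"alpha", "beta", "gamma", "threshold_pa", "velocity_first",
             "consistency_tol"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    constants = CorrelationConstants(
        alpha=float(raw.get("alpha", DEFAULT_CONSTANTS.alpha)),
        beta=float(raw.get("beta", DEFAULT_CONSTANTS.beta)),
        gamma=float(raw.get("gamma", DEFAULT_CONSTANTS.gamma)),
    )
    return PipelineConfig(
        constants=constants,
        threshold_pa=float(raw.get("threshold_pa", DEFAULT_THRESHOLD_PA)),
        velocity_first=bool(raw.get("velocity_first", True)),
        consistency_tol=float(raw.get("consistency_tol", 0.02)),
    )
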