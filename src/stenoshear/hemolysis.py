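"""Hemolysis fraction, risk classification, and critical-velocity inversion.

The hemolysis fraction follows a population-balance view of blood: red
blood cells circulate both as single cells (number concentration ``ms``,
cell size ``L0``) and as agglomerates represented by three quadrature nodes
(weight ``wi``, size ``Li``).  Only fully deagglomerated single cells are
exposed to damaging shear, so the released-hemoglobin fraction is the
single-cell hemolysis level ``H`` scaled by the single-cell volume share:

    dHb/Hb = H * ms*L0**3 / (ms*L0**3 + sum_i wi*Li**3)

``H`` — the damage level of a single cell under the local shear history —
comes from an upstream power-law damage model and is supplied by the
caller; this module treats it as an input.

Risk classification compares the predicted maximum shear stress against a
hemolysis threshold (default 150 Pa, the commonly cited onset of
shear-induced red-cell damage); the boundary case counts as at-risk.  The
critical velocity is the upstream mean velocity at which the predicted
maximum shear stress first reaches the threshold, found by bracketed root
finding on the (monotone) correlation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from .correlation import (
    DEFAULT_CONSTANTS,
    CorrelationConstants,
    ShearPrediction,
    tau_max,
)
from .geometry import BASE, BaseGeometry, FlowCondition, StenosisGeometry

#: Shear-stress threshold above which hemolysis is expected, Pa.
DEFAULT_THRESHOLD_PA = 150.0

#: Velocity bracket for the critical-velocity search, m/s.
VELOCITY_BRACKET = (0.01, 2.0)


class HemolysisError(ValueError):
    """Raised for invalid population-balance states or thresholds."""


@dataclass(frozen=True)
class DQMOMState:
    """Single-cell concentration plus three agglomerate quadrature nodes.

    Concentrations are in any consistent unit; lengths likewise (the
    fraction is invariant under common rescaling of either).
    """

    ms: float
    L0: float
    weights: tuple[float, float, float]
    sizes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.ms < 0:
            raise HemolysisError("single-cell concentration must be non-negative")
        if self.L0 <= 0:
            raise HemolysisError("single-cell size must be positive")
        if len(self.weights) != 3 or len(self.sizes) != 3:
            raise HemolysisError("exactly three agglomerate nodes are required")
        if any(w < 0 for w in self.weights):
            raise HemolysisError("agglomerate weights must be non-negative")
        if any(L <= 0 for L in self.sizes):
            raise HemolysisError("agglomerate sizes must be positive")


def hemolysis_fraction(H: float, state: DQMOMState) -> float:
    """Released-hemoglobin fraction dHb/Hb for a population-balance state.

    Bounded by [0, H]: equals H when all cells are single (weights zero)
    and 0 when no single cells remain (ms = 0).
    """
    if H < 0:
        raise HemolysisError("single-cell hemolysis level H must be non-negative")
    single = state.ms * state.L0**3
    agglomerated = sum(w * L**3 for w, L in zip(state.weights, state.sizes))
    total = single + agglomerated
    if total == 0:
        raise HemolysisError("all-zero state: hemolysis fraction undefined")
    return H * single / total


class RiskClass(str, enum.Enum):
    BELOW_THRESHOLD = "below_threshold"
    AT_RISK = "at_risk"


@dataclass(frozen=True)
class RiskAssessment:
    tau_max: float
    threshold: float
    risk_class: RiskClass
    margin: float                      # tau_max / threshold
    critical_velocity: Optional[float] = None


def classify_risk(
    prediction: ShearPrediction, threshold: float = DEFAULT_THRESHOLD_PA
) -> RiskAssessment:
    """Threshold the predicted maximum shear stress.

    The boundary tau_max == threshold is classified at-risk — the
    conservative choice for a screening tool.
    """
    if threshold <= 0:
        raise HemolysisError("threshold must be positive")
    tm = prediction.tau_max
    risk = RiskClass.AT_RISK if tm >= threshold else RiskClass.BELOW_THRESHOLD
    return RiskAssessment(
        tau_max=tm, threshold=threshold, risk_class=risk, margin=tm / threshold
    )


class NoRiskInRange(Exception):
    """The threshold is not reached anywhere in the velocity bracket."""


def critical_velocity(
    geometry: StenosisGeometry,
    base: BaseGeometry = BASE,
    constants: CorrelationConstants = DEFAULT_CONSTANTS,
    threshold: float = DEFAULT_THRESHOLD_PA,
    rtol: float = 1e-4,
) -> tuple[float, bool]:
    """Upstream velocity at which tau_max first reaches the threshold.

    Returns ``(u_star, floored)``.  ``floored`` is True when the threshold
    is already exceeded at the lower bracket edge (0.01 m/s), in which case
    that edge is returned.  Raises :class:`NoRiskInRange` when even 2 m/s
    does not reach the threshold.  The search uses bracketed root finding;
    tau_max is strictly increasing in velocity, so the root is unique.
    """
    if threshold <= 0:
        raise HemolysisError("threshold must be positive")
    lo, hi = VELOCITY_BRACKET

    def excess(u: float) -> float:
        flow = FlowCondition(mean_velocity_before_stenosis=u)
        return tau_max(geometry, flow, base, constants).tau_max - threshold

    f_lo, f_hi = excess(lo), excess(hi)
    if f_lo > 0:
        return lo, True
    if f_hi < 0:
        raise NoRiskInRange(
            f"tau_max({hi} m/s) stays below the {threshold} Pa threshold"
        )
    u_star = brentq(excess, lo, hi, xtol=1e-10, rtol=1e-12)
    if abs(excess(u_star)) / threshold >= rtol:
        raise RuntimeError("root finding failed to converge on the threshold")
    return float(u_star), False
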