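"""Maximum-shear-stress correlation for stenosed arteries.

The estimator is a two-stage surrogate for full CFD:

1.  A baseline power law for the peak shear stress in a reference stenosis
    geometry,

        tau0 = alpha * u**beta * r**gamma,

    with ``u`` the upstream mean velocity (m/s), ``r`` the degree of
    stenosis sqrt(Ac/A0), and fitted constants alpha = 24.21 Pa·(s/m)^beta,
    beta = 1.346, gamma = -3.385.

2.  Multiplicative correction coefficients read from tabulated CFD results:
    beta1 for vessel scale k, beta2 for dimensionless stenosis length z,
    beta3 for throat flattening w, giving

        tau_max = tau0 * beta1 * beta2 * beta3.

Within each table the coefficient is interpolated with shape-preserving
piecewise cubics (PCHIP), first along the velocity axis and then along the
shape-parameter axis; this is exact at every printed node and never
overshoots the bracketing node values.  Outside the tabulated scale-factor
range, beta1 is extrapolated with a per-velocity power-law fit a·k^b whose
log-log least-squares R² exceeds 0.99 on the printed nodes.  Velocities
outside the tabulated range, z outside its column range and w outside its
column range are clamped, and every clamp or extrapolation is reported as a
provenance flag on the prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .geometry import (
    BASE,
    BaseGeometry,
    FlowCondition,
    StenosisGeometry,
    resolve_velocity,
    shape_parameters,
)

# provenance flags
EXTRAPOLATED_K = "extrapolated_k"
CLAMPED_VELOCITY = "clamped_velocity"
CLAMPED_Z = "clamped_z"
CLAMPED_W = "clamped_w"
BETA3_DEFAULTED = "beta3_defaulted"


class CorrelationError(ValueError):
    """Raised for inputs outside the correlation's domain."""


@dataclass(frozen=True)
class CorrelationConstants:
    """Constants of the baseline power law; override only deliberately."""

    alpha: float = 24.21   # Pa per (m/s)**beta
    beta: float = 1.346    # velocity exponent
    gamma: float = -3.385  # stenosis-degree exponent


DEFAULT_CONSTANTS = CorrelationConstants()


def tau0(
    u: float,
    stenosis_degree: float,
    constants: CorrelationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Baseline maximum shear stress (Pa) for the reference geometry.

    Strictly increasing in ``u`` and, because gamma < 0, strictly
    decreasing in the degree of stenosis (tighter throats give higher
    stress).
    """
    if u <= 0:
        raise CorrelationError("velocity must be positive")
    if stenosis_degree <= 0:
        raise CorrelationError("fully occluded vessel: stenosis degree must be > 0")
    if stenosis_degree > 1:
        raise CorrelationError("stenosis degree must lie in (0, 1]")
    return constants.alpha * u**constants.beta * stenosis_degree**constants.gamma


def relative_deviation(predicted: float, reference: float) -> float:
    """Signed percent deviation 100·(predicted − reference)/reference."""
    if reference <= 0:
        raise CorrelationError("reference stress must be positive")
    return 100.0 * (predicted - reference) / reference


class CorrectionTable:
    """One tabulated correction coefficient: velocity grid × shape grid.

    Interpolation is PCHIP along each axis (exact at nodes, no overshoot);
    the axis order is velocity first by default.  Queries outside the
    velocity grid clamp to the nearest grid row.  Shape-axis behaviour is
    controlled per table by the owner (clamping or power-law
    extrapolation).
    """

    def __init__(self, velocity_grid: np.ndarray, shape_grid: np.ndarray,
                 values: np.ndarray, name: str = "") -> None:
        velocity_grid = np.asarray(velocity_grid, dtype=float)
        shape_grid = np.asarray(shape_grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if values.shape != (velocity_grid.size, shape_grid.size):
            raise ValueError("coefficient matrix does not match the grids")
        if np.any(values <= 0):
            raise ValueError("correction coefficients must be positive")
        if np.any(np.diff(velocity_grid) <= 0) or np.any(np.diff(shape_grid) <= 0):
            raise ValueError("grids must be strictly ascending")
        self.velocity_grid = velocity_grid
        self.shape_grid = shape_grid
        self.values = values
        self.name = name

    @classmethod
    def from_packaged_csv(cls, filename: str) -> "CorrectionTable":
        with resources.files("stenoshear.data").joinpath(filename).open() as fh:
            df = pd.read_csv(fh)
        velocity = df.iloc[:, 0].to_numpy(float)
        shape = np.array([float(c) for c in df.columns[1:]])
        return cls(velocity, shape, df.iloc[:, 1:].to_numpy(float), name=filename)

    def clamp_velocity(self, u: float) -> tuple[float, bool]:
        lo, hi = self.velocity_grid[0], self.velocity_grid[-1]
        if u < lo:
            return lo, True
        if u > hi:
            return hi, True
        return u, False

    def row_at_velocity(self, u: float) -> np.ndarray:
        """Coefficient values at every shape node, interpolated in velocity."""
        return np.array([
            PchipInterpolator(self.velocity_grid, self.values[:, j])(u)
            for j in range(self.shape_grid.size)
        ])

    def interpolate(self, u: float, s: float, velocity_first: bool = True) -> float:
        """Bivariate lookup at in-range (u, s); caller handles clamping."""
        if velocity_first:
            row = self.row_at_velocity(u)
            return float(PchipInterpolator(self.shape_grid, row)(s))
        col = np.array([
            PchipInterpolator(self.shape_grid, self.values[i, :])(s)
            for i in range(self.velocity_grid.size)
        ])
        return float(PchipInterpolator(self.velocity_grid, col)(u))


def _load_tables() -> dict[str, CorrectionTable]:
    return {
        "beta1": CorrectionTable.from_packaged_csv("beta1_scale.csv"),
        "beta2": CorrectionTable.from_packaged_csv("beta2_length.csv"),
        "beta3": CorrectionTable.from_packaged_csv("beta3_throat.csv"),
    }


_TABLES: Optional[dict[str, CorrectionTable]] = None


def tables() -> dict[str, CorrectionTable]:
    """Packaged correction tables, loaded once per process."""
    global _TABLES
    if _TABLES is None:
        _TABLES = _load_tables()
    return _TABLES


@dataclass(frozen=True)
class PowerFit:
    """Per-velocity power-law fit beta1(k) = a·k^b with its log-log R²."""

    a: float
    b: float
    r_squared: float

    def __call__(self, k: float) -> float:
        return self.a * k**self.b


_POWER_FITS: Optional[list[PowerFit]] = None


def beta1_power_fits() -> list[PowerFit]:
    """Least-squares power-law fits of the scale-factor table, one per
    velocity row, used to extrapolate beta1 beyond the tabulated k range."""
    global _POWER_FITS
    if _POWER_FITS is None:
        table = tables()["beta1"]
        logk = np.log(table.shape_grid)
        fits = []
        for i in range(table.velocity_grid.size):
            logy = np.log(table.values[i, :])
            b, loga = np.polyfit(logk, logy, 1)
            resid = logy - (loga + b * logk)
            ss_tot = np.sum((logy - logy.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot
            fits.append(PowerFit(a=math.exp(loga), b=b, r_squared=r2))
        _POWER_FITS = fits
    return _POWER_FITS


def beta1(u: float, k: float, velocity_first: bool = True) -> tuple[float, set[str]]:
    """Vessel-scale correction coefficient with provenance flags.

    In-range k uses the bivariate spline; k outside the tabulated
    [0.50, 1.25] range is extrapolated with the per-velocity power fits.
    """
    if u <= 0 or k <= 0:
        raise CorrelationError("velocity and scale factor must be positive")
    flags: set[str] = set()
    table = tables()["beta1"]
    uc, clamped = table.clamp_velocity(u)
    if clamped:
        flags.add(CLAMPED_VELOCITY)
    if table.shape_grid[0] <= k <= table.shape_grid[-1]:
        value = table.interpolate(uc, k, velocity_first)
    else:
        flags.add(EXTRAPOLATED_K)
        fits = beta1_power_fits()
        per_velocity = np.array([fit(k) for fit in fits])
        value = float(PchipInterpolator(table.velocity_grid, per_velocity)(uc))
    return value, flags


def beta2(u: float, z: float, velocity_first: bool = True) -> tuple[float, set[str]]:
    """Stenosis-length correction coefficient with provenance flags.

    z above the tabulated range clamps to 1 (stenoses longer than the
    reference are milder); z below it clamps to the shortest-stenosis
    column.
    """
    if u <= 0 or z <= 0:
        raise CorrelationError("velocity and dimensionless length must be positive")
    flags: set[str] = set()
    table = tables()["beta2"]
    uc, clamped = table.clamp_velocity(u)
    if clamped:
        flags.add(CLAMPED_VELOCITY)
    if z > table.shape_grid[-1]:
        return 1.0, flags | {CLAMPED_Z}
    if z < table.shape_grid[0]:
        flags.add(CLAMPED_Z)
        z = table.shape_grid[0]
    return table.interpolate(uc, z, velocity_first), flags


def beta3(
    u: float, w: Optional[float], velocity_first: bool = True
) -> tuple[float, set[str]]:
    """Throat-flattening correction coefficient with provenance flags.

    Returns 1 with a flag when the throat shape is unknown; the flattening
    correction is negligible except for strongly flattened throats.
    """
    if u <= 0:
        raise CorrelationError("velocity must be positive")
    if w is None:
        return 1.0, {BETA3_DEFAULTED}
    if w <= 0:
        raise CorrelationError("dimensionless throat diameter must be positive")
    flags: set[str] = set()
    table = tables()["beta3"]
    uc, clamped = table.clamp_velocity(u)
    if clamped:
        flags.add(CLAMPED_VELOCITY)
    if w < table.shape_grid[0]:
        flags.add(CLAMPED_W)
        w = table.shape_grid[0]
    elif w > table.shape_grid[-1]:
        flags.add(CLAMPED_W)
        w = table.shape_grid[-1]
    return table.interpolate(uc, w, velocity_first), flags


@dataclass(frozen=True)
class ShearPrediction:
    """Corrected maximum-shear-stress prediction with full provenance."""

    u: float
    tau0: float
    beta1: float
    beta2: float
    beta3: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def tau_max(self) -> float:
        return self.tau0 * self.beta1 * self.beta2 * self.beta3


def tau_max(
    geometry: StenosisGeometry,
    flow: FlowCondition,
    base: BaseGeometry = BASE,
    constants: CorrelationConstants = DEFAULT_CONSTANTS,
    velocity_first: bool = True,
) -> ShearPrediction:
    """Corrected maximum shear stress for a measured stenosis and flow.

    Derives (k, z, w), evaluates the baseline power law and the three
    correction coefficients, and returns their product with every clamp or
    extrapolation flagged.  For the reference geometry itself all
    corrections equal 1 and the prediction reduces to the baseline value.
    """
    u = resolve_velocity(flow, geometry)
    shape = shape_parameters(geometry, base)
    t0 = tau0(u, geometry.stenosis_degree, constants)
    b1, f1 = beta1(u, shape.k, velocity_first)
    b2, f2 = beta2(u, shape.z, velocity_first)
    b3, f3 = beta3(u, shape.w, velocity_first)
    return ShearPrediction(
        u=u, tau0=t0, beta1=b1, beta2=b2, beta3=b3,
        flags=frozenset(f1 | f2 | f3),
    )
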