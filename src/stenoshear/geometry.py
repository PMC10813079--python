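"""Stenosis geometry descriptors and their dimensionless shape parameters.

All public interfaces use clinical units (mm, mm², mL/s); velocities are in
m/s and stresses in Pa.  Conversions to SI happen exactly once, inside the
functions that need them.

The dimensionless parameters normalise a measured stenosis against a fixed
reference ("base") geometry:

* ``k`` — scale factor, the ratio of the measured inlet hydraulic diameter
  to the base inlet hydraulic diameter;
* ``z`` — dimensionless stenosis length, the stenosis length divided by the
  scaled base inlet hydraulic diameter;
* ``w`` — dimensionless throat hydraulic diameter, the throat hydraulic
  diameter divided by the scaled base throat hydraulic diameter.  ``w < 1``
  means the throat lumen is flattened relative to a circular throat of the
  same area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


class GeometryError(ValueError):
    """Raised for physically invalid geometry or flow descriptors."""


@dataclass(frozen=True)
class BaseGeometry:
    """Reference geometry against which shape parameters are normalised.

    The defaults describe a 4 mm idealised vessel with a 16 mm stenosis:
    the size/length reference has a stenosis degree of 0.4 (throat hydraulic
    diameter 1.53 mm), while the throat-flattening reference uses the
    degree-0.3 variant of the same vessel (circular throat hydraulic
    diameter 1.15 mm).
    """

    Dh0: float = 3.83  # inlet hydraulic diameter, mm
    Dh: float = 1.15   # throat hydraulic diameter of the flattening reference, mm
    L: float = 16.0    # stenosis length, mm
    D: float = 4.0     # vessel diameter, mm

    def __post_init__(self) -> None:
        for name in ("Dh0", "Dh", "L", "D"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"base geometry {name} must be positive")


#: Module-wide default reference geometry.
BASE = BaseGeometry()


@dataclass(frozen=True)
class StenosisGeometry:
    """Per-case vessel and stenosis dimensions.

    Parameters
    ----------
    inlet_hydraulic_diameter : float
        Hydraulic diameter of the unstenosed inlet, mm.
    stenosis_length : float
        Length of the stenosis (onset to maximal narrowing), mm.
    stenosis_degree : float
        sqrt(throat area / reference area), in (0, 1].
    throat_hydraulic_diameter : float, optional
        Hydraulic diameter of the throat lumen, mm.  When absent the
        throat-flattening correction defaults to 1.
    """

    inlet_hydraulic_diameter: float
    stenosis_length: float
    stenosis_degree: float
    throat_hydraulic_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.inlet_hydraulic_diameter <= 0:
            raise GeometryError("inlet hydraulic diameter must be positive")
        if self.stenosis_length <= 0:
            raise GeometryError("stenosis length must be positive")
        if not 0 < self.stenosis_degree <= 1:
            raise GeometryError("stenosis degree must lie in (0, 1]")
        if self.throat_hydraulic_diameter is not None:
            if self.throat_hydraulic_diameter <= 0:
                raise GeometryError("throat hydraulic diameter must be positive")
            if self.throat_hydraulic_diameter >= self.inlet_hydraulic_diameter:
                raise GeometryError(
                    "throat hydraulic diameter must be smaller than the inlet"
                )


@dataclass(frozen=True)
class FlowCondition:
    """A physiological flow state (e.g. rest, exercise mean, systole peak).

    At least one of ``volumetric_flow`` (mL/s) or
    ``mean_velocity_before_stenosis`` (m/s) must be given.  If both are
    given they must agree, through the inlet cross-section, to within 2 %.
    Consistency is checked lazily by :func:`resolve_velocity` because it
    needs the inlet diameter.
    """

    volumetric_flow: Optional[float] = None          # mL/s
    mean_velocity_before_stenosis: Optional[float] = None  # m/s
    label: str = ""

    def __post_init__(self) -> None:
        if self.volumetric_flow is None and self.mean_velocity_before_stenosis is None:
            raise GeometryError("flow condition needs a flow or a velocity")
        if self.volumetric_flow is not None and self.volumetric_flow <= 0:
            raise GeometryError("volumetric flow must be positive")
        if (
            self.mean_velocity_before_stenosis is not None
            and self.mean_velocity_before_stenosis <= 0
        ):
            raise GeometryError("mean velocity must be positive")


@dataclass(frozen=True)
class DimensionlessShape:
    """The (k, z, w) triple consumed by the correction-table lookups."""

    k: float
    z: float
    w: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k <= 0 or self.z <= 0:
            raise GeometryError("k and z must be positive")
        if self.w is not None and not 0 < self.w <= 1.05:
            raise GeometryError("w must lie in (0, 1.05]")


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """Hydraulic diameter 4A/P of a cross-section (mm² and mm in, mm out).

    Equals the diameter for a circle and the side for a square.
    """
    if area <= 0 or perimeter <= 0:
        raise GeometryError("area and perimeter must be positive")
    return 4.0 * area / perimeter


def stenosis_degree(throat_area: float, reference_area: float) -> float:
    """Degree of stenosis sqrt(Ac/A0) from throat and reference areas (mm²).

    Smaller values mean tighter narrowing; 1 means no stenosis.
    """
    if throat_area <= 0 or reference_area <= 0:
        raise GeometryError("areas must be positive")
    if throat_area > reference_area:
        raise GeometryError("throat area cannot exceed the reference area")
    return math.sqrt(throat_area / reference_area)


def scale_factor(geometry: StenosisGeometry, base: BaseGeometry = BASE) -> float:
    """Scale factor k: measured inlet hydraulic diameter over the base's."""
    return geometry.inlet_hydraulic_diameter / base.Dh0


def dimensionless_length(
    geometry: StenosisGeometry, k: float, base: BaseGeometry = BASE
) -> float:
    """Dimensionless stenosis length z = l / (k · Dh0)."""
    if k <= 0:
        raise GeometryError("scale factor must be positive")
    return geometry.stenosis_length / (k * base.Dh0)


def dimensionless_throat_diameter(
    geometry: StenosisGeometry, k: float, base: BaseGeometry = BASE
) -> Optional[float]:
    """Dimensionless throat hydraulic diameter w = dh / (k · Dh).

    Returns ``None`` when the throat hydraulic diameter was not measured;
    the caller then falls back to a throat-flattening correction of 1.
    """
    if k <= 0:
        raise GeometryError("scale factor must be positive")
    if geometry.throat_hydraulic_diameter is None:
        return None
    return geometry.throat_hydraulic_diameter / (k * base.Dh)


def shape_parameters(
    geometry: StenosisGeometry, base: BaseGeometry = BASE
) -> DimensionlessShape:
    """Derive the full (k, z, w) triple for a measured geometry."""
    k = scale_factor(geometry, base)
    z = dimensionless_length(geometry, k, base)
    w = dimensionless_throat_diameter(geometry, k, base)
    if w is not None and w > 1.05:
        # a throat cannot be wider than the equal-area circular reference
        # beyond rounding; treat it as circular
        w = 1.0
    return DimensionlessShape(k=k, z=z, w=w)


def _inlet_area_m2(inlet_hydraulic_diameter_mm: float, area_mm2: Optional[float]) -> float:
    if area_mm2 is not None:
        if area_mm2 <= 0:
            raise GeometryError("cross-section area must be positive")
        return area_mm2 * 1e-6
    d = inlet_hydraulic_diameter_mm * 1e-3
    return math.pi * d * d / 4.0


def flow_to_velocity(
    flow: float,
    inlet_hydraulic_diameter: float,
    area_mm2: Optional[float] = None,
) -> float:
    """Mean velocity (m/s) from volumetric flow (mL/s) and inlet size (mm).

    Assumes a circular cross-section with diameter equal to the hydraulic
    diameter unless an explicit area (mm²) is given.
    """
    if flow <= 0:
        raise GeometryError("volumetric flow must be positive")
    return flow * 1e-6 / _inlet_area_m2(inlet_hydraulic_diameter, area_mm2)


def velocity_to_flow(
    velocity: float,
    inlet_hydraulic_diameter: float,
    area_mm2: Optional[float] = None,
) -> float:
    """Volumetric flow (mL/s) from mean velocity (m/s); inverse of
    :func:`flow_to_velocity`."""
    if velocity <= 0:
        raise GeometryError("velocity must be positive")
    return velocity * _inlet_area_m2(inlet_hydraulic_diameter, area_mm2) * 1e6


def resolve_velocity(
    condition: FlowCondition,
    geometry: StenosisGeometry,
    consistency_tol: float = 0.02,
) -> float:
    """Upstream mean velocity (m/s) for a flow condition.

    Prefers the measured velocity; otherwise converts the volumetric flow
    through the (circular) inlet cross-section.  When both are present they
    must agree to within ``consistency_tol`` relative error.
    """
    u_from_flow = None
    if condition.volumetric_flow is not None:
        u_from_flow = flow_to_velocity(
            condition.volumetric_flow, geometry.inlet_hydraulic_diameter
        )
    u = condition.mean_velocity_before_stenosis
    if u is not None and u_from_flow is not None:
        if abs(u - u_from_flow) / u > consistency_tol:
            raise GeometryError(
                f"flow ({condition.volumetric_flow} mL/s -> {u_from_flow:.4f} m/s) "
                f"and velocity ({u} m/s) disagree by more than "
                f"{consistency_tol:.0%} for condition {condition.label!r}"
            )
    if u is not None:
        return u
    assert u_from_flow is not None
    return u_from_flow
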