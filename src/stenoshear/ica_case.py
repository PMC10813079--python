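"""Packaged worked example: a patient internal-carotid-artery stenosis.

A symptomatic ICA stenosis measured from routine CT before angioplasty:
inlet hydraulic diameter 7.6 mm (enlarged by an aneurysm upstream of the
plaque), 10 mm from stenosis onset to maximal narrowing, degree of stenosis
sqrt(Ac/A0) = 0.29.  Three flow states are screened — mean flow at rest,
mean flow during exercise, and the systole peak during exercise.

``REFERENCE`` holds the published comparison for this case: the baseline
stress, the correction coefficients obtained there by spline interpolation
and power-law extrapolation, the corrected prediction, and the full-CFD
reference stress.  These printed values are the benchmark the demo and the
regression tests compare against; the package recomputes everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import FlowCondition, StenosisGeometry

GEOMETRY = StenosisGeometry(
    inlet_hydraulic_diameter=7.6,
    stenosis_length=10.0,
    stenosis_degree=0.29,
)

CONDITIONS = (
    FlowCondition(volumetric_flow=4.00, mean_velocity_before_stenosis=0.088,
                  label="mean flow at rest"),
    FlowCondition(volumetric_flow=7.95, mean_velocity_before_stenosis=0.174,
                  label="mean flow during exercise"),
    FlowCondition(volumetric_flow=20.6, mean_velocity_before_stenosis=0.451,
                  label="systole peak flow during exercise"),
)


@dataclass(frozen=True)
class ReferenceRow:
    """Published correlation-vs-CFD comparison for one flow state."""

    label: str
    flow_ml_s: float
    u: float          # m/s
    tau0: float       # Pa
    beta1: float
    beta2: float
    tau_max: float    # Pa
    tau_cfd: float    # Pa
    deviation_pct: float


REFERENCE = (
    ReferenceRow("mean flow at rest", 4.00, 0.088,
                 60.3, 0.6179, 1.1397, 42.5, 51.6, -17.6),
    ReferenceRow("mean flow during exercise", 7.95, 0.174,
                 152.0, 0.6436, 1.2125, 118.7, 132.0, -10.1),
    ReferenceRow("systole peak flow during exercise", 20.6, 0.451,
                 548.1, 0.6829, 1.2456, 466.2, 496.7, -6.1),
)
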