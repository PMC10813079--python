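"""Cohort ingestion, synthetic-cohort generation, and the batch pipeline.

A cohort is a list of cases, each with one measured stenosis geometry and
one or more flow conditions.  The on-disk format is a plain CSV with one
row per (case, condition):

    case_id, inlet_dh_mm, throat_dh_mm, stenosis_length_mm,
    stenosis_degree, flow_ml_s, velocity_m_s, label

``throat_dh_mm`` and one of ``flow_ml_s`` / ``velocity_m_s`` may be empty.
Rows sharing a ``case_id`` must agree on the geometry columns.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import correlation, geometry, hemolysis
from .config import PipelineConfig
from .geometry import FlowCondition, GeometryError, StenosisGeometry

logger = logging.getLogger("stenoshear")

REQUIRED_COLUMNS = ("case_id", "inlet_dh_mm", "stenosis_length_mm",
                    "stenosis_degree")
OPTIONAL_COLUMNS = ("throat_dh_mm", "flow_ml_s", "velocity_m_s", "label")

REPORT_COLUMNS = ("case_id", "label", "u_m_s", "tau0_pa", "beta1", "beta2",
                  "beta3", "tau_max_pa", "threshold_pa", "risk_class",
                  "critical_velocity_m_s", "flags", "error")


class CohortSchemaError(ValueError):
    """The cohort file is structurally unusable (missing columns, no header)."""


@dataclass(frozen=True)
class CohortRecord:
    case_id: str
    geometry: StenosisGeometry
    conditions: tuple[FlowCondition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError(f"case {self.case_id!r} has no flow conditions")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameter ranges for seeded synthetic cohorts.

    Defaults span the validity region of the correction tables: inlet
    hydraulic diameters of 2–10 mm, stenosis degrees of 0.2–0.8, stenosis
    lengths of 4–20 mm and upstream velocities of 0.05–0.53 m/s.
    """

    n_cases: int = 10
    seed: int = 0
    inlet_dh_mm: tuple[float, float] = (2.0, 10.0)
    stenosis_degree: tuple[float, float] = (0.2, 0.8)
    stenosis_length_mm: tuple[float, float] = (4.0, 20.0)
    velocity_m_s: tuple[float, float] = (0.05, 0.53)
    throat_fraction: float = 0.5  # probability a case has a measured throat

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        for name in ("inlet_dh_mm", "stenosis_degree", "stenosis_length_mm",
                     "velocity_m_s"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_cohort(path: Union[str, Path]) -> list[CohortRecord]:
    """Read and validate a cohort CSV.

    Rows that violate the geometry or flow invariants are rejected with a
    row-numbered warning; a missing required column raises
    :class:`CohortSchemaError`.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    if "flow_ml_s" not in df.columns and "velocity_m_s" not in df.columns:
        raise CohortSchemaError(
            "cohort needs a flow_ml_s or velocity_m_s column"
        )
    if df.empty:
        logger.warning("cohort file %s has a header but no rows", path)
        return []

    cases: dict[str, tuple[StenosisGeometry, list[FlowCondition]]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            geom = StenosisGeometry(
                inlet_hydraulic_diameter=float(row["inlet_dh_mm"]),
                stenosis_length=float(row["stenosis_length_mm"]),
                stenosis_degree=float(row["stenosis_degree"]),
                throat_hydraulic_diameter=_opt(row.get("throat_dh_mm")),
            )
            cond = FlowCondition(
                volumetric_flow=_opt(row.get("flow_ml_s")),
                mean_velocity_before_stenosis=_opt(row.get("velocity_m_s")),
                label=str(row.get("label", "") or ""),
            )
            # surfaces inconsistent flow/velocity pairs at read time
            geometry.resolve_velocity(cond, geom)
        except (GeometryError, ValueError, TypeError) as exc:
            logger.warning("row %d rejected: %s", line, exc)
            continue
        case_id = str(row["case_id"])
        if case_id in cases:
            if cases[case_id][0] != geom:
                logger.warning(
                    "row %d rejected: case %r repeats with a different "
                    "geometry", line, case_id,
                )
                continue
            cases[case_id][1].append(cond)
        else:
            cases[case_id] = (geom, [cond])
    return [CohortRecord(cid, geom, tuple(conds))
            for cid, (geom, conds) in cases.items()]


def generate_fixture_cohort(spec: FixtureSpec) -> list[CohortRecord]:
    """Draw a synthetic cohort uniformly within the spec's ranges.

    Fully reproducible: the same spec (including seed) yields the same
    cohort.  Throat hydraulic diameters, when present, are drawn between
    70 % and 100 % of the equal-area circular throat diameter
    (degree × inlet diameter), mirroring realistic lumen flattening.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_cases):
        inlet = round(rng.uniform(*spec.inlet_dh_mm), 4)
        degree = round(rng.uniform(*spec.stenosis_degree), 4)
        length = round(rng.uniform(*spec.stenosis_length_mm), 4)
        u = round(rng.uniform(*spec.velocity_m_s), 4)
        throat: Optional[float] = None
        if rng.random() < spec.throat_fraction:
            throat = round(degree * inlet * rng.uniform(0.7, 1.0), 4)
        records.append(CohortRecord(
            case_id=f"case{i:04d}",
            geometry=StenosisGeometry(
                inlet_hydraulic_diameter=inlet,
                stenosis_length=length,
                stenosis_degree=degree,
                throat_hydraulic_diameter=throat,
            ),
            conditions=(FlowCondition(
                mean_velocity_before_stenosis=u, label="synthetic"),),
        ))
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Flatten a cohort to the on-disk one-row-per-condition layout."""
    rows = []
    for rec in records:
        for cond in rec.conditions:
            rows.append({
                "case_id": rec.case_id,
                "inlet_dh_mm": rec.geometry.inlet_hydraulic_diameter,
                "throat_dh_mm": rec.geometry.throat_hydraulic_diameter,
                "stenosis_length_mm": rec.geometry.stenosis_length,
                "stenosis_degree": rec.geometry.stenosis_degree,
                "flow_ml_s": cond.volumetric_flow,
                "velocity_m_s": cond.mean_velocity_before_stenosis,
                "label": cond.label,
            })
    return pd.DataFrame(rows, columns=["case_id", "inlet_dh_mm",
                                       "throat_dh_mm", "stenosis_length_mm",
                                       "stenosis_degree", "flow_ml_s",
                                       "velocity_m_s", "label"])


def write_cohort(records: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def run_pipeline(
    records: Sequence[CohortRecord],
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Screen every (case, condition) pair and return the report table.

    One output row per condition: velocity, baseline stress, the three
    correction coefficients, the corrected maximum stress, the risk class,
    the case's critical velocity, and any provenance flags.  Failures are
    isolated per row (reported in the ``error`` column), never fatal to
    the batch.
    """
    rows = []
    for rec in records:
        # critical velocity depends only on the geometry, not the condition
        crit: Optional[float]
        try:
            crit, floored = hemolysis.critical_velocity(
                rec.geometry, constants=config.constants,
                threshold=config.threshold_pa)
            if floored:
                logger.warning(
                    "case %s: threshold already exceeded at %.2f m/s",
                    rec.case_id, crit)
        except hemolysis.NoRiskInRange:
            crit = None
        except Exception as exc:  # pragma: no cover - defensive isolation
            logger.warning("case %s: critical velocity failed: %s",
                           rec.case_id, exc)
            crit = None
        for cond in rec.conditions:
            base_row = {"case_id": rec.case_id, "label": cond.label,
                        "threshold_pa": config.threshold_pa,
                        "critical_velocity_m_s": crit, "error": ""}
            try:
                u = geometry.resolve_velocity(cond, rec.geometry,
                                              config.consistency_tol)
                shape = geometry.shape_parameters(rec.geometry)
                t0 = correlation.tau0(u, rec.geometry.stenosis_degree,
                                      config.constants)
                b1, f1 = correlation.beta1(u, shape.k, config.velocity_first)
                b2, f2 = correlation.beta2(u, shape.z, config.velocity_first)
                b3, f3 = correlation.beta3(u, shape.w, config.velocity_first)
                pred = correlation.ShearPrediction(
                    u=u, tau0=t0, beta1=b1, beta2=b2, beta3=b3,
                    flags=frozenset(f1 | f2 | f3))
                assessment = hemolysis.classify_risk(pred, config.threshold_pa)
                for flag in sorted(pred.flags):
                    logger.warning("case %s (%s): %s", rec.case_id,
                                   cond.label, flag)
                rows.append({**base_row,
                             "u_m_s": u, "tau0_pa": t0, "beta1": b1,
                             "beta2": b2, "beta3": b3,
                             "tau_max_pa": pred.tau_max,
                             "risk_class": assessment.risk_class.value,
                             "flags": "|".join(sorted(pred.flags))})
            except (GeometryError, correlation.CorrelationError,
                    hemolysis.HemolysisError) as exc:
                logger.warning("case %s (%s) failed: %s", rec.case_id,
                               cond.label, exc)
                rows.append({**base_row, "u_m_s": np.nan, "tau0_pa": np.nan,
                             "beta1": np.nan, "beta2": np.nan,
                             "beta3": np.nan, "tau_max_pa": np.nan,
                             "risk_class": "", "flags": "",
                             "error": str(exc)})
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def write_report(report: pd.DataFrame, csv_path: Union[str, Path, None] = None,
                 json_path: Union[str, Path, None] = None) -> None:
    """Emit the report as CSV (stresses to 0.1 Pa) and/or full-precision JSON."""
    if csv_path is not None:
        formatted = report.copy()
        for col in ("tau0_pa", "tau_max_pa", "threshold_pa"):
            formatted[col] = formatted[col].round(1)
        for col in ("u_m_s", "beta1", "beta2", "beta3",
                    "critical_velocity_m_s"):
            formatted[col] = formatted[col].round(4)
        formatted.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = report.replace({np.nan: None}).to_dict(orient="records")
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
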