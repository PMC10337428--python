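"""End-to-end mass-casualty scenario runner and the bundled demo.

The bundled 10-casualty roster is a documented reconstruction of the
kind of multiple-vehicle-collision scenario the ranking method is meant
for: it contains a walking casualty with severe internal injuries
(classified "green" by START but ranked near the top by survival time)
and an equal-NISS pair separated only by vital signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import (
    DEFAULT_PARAMS,
    LifeModelParams,
    LifeTrajectory,
    rank_cohort,
    trajectory,
)
from .scores import Injury, ScoredPatient, VitalSigns, score_patient
from .triage import (
    DEFAULT_THRESHOLDS,
    LifeTriageThresholds,
    triage_all,
)


class ScenarioSpec(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    patients: tuple = Field(min_length=1)
    label: str = "scenario"

    @field_validator("patients")
    @classmethod
    def _unique_ids(cls, patients: tuple) -> tuple:
        ids = [p.patient_id for p in patients]
        if len(set(ids)) != len(ids):
            raise ValueError("scenario patient ids must be unique")
        return patients


@dataclass(frozen=True)
class ScenarioReport:
    label: str
    table: pd.DataFrame
    trajectories: Dict[str, LifeTrajectory]


def run_scenario(
    spec: ScenarioSpec,
    params: LifeModelParams = DEFAULT_PARAMS,
    thresholds: LifeTriageThresholds = DEFAULT_THRESHOLDS,
    t_grid: Optional[np.ndarray] = None,
) -> ScenarioReport:
    """Score, triage (all algorithms), rank and sample every patient."""
    patients: Sequence[ScoredPatient] = spec.patients
    table = triage_all(patients, ("start", "rts", "life"), thresholds, params)
    ranked = rank_cohort(patients, params)
    table = table.sort_values("life_priority").reset_index(drop=True)
    if t_grid is None:
        t_grid = np.linspace(0.0, 1440.0, 145)
    trajectories = {
        p.patient_id: trajectory(p.rts, p.niss, t_grid, params) for p in patients
    }
    assert list(table["life_priority"]) == list(range(1, len(patients) + 1))
    del ranked
    return ScenarioReport(label=spec.label, table=table, trajectories=trajectories)


def trajectories_frame(report: ScenarioReport) -> pd.DataFrame:
    """Long-format (patient_id, time_min, life_pct) trajectory samples."""
    frames = []
    for pid, traj in report.trajectories.items():
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "time_min": traj.time_grid,
                    "life_pct": traj.life_pct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _vs(gcs, sbp, rr, walking, cap=1.0, hr=80.0, spo2=98.0, breathing=True):
    return VitalSigns(
        gcs_total=gcs,
        sbp=sbp,
        rr=rr,
        walking=walking,
        radial_pulse_palpable=sbp >= 80,
        cap_refill_s=cap,
        obeys_commands=gcs >= 13,
        breathing_after_airway_maneuver=breathing,
        heart_rate=hr,
        spo2=spo2,
    )


def demo_scenario() -> ScenarioSpec:
    """The bundled 10-casualty multiple-vehicle-collision demo.

    Notable casualties:

    * ``P02`` — walking with stable vitals (RTS 6.8174) but NISS 35:
      START calls them green, yet they rank second by survival time.
    * ``P06``/``P07`` — identical NISS 14; P06 has the worse vitals and
      therefore the higher priority.
    """
    roster = [
        # (id, injuries, vitals)
        ("P01",
         [Injury(trauma_type="crush", body_location="chest", ais=4),
          Injury(trauma_type="hemorrhage", body_location="abdomen", ais=4),
          Injury(trauma_type="fracture", body_location="pelvis", ais=3)],
         _vs(6, 70, 5, False, cap=3.5, hr=130.0, spo2=82.0)),
        ("P02",
         [Injury(trauma_type="blast", body_location="chest", ais=5),
          Injury(trauma_type="penetrating", body_location="abdomen", ais=3),
          Injury(trauma_type="laceration", body_location="skin", ais=1)],
         _vs(15, 85, 35, True, cap=1.5, hr=110.0, spo2=93.0)),
        ("P03",
         [Injury(trauma_type="brain_injury", body_location="head", ais=4),
          Injury(trauma_type="fracture", body_location="left_leg", ais=2)],
         _vs(13, 95, 24, False, cap=2.0, hr=105.0, spo2=92.0)),
        ("P04",
         [Injury(trauma_type="penetrating", body_location="chest", ais=4),
          Injury(trauma_type="fracture", body_location="left_arm", ais=2),
          Injury(trauma_type="laceration", body_location="face", ais=1)],
         _vs(14, 90, 28, False, cap=1.8, hr=115.0, spo2=90.0)),
        ("P05",
         [Injury(trauma_type="crush", body_location="pelvis", ais=3),
          Injury(trauma_type="hemorrhage", body_location="left_leg", ais=2)],
         _vs(15, 100, 22, False, cap=1.8, hr=100.0, spo2=95.0)),
        ("P06",
         [Injury(trauma_type="fracture", body_location="pelvis", ais=3),
          Injury(trauma_type="burn", body_location="left_arm", ais=2),
          Injury(trauma_type="contusion", body_location="head", ais=1)],
         _vs(12, 110, 20, False, cap=1.5, hr=95.0, spo2=96.0)),
        ("P07",
         [Injury(trauma_type="fracture", body_location="spine", ais=3),
          Injury(trauma_type="burn", body_location="right_arm", ais=2),
          Injury(trauma_type="laceration", body_location="face", ais=1)],
         _vs(15, 120, 18, True, cap=1.0, hr=85.0, spo2=98.0)),
        ("P08",
         [Injury(trauma_type="fracture", body_location="left_arm", ais=2),
          Injury(trauma_type="laceration", body_location="face", ais=1)],
         _vs(15, 125, 16, True)),
        ("P09",
         [Injury(trauma_type="contusion", body_location="left_leg", ais=1),
          Injury(trauma_type="laceration", body_location="skin", ais=1)],
         _vs(15, 130, 14, True)),
        ("P10",
         [Injury(trauma_type="dislocation", body_location="right_arm", ais=1)],
         _vs(15, 120, 15, True)),
    ]
    patients = tuple(
        score_patient(pid, injuries, vitals) for pid, injuries, vitals in roster
    )
    return ScenarioSpec(patients=patients, label="multiple-vehicle collision demo")
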