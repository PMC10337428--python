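"""Comparator triage classifiers: START, RTS triage, and LIFE triage.

Each classifier maps a scored patient to one of the four classic
categories.  START and RTS triage read vital signs only; LIFE triage
bands the model's survival time without treatment.  All three share the
apnoea rule: a patient not breathing after an airway maneuver is black
under every algorithm.
"""

from __future__ import annotations

from enum import Enum
from typing import Dict, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import (
    DEFAULT_PARAMS,
    LifeModelParams,
    rank_cohort,
    survival_time_without_treatment,
)
from .scores import ScoredPatient


class TriageCategory(str, Enum):
    GREEN = "green"      # minimal / minor
    YELLOW = "yellow"    # delayed
    RED = "red"          # immediate
    BLACK = "black"      # deceased / expectant


class LifeTriageThresholds(BaseModel):
    """Survival-time bands (minutes) defining the LIFE triage categories.

    Defaults are calibrated against the default model constants so that
    (on generated cohorts) no green patient has NISS > 25, every yellow
    patient has NISS 10-25, and every green patient has RTS > 7.5.
    """

    model_config = ConfigDict(frozen=True)

    black_max_min: float = Field(default=30.0, gt=0)
    red_max_min: float = 738.0
    yellow_max_min: float = 967.0

    @model_validator(mode="after")
    def _ordered(self) -> "LifeTriageThresholds":
        if not self.black_max_min < self.red_max_min < self.yellow_max_min:
            raise ValueError(
                "thresholds must satisfy black_max < red_max < yellow_max"
            )
        return self


DEFAULT_THRESHOLDS = LifeTriageThresholds()

#: Default START capillary-refill cutoff (seconds).
CAP_REFILL_MAX_S = 2.0
#: Default START respiratory-rate cutoff (breaths/min, strict).
RR_RED_THRESHOLD = 30.0


def start_triage(patient: ScoredPatient) -> TriageCategory:
    """START decision cascade (walking, breathing, RR, perfusion, mental)."""
    v = patient.vitals
    if v.walking:
        return TriageCategory.GREEN
    if not v.breathing_after_airway_maneuver:
        return TriageCategory.BLACK
    if v.rr > RR_RED_THRESHOLD:
        return TriageCategory.RED
    if v.cap_refill_s > CAP_REFILL_MAX_S or not v.radial_pulse_palpable:
        return TriageCategory.RED
    if not v.obeys_commands:
        return TriageCategory.RED
    return TriageCategory.YELLOW


#: T-RTS bands of the common field-triage convention (config stand-in).
T_RTS_GREEN = 12
T_RTS_YELLOW = 11
T_RTS_BLACK_MAX = 3


def rts_triage(patient: ScoredPatient) -> TriageCategory:
    """Triage from the unweighted T-RTS sum."""
    if not patient.vitals.breathing_after_airway_maneuver:
        return TriageCategory.BLACK
    t = patient.t_rts
    if t == T_RTS_GREEN:
        return TriageCategory.GREEN
    if t == T_RTS_YELLOW:
        return TriageCategory.YELLOW
    if t <= T_RTS_BLACK_MAX:
        return TriageCategory.BLACK
    return TriageCategory.RED


def life_triage(
    patient: ScoredPatient,
    thresholds: LifeTriageThresholds = DEFAULT_THRESHOLDS,
    params: LifeModelParams = DEFAULT_PARAMS,
) -> TriageCategory:
    """Triage from banded survival time without treatment."""
    if thresholds.yellow_max_min >= params.t_horizon_min:
        raise ValueError("yellow_max_min must lie below the model horizon")
    if not patient.vitals.breathing_after_airway_maneuver:
        return TriageCategory.BLACK
    s = survival_time_without_treatment(patient.rts, patient.niss, params)
    if s <= thresholds.black_max_min:
        return TriageCategory.BLACK
    if s <= thresholds.red_max_min:
        return TriageCategory.RED
    if s <= thresholds.yellow_max_min:
        return TriageCategory.YELLOW
    return TriageCategory.GREEN


ALGORITHMS = {
    "start": lambda p, thresholds, params: start_triage(p),
    "rts": lambda p, thresholds, params: rts_triage(p),
    "life": life_triage,
}


def triage_all(
    cohort: Sequence[ScoredPatient],
    algorithms: Sequence[str] = ("start", "rts", "life"),
    thresholds: LifeTriageThresholds = DEFAULT_THRESHOLDS,
    params: LifeModelParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """One categorical result per (patient, algorithm), as a data frame.

    When ``"life"`` is among the algorithms, survival time and LIFE
    priority columns are appended as well.
    """
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise KeyError(
            f"unknown algorithm(s) {unknown}; registered: {sorted(ALGORITHMS)}"
        )
    out: Dict[str, list] = {"patient_id": [p.patient_id for p in cohort]}
    out["niss"] = [p.niss for p in cohort]
    out["rts"] = [p.rts for p in cohort]
    for name in algorithms:
        fn = ALGORITHMS[name]
        out[f"{name}_category"] = [
            fn(p, thresholds, params).value for p in cohort
        ]
    frame = pd.DataFrame(out)
    if "life" in algorithms and len(cohort) > 0:
        ranked = rank_cohort(cohort, params)
        frame["survival_time_min"] = [
            ranked.survival_times[p.patient_id] for p in cohort
        ]
        frame["life_priority"] = [
            ranked.life_priority[p.patient_id] for p in cohort
        ]
    return frame
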