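"""Standard trauma scores: RTS coding and weighting, T-RTS, and NISS.

The Revised Trauma Score (RTS) maps the Glasgow Coma Scale, systolic
blood pressure, and respiratory rate onto 0-4 codes and combines them
with fixed weights.  The New Injury Severity Score (NISS) is the sum of
squares of a patient's three highest AIS severities.  Both scores are
kept at full floating-point precision internally; rounding to four
decimals is a display concern only.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Fixed RTS coefficients for (GCS, SBP, RR) codes.
RTS_WEIGHTS: Tuple[float, float, float] = (0.9368, 0.7326, 0.2908)

#: Maximum attainable weighted RTS, i.e. codes (4, 4, 4).
RTS_MAX: float = 7.8408

#: Maximum attainable NISS (three AIS-5 injuries, or any AIS-6 injury).
NISS_MAX: int = 75


class Injury(BaseModel):
    """A single trauma: a type, a body location, and an AIS severity."""

    model_config = ConfigDict(frozen=True)

    trauma_type: str
    body_location: str
    ais: int = Field(ge=1, le=6, description="Abbreviated Injury Scale severity")


class VitalSigns(BaseModel):
    """Primary-assessment vital signs.

    Cross-field physiological invariants are enforced at construction:
    a radial pulse cannot be palpated below 80 mmHg systolic, a patient
    with GCS < 9 cannot obey commands, and an apnoeic patient cannot
    walk.
    """

    model_config = ConfigDict(frozen=True)

    gcs_total: int = Field(ge=3, le=15)
    sbp: float = Field(ge=0, description="systolic blood pressure, mmHg")
    rr: float = Field(ge=0, description="respiratory rate, breaths/min")
    walking: bool
    radial_pulse_palpable: bool
    cap_refill_s: float = Field(ge=0)
    obeys_commands: bool
    breathing_after_airway_maneuver: bool
    heart_rate: Optional[float] = Field(default=None, ge=0)
    spo2: Optional[float] = Field(default=None, ge=0, le=100)

    @model_validator(mode="after")
    def _physiology(self) -> "VitalSigns":
        if self.sbp < 80 and self.radial_pulse_palpable:
            raise ValueError(
                "radial_pulse_palpable must be False when sbp < 80 mmHg"
            )
        if self.gcs_total < 9 and self.obeys_commands:
            raise ValueError("obeys_commands must be False when gcs_total < 9")
        if self.rr == 0 and self.walking:
            raise ValueError("walking must be False when rr == 0")
        return self


class RtsCoding(BaseModel):
    """The three 0-4 RTS codes together with the fixed weights."""

    model_config = ConfigDict(frozen=True)

    gcs_code: int = Field(ge=0, le=4)
    sbp_code: int = Field(ge=0, le=4)
    rr_code: int = Field(ge=0, le=4)
    weights: Tuple[float, float, float] = RTS_WEIGHTS


def code_gcs(gcs_total: int) -> int:
    """Map a total GCS (3-15) onto its 0-4 RTS code."""
    if not 3 <= gcs_total <= 15:
        raise ValueError(f"gcs_total out of range 3-15: {gcs_total}")
    if gcs_total >= 13:
        return 4
    if gcs_total >= 9:
        return 3
    if gcs_total >= 6:
        return 2
    if gcs_total >= 4:
        return 1
    return 0


def code_sbp(sbp: float) -> int:
    """Map systolic blood pressure (mmHg) onto its 0-4 RTS code."""
    if sbp < 0:
        raise ValueError(f"sbp must be >= 0: {sbp}")
    if sbp > 89:
        return 4
    if sbp >= 76:
        return 3
    if sbp >= 50:
        return 2
    if sbp >= 1:
        return 1
    return 0


def code_rr(rr: float) -> int:
    """Map respiratory rate (breaths/min) onto its 0-4 RTS code."""
    if rr < 0:
        raise ValueError(f"rr must be >= 0: {rr}")
    if 10 <= rr <= 29:
        return 4
    if rr > 29:
        return 3
    if rr >= 6:
        return 2
    if rr >= 1:
        return 1
    return 0


def code_vitals(vitals: VitalSigns) -> RtsCoding:
    """Code a full vital-sign record into the three RTS components."""
    return RtsCoding(
        gcs_code=code_gcs(vitals.gcs_total),
        sbp_code=code_sbp(vitals.sbp),
        rr_code=code_rr(vitals.rr),
    )


def compute_rts(coding: RtsCoding) -> float:
    """Weighted RTS: 0.9368*GCS + 0.7326*SBP + 0.2908*RR codes."""
    w = coding.weights
    return w[0] * coding.gcs_code + w[1] * coding.sbp_code + w[2] * coding.rr_code


def compute_t_rts(coding: RtsCoding) -> int:
    """Triage RTS: the plain sum of the three codes (0-12)."""
    return coding.gcs_code + coding.sbp_code + coding.rr_code


def compute_niss(injuries: Sequence[Injury]) -> int:
    """NISS: sum of squares of the (up to) three highest AIS severities.

    An AIS-6 injury is unsurvivable by convention and forces NISS 75.
    """
    if not injuries:
        raise ValueError("at least one injury is required to compute the NISS")
    severities = sorted((inj.ais for inj in injuries), reverse=True)[:3]
    if severities[0] >= 6:
        return NISS_MAX
    return min(sum(s * s for s in severities), NISS_MAX)


class ScoredPatient(BaseModel):
    """A patient with injuries, vitals, and self-consistent derived scores."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    injuries: Tuple[Injury, ...] = Field(min_length=1, max_length=3)
    vitals: VitalSigns
    niss: int = Field(ge=1, le=NISS_MAX)
    rts: float = Field(ge=0, le=RTS_MAX)
    t_rts: int = Field(ge=0, le=12)

    @model_validator(mode="after")
    def _consistent(self) -> "ScoredPatient":
        coding = code_vitals(self.vitals)
        if self.niss != compute_niss(self.injuries):
            raise ValueError(
                f"patient {self.patient_id}: niss {self.niss} does not match injuries"
            )
        if abs(self.rts - compute_rts(coding)) > 1e-9:
            raise ValueError(
                f"patient {self.patient_id}: rts {self.rts} does not match vitals"
            )
        if self.t_rts != compute_t_rts(coding):
            raise ValueError(
                f"patient {self.patient_id}: t_rts {self.t_rts} does not match vitals"
            )
        return self


def score_patient(
    patient_id: str, injuries: Sequence[Injury], vitals: VitalSigns
) -> ScoredPatient:
    """Build a :class:`ScoredPatient`, deriving NISS, RTS and T-RTS."""
    coding = code_vitals(vitals)
    return ScoredPatient(
        patient_id=patient_id,
        injuries=tuple(injuries),
        vitals=vitals,
        niss=compute_niss(injuries),
        rts=compute_rts(coding),
        t_rts=compute_t_rts(coding),
    )
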