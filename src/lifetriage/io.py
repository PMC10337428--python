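"""Patient table readers/writers (CSV and JSON).

CSV layout: one row per patient with flat injury columns
``trauma_{i}_type / trauma_{i}_location / trauma_{i}_ais`` (i = 1..3,
blank when absent), the vital-sign columns, and the derived score
columns.  Scores are recomputed and validated on read, so a table whose
stored scores disagree with its vitals/injuries is rejected.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .scores import Injury, ScoredPatient, VitalSigns, score_patient

MAX_INJURIES = 3

_VITAL_COLUMNS = [
    "gcs_total", "sbp", "rr", "walking", "radial_pulse_palpable",
    "cap_refill_s", "obeys_commands", "breathing_after_airway_maneuver",
    "heart_rate", "spo2",
]
_SCORE_COLUMNS = ["niss", "rts", "t_rts"]

_BOOL_COLUMNS = {
    "walking", "radial_pulse_palpable", "obeys_commands",
    "breathing_after_airway_maneuver",
}


def patient_columns() -> List[str]:
    cols = ["patient_id"]
    for i in range(1, MAX_INJURIES + 1):
        cols += [f"trauma_{i}_type", f"trauma_{i}_location", f"trauma_{i}_ais"]
    return cols + _VITAL_COLUMNS + _SCORE_COLUMNS


def patients_to_frame(patients: Sequence[ScoredPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id}
        for i in range(MAX_INJURIES):
            prefix = f"trauma_{i + 1}"
            if i < len(p.injuries):
                inj = p.injuries[i]
                row[f"{prefix}_type"] = inj.trauma_type
                row[f"{prefix}_location"] = inj.body_location
                row[f"{prefix}_ais"] = inj.ais
            else:
                row[f"{prefix}_type"] = ""
                row[f"{prefix}_location"] = ""
                row[f"{prefix}_ais"] = ""
        for col in _VITAL_COLUMNS:
            row[col] = getattr(p.vitals, col)
        row["niss"] = p.niss
        row["rts"] = p.rts
        row["t_rts"] = p.t_rts
        rows.append(row)
    return pd.DataFrame(rows, columns=patient_columns())


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _is_blank(value: object) -> bool:
    if value is None or value == "":
        return True
    return isinstance(value, float) and math.isnan(value)


def _patient_from_row(row: dict, line: int, validate_scores: bool) -> ScoredPatient:
    try:
        injuries = []
        for i in range(1, MAX_INJURIES + 1):
            t = row.get(f"trauma_{i}_type")
            if _is_blank(t):
                continue
            injuries.append(
                Injury(
                    trauma_type=str(t),
                    body_location=str(row[f"trauma_{i}_location"]),
                    ais=int(row[f"trauma_{i}_ais"]),
                )
            )
        vital_kwargs = {}
        for col in _VITAL_COLUMNS:
            value = row.get(col)
            if col in ("heart_rate", "spo2") and _is_blank(value):
                vital_kwargs[col] = None
            elif col in _BOOL_COLUMNS:
                vital_kwargs[col] = _parse_bool(value)
            elif col == "gcs_total":
                vital_kwargs[col] = int(float(value))
            else:
                vital_kwargs[col] = float(value)
        patient = score_patient(
            str(row["patient_id"]), injuries, VitalSigns(**vital_kwargs)
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed patient row {line}: {exc}") from exc
    if validate_scores:
        for col, stored in (
            ("niss", patient.niss), ("t_rts", patient.t_rts),
        ):
            if col in row and not _is_blank(row[col]) and int(float(row[col])) != stored:
                raise ValueError(
                    f"patient {patient.patient_id}: stored {col} "
                    f"{row[col]} disagrees with recomputed {stored}"
                )
        if "rts" in row and not _is_blank(row["rts"]):
            if abs(float(row["rts"]) - patient.rts) > 1e-6:
                raise ValueError(
                    f"patient {patient.patient_id}: stored rts {row['rts']} "
                    f"disagrees with recomputed {patient.rts}"
                )
    return patient


def _infer_format(path: str | Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    return "csv"


def read_patients(path: str | Path, fmt: Optional[str] = None) -> List[ScoredPatient]:
    """Read a patient table; scores are recomputed and cross-checked."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(
            path, dtype={"patient_id": str}, float_precision="round_trip"
        )
        rows = frame.to_dict(orient="records")
    elif fmt == "json":
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise ValueError("JSON patient file must hold a list of records")
    else:
        raise ValueError(f"unknown format: {fmt}")
    return [
        _patient_from_row(row, line, validate_scores=True)
        for line, row in enumerate(rows, start=2 if fmt == "csv" else 1)
    ]


def write_patients(
    patients: Sequence[ScoredPatient], path: str | Path, fmt: Optional[str] = None
) -> None:
    fmt = _infer_format(path, fmt)
    frame = patients_to_frame(patients)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        records = frame.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown format: {fmt}")


def write_table(frame: pd.DataFrame, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a generic result table as CSV or JSON records."""
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown format: {fmt}")
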