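"""Semisupervised synthetic trauma-cohort generation.

Pipeline: enumerate all 1-3 injury combinations over the allowed
(trauma type, body location, AIS) catalog entries, drop anatomically
impossible combinations, compute the NISS, draw vital signs from the
NISS-banded parameter set, apply dependency rules, then score.

The shipped default catalog (14 trauma types x 13 body locations, each
realistic pair carrying one AIS) and the default vital bands are
documented stand-ins: both are fully replaceable via CSV so domain
tables can be dropped in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .scores import (
    Injury,
    ScoredPatient,
    VitalSigns,
    compute_niss,
    score_patient,
)

PairKey = Tuple[str, str]

#: Paired (left/right) extremity location groups; all other locations
#: are unpaired ("azygos") and cannot plausibly carry duplicate injuries.
PAIRED_LOCATION_GROUPS: Tuple[FrozenSet[str], ...] = (
    frozenset({"left_arm", "right_arm"}),
    frozenset({"left_leg", "right_leg"}),
)

LOWER_EXTREMITY_LOCATIONS = frozenset({"left_leg", "right_leg"})


@dataclass(frozen=True)
class TraumaCatalog:
    """The trauma-type x body-location universe with per-pair AIS."""

    trauma_types: Tuple[str, ...]
    body_locations: Tuple[str, ...]
    allowed: Dict[PairKey, int] = field(default_factory=dict)
    paired_groups: Tuple[FrozenSet[str], ...] = PAIRED_LOCATION_GROUPS

    def __post_init__(self) -> None:
        if len(set(self.trauma_types)) != len(self.trauma_types):
            raise ValueError("duplicate trauma types")
        if len(set(self.body_locations)) != len(self.body_locations):
            raise ValueError("duplicate body locations")
        for (ttype, loc), ais in self.allowed.items():
            if ttype not in self.trauma_types:
                raise ValueError(f"unknown trauma type in allowed pairs: {ttype}")
            if loc not in self.body_locations:
                raise ValueError(f"unknown body location in allowed pairs: {loc}")
            if not 1 <= ais <= 6:
                raise ValueError(f"AIS out of range 1-6 for {(ttype, loc)}: {ais}")

    @property
    def azygos_locations(self) -> FrozenSet[str]:
        paired = frozenset().union(*self.paired_groups) if self.paired_groups else frozenset()
        return frozenset(self.body_locations) - paired

    def injuries(self) -> List[Injury]:
        """All allowed injuries in deterministic (catalog) order."""
        return [
            Injury(trauma_type=t, body_location=l, ais=a)
            for (t, l), a in sorted(self.allowed.items())
        ]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["trauma_type", "body_location", "ais"])
            for (t, l), a in sorted(self.allowed.items()):
                writer.writerow([t, l, a])

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        trauma_types: Optional[Sequence[str]] = None,
        body_locations: Optional[Sequence[str]] = None,
        paired_groups: Tuple[FrozenSet[str], ...] = PAIRED_LOCATION_GROUPS,
    ) -> "TraumaCatalog":
        allowed: Dict[PairKey, int] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                allowed[(row["trauma_type"], row["body_location"])] = int(row["ais"])
        types = tuple(trauma_types or sorted({k[0] for k in allowed}))
        locs = tuple(body_locations or sorted({k[1] for k in allowed}))
        return cls(
            trauma_types=types,
            body_locations=locs,
            allowed=allowed,
            paired_groups=paired_groups,
        )


TRAUMA_TYPES: Tuple[str, ...] = (
    "fracture", "laceration", "burn", "penetrating", "blunt", "amputation",
    "crush", "contusion", "brain_injury", "hemorrhage", "blast",
    "dislocation", "spinal_cord_injury", "inhalation",
)

BODY_LOCATIONS: Tuple[str, ...] = (
    "head", "face", "neck", "chest", "abdomen", "pelvis", "spine",
    "left_arm", "right_arm", "left_leg", "right_leg", "skin", "airway",
)

# Realistic (type, location) -> AIS table; a documented stand-in, not a
# clinical reference.  Severities are skewed low so that combined NISS
# values concentrate in the 10-25 band.
_DEFAULT_ALLOWED: Dict[str, Dict[str, int]] = {
    "fracture": {"left_arm": 2, "right_arm": 2, "left_leg": 2, "right_leg": 2,
                 "face": 1, "pelvis": 3, "spine": 3, "head": 3},
    "laceration": {"face": 1, "skin": 1, "left_arm": 1, "right_arm": 1,
                   "left_leg": 1, "right_leg": 1, "neck": 2},
    "burn": {"skin": 2, "face": 2, "left_arm": 2, "right_arm": 2,
             "left_leg": 2, "right_leg": 2, "chest": 3, "airway": 4},
    "penetrating": {"chest": 4, "abdomen": 3, "neck": 3, "left_arm": 2,
                    "right_arm": 2, "left_leg": 2, "right_leg": 2, "head": 6},
    "blunt": {"chest": 2, "abdomen": 2, "head": 2, "pelvis": 2},
    "amputation": {"left_arm": 3, "right_arm": 3, "left_leg": 3, "right_leg": 3},
    "crush": {"chest": 4, "pelvis": 3, "abdomen": 4, "left_arm": 2,
              "right_arm": 2, "left_leg": 3, "right_leg": 3},
    "contusion": {"head": 1, "chest": 1, "abdomen": 1, "left_arm": 1,
                  "right_arm": 1, "left_leg": 1, "right_leg": 1},
    "brain_injury": {"head": 4},
    "hemorrhage": {"abdomen": 4, "chest": 4, "pelvis": 3, "neck": 3,
                   "left_leg": 2, "right_leg": 2},
    "blast": {"chest": 5, "abdomen": 4, "head": 5, "skin": 2},
    "dislocation": {"left_arm": 1, "right_arm": 1, "left_leg": 2,
                    "right_leg": 2, "spine": 2},
    "spinal_cord_injury": {"spine": 5, "neck": 4},
    "inhalation": {"airway": 3},
}


def default_catalog() -> TraumaCatalog:
    """The shipped 14-type x 13-location catalog (72 allowed pairs)."""
    allowed = {
        (ttype, loc): ais
        for ttype, locs in _DEFAULT_ALLOWED.items()
        for loc, ais in locs.items()
    }
    return TraumaCatalog(
        trauma_types=TRAUMA_TYPES,
        body_locations=BODY_LOCATIONS,
        allowed=allowed,
    )


class VitalParameterSet(BaseModel):
    """Per-NISS-band vital ranges; single values are drawn uniformly."""

    model_config = ConfigDict(frozen=True)

    niss_lo: int = Field(ge=1, le=75)
    niss_hi: int = Field(ge=1, le=75)
    gcs: Tuple[int, int]
    sbp: Tuple[float, float]
    rr: Tuple[float, float]
    heart_rate: Tuple[float, float]
    spo2: Tuple[float, float]
    cap_refill_s: Tuple[float, float]
    walking_probability: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _ranges(self) -> "VitalParameterSet":
        if self.niss_lo > self.niss_hi:
            raise ValueError("niss_lo must be <= niss_hi")
        for name in ("gcs", "sbp", "rr", "heart_rate", "spo2", "cap_refill_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has low > high")
        return self


def default_vital_sets() -> List[VitalParameterSet]:
    """Default NISS-banded vital ranges (partition of 1-75).

    The lowest band pins perfect RTS coding (GCS 15, SBP > 89,
    RR 10-29); severity of derangement then increases bandwise.
    """
    return [
        VitalParameterSet(
            niss_lo=1, niss_hi=9, gcs=(15, 15), sbp=(110, 140), rr=(12, 24),
            heart_rate=(60, 100), spo2=(96, 100), cap_refill_s=(0.5, 1.5),
            walking_probability=0.9,
        ),
        VitalParameterSet(
            niss_lo=10, niss_hi=25, gcs=(13, 15), sbp=(95, 130), rr=(10, 28),
            heart_rate=(70, 115), spo2=(92, 99), cap_refill_s=(1.0, 2.0),
            walking_probability=0.6,
        ),
        VitalParameterSet(
            niss_lo=26, niss_hi=40, gcs=(9, 14), sbp=(70, 110), rr=(8, 32),
            heart_rate=(90, 135), spo2=(85, 96), cap_refill_s=(1.5, 3.0),
            walking_probability=0.25,
        ),
        VitalParameterSet(
            niss_lo=41, niss_hi=75, gcs=(3, 12), sbp=(0, 90), rr=(0, 30),
            heart_rate=(0, 140), spo2=(50, 92), cap_refill_s=(2.0, 5.0),
            walking_probability=0.05,
        ),
    ]


def validate_vital_sets(vital_sets: Sequence[VitalParameterSet]) -> None:
    """Check that the bands partition 1-75 without overlap."""
    covered: List[bool] = [False] * 75
    for vs in vital_sets:
        for n in range(vs.niss_lo, vs.niss_hi + 1):
            if covered[n - 1]:
                raise ValueError(f"NISS {n} covered by more than one band")
            covered[n - 1] = True
    missing = [i + 1 for i, c in enumerate(covered) if not c]
    if missing:
        raise ValueError(f"NISS values not covered by any band: {missing[:5]}...")


class GeneratorConfig(BaseModel):
    """Full, reproducible cohort-generation configuration."""

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    catalog: TraumaCatalog
    vital_sets: Tuple[VitalParameterSet, ...]
    seed: int = 0
    max_injuries: int = Field(default=3, ge=1, le=3)
    max_patients: Optional[int] = Field(default=None, ge=1)

    @classmethod
    def default(cls, seed: int = 0, max_patients: Optional[int] = None) -> "GeneratorConfig":
        return cls(
            catalog=default_catalog(),
            vital_sets=tuple(default_vital_sets()),
            seed=seed,
            max_patients=max_patients,
        )


def anatomical_filter(injuries: Sequence[Injury], catalog: TraumaCatalog) -> bool:
    """Return True if the combination is anatomically plausible.

    Drops (i) three same-type injuries confined to at most two paired
    extremity locations, and (ii) two or more injuries in one unpaired
    (azygos) body region.
    """
    locations = [inj.body_location for inj in injuries]
    for loc in locations:
        if loc not in catalog.body_locations:
            raise ValueError(f"body location not in catalog: {loc}")
    azygos = catalog.azygos_locations
    for loc in set(locations):
        if loc in azygos and locations.count(loc) >= 2:
            return False
    paired = frozenset().union(*catalog.paired_groups) if catalog.paired_groups else frozenset()
    by_type: Dict[str, List[str]] = {}
    for inj in injuries:
        by_type.setdefault(inj.trauma_type, []).append(inj.body_location)
    for locs in by_type.values():
        if len(locs) >= 3 and all(l in paired for l in locs) and len(set(locs)) <= 2:
            return False
    return True


def enumerate_injury_combinations(
    catalog: TraumaCatalog, max_injuries: int = 3
) -> List[Tuple[Injury, ...]]:
    """All anatomically plausible size-1..3 combinations of allowed injuries.

    Combinations are over distinct (type, location) pairs, in a
    deterministic order derived from the sorted catalog.
    """
    pool = catalog.injuries()
    if not pool:
        raise ValueError("catalog has no allowed (type, location) pairs")
    out: List[Tuple[Injury, ...]] = []
    for size in range(1, max_injuries + 1):
        for combo in combinations(pool, size):
            if anatomical_filter(combo, catalog):
                out.append(combo)
    return out


def _band_for(niss: int, vital_sets: Sequence[VitalParameterSet]) -> VitalParameterSet:
    for vs in vital_sets:
        if vs.niss_lo <= niss <= vs.niss_hi:
            return vs
    raise ValueError(f"no vital parameter band covers NISS {niss}")


def _cap_refill_adjust(base: float, sbp: float, band_midpoint: float) -> float:
    """Low blood pressure prolongs capillary refill.

    Below the band midpoint, add 1 s per 20 mmHg of SBP below 100,
    capped at +4 s.
    """
    if sbp >= band_midpoint or sbp >= 100:
        return base
    return base + min((100.0 - sbp) / 20.0, 4.0)


def assign_vitals(
    niss: int,
    vital_sets: Sequence[VitalParameterSet],
    rng: np.random.Generator,
    immobilizing_injury: bool = False,
) -> VitalSigns:
    """Draw one vital-sign record from the band covering ``niss``.

    Draw order is fixed for determinism.  Dependency rules applied
    after drawing: no radial pulse below 80 mmHg, capillary refill
    prolonged at low pressure, walking impossible with an immobilizing
    lower-extremity injury, reduced consciousness, or apnoea.
    """
    band = _band_for(niss, vital_sets)
    gcs = int(rng.integers(band.gcs[0], band.gcs[1] + 1))
    sbp = float(np.round(rng.uniform(*band.sbp)))
    rr = float(np.round(rng.uniform(*band.rr)))
    hr = float(np.round(rng.uniform(*band.heart_rate)))
    spo2 = float(np.round(rng.uniform(*band.spo2)))
    cap = float(np.round(rng.uniform(*band.cap_refill_s), 1))
    walk_draw = float(rng.random())

    sbp_mid = (band.sbp[0] + band.sbp[1]) / 2.0
    cap = _cap_refill_adjust(cap, sbp, sbp_mid)
    walking = (
        walk_draw < band.walking_probability
        and not immobilizing_injury
        and gcs >= 13
        and rr > 0
    )
    return VitalSigns(
        gcs_total=gcs,
        sbp=sbp,
        rr=rr,
        walking=walking,
        radial_pulse_palpable=sbp >= 80,
        cap_refill_s=cap,
        obeys_commands=gcs >= 13,
        breathing_after_airway_maneuver=rr > 0,
        heart_rate=hr,
        spo2=spo2,
    )


def generate_cohort(config: GeneratorConfig) -> List[ScoredPatient]:
    """Generate the full scored cohort, bit-reproducible from the seed."""
    validate_vital_sets(config.vital_sets)
    combos = enumerate_injury_combinations(config.catalog, config.max_injuries)
    rng = np.random.default_rng(config.seed)
    if config.max_patients is not None and config.max_patients < len(combos):
        keep = rng.choice(len(combos), size=config.max_patients, replace=False)
        combos = [combos[i] for i in sorted(keep)]
    patients: List[ScoredPatient] = []
    width = max(6, len(str(len(combos))))
    for idx, injuries in enumerate(combos, start=1):
        niss = compute_niss(injuries)
        immobilizing = any(
            inj.body_location in LOWER_EXTREMITY_LOCATIONS and inj.ais >= 2
            for inj in injuries
        )
        vitals = assign_vitals(niss, config.vital_sets, rng, immobilizing)
        patients.append(
            score_patient(f"P{idx:0{width}d}", injuries, vitals)
        )
    return patients
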