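"""Sigmoidal time-course model of a casualty's expected condition.

A patient's latent condition ("LIFE percentage", 100 = unharmed) is
modelled as a normalised falling sigmoid.  Current vital signs (via the
weighted RTS) set the starting level; anatomical injury severity (via
the NISS) sets when and how fast decompensation occurs:

    L(t)  = L0 * B(t) / B(0)
    L0    = 100 * rts / rts_max
    B(t)  = 1 / (1 + exp((t - t50) / tau))
    t50   = t_ref * (1 - niss/niss_max) * (f + (1 - f) * rts/rts_max)
    tau   = tau_ref * (1 - niss/niss_max) + tau_min

with f = ``rts_floor_frac``.  The curve shows the expected three
phases: a compensation plateau at L0, a near-linear decline around t50,
and a prolonged asymptotic tail.  "Survival time without treatment" is
the closed-form crossing of a small death threshold and is the ranking
key for treatment priority.

All time quantities are minutes.  Constants are deliberately
config-exposed: the model is a proof of concept and does not claim
calibrated real-world survival times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .scores import NISS_MAX, RTS_MAX, ScoredPatient

ArrayLike = Union[float, Sequence[float], np.ndarray]


class LifeModelParams(BaseModel):
    """All constants of the time-course model."""

    model_config = ConfigDict(frozen=True)

    rts_max: float = Field(default=RTS_MAX, gt=0)
    niss_max: int = Field(default=NISS_MAX, gt=0)
    death_threshold_pct: float = Field(default=5.0, gt=0, lt=100)
    t_ref_min: float = Field(default=720.0, gt=0)
    tau_ref_min: float = Field(default=120.0, gt=0)
    tau_min_min: float = Field(default=10.0, gt=0)
    rts_floor_frac: float = Field(default=0.25, gt=0, lt=1)
    t_horizon_min: float = Field(default=10080.0, gt=0)


DEFAULT_PARAMS = LifeModelParams()


def _validate_inputs(rts: float, niss: int, params: LifeModelParams) -> None:
    if not 0 <= rts <= params.rts_max + 1e-9:
        raise ValueError(f"rts out of range [0, {params.rts_max}]: {rts}")
    if not 1 <= niss <= params.niss_max:
        raise ValueError(f"niss out of range [1, {params.niss_max}]: {niss}")


def midpoint_minutes(rts: float, niss: int, params: LifeModelParams = DEFAULT_PARAMS) -> float:
    """Decompensation midpoint t50 of the sigmoid, in minutes."""
    _validate_inputs(rts, niss, params)
    f = params.rts_floor_frac
    return (
        params.t_ref_min
        * (1.0 - niss / params.niss_max)
        * (f + (1.0 - f) * rts / params.rts_max)
    )


def slope_minutes(niss: int, params: LifeModelParams = DEFAULT_PARAMS) -> float:
    """Sigmoid slope constant tau, in minutes."""
    if not 1 <= niss <= params.niss_max:
        raise ValueError(f"niss out of range [1, {params.niss_max}]: {niss}")
    return params.tau_ref_min * (1.0 - niss / params.niss_max) + params.tau_min_min


def life_percentage(
    rts: float,
    niss: int,
    t_minutes: ArrayLike,
    params: LifeModelParams = DEFAULT_PARAMS,
) -> Union[float, np.ndarray]:
    """Expected LIFE percentage at time ``t_minutes`` after assessment.

    Vectorised over ``t_minutes``; normalised so L(0) = 100*rts/rts_max.
    """
    _validate_inputs(rts, niss, params)
    t = np.asarray(t_minutes, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_minutes must be >= 0")
    t50 = midpoint_minutes(rts, niss, params)
    tau = slope_minutes(niss, params)
    l0 = 100.0 * rts / params.rts_max
    out = l0 * expit((t50 - t) / tau) / expit(t50 / tau)
    return float(out) if out.ndim == 0 else out


def survival_time_without_treatment(
    rts: float, niss: int, params: LifeModelParams = DEFAULT_PARAMS
) -> float:
    """Minutes until L(t) crosses the death threshold, closed form.

    Returns 0 when the patient is already at or below the threshold at
    assessment, and ``t_horizon_min`` (the "stable" sentinel) when the
    crossing lies beyond the model horizon.
    """
    _validate_inputs(rts, niss, params)
    l0 = 100.0 * rts / params.rts_max
    thr = params.death_threshold_pct
    if l0 <= thr:
        return 0.0
    t50 = midpoint_minutes(rts, niss, params)
    tau = slope_minutes(niss, params)
    b0 = expit(t50 / tau)
    # L(t) = thr  <=>  B(t) = (thr/L0) * B(0); invert the sigmoid.
    b_target = (thr / l0) * b0
    t = t50 + tau * math.log(1.0 / b_target - 1.0)
    return float(min(max(t, 0.0), params.t_horizon_min))


@dataclass(frozen=True)
class LifeTrajectory:
    """A sampled LIFE-percentage curve plus its characteristic times."""

    time_grid: np.ndarray
    life_pct: np.ndarray
    t50: float
    tau: float
    survival_time_min: float


def trajectory(
    rts: float,
    niss: int,
    t_grid: ArrayLike,
    params: LifeModelParams = DEFAULT_PARAMS,
) -> LifeTrajectory:
    """Sample the LIFE curve on ``t_grid`` (strictly increasing from 0)."""
    grid = np.asarray(t_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or grid[0] != 0:
        raise ValueError("t_grid must be a 1-D grid starting at 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    return LifeTrajectory(
        time_grid=grid,
        life_pct=np.asarray(life_percentage(rts, niss, grid, params)),
        t50=midpoint_minutes(rts, niss, params),
        tau=slope_minutes(niss, params),
        survival_time_min=survival_time_without_treatment(rts, niss, params),
    )


@dataclass(frozen=True)
class RankedCohort:
    """A cohort ordered by ascending survival time (rank 1 = treat first)."""

    ordering: List[str]
    survival_times: Dict[str, float]
    life_priority: Dict[str, int]


def rank_cohort(
    patients: Sequence[ScoredPatient], params: LifeModelParams = DEFAULT_PARAMS
) -> RankedCohort:
    """Rank patients by survival time without treatment.

    Ties are broken deterministically by patient id (lexicographic).
    """
    if not patients:
        raise ValueError("cannot rank an empty cohort")
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    times = {
        p.patient_id: survival_time_without_treatment(p.rts, p.niss, params)
        for p in patients
    }
    ordering = sorted(ids, key=lambda pid: (times[pid], pid))
    priority = {pid: rank for rank, pid in enumerate(ordering, start=1)}
    return RankedCohort(ordering=ordering, survival_times=times, life_priority=priority)
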