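"""Mixed-data cohort analytics.

Gower dissimilarity over mixed numeric/binary/categorical patient
features, k-medoids (PAM, BUILD+SWAP) clustering with silhouette-based
k selection, a 2-D embedding adapter, triage cross-tabulations, and
consensus comparison of clusters against unanimously triaged patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .model import DEFAULT_PARAMS, LifeModelParams, survival_time_without_treatment
from .scores import ScoredPatient


class FeatureKind(str, Enum):
    NUMERIC = "numeric"
    BINARY = "binary"
    CATEGORICAL = "categorical"


class FeatureSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    kind: FeatureKind
    range: Optional[float] = None  # numeric features only

    @model_validator(mode="after")
    def _numeric_needs_range(self) -> "FeatureSpec":
        if self.kind is FeatureKind.NUMERIC:
            if self.range is None or not np.isfinite(self.range) or self.range <= 0:
                raise ValueError(
                    f"numeric feature {self.name!r} needs a finite nonzero range"
                )
        return self


class MixedFeatureSpec(BaseModel):
    """Declares each clustering feature's scale type for Gower distance."""

    model_config = ConfigDict(frozen=True)

    features: Tuple[FeatureSpec, ...] = Field(min_length=1)

    @property
    def names(self) -> List[str]:
        return [f.name for f in self.features]


# Numeric feature kinds of the default 27-feature frame; everything else
# is binary (vitals flags, per-location involvement) or categorical.
_NUMERIC_FEATURES = (
    "gcs_total", "sbp", "rr", "heart_rate", "spo2", "cap_refill_s",
    "injury_count", "niss", "rts", "survival_time_min",
)
_BINARY_VITALS = (
    "walking", "radial_pulse_palpable", "obeys_commands",
    "breathing_after_airway_maneuver",
)


def cohort_feature_frame(
    patients: Sequence[ScoredPatient],
    params: LifeModelParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """The default 27-feature clustering frame, indexed by patient id.

    Features: 10 vitals (6 numeric + 4 flags), 13 per-location maximum
    AIS values, injury count, NISS, RTS, and survival time without
    treatment.  Triage categories are deliberately excluded to avoid
    circularity with the triage comparisons.
    """
    from .generator import BODY_LOCATIONS

    rows = []
    for p in patients:
        v = p.vitals
        row: Dict[str, object] = {
            "patient_id": p.patient_id,
            "gcs_total": v.gcs_total,
            "sbp": v.sbp,
            "rr": v.rr,
            "heart_rate": v.heart_rate if v.heart_rate is not None else np.nan,
            "spo2": v.spo2 if v.spo2 is not None else np.nan,
            "cap_refill_s": v.cap_refill_s,
            "walking": v.walking,
            "radial_pulse_palpable": v.radial_pulse_palpable,
            "obeys_commands": v.obeys_commands,
            "breathing_after_airway_maneuver": v.breathing_after_airway_maneuver,
        }
        for loc in BODY_LOCATIONS:
            row[f"ais_{loc}"] = max(
                (inj.ais for inj in p.injuries if inj.body_location == loc),
                default=0,
            )
        row["injury_count"] = len(p.injuries)
        row["niss"] = p.niss
        row["rts"] = p.rts
        row["survival_time_min"] = survival_time_without_treatment(
            p.rts, p.niss, params
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def feature_spec_from_frame(frame: pd.DataFrame) -> MixedFeatureSpec:
    """Infer a Gower spec from a feature frame, with cohort-wide ranges."""
    specs: List[FeatureSpec] = []
    for col in frame.columns:
        if col in _BINARY_VITALS or frame[col].dropna().isin([0, 1, True, False]).all():
            kind = FeatureKind.BINARY
            rng = None
        elif col.startswith("ais_") or col in _NUMERIC_FEATURES or pd.api.types.is_numeric_dtype(frame[col]):
            kind = FeatureKind.NUMERIC
            lo, hi = frame[col].min(), frame[col].max()
            rng = float(hi - lo)
            if not np.isfinite(rng) or rng == 0:
                # constant column: treat as categorical so it contributes 0
                kind = FeatureKind.CATEGORICAL
                rng = None
        else:
            kind = FeatureKind.CATEGORICAL
            rng = None
        specs.append(FeatureSpec(name=col, kind=kind, range=rng))
    return MixedFeatureSpec(features=tuple(specs))


def gower_distance(
    a: Mapping[str, object], b: Mapping[str, object], spec: MixedFeatureSpec
) -> float:
    """Gower dissimilarity between two records, in [0, 1].

    Numeric features contribute |a-b|/range; binary and categorical
    features contribute 0/1 mismatch.  Missing values are excluded and
    the mean reweighted over the remaining features.
    """
    total = 0.0
    weight = 0
    for f in spec.features:
        va, vb = a.get(f.name), b.get(f.name)
        if va is None or vb is None:
            continue
        if isinstance(va, float) and np.isnan(va):
            continue
        if isinstance(vb, float) and np.isnan(vb):
            continue
        if f.kind is FeatureKind.NUMERIC:
            total += min(abs(float(va) - float(vb)) / f.range, 1.0)
        else:
            total += 0.0 if va == vb else 1.0
        weight += 1
    if weight == 0:
        raise ValueError("all features missing in at least one record")
    return total / weight


def gower_matrix(
    frame: pd.DataFrame, spec: Optional[MixedFeatureSpec] = None
) -> np.ndarray:
    """Pairwise Gower dissimilarity matrix for a feature frame."""
    if spec is None:
        spec = feature_spec_from_frame(frame)
    n = len(frame)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for f in spec.features:
        if f.name not in frame.columns:
            raise KeyError(f"feature {f.name!r} missing from frame")
        col = frame[f.name].to_numpy()
        if f.kind is FeatureKind.NUMERIC:
            x = col.astype(float)
            ok = np.isfinite(x)
            d = np.minimum(np.abs(x[:, None] - x[None, :]) / f.range, 1.0)
        else:
            ok = pd.notna(col)
            d = (col[:, None] != col[None, :]).astype(float)
        w = (ok[:, None] & ok[None, :]).astype(float)
        num += np.where(w > 0, d, 0.0) * w
        den += w
    if np.any(den == 0):
        raise ValueError("some record pairs share no observed features")
    dist = num / den
    np.fill_diagonal(dist, 0.0)
    return dist


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return dist


@dataclass(frozen=True)
class ClusterResult:
    """PAM output: medoids are actual members of the input."""

    k: int
    medoid_indices: np.ndarray
    medoid_ids: List[str]
    assignments: np.ndarray
    total_cost: float
    silhouette: float
    cost_history: Tuple[float, ...] = ()


#: Instances with at most this many candidate medoid subsets are solved
#: exactly, which guarantees optimality on desk-scale inputs where the
#: BUILD+SWAP local search could otherwise stall in a local optimum.
_EXHAUSTIVE_SUBSET_LIMIT = 120


def pam_cluster(
    dist: np.ndarray,
    k: int,
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
) -> ClusterResult:
    """Partitioning around medoids with deterministic BUILD + SWAP.

    BUILD greedily adds the medoid giving the largest cost decrease;
    SWAP accepts the best single medoid/non-medoid exchange until no
    exchange lowers the total cost.  Ties break on the lowest index, so
    the result is deterministic regardless of ``seed`` (kept for
    interface symmetry with the stochastic stages).  Tiny instances are
    minimised exhaustively instead.
    """
    from math import comb
    from itertools import combinations

    dist = _check_distance_matrix(dist)
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    if comb(n, k) <= _EXHAUSTIVE_SUBSET_LIMIT:
        med, cost = None, np.inf
        for subset in combinations(range(n), k):
            c = dist[:, subset].min(axis=1).sum()
            if c < cost - 1e-12:
                med, cost = np.array(subset), c
        history = [float(cost)]
    else:
        # BUILD
        medoids: List[int] = [int(np.argmin(dist.sum(axis=1)))]
        nearest = dist[:, medoids[0]].copy()
        while len(medoids) < k:
            gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            best = int(np.argmax(gains))
            medoids.append(best)
            nearest = np.minimum(nearest, dist[:, best])

        med = np.array(sorted(medoids))
        cost = dist[:, med].min(axis=1).sum()
        history = [float(cost)]

        # SWAP
        improved = True
        while improved:
            improved = False
            best_cost, best_swap = cost, None
            for mi, m in enumerate(med):
                others = np.delete(med, mi)
                for h in range(n):
                    if h in med:
                        continue
                    cand = np.append(others, h)
                    c = dist[:, cand].min(axis=1).sum()
                    if c < best_cost - 1e-12:
                        best_cost, best_swap = c, (mi, h)
            if best_swap is not None:
                mi, h = best_swap
                med[mi] = h
                med = np.array(sorted(med))
                cost = best_cost
                history.append(float(cost))
                improved = True

    assignments = np.argmin(dist[:, med], axis=1)
    labels = assignments
    if k == 1 or n == 1 or len(np.unique(labels)) < 2 or len(np.unique(labels)) >= n:
        sil = 0.0
    else:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    id_list = list(ids) if ids is not None else [str(i) for i in range(n)]
    return ClusterResult(
        k=k,
        medoid_indices=med,
        medoid_ids=[id_list[i] for i in med],
        assignments=assignments,
        total_cost=float(cost),
        silhouette=sil,
        cost_history=tuple(history),
    )


def silhouette_select_k(
    dist: np.ndarray,
    k_range: Iterable[int],
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
) -> Tuple[int, Dict[int, float]]:
    """Mean silhouette width per k; returns (argmax k, full profile).

    Ties resolve to the smaller k.
    """
    dist = _check_distance_matrix(dist)
    n = dist.shape[0]
    if np.all(dist == 0):
        raise ValueError("degenerate distance matrix: all distances zero")
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k range must lie within [2, {n - 1}]")
    profile: Dict[int, float] = {}
    for k in ks:
        profile[k] = pam_cluster(dist, k, seed=seed, ids=ids).silhouette
    best = max(profile, key=lambda k: (profile[k], -k))
    return best, profile


def embed_2d(dist: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """t-SNE embedding from a precomputed distance matrix.

    The contract is structural: n x 2, finite, deterministic per seed.
    Geometric layout is not asserted beyond coarse cluster separation.
    """
    dist = _check_distance_matrix(dist)
    n = dist.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for n={n}; need < (n-1)/3"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    )
    return tsne.fit_transform(dist)


#: Fig-style default score bands for cross-tabulation.
DEFAULT_NISS_BANDS: Tuple[float, ...] = (0, 10, 25, 40, 75)
DEFAULT_NISS_LABELS = ("1-10", "10-25", "25-40", "40-75")
DEFAULT_RTS_BANDS: Tuple[float, ...] = (-0.001, 2.5, 5.0, 7.5, 7.8408)
DEFAULT_RTS_LABELS = ("<2.5", "2.5-5", "5-7.5", ">7.5")


def triage_crosstab(
    table: pd.DataFrame,
    niss_bands: Sequence[float] = DEFAULT_NISS_BANDS,
    niss_labels: Sequence[str] = DEFAULT_NISS_LABELS,
    rts_bands: Sequence[float] = DEFAULT_RTS_BANDS,
    rts_labels: Sequence[str] = DEFAULT_RTS_LABELS,
) -> pd.DataFrame:
    """Counts and percentages per (algorithm, category, score band).

    ``table`` is the output of :func:`lifetriage.triage.triage_all`:
    it must carry ``niss``, ``rts`` and one or more ``*_category``
    columns.  Returns a long frame with one row per non-empty cell for
    both band axes (``band_type`` in {"niss", "rts"}).
    """
    if len(niss_bands) != len(niss_labels) + 1 or len(rts_bands) != len(rts_labels) + 1:
        raise ValueError("band edges must be one longer than band labels")
    algorithms = [c[: -len("_category")] for c in table.columns if c.endswith("_category")]
    if not algorithms:
        raise ValueError("table has no *_category columns")
    n = len(table)
    banded = table.assign(
        niss_band=pd.cut(table["niss"], bins=list(niss_bands), labels=list(niss_labels)),
        rts_band=pd.cut(table["rts"], bins=list(rts_bands), labels=list(rts_labels)),
    )
    rows = []
    for alg in algorithms:
        for band_type, band_col in (("niss", "niss_band"), ("rts", "rts_band")):
            counts = (
                banded.groupby([f"{alg}_category", band_col], observed=True)
                .size()
                .reset_index(name="count")
            )
            for _, r in counts.iterrows():
                rows.append(
                    {
                        "algorithm": alg,
                        "category": r[f"{alg}_category"],
                        "band_type": band_type,
                        "band": str(r[band_col]),
                        "count": int(r["count"]),
                        "pct": 100.0 * r["count"] / n,
                    }
                )
    return pd.DataFrame(rows)


def consensus_compare(
    table: pd.DataFrame,
    assignments: np.ndarray,
    focus_cluster: int,
    variables: Sequence[str] = ("niss", "rts", "survival_time_min"),
) -> Dict[str, object]:
    """Compare a cluster against unanimously triaged ("consensus") patients.

    Consensus subsets collect patients to whom all ``*_category``
    algorithms assigned the same category.  Returns per-variable means
    for the focus cluster and each consensus subset, plus the nearest
    consensus label by normalised mean distance across the variables.
    Empty consensus subsets are excluded with a warning.
    """
    cat_cols = [c for c in table.columns if c.endswith("_category")]
    if len(cat_cols) < 2:
        raise ValueError("consensus needs at least two triage algorithms")
    assignments = np.asarray(assignments)
    if len(assignments) != len(table):
        raise ValueError("assignments length must match table length")
    mask_focus = assignments == focus_cluster
    if not mask_focus.any():
        raise ValueError(f"focus cluster {focus_cluster} is empty")

    agree = table[cat_cols].nunique(axis=1) == 1
    consensus_label = table[cat_cols[0]].where(agree)

    stds = {v: float(table[v].std(ddof=0)) or 1.0 for v in variables}
    focus_means = {v: float(table.loc[mask_focus, v].mean()) for v in variables}

    subsets: Dict[str, Dict[str, float]] = {}
    for label in ("green", "yellow", "red", "black"):
        sel = consensus_label == label
        if not sel.any():
            warnings.warn(f"empty consensus subset: {label!r}", stacklevel=2)
            continue
        subsets[label] = {v: float(table.loc[sel, v].mean()) for v in variables}

    if not subsets:
        raise ValueError("no non-empty consensus subset")
    distances = {
        label: sum(abs(focus_means[v] - means[v]) / stds[v] for v in variables)
        for label, means in subsets.items()
    }
    nearest = min(distances, key=lambda l: (distances[l], l))
    return {
        "focus_cluster": int(focus_cluster),
        "focus_size": int(mask_focus.sum()),
        "focus_means": focus_means,
        "consensus_means": subsets,
        "consensus_sizes": {
            label: int((consensus_label == label).sum()) for label in subsets
        },
        "distances": distances,
        "nearest_consensus": nearest,
    }
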