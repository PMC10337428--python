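from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifetriage.analytics import (
    FeatureKind,
    FeatureSpec,
    MixedFeatureSpec,
    cohort_feature_frame,
    consensus_compare,
    embed_2d,
    feature_spec_from_frame,
    gower_distance,
    gower_matrix,
    pam_cluster,
    silhouette_select_k,
    triage_crosstab,
)
from lifetriage.triage import triage_all

from helpers import patient


def spec(*features):
    return MixedFeatureSpec(features=tuple(features))


NUM = lambda name, rng: FeatureSpec(name=name, kind=FeatureKind.NUMERIC, range=rng)
CAT = lambda name: FeatureSpec(name=name, kind=FeatureKind.CATEGORICAL)
BIN = lambda name: FeatureSpec(name=name, kind=FeatureKind.BINARY)


class TestGowerDistance:
    def test_identity(self):
        s = spec(NUM("a", 10), CAT("b"))
        rec = {"a": 3.0, "b": "x"}
        assert gower_distance(rec, rec, s) == 0.0

    def test_maximal_mismatch_categoricals(self):
        s = spec(CAT("a"), CAT("b"), CAT("c"))
        assert gower_distance(
            {"a": 1, "b": "u", "c": "p"}, {"a": 2, "b": "v", "c": "q"}, s
        ) == 1.0

    def test_hand_computed_mean(self):
        # numeric |2-7|/10 = 0.5; categorical equal = 0; mean = 0.25
        s = spec(NUM("a", 10), CAT("b"))
        assert gower_distance({"a": 2, "b": "x"}, {"a": 7, "b": "x"}, s) == 0.25

    def test_missing_values_reweighted(self):
        s = spec(NUM("a", 10), CAT("b"))
        d = gower_distance({"a": np.nan, "b": "x"}, {"a": 7.0, "b": "y"}, s)
        assert d == 1.0  # only the categorical mismatch remains

    def test_all_missing_rejected(self):
        s = spec(NUM("a", 10))
        with pytest.raises(ValueError):
            gower_distance({"a": np.nan}, {"a": 1.0}, s)

    @given(
        a=st.tuples(st.floats(0, 10), st.integers(0, 3), st.booleans()),
        b=st.tuples(st.floats(0, 10), st.integers(0, 3), st.booleans()),
    )
    @settings(max_examples=200, deadline=None)
    def test_properties_random_mixed_records(self, a, b):
        s = spec(NUM("x", 10), CAT("c"), BIN("f"))
        ra = {"x": a[0], "c": a[1], "f": a[2]}
        rb = {"x": b[0], "c": b[1], "f": b[2]}
        d = gower_distance(ra, rb, s)
        assert 0.0 <= d <= 1.0
        assert d == gower_distance(rb, ra, s)
        assert gower_distance(ra, ra, s) == 0.0

    def test_matrix_agrees_with_record_oracle(self, cohort_small):
        frame = cohort_feature_frame(cohort_small[:20])
        fspec = feature_spec_from_frame(frame)
        dist = gower_matrix(frame, fspec)
        assert dist.shape == (20, 20)
        assert np.allclose(dist, dist.T)
        assert np.all(np.diag(dist) == 0)
        assert np.all((dist >= 0) & (dist <= 1 + 1e-12))
        records = frame.to_dict(orient="records")
        for i in (0, 5, 13):
            for j in (2, 7, 19):
                assert dist[i, j] == pytest.approx(
                    gower_distance(records[i], records[j], fspec)
                )

    def test_numeric_spec_requires_range(self):
        with pytest.raises(Exception):
            FeatureSpec(name="a", kind=FeatureKind.NUMERIC, range=0.0)


def bruteforce_kmedoids(dist, k):
    """Exhaustive minimum over all C(n, k) medoid subsets."""
    n = dist.shape[0]
    best = np.inf
    for subset in combinations(range(n), k):
        cost = dist[:, subset].min(axis=1).sum()
        best = min(best, cost)
    return best


def blob_distance_matrix(seed=0, n_per=15, separation=10.0):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [
            rng.normal(0.0, 0.5, size=(n_per, 2)),
            rng.normal(separation, 0.5, size=(n_per, 2)),
        ]
    )
    labels = np.array([0] * n_per + [1] * n_per)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return d / d.max(), labels


class TestPam:
    def test_k_equals_n(self):
        d, _ = blob_distance_matrix(n_per=3)
        res = pam_cluster(d, k=6)
        assert res.total_cost == 0.0
        assert sorted(res.medoid_indices) == list(range(6))

    def test_two_blobs_recovered(self):
        d, labels = blob_distance_matrix(seed=1)
        res = pam_cluster(d, k=2)
        assigned = res.assignments
        # cluster labelling is arbitrary; compare both orientations
        agreement = max(
            (assigned == labels).mean(), (assigned == 1 - labels).mean()
        )
        assert agreement == 1.0

    @pytest.mark.parametrize("n,k", [(6, 2), (7, 3), (8, 2), (8, 4)])
    def test_matches_bruteforce_oracle(self, n, k):
        rng = np.random.default_rng(n * 10 + k)
        pts = rng.random((n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pam_cluster(d, k=k)
        assert res.total_cost == pytest.approx(bruteforce_kmedoids(d, k))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_build_swap_path_matches_bruteforce(self, seed):
        # n=20, k=2 exceeds the exhaustive-subset cutoff, so this
        # exercises the BUILD+SWAP local search against the oracle
        rng = np.random.default_rng(seed)
        pts = rng.random((20, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pam_cluster(d, k=2)
        assert len(res.cost_history) >= 1
        assert res.total_cost == pytest.approx(bruteforce_kmedoids(d, 2))

    def test_swap_cost_nonincreasing(self):
        d, _ = blob_distance_matrix(seed=8, n_per=20)
        res = pam_cluster(d, k=4)
        hist = np.array(res.cost_history)
        assert np.all(np.diff(hist) <= 0)
        assert hist[-1] == pytest.approx(res.total_cost)

    def test_medoids_are_members_and_nearest(self):
        d, _ = blob_distance_matrix(seed=2)
        res = pam_cluster(d, k=2, ids=[f"p{i}" for i in range(d.shape[0])])
        assert all(m in res.medoid_ids for m in res.medoid_ids)
        nearest = np.argmin(d[:, res.medoid_indices], axis=1)
        assert np.array_equal(nearest, res.assignments)

    def test_k_out_of_range(self):
        d, _ = blob_distance_matrix(n_per=3)
        with pytest.raises(ValueError):
            pam_cluster(d, k=7)

    def test_deterministic(self):
        d, _ = blob_distance_matrix(seed=3)
        r1 = pam_cluster(d, k=3, seed=1)
        r2 = pam_cluster(d, k=3, seed=99)
        assert np.array_equal(r1.medoid_indices, r2.medoid_indices)


class TestSilhouetteSelect:
    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(4)
        pts = np.vstack(
            [rng.normal(c, 0.4, size=(12, 2)) for c in ((0, 0), (8, 0), (0, 8))]
        )
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        k_star, profile = silhouette_select_k(d, range(2, 7))
        assert k_star == 3
        assert all(-1.0 <= v <= 1.0 for v in profile.values())

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError):
            silhouette_select_k(np.zeros((5, 5)), [2, 3])

    def test_bounds_enforced(self):
        d, _ = blob_distance_matrix(n_per=2)
        with pytest.raises(ValueError):
            silhouette_select_k(d[:2, :2], [2])


class TestEmbed:
    def test_shape_finite_deterministic(self):
        d, _ = blob_distance_matrix(seed=5)
        a = embed_2d(d, perplexity=5, seed=7)
        b = embed_2d(d, perplexity=5, seed=7)
        assert a.shape == (d.shape[0], 2)
        assert np.all(np.isfinite(a))
        assert np.array_equal(a, b)

    def test_blob_separation(self):
        d, labels = blob_distance_matrix(seed=6)
        coords = embed_2d(d, perplexity=5, seed=0)
        ed = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert ed[~same].mean() > ed[same & off_diag].mean()

    def test_perplexity_bound(self):
        d, _ = blob_distance_matrix(n_per=5)
        with pytest.raises(ValueError):
            embed_2d(d, perplexity=5.0)


class TestCrosstab:
    def test_marginals_sum_to_cohort(self, cohort_small):
        sub = cohort_small[:500]
        table = triage_all(sub)
        tab = triage_crosstab(table)
        for alg in ("start", "rts", "life"):
            for band_type in ("niss", "rts"):
                sel = (tab.algorithm == alg) & (tab.band_type == band_type)
                assert tab.loc[sel, "count"].sum() == 500

    def test_hand_tabulated_toy_cohort(self):
        toy = [
            patient("t1", [1], gcs=15, sbp=120, rr=16, walking=True),
            patient("t2", [1], gcs=15, sbp=120, rr=16, walking=True),
            patient("t3", [5, 4], gcs=12, sbp=70, rr=35, walking=False,
                    radial_pulse_palpable=False, obeys_commands=False),
            patient("t4", [3, 3], gcs=15, sbp=110, rr=18, walking=False),
        ]
        table = triage_all(toy, ("start",))
        tab = triage_crosstab(table)
        niss = tab[tab.band_type == "niss"].set_index(["category", "band"])["count"]
        assert niss[("green", "1-10")] == 2
        assert niss[("red", "40-75")] == 1
        assert niss[("yellow", "10-25")] == 1

    def test_life_green_high_niss_cell_empty(self, cohort_large):
        table = triage_all(cohort_large)
        tab = triage_crosstab(table)
        bad = tab[
            (tab.algorithm == "life")
            & (tab.category == "green")
            & (tab.band_type == "niss")
            & (tab.band.isin(["25-40", "40-75"]))
        ]
        assert bad["count"].sum() == 0

    def test_unknown_band_spec_rejected(self, cohort_small):
        table = triage_all(cohort_small[:10])
        with pytest.raises(ValueError):
            triage_crosstab(table, niss_bands=(0, 10), niss_labels=("a", "b"))


class TestConsensusCompare:
    def test_unanimous_cluster_trivially_nearest(self):
        cohort = [
            patient(f"g{i}", [1], gcs=15, sbp=120, rr=16, walking=True)
            for i in range(5)
        ] + [
            patient(f"r{i}", [5, 4, 3], gcs=9, sbp=70, rr=35, walking=False,
                    radial_pulse_palpable=False, obeys_commands=False)
            for i in range(5)
        ]
        table = triage_all(cohort)
        # greens in cluster 0, reds in cluster 1
        assignments = np.array([0] * 5 + [1] * 5)
        with pytest.warns(UserWarning):  # some consensus subsets are empty
            out = consensus_compare(table, assignments, focus_cluster=1)
        assert out["nearest_consensus"] == table.loc[5, "start_category"]

    def test_synthetic_cluster_matches_yellow_consensus(self):
        # hand-built triaged table: consensus subsets by construction,
        # focus cluster drawn from the yellow-consensus distribution
        rng = np.random.default_rng(12)
        def block(cat, niss_mu, rts_mu, surv_mu, n, cluster):
            return pd.DataFrame(
                {
                    "niss": rng.normal(niss_mu, 2, n),
                    "rts": rng.normal(rts_mu, 0.2, n),
                    "survival_time_min": rng.normal(surv_mu, 30, n),
                    "start_category": cat,
                    "rts_category": cat,
                    "life_category": cat,
                    "cluster": cluster,
                }
            )
        table = pd.concat(
            [
                block("green", 5, 7.8, 1000, 50, 0),
                block("yellow", 17, 7.2, 850, 50, 0),
                block("red", 32, 5.5, 400, 50, 0),
                block("yellow", 17, 7.2, 850, 40, 1),  # the focus draw
            ],
            ignore_index=True,
        )
        # focus patients are triaged heterogeneously (no consensus)
        focus = table["cluster"] == 1
        table.loc[focus, "start_category"] = "green"
        table.loc[focus, "rts_category"] = "red"
        with pytest.warns(UserWarning, match="black"):
            out = consensus_compare(
                table, table["cluster"].to_numpy(), focus_cluster=1
            )
        assert out["nearest_consensus"] == "yellow"

    def test_empty_focus_rejected(self, cohort_small):
        table = triage_all(cohort_small[:20])
        with pytest.raises(ValueError):
            consensus_compare(table, np.zeros(20, dtype=int), focus_cluster=3)

    def test_subsampling_before_clustering_is_seeded(self, cohort_small):
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        pick1 = sorted(rng1.choice(len(cohort_small), 100, replace=False))
        pick2 = sorted(rng2.choice(len(cohort_small), 100, replace=False))
        assert pick1 == pick2


class TestFeatureFrame:
    def test_default_feature_count(self, cohort_small):
        frame = cohort_feature_frame(cohort_small[:10])
        assert frame.shape[1] == 27

    def test_excludes_triage_categories(self, cohort_small):
        frame = cohort_feature_frame(cohort_small[:10])
        assert not any("category" in c for c in frame.columns)
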