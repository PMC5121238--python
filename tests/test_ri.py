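import numpy as np
import pytest
from oracles import brute_dbscan, canonical_labels

from riscape.fixtures import PlantedPattern, make_planted_pattern
from riscape.ri import (
    DBSCANParams,
    Detection,
    dbscan,
    detect_ri,
    summarize,
    track_events,
)
from riscape.simulator import GenerationRecord


def record_with(upper, lower, generation=0):
    upper = np.asarray(upper, dtype=float).reshape(-1, 2)
    lower = np.asarray(lower, dtype=float).reshape(-1, 2)
    counts = np.zeros(9, dtype=np.int64)
    counts[8], counts[0] = len(upper), len(lower)
    return GenerationRecord(
        generation=generation, selection_on=True,
        pop_size=len(upper) + len(lower), class_counts=counts,
        coords_aabb_upper=upper, coords_aabb_lower=lower,
    )


class TestDBSCAN:
    def test_minimal_core_cluster(self):
        pts = [(0, 0), (1, 0), (0, 1), (1, 1)]
        lab = dbscan(pts, DBSCANParams(eps=2.0, min_pts=4))
        assert lab.n_clusters == 1
        assert list(lab.labels) == [0, 0, 0, 0]

    def test_below_min_pts_is_noise(self):
        pts = [(0, 0), (1, 0), (0, 1)]
        lab = dbscan(pts, DBSCANParams(eps=2.0, min_pts=4))
        assert lab.n_clusters == 0
        assert (lab.labels == -1).all()

    def test_empty_input(self):
        lab = dbscan(np.empty((0, 2)), DBSCANParams(eps=1.0, min_pts=4))
        assert lab.n_clusters == 0 and len(lab.labels) == 0

    def test_sizes_plus_noise_partition_points(self, rng):
        pts = rng.uniform(0, 50, size=(300, 2))
        lab = dbscan(pts, DBSCANParams(eps=3.0, min_pts=4))
        assert lab.sizes().sum() + (lab.labels == -1).sum() == 300

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_reachability_oracle(self, seed):
        """Cluster partition identical to an explicit reachability-graph
        flood fill on random 200-point instances with varied parameters."""
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 100, size=(200, 2))
        eps = float(r.uniform(3, 10))
        min_pts = int(r.integers(3, 7))
        ours = canonical_labels(dbscan(pts, DBSCANParams(eps, min_pts)).labels)
        ref = canonical_labels(brute_dbscan(pts, eps, min_pts))
        assert np.array_equal(ours, ref)

    def test_permutation_stable_core_partition(self, rng):
        pts = rng.uniform(0, 60, size=(150, 2))
        params = DBSCANParams(eps=5.0, min_pts=4)
        base = dbscan(pts, params)
        perm = rng.permutation(150)
        shuffled = dbscan(pts[perm], params)
        # compare partitions as sets of frozensets of point ids
        def partition(labels, ids):
            groups = {}
            for pid, lab in zip(ids, labels):
                if lab != -1:
                    groups.setdefault(lab, set()).add(pid)
            return {frozenset(g) for g in groups.values()}
        # restrict to core points, whose partition is order-independent
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        core = (d <= params.eps).sum(1) >= params.min_pts
        assert partition(base.labels[core[np.arange(150)]],
                         np.flatnonzero(core)) == \
               partition(shuffled.labels[core[perm]],
                         perm[core[perm]])


class TestDetectRI:
    def test_single_genotype_cluster_is_not_an_event(self):
        upper = np.random.default_rng(0).normal((10, 10), 0.5, size=(10, 2))
        det = detect_ri(record_with(upper, np.empty((0, 2))),
                        DBSCANParams(eps=5.0, min_pts=4))
        assert not det.is_event
        assert det.clusters_aabb_upper.n_clusters == 1

    def test_planted_two_plus_two_clusters(self):
        rec = make_planted_pattern(PlantedPattern(
            centers_upper=((10_000, 10_000), (90_000, 90_000)),
            centers_lower=((10_000, 90_000), (90_000, 10_000)),
            points_per_cluster=20, spread=200.0, noise_points=30, seed=3,
        ))
        det = detect_ri(rec.record)
        assert det.is_event
        assert det.clusters_aabb_upper.n_clusters == 2
        assert det.clusters_aabb_lower.n_clusters == 2
        assert sorted(det.clusters_aabb_upper.sizes()) == [20, 20]

    def test_sparse_scatter_is_not_an_event(self):
        rec = make_planted_pattern(PlantedPattern(noise_points=50, seed=4))
        assert not detect_ri(rec.record).is_event

    def test_adding_points_to_cluster_preserves_event(self, rng):
        params = DBSCANParams(eps=5.0, min_pts=4)
        upper = rng.normal((10, 10), 1.0, size=(8, 2))
        lower = rng.normal((80, 80), 1.0, size=(8, 2))
        base = detect_ri(record_with(upper, lower), params)
        assert base.is_event
        grown = detect_ri(record_with(
            np.vstack([upper, rng.normal((10, 10), 1.0, size=(10, 2))]),
            lower,
        ), params)
        assert grown.is_event


def _det(gen, is_event, n_up=1, n_lo=1, size=5):
    """Hand-built Detection for run-length bookkeeping tests."""
    from riscape.ri import ClusterLabeling
    def lab(k):
        if not is_event or k == 0:
            return ClusterLabeling(points=np.empty((0, 2)),
                                   labels=np.empty(0, dtype=np.int64))
        pts = np.zeros((k * size, 2))
        return ClusterLabeling(points=pts,
                               labels=np.repeat(np.arange(k), size))
    return Detection(generation=gen, is_event=is_event,
                     clusters_aabb_upper=lab(n_up), clusters_aabb_lower=lab(n_lo))


class TestEventTracking:
    def test_runs_split_on_gaps_and_negatives(self):
        dets = [_det(1, True), _det(2, True), _det(3, False),
                _det(4, True), _det(6, True)]
        events = track_events(dets)
        assert [(e.start, e.end, e.duration) for e in events] == \
            [(1, 2, 2), (4, 4, 1), (6, 6, 1)]

    def test_summarize_means(self):
        dets = [_det(1, True, n_up=2, n_lo=1), _det(2, True, n_up=1, n_lo=1),
                _det(3, False)]
        events = track_events(dets)
        duration, number, size = summarize(events, dets)
        assert duration == 2.0  # single run of length 2
        assert number == pytest.approx((3 + 2) / 2)
        assert size == 5.0

    def test_no_events_gives_zeros(self):
        dets = [_det(1, False), _det(2, False)]
        assert summarize(track_events(dets), dets) == (0.0, 0.0, 0.0)

    def test_detections_frame_is_tidy(self):
        from riscape.ri import detections_to_frame
        df = detections_to_frame([_det(1, True, n_up=2, n_lo=1), _det(2, False)])
        assert list(df["generation"]) == [1, 2]
        assert list(df["is_event"]) == [True, False]
        assert df.loc[0, "n_clusters_AABB"] == 2
        assert df.loc[0, "cluster_sizes"] == "5;5;5"
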