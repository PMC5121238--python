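"""Detection and bookkeeping of reproductively isolated (RI) clusters.

An RI event in one generation is the simultaneous presence of at least one
dense spatial cluster of AABB carriers and at least one of aabb carriers —
two groups whose F1 offspring (AaBb) are inviable, so adjacent clusters of
the two types are truly reproductively isolated.  Clusters are found with
DBSCAN (a point is a core point when at least ``min_pts`` points, itself
included, lie within ``eps``; clusters are the eps-reachability components
of core points plus their border points).  Durations are run lengths of
consecutive event-positive generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .simulator import GenerationRecord

__all__ = [
    "DBSCANParams",
    "ClusterLabeling",
    "Detection",
    "RIEventRecord",
    "dbscan",
    "detect_ri",
    "track_events",
    "summarize",
]

NOISE = -1


@dataclass(frozen=True)
class DBSCANParams:
    """Neighborhood radius (distance units) and minimum neighborhood size."""

    eps: float = 2000.0
    min_pts: int = 4

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class ClusterLabeling:
    """Per-point cluster labels; -1 marks noise."""

    points: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) ints, -1 = noise

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels != NOISE])))

    def sizes(self) -> np.ndarray:
        """Cluster sizes (individuals), ordered by cluster label."""
        lab = self.labels[self.labels != NOISE]
        if lab.size == 0:
            return np.empty(0, dtype=np.int64)
        return np.bincount(lab)


def dbscan(points, params: DBSCANParams = DBSCANParams()) -> ClusterLabeling:
    """Classical DBSCAN on 2-D points.

    ``min_pts`` counts the point itself.  Border points reachable from more
    than one cluster go to the cluster discovered first in point-index scan
    order, which makes labelings reproducible for a fixed point order; the
    partition of core points does not depend on order.  Empty input yields
    an empty labeling.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return ClusterLabeling(points=pts, labels=np.empty(0, dtype=np.int64))
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    model = DBSCAN(eps=params.eps, min_samples=params.min_pts)
    labels = model.fit_predict(pts).astype(np.int64)
    return ClusterLabeling(points=pts, labels=labels)


@dataclass
class Detection:
    """Outcome of RI detection for one generation."""

    generation: int
    is_event: bool
    clusters_aabb_upper: ClusterLabeling  # AABB carriers
    clusters_aabb_lower: ClusterLabeling  # aabb carriers

    @property
    def n_clusters(self) -> int:
        """Total cluster count, pooling both genotypes."""
        return (self.clusters_aabb_upper.n_clusters
                + self.clusters_aabb_lower.n_clusters)

    def cluster_sizes(self) -> np.ndarray:
        return np.concatenate([
            self.clusters_aabb_upper.sizes(),
            self.clusters_aabb_lower.sizes(),
        ])


def detect_ri(record: GenerationRecord,
              params: DBSCANParams = DBSCANParams()) -> Detection:
    """Run DBSCAN separately on AABB and aabb carriers of one generation.

    The generation is an RI event iff both genotypes form at least one
    cluster each.
    """
    upper = dbscan(record.coords_aabb_upper, params)
    lower = dbscan(record.coords_aabb_lower, params)
    return Detection(
        generation=record.generation,
        is_event=upper.n_clusters >= 1 and lower.n_clusters >= 1,
        clusters_aabb_upper=upper,
        clusters_aabb_lower=lower,
    )


@dataclass
class RIEventRecord:
    """One maximal run of consecutive event-positive generations."""

    start: int
    end: int  # inclusive
    detections: list[Detection] = field(repr=False, default_factory=list)

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


def track_events(detections: list[Detection]) -> list[RIEventRecord]:
    """Group consecutive event-positive generations into RI event records.

    Consecutiveness is judged on generation numbers, so gaps in the supplied
    detections (e.g. burn-in excluded) break runs.
    """
    events: list[RIEventRecord] = []
    current: RIEventRecord | None = None
    for det in sorted(detections, key=lambda d: d.generation):
        if det.is_event:
            if current is not None and det.generation == current.end + 1:
                current.end = det.generation
                current.detections.append(det)
            else:
                current = RIEventRecord(start=det.generation,
                                        end=det.generation, detections=[det])
                events.append(current)
        else:
            current = None
    return events


def detections_to_frame(detections: list[Detection]):
    """Tidy per-generation detection table (sizes packed as ';'-joined)."""
    import pandas as pd

    rows = []
    for d in detections:
        rows.append({
            "generation": d.generation,
            "is_event": d.is_event,
            "n_clusters_AABB": d.clusters_aabb_upper.n_clusters,
            "n_clusters_aabb": d.clusters_aabb_lower.n_clusters,
            "cluster_sizes": ";".join(map(str, d.cluster_sizes().tolist())),
        })
    return pd.DataFrame(rows)


def summarize(events: list[RIEventRecord],
              detections: list[Detection]) -> tuple[float, float, float]:
    """(mean_duration, mean_number, mean_size) over a run.

    mean_duration averages event run lengths (generations); mean_number
    averages the pooled AABB + aabb cluster count over event-positive
    generations; mean_size averages individuals per cluster over
    event-positive generations.  All three are 0 when no event occurred.
    """
    if not events:
        return 0.0, 0.0, 0.0
    mean_duration = float(np.mean([e.duration for e in events]))
    positive = [d for d in detections if d.is_event]
    mean_number = float(np.mean([d.n_clusters for d in positive]))
    sizes = np.concatenate([d.cluster_sizes() for d in positive])
    mean_size = float(sizes.mean())
    return mean_duration, mean_number, mean_size
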