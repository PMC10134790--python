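"""Genomic-context fingerprints of solo clusters and their subgrouping.

For each sufficiently large sequence cluster (>50 members) the fraction of
members whose detection window contains each Pfam accession is recorded;
rare accessions (<5% of members) are dropped.  The per-cluster frequency
vectors are embedded in three dimensions — deterministic PCA by default,
seeded UMAP optionally — and density-clustered with DBSCAN (eps 0.5,
min_samples 10); clusters falling in no dense region get the noise label
-1.  DBSCAN labels are renumbered by the first-encountered core point in
id-sorted order so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .cluster import SequenceCluster
from .detect import LUXR_PFAM, SoloCall
from .errors import ContractViolationError, DegenerateInputError

log = logging.getLogger(__name__)

MIN_MEMBERS = 51       # "more than 50 members" — strict
FREQ_FLOOR = 0.05      # "less than 5% appearance ... dropped"
DBSCAN_EPS = 0.5
DBSCAN_MIN_SAMPLES = 10


@dataclass(frozen=True)
class ContextProfile:
    cluster_id: int
    n_members: int
    pfam_freqs: dict[str, float]     # all frequencies, pre-floor
    retained_pfams: tuple[str, ...]  # frequency >= floor, sorted

    def vector(self, feature_order: list[str]) -> np.ndarray:
        return np.array([self.pfam_freqs.get(p, 0.0)
                         if p in self.retained_pfams else 0.0
                         for p in feature_order])


@dataclass(frozen=True)
class SubgroupAssignment:
    cluster_id: int
    embedding: tuple[float, float, float]
    subgroup_id: int  # -1 = noise


def build_context_profile(cluster: SequenceCluster,
                          solo_calls: dict[str, SoloCall],
                          min_members: int = MIN_MEMBERS,
                          freq_floor: float = FREQ_FLOOR) -> ContextProfile | None:
    """Per-pfam member prevalence for one cluster, or None if too small.

    Presence is counted once per member regardless of how many window
    genes carry the pfam; the focal gene and the LuxR-family domain itself
    are excluded as uninformative.
    """
    n = cluster.n_members
    if n < min_members:
        log.info("cluster %d skipped for profiling: %d members < %d",
                 cluster.cluster_id, n, min_members)
        return None
    counts: dict[str, int] = {}
    for pid in cluster.member_ids:
        call = solo_calls.get(pid)
        if call is None:
            raise ContractViolationError(
                f"cluster {cluster.cluster_id}: member {pid} has no solo call")
        for pfam in call.neighborhood_pfams(exclude_self=True,
                                            exclude=frozenset({LUXR_PFAM})):
            counts[pfam] = counts.get(pfam, 0) + 1
    freqs = {p: c / n for p, c in counts.items()}
    retained = tuple(sorted(p for p, f in freqs.items() if f >= freq_floor))
    return ContextProfile(cluster_id=cluster.cluster_id, n_members=n,
                          pfam_freqs=freqs, retained_pfams=retained)


def vectorize_profiles(profiles: list[ContextProfile]
                       ) -> tuple[list[int], list[str], np.ndarray]:
    """(cluster ids, feature order, matrix) over the union of retained pfams."""
    ids = [p.cluster_id for p in profiles]
    features = sorted({f for p in profiles for f in p.retained_pfams})
    X = np.array([[p.pfam_freqs.get(f, 0.0) if f in p.retained_pfams else 0.0
                   for f in features] for p in profiles])
    return ids, features, X


def embed_profiles(profiles: list[ContextProfile], method: str = "pca",
                   n_components: int = 3, seed: int = 0
                   ) -> dict[int, np.ndarray]:
    """Embed context profiles into `n_components` dimensions.

    pca is fully deterministic (components signed so the largest-magnitude
    loading is positive); umap is stochastic but reproducible for a fixed
    seed.  Missing dimensions (fewer samples/features than requested) are
    zero-padded so downstream geometry is unaffected.
    """
    if len(profiles) < 2:
        raise DegenerateInputError("need at least 2 profiles to embed")
    ids, _features, X = vectorize_profiles(profiles)
    if method == "pca":
        k = min(n_components, X.shape[0], X.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        Y = pca.fit_transform(X)
        for j in range(k):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                Y[:, j] *= -1
    elif method == "umap":
        import umap  # heavy import; deferred

        n_neighbors = min(15, len(profiles) - 1)
        reducer = umap.UMAP(n_components=min(n_components, len(profiles) - 2) or 1,
                            n_neighbors=n_neighbors, random_state=seed)
        Y = reducer.fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    if Y.shape[1] < n_components:
        Y = np.hstack([Y, np.zeros((Y.shape[0], n_components - Y.shape[1]))])
    return {cid: Y[i] for i, cid in enumerate(ids)}


def dbscan(points: dict[int | str, np.ndarray], eps: float = DBSCAN_EPS,
           min_samples: int = DBSCAN_MIN_SAMPLES) -> dict[int | str, int]:
    """Euclidean DBSCAN with deterministic label numbering.

    A point is core iff at least `min_samples` points (itself included)
    lie within `eps`.  Non-core points density-reachable from a core point
    join its cluster; the rest are noise (-1).  Cluster numbers follow the
    first-encountered core point in id-sorted order.
    """
    if not points:
        return {}
    ids = sorted(points)
    X = np.asarray([points[i] for i in ids], dtype=float)
    model = DBSCAN(eps=eps, min_samples=min_samples).fit(X)
    labels = model.labels_
    remap: dict[int, int] = {}
    for idx in sorted(model.core_sample_indices_):
        lab = labels[idx]
        if lab not in remap:
            remap[lab] = len(remap)
    return {pid: (remap[lab] if lab != -1 else -1)
            for pid, lab in zip(ids, labels)}


def assign_subgroups(profiles: list[ContextProfile], method: str = "pca",
                     seed: int = 0, eps: float = DBSCAN_EPS,
                     min_samples: int = DBSCAN_MIN_SAMPLES
                     ) -> list[SubgroupAssignment]:
    """Embed + density-cluster; every profiled cluster gets one assignment."""
    coords = embed_profiles(profiles, method=method, seed=seed)
    labels = dbscan(coords, eps=eps, min_samples=min_samples)
    return [SubgroupAssignment(cluster_id=cid,
                               embedding=tuple(float(v) for v in coords[cid]),
                               subgroup_id=labels[cid])
            for cid in sorted(coords)]
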