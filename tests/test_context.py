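"""Context profiling, embedding and density-based subgrouping."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from solomine.cluster import SequenceCluster
from solomine.context import (build_context_profile, dbscan, embed_profiles,
                              assign_subgroups)
from solomine.errors import ContractViolationError, DegenerateInputError
from solomine.simulate import generate_profile_blobs

from conftest import make_solo_call


def _cluster_with_calls(n_members, pfam_in_first_k, pfam="PF00005"):
    members = [f"m{i}" for i in range(n_members)]
    cluster = SequenceCluster(cluster_id=0, representative_id="m0",
                              member_ids=members,
                              member_identities=[1.0] * n_members,
                              member_coverages=[(1.0, 1.0)] * n_members)
    calls = {}
    for i, pid in enumerate(members):
        pfams = [{pfam}] if i < pfam_in_first_k else [set()]
        calls[pid] = make_solo_call(pid, pfams)
    return cluster, calls


def test_frequency_at_floor_is_retained():
    cluster, calls = _cluster_with_calls(60, 3)  # 3/60 = 0.05 exactly
    prof = build_context_profile(cluster, calls)
    assert prof.pfam_freqs["PF00005"] == pytest.approx(0.05)
    assert "PF00005" in prof.retained_pfams


def test_frequency_below_floor_is_dropped():
    cluster, calls = _cluster_with_calls(60, 2)  # 2/60 < 0.05
    prof = build_context_profile(cluster, calls)
    assert "PF00005" not in prof.retained_pfams
    assert prof.pfam_freqs["PF00005"] == pytest.approx(2 / 60)


def test_cluster_of_exactly_50_members_is_skipped():
    cluster, calls = _cluster_with_calls(50, 10)
    assert build_context_profile(cluster, calls) is None


def test_member_presence_counted_once():
    cluster, calls = _cluster_with_calls(60, 0)
    # one member with the pfam on two window genes still counts once
    calls["m0"] = make_solo_call("m0", [{"PF00005"}, {"PF00005"}])
    prof = build_context_profile(cluster, calls)
    assert prof.pfam_freqs["PF00005"] == pytest.approx(1 / 60)


def test_missing_solo_call_is_contract_violation():
    cluster, calls = _cluster_with_calls(60, 5)
    del calls["m3"]
    with pytest.raises(ContractViolationError, match="m3"):
        build_context_profile(cluster, calls)


def test_embedding_requires_two_profiles():
    profiles, _ = generate_profile_blobs(1, 1, 0, seed=0)
    with pytest.raises(DegenerateInputError):
        embed_profiles(profiles[:1])


def test_identical_profiles_get_identical_coordinates():
    profiles, _ = generate_profile_blobs(2, 12, 0, seed=1)
    dup = [profiles[0], profiles[0], profiles[-1]]
    coords = embed_profiles(
        [p if i != 1 else type(p)(cluster_id=999, n_members=p.n_members,
                                  pfam_freqs=p.pfam_freqs,
                                  retained_pfams=p.retained_pfams)
         for i, p in enumerate(dup)])
    assert np.allclose(coords[profiles[0].cluster_id], coords[999])


def test_pca_embedding_deterministic():
    profiles, _ = generate_profile_blobs(3, 12, 4, seed=2)
    c1 = embed_profiles(profiles, method="pca")
    c2 = embed_profiles(profiles, method="pca")
    assert all(np.array_equal(c1[k], c2[k]) for k in c1)


def test_seeded_umap_reproducible():
    profiles, _ = generate_profile_blobs(2, 10, 3, seed=3)
    c1 = embed_profiles(profiles, method="umap", seed=42)
    c2 = embed_profiles(profiles, method="umap", seed=42)
    assert all(np.allclose(c1[k], c2[k]) for k in c1)


def dbscan_oracle(points, eps, min_samples):
    """BFS over the eps-graph restricted to core points.

    Returns (core partition as a set of frozensets, noise ids, and for each
    border point the set of adjacent core clusters it may join).
    """
    ids = sorted(points)
    X = np.array([points[i] for i in ids])
    D = cdist(X, X)
    near = D <= eps
    core = near.sum(axis=1) >= min_samples
    unvisited = set(np.nonzero(core)[0])
    comps = []
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            u = frontier.pop()
            for v in np.nonzero(near[u] & core)[0]:
                if v in unvisited:
                    unvisited.discard(int(v))
                    comp.add(int(v))
                    frontier.append(int(v))
        comps.append(comp)
    border = {}
    noise = set()
    for i in range(len(ids)):
        if core[i]:
            continue
        adjacent = {k for k, comp in enumerate(comps)
                    if any(near[i, j] for j in comp)}
        if adjacent:
            border[i] = adjacent
        else:
            noise.add(i)
    part = {frozenset(ids[i] for i in comp) for comp in comps}
    return ids, part, {ids[i] for i in noise}, \
        {ids[i]: adj for i, adj in border.items()}, comps


def test_dbscan_coincident_points_form_one_cluster():
    pts = {i: np.zeros(3) for i in range(12)}
    labels = dbscan(pts, eps=0.5, min_samples=10)
    assert set(labels.values()) == {0}


def test_dbscan_too_few_points_all_noise():
    pts = {i: np.zeros(3) for i in range(5)}
    labels = dbscan(pts, eps=0.5, min_samples=10)
    assert set(labels.values()) == {-1}


def test_dbscan_empty_input():
    assert dbscan({}) == {}


def test_dbscan_matches_brute_force_oracle(rng):
    for trial in range(15):
        n = int(rng.integers(20, 200))
        pts = {int(i): rng.uniform(0, 4, 3) for i in range(n)}
        eps, min_samples = 0.6, int(rng.integers(2, 8))
        labels = dbscan(pts, eps=eps, min_samples=min_samples)
        ids, part, noise, border, comps = dbscan_oracle(pts, eps, min_samples)
        got_clusters = {}
        for pid, lab in labels.items():
            if lab != -1:
                got_clusters.setdefault(lab, set()).add(pid)
        # noise identical
        assert {p for p, l in labels.items() if l == -1} == noise
        # core partition identical up to label permutation
        core_ids = {i for comp in part for i in comp}
        got_core_part = {frozenset(m & core_ids)
                         for m in map(set, got_clusters.values())}
        assert got_core_part == part
        # each border point joined one of its density-reachable clusters
        comp_sets = [frozenset(ids[i] for i in c) for c in comps]
        for pid, adj in border.items():
            lab = labels[pid]
            assert lab != -1
            members = frozenset(got_clusters[lab] & core_ids)
            assert any(members == comp_sets[k] for k in adj)


def test_dbscan_invariant_under_permutation(rng):
    pts = {int(i): rng.uniform(0, 2, 3) for i in range(60)}
    labels1 = dbscan(pts, eps=0.5, min_samples=5)
    shuffled = {k: pts[k] for k in reversed(sorted(pts))}
    labels2 = dbscan(shuffled, eps=0.5, min_samples=5)
    assert labels1 == labels2


def test_planted_archetypes_recovered_with_noise():
    hits = 0
    for seed in range(20):
        profiles, truth = generate_profile_blobs(3, 15, 5, seed=seed)
        got = {a.cluster_id: a.subgroup_id
               for a in assign_subgroups(profiles, method="pca", seed=seed)}
        k = len({v for v in got.values() if v != -1})
        noise_ok = all(got[c] == -1 for c, l in truth.items() if l == -1)
        if k == 3 and noise_ok:
            hits += 1
    assert hits >= 19  # >=95% of seeds


def test_zero_separation_merges_archetypes():
    profiles, _ = generate_profile_blobs(3, 12, 0, separation=0.0, seed=4)
    got = assign_subgroups(profiles, method="pca", seed=4)
    assert len({a.subgroup_id for a in got if a.subgroup_id != -1}) <= 1


def test_no_retained_pfam_below_floor():
    profiles, _ = generate_profile_blobs(2, 12, 3, seed=5)
    for p in profiles:
        assert all(p.pfam_freqs[f] >= 0.05 for f in p.retained_pfams)
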