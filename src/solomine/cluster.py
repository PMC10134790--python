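"""Greedy incremental clustering of protein sequences.

Sequences are processed longest-first (ties broken by id) and each joins
the first existing representative it matches at >=80% identity with >=80%
bidirectional coverage, else founds a new cluster — the classic
representative-led greedy scheme used for redundancy reduction of protein
sets.  Identity is counted over the shorter sequence; because coverage of
the longer sequence in a pair is bounded by the length ratio, pairs whose
ratio is below the coverage threshold are skipped without aligning.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import pairwise_identity


@dataclass
class SequenceCluster:
    cluster_id: int
    representative_id: str
    member_ids: list[str]
    member_identities: list[float]
    member_coverages: list[tuple[float, float]]  # (cov_member, cov_rep)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def greedy_cluster(sequences: dict[str, str], id_threshold: float = 0.80,
                   cov_threshold: float = 0.80) -> list[SequenceCluster]:
    """Single-pass greedy clustering; deterministic for any dict order."""
    order = sorted(sequences, key=lambda pid: (-len(sequences[pid]), pid))
    clusters: list[SequenceCluster] = []
    for pid in order:
        seq = sequences[pid]
        placed = False
        for cl in clusters:
            rep_seq = sequences[cl.representative_id]
            # coverage of the longer sequence can never exceed len ratio
            if len(seq) < cov_threshold * len(rep_seq):
                continue
            ident, cov_m, cov_r = pairwise_identity(seq, rep_seq)
            if ident >= id_threshold and cov_m >= cov_threshold and cov_r >= cov_threshold:
                cl.member_ids.append(pid)
                cl.member_identities.append(ident)
                cl.member_coverages.append((cov_m, cov_r))
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(
                cluster_id=len(clusters), representative_id=pid,
                member_ids=[pid], member_identities=[1.0],
                member_coverages=[(1.0, 1.0)]))
    return clusters
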