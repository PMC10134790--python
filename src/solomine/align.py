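"""Global pairwise protein alignment with a linear gap model.

The clustering and residue-anchoring stages both rely on one alignment
contract: Needleman–Wunsch with match +1, mismatch 0, gap -1 (linear),
deterministic traceback (diagonal preferred over up over left), identity
computed over the shorter sequence, and per-sequence coverage measured as
the span between the first and last aligned (residue-vs-residue) columns.
The DP fill is vectorized row-wise with a running-maximum scan for the
horizontal (gap-in-query) moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


def validate_protein(seq: str, name: str = "sequence") -> str:
    """Return *seq* uppercased, or raise ValidationError on a bad alphabet."""
    s = seq.upper()
    bad = set(s) - _AA_SET
    if not s:
        raise ValidationError(f"{name} is empty")
    if bad:
        raise ValidationError(
            f"{name} contains non-amino-acid characters: {sorted(bad)!r}"
        )
    return s


@dataclass(frozen=True)
class Alignment:
    """A global alignment of two sequences.

    ``pairs`` holds, per alignment column, the 0-based indices into each
    sequence or -1 for a gap.
    """

    a: str
    b: str
    score: float
    pairs: tuple[tuple[int, int], ...]

    @property
    def identity(self) -> float:
        """Identical aligned columns / length of the shorter sequence."""
        matches = sum(
            1
            for i, j in self.pairs
            if i >= 0 and j >= 0 and self.a[i] == self.b[j]
        )
        return matches / min(len(self.a), len(self.b))

    def coverage(self) -> tuple[float, float]:
        """(cov_a, cov_b): aligned span of each sequence / its length."""
        aligned = [(i, j) for i, j in self.pairs if i >= 0 and j >= 0]
        if not aligned:
            return 0.0, 0.0
        a_pos = [i for i, _ in aligned]
        b_pos = [j for _, j in aligned]
        cov_a = (max(a_pos) - min(a_pos) + 1) / len(self.a)
        cov_b = (max(b_pos) - min(b_pos) + 1) / len(self.b)
        return cov_a, cov_b

    def ref_to_query(self) -> dict[int, str | None]:
        """Map 1-based positions of ``a`` to the aligned residue of ``b`` (None = gap)."""
        out: dict[int, str | None] = {}
        for i, j in self.pairs:
            if i >= 0:
                out[i + 1] = self.b[j] if j >= 0 else None
        return out


def _dp_matrix(a: np.ndarray, b: np.ndarray, match: float, mismatch: float,
               gap: float) -> np.ndarray:
    n, m = len(a), len(b)
    S = np.empty((n + 1, m + 1))
    S[0] = gap * np.arange(m + 1)
    idx = np.arange(m + 1)
    sub = np.where(a[:, None] == b[None, :], match, mismatch)
    for i in range(1, n + 1):
        # candidates from diagonal and vertical moves, for columns 1..m
        t = np.maximum(S[i - 1, :-1] + sub[i - 1], S[i - 1, 1:] + gap)
        c = np.concatenate(([i * gap], t))
        # fold in horizontal moves: S[i,j] = max_{k<=j} c[k] + gap*(j-k)
        S[i] = np.maximum.accumulate(c - gap * idx) + gap * idx
    return S


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                 gap: float = -1.0) -> Alignment:
    """Optimal global alignment; traceback prefers diagonal, then up, then left."""
    a = validate_protein(a, "first sequence")
    b = validate_protein(b, "second sequence")
    ca = np.frombuffer(a.encode(), dtype=np.uint8)
    cb = np.frombuffer(b.encode(), dtype=np.uint8)
    S = _dp_matrix(ca, cb, match, mismatch, gap)
    pairs: list[tuple[int, int]] = []
    i, j = len(a), len(b)
    eps = 1e-9
    while i > 0 or j > 0:
        here = S[i, j]
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if abs(here - (S[i - 1, j - 1] + sub)) < eps:
                i, j = i - 1, j - 1
                pairs.append((i, j))
                continue
        if i > 0 and abs(here - (S[i - 1, j] + gap)) < eps:
            i -= 1
            pairs.append((i, -1))
            continue
        j -= 1
        pairs.append((-1, j))
    pairs.reverse()
    return Alignment(a=a, b=b, score=float(S[len(a), len(b)]), pairs=tuple(pairs))


def pairwise_identity(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                      gap: float = -1.0) -> tuple[float, float, float]:
    """(identity, cov_a, cov_b) under the clustering alignment contract.

    Symmetric by construction: the pair is aligned in a canonical
    (lexicographic) order and the coverages swapped back, so exchanging the
    arguments exchanges cov_a/cov_b and leaves the identity unchanged even
    when co-optimal alignments exist.
    """
    if a <= b:
        aln = global_align(a, b, match=match, mismatch=mismatch, gap=gap)
        cov_a, cov_b = aln.coverage()
    else:
        aln = global_align(b, a, match=match, mismatch=mismatch, gap=gap)
        cov_b, cov_a = aln.coverage()
    return aln.identity, cov_a, cov_b
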