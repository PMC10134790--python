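"""Distance-based tree of cluster representatives.

Distances are 1 - pairwise identity; the tree is built with classical
neighbor joining (Saitou-Nei, with the Studier-Keppler O(n^3) update),
which recovers additive distance matrices exactly.  Determinism: Q-ties
are broken on the lexically smallest (label, label) pair, where an
internal node inherits the smaller of its children's labels.  Negative
branch lengths are clamped to zero with the deficit moved to the sister
branch, preserving the joined pair's path length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import pairwise_identity
from .errors import DegenerateInputError


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distances must be non-negative with zero diagonal")


def distance_matrix(representatives: dict[str, str]) -> DistanceMatrix:
    """All-vs-all 1 - identity distances between representative sequences."""
    if len(representatives) < 2:
        raise DegenerateInputError("need at least 2 sequences for distances")
    ids = tuple(sorted(representatives))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident, _, _ = pairwise_identity(representatives[ids[i]],
                                            representatives[ids[j]])
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(ids=ids, d=d)


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for child, _ in self.children for lf in child.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def newick(self, label_map: dict[str, str] | None = None) -> str:
        return self._nwk(label_map or {}) + ";"

    def _nwk(self, label_map: dict[str, str]) -> str:
        if self.is_leaf:
            return _quote_label(label_map.get(self.name, self.name or ""))
        inner = ",".join(f"{c._nwk(label_map)}:{ln:.10g}"
                         for c, ln in self.children)
        return f"({inner})"

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (keys are sorted name pairs)."""
        out: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = []
            for child, ln in node.children:
                depths = {k: v + ln for k, v in walk(child).items()}
                sub.append(depths)
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for a, da in sub[i].items():
                        for b, db in sub[j].items():
                            out[tuple(sorted((a, b)))] = da + db
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self)
        return out


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.-]+$")


def _quote_label(label: str) -> str:
    """Single-quote labels containing characters Newick readers reserve."""
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical NJ; returns a tree rooted at the final trifurcation."""
    n = len(dm.ids)
    if n < 3:
        raise DegenerateInputError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    labels = list(dm.ids)  # tie-break labels; internal = min of children
    D = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    la, lb = labels[active[a]], labels[active[b]]
                    key = (min(la, lb), max(la, lb))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = dij / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # reuse slot i for the merged node
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_d
        D[:, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = max(0.0, (dij + dik - djk) / 2)
    lj = max(0.0, (dij + djk - dik) / 2)
    lk = max(0.0, (dik + djk - dij) / 2)
    order = sorted([(labels[i], i, li), (labels[j], j, lj), (labels[k], k, lk)])
    return TreeNode(children=[(nodes[idx], ln) for _, idx, ln in order])


def write_annotated_newick(tree: TreeNode,
                           annotations: dict[str, dict] | None = None
                           ) -> tuple[str, pd.DataFrame]:
    """Newick string with annotation suffixes on leaf labels, plus sidecar table.

    Suffix format: ``id|sg=<subgroup_id>|class=<class_hint>|env=<environment>``
    (missing fields are omitted).  Annotations for unknown leaves are
    dropped with a warning, never an error.
    """
    import logging

    annotations = annotations or {}
    leaf_names = set(tree.leaf_names())
    for unknown in sorted(set(annotations) - leaf_names):
        logging.getLogger(__name__).warning(
            "annotation for unknown leaf %s ignored", unknown)
    label_map: dict[str, str] = {}
    rows = []
    for name in sorted(leaf_names):
        ann = annotations.get(name, {})
        parts = [name]
        if ann.get("subgroup_id") is not None:
            parts.append(f"sg={ann['subgroup_id']}")
        if ann.get("class_hint"):
            parts.append(f"class={ann['class_hint']}")
        if ann.get("environment_label"):
            parts.append(f"env={ann['environment_label']}")
        if len(parts) > 1:
            label_map[name] = "|".join(parts)
        rows.append({"leaf": name,
                     "subgroup_id": ann.get("subgroup_id", ""),
                     "class_hint": ann.get("class_hint", ""),
                     "environment_label": ann.get("environment_label", "")})
    sidecar = pd.DataFrame(rows, columns=["leaf", "subgroup_id", "class_hint",
                                          "environment_label"])
    return tree.newick(label_map), sidecar
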