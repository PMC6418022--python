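"""Distance matrices in index space and group-average (UPGMA) trees.

Sequences are points (v1, v2, v3) in index space; pairwise Euclidean
distances feed group-average agglomerative clustering: at each round the
pair of clusters with the smallest average inter-point distance is merged
at height = average/2, and distances to the merged cluster are updated as
size-weighted averages. The result is an ultrametric dendrogram — every
leaf sits at the same distance from the root, and the cophenetic distance
between two leaves is twice the height of their lowest common ancestor.

Ties on the minimal average distance are broken deterministically: each
cluster is keyed by its lexicographically smallest leaf label and the
smallest (key_a, key_b) pair wins, so label permutations of the input give
isomorphic trees.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValueError(f"distance matrix shape {v.shape} does not match {k} labels")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclasses.dataclass(frozen=True)
class Merge:
    """One agglomeration: clusters ``a`` and ``b`` joined at ``height``.

    Cluster ids follow the usual convention: leaves are 0..n−1 in label
    order; the i-th merge creates cluster n+i of size ``size``.
    """

    a: int
    b: int
    height: float
    size: int


@dataclasses.dataclass(frozen=True)
class Dendrogram:
    """An ultrametric merge tree over labelled leaves."""

    labels: tuple[str, ...]
    merges: tuple[Merge, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def cophenetic_matrix(self) -> DistanceMatrix:
        """coph(i, j) = 2 × height of the lowest common ancestor of i and j."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for k, m in enumerate(self.merges):
            left, right = members.pop(m.a), members.pop(m.b)
            for i in left:
                for j in right:
                    coph[i, j] = coph[j, i] = 2.0 * m.height
            members[n + k] = left + right
        return DistanceMatrix(labels=self.labels, values=coph)


def euclidean_distances(vectors: Sequence) -> DistanceMatrix:
    """Pairwise Euclidean distances between (v1, v2, v3) feature vectors.

    ``vectors`` are objects with ``id``, ``v1``, ``v2``, ``v3`` attributes
    (e.g. :class:`dnawalk.indices.FeatureVector`). Ids must be unique and
    all components finite.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 feature vectors")
    labels = [v.id for v in vectors]
    if len(set(labels)) != len(labels):
        dups = sorted({lab for i, lab in enumerate(labels) if lab in labels[:i]})
        raise ValueError(f"duplicate ids: {dups}")
    pts = np.array([[v.v1, v.v2, v.v3] for v in vectors], dtype=float)
    bad = ~np.isfinite(pts).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite index components for: {[labels[i] for i in np.nonzero(bad)[0]]}"
        )
    return DistanceMatrix(labels=tuple(labels), values=squareform(pdist(pts)))


def standardize_features(vectors: Sequence) -> np.ndarray:
    """Z-score each index across vectors; returns the standardized points."""
    pts = np.array([[v.v1, v.v2, v.v3] for v in vectors], dtype=float)
    sd = pts.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0  # constant column: leave centered at zero
    return (pts - pts.mean(axis=0)) / sd


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Group-average agglomerative clustering of a distance matrix."""
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 leaves")
    # active cluster id -> (tie-break key, size)
    key = {i: dm.labels[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.values[i, j])
    active = set(range(n))
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            ki, kj = sorted((key[i], key[j]))
            cand = (d, ki, kj, i, j)
            if best is None or cand < best:
                best = cand
        d, _, _, i, j = best
        new_size = size[i] + size[j]
        # children ordered by tie-break key for a canonical Newick layout
        a, b = (i, j) if key[i] <= key[j] else (j, i)
        merges.append(Merge(a=a, b=b, height=d / 2.0, size=new_size))
        # size-weighted average distance to every other active cluster
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (
                size[i] * dik + size[j] * djk
            ) / new_size
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        active -= {i, j}
        active.add(next_id)
        key[next_id] = min(key[i], key[j])
        size[next_id] = new_size
        next_id += 1
    return Dendrogram(labels=dm.labels, merges=tuple(merges))


def to_newick(tree: Dendrogram, precision: int = 6) -> str:
    """Serialize a dendrogram as Newick with branch lengths.

    A child's branch length is its parent's height minus its own height
    (leaves sit at height 0), so root-to-leaf path lengths all equal the
    root height — the ultrametric property in Newick form.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {}
    for i, lab in enumerate(tree.labels):
        node[i] = _escape_label(lab)
    for k, m in enumerate(tree.merges):
        for child in (m.a, m.b):
            bl = m.height - height[child]
            node[child] = f"{node[child]}:{bl:.{precision}g}"
        cid = n + k
        node[cid] = f"({node[m.a]},{node[m.b]})"
        height[cid] = m.height
    return node[n + len(tree.merges) - 1] + ";"


def _escape_label(label: str) -> str:
    if any(c in label for c in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_cophenetic_table(tree: Dendrogram, path) -> None:
    """Export the cophenetic matrix as a labelled TSV."""
    from pathlib import Path

    dm = tree.cophenetic_matrix()
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(dm.labels) + "\n")
        for lab, row in zip(dm.labels, dm.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
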