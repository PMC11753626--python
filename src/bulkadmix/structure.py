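"""Distance-based structure analysis: PCoA, neighbor joining, Ward clustering.

All three consume a symmetric zero-diagonal distance matrix (typically
the modified Rogers distance) with population IDs as labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "PCoAResult",
    "TreeNode",
    "pcoa",
    "neighbor_joining",
    "ward_linkage",
    "linkage_table",
    "cluster_labels",
    "newick",
    "write_newick",
    "tree_distance_matrix",
    "leaf_names",
]

_SYM_TOL = 1e-8


def _validate_distance(d: pd.DataFrame) -> np.ndarray:
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=_SYM_TOL):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=_SYM_TOL):
        raise ValueError("distance matrix must have a zero diagonal")
    return 0.5 * (arr + arr.T)


# ---------------------------------------------------------------------------
# Principal coordinate analysis (classical metric scaling)


@dataclass
class PCoAResult:
    """Classical-scaling result.

    ``coordinates`` holds one column per retained axis (positive
    eigenvalue), each column's squared norm equal to its eigenvalue;
    ``pct_variance`` is each eigenvalue as a percentage of the sum of
    positive eigenvalues. ``all_eigenvalues`` keeps the full spectrum
    (descending) so near-zero/negative tail mass can be inspected.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    all_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def pcoa(d: pd.DataFrame) -> PCoAResult:
    """Principal coordinate analysis by Gower double-centering.

    Eigendecomposes ``B = -1/2 J D^2 J`` (J the centering matrix) and
    scales eigenvectors by the square roots of their eigenvalues. Axes
    are ordered by descending eigenvalue; only positive eigenvalues
    produce coordinates and enter the percent-variance denominator (no
    Lingoes/Cailliez correction — the modified Rogers distance is
    Euclidean-embeddable). Each axis is oriented so that its
    largest-magnitude score is positive, for reproducible output.
    """
    arr = _validate_distance(d)
    n = arr.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (arr**2) @ j
    eigvals, eigvecs = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-12 if n else 0.0
    pos = eigvals > tol
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    # deterministic sign: largest-|score| entry positive per axis
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] *= -1
    pct = lam / lam.sum() * 100.0 if lam.size else lam
    axes = [f"Axis{k + 1}" for k in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=axes),
        eigenvalues=lam,
        pct_variance=pct,
        all_eigenvalues=eigvals,
    )


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def leaf_names(tree: TreeNode) -> list[str]:
    if tree.is_leaf:
        return [tree.name]
    out: list[str] = []
    for c in tree.children:
        out.extend(leaf_names(c))
    return out


def neighbor_joining(d: pd.DataFrame) -> TreeNode:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Exact on additive matrices. Deterministic given the input ordering:
    Q-ties are broken by the lexicographically smallest row-index pair.
    Negative branch lengths are clamped to zero with the deficit moved
    to the sibling branch, preserving the pair's total length. The
    result is unrooted, represented with a trifurcating root (a single
    bifurcation for two leaves).
    """
    arr = _validate_distance(d)
    labels = [str(x) for x in d.index]
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 populations")
    nodes = [TreeNode(name=lab) for lab in labels]
    if n == 2:
        half = arr[0, 1] / 2.0
        nodes[0].length = nodes[1].length = half
        return TreeNode(children=nodes)

    D = arr.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major: first minimum is the smallest (i, j) pair
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        nodes[i].length, nodes[j].length = li, lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # three remaining nodes joined at the trifurcating root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = max(0.0, (d01 + d02 - d12) / 2.0)
    nodes[1].length = max(0.0, (d01 + d12 - d02) / 2.0)
    nodes[2].length = max(0.0, (d02 + d12 - d01) / 2.0)
    return TreeNode(children=nodes)


def tree_distance_matrix(tree: TreeNode, labels: list[str] | None = None) -> pd.DataFrame:
    """Leaf-to-leaf path-length distances of a tree (additivity check)."""
    dists: dict[tuple[str, str], float] = {}

    def down(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        maps = []
        for c in down_children(node):
            maps.append(c)
        merged: dict[str, float] = {}
        for a in range(len(maps)):
            for b in range(a + 1, len(maps)):
                for la, da in maps[a].items():
                    for lb, db in maps[b].items():
                        key = (la, lb) if la <= lb else (lb, la)
                        dists[key] = da + db
            merged.update(maps[a])
        merged.update(maps[-1])
        return merged

    def down_children(node: TreeNode) -> list[dict[str, float]]:
        return [{k: v + c.length for k, v in down(c).items()} for c in node.children]

    down(tree)
    if labels is None:
        labels = sorted(leaf_names(tree))
    n = len(labels)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            la, lb = labels[a], labels[b]
            key = (la, lb) if la <= lb else (lb, la)
            out[a, b] = out[b, a] = dists[key]
    return pd.DataFrame(out, index=labels, columns=labels)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,']")


def _quote(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick with branch lengths."""
    names = leaf_names(tree)
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels; Newick output would be ambiguous")

    def render(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            body = _quote(node.name)
        else:
            body = "(" + ",".join(render(c, True) for c in node.children) + ")"
        return f"{body}:{node.length:.12g}" if with_length else body

    return render(tree, False) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Ward hierarchical clustering


def ward_linkage(d: pd.DataFrame) -> np.ndarray:
    """Ward's minimum-variance agglomeration of a distance matrix.

    Lance–Williams recursion on squared distances (the hclust "ward.D2"
    convention); merge heights are non-decreasing. Returns the standard
    4-column linkage record (child1, child2, height, size).
    """
    arr = _validate_distance(d)
    if arr.shape[0] < 2:
        raise ValueError("ward clustering needs at least 2 populations")
    return linkage(squareform(arr, checks=False), method="ward")


def linkage_table(z: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """Linkage record as a table; leaf indices are replaced by labels."""
    n = z.shape[0] + 1

    def name(idx: float) -> str:
        i = int(idx)
        if labels is not None and i < n:
            return str(labels[i])
        return str(i)

    return pd.DataFrame(
        {
            "child1": [name(r[0]) for r in z],
            "child2": [name(r[1]) for r in z],
            "height": z[:, 2],
            "size": z[:, 3].astype(int),
        }
    )


def cluster_labels(z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster assignment cutting the dendrogram into k groups."""
    return fcluster(z, t=k, criterion="maxclust")
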