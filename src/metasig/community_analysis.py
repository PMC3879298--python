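"""Clustering, tree comparison, ordination and gradient correlation.

The evaluation framework for a panel of samples: UPGMA average-linkage
clustering of a dissimilarity matrix into an ultrametric rooted tree,
symmetric-difference comparison of trees (branch lengths ignored), classical
principal coordinates analysis with a first-axis goodness of fit, and
Spearman rank correlation between the first principal coordinate and an
external gradient covariate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import TreeNode

from .dissimilarity import DissimilarityMatrix
from .errors import (
    DegenerateSampleError,
    FormatError,
    LabelError,
    ParameterError,
    UndefinedCorrelationError,
)


@dataclass
class Dendrogram:
    """A rooted tree with labelled leaves; UPGMA output is ultrametric."""

    root: TreeNode

    def leaf_names(self) -> frozenset[str]:
        return frozenset(tip.name for tip in self.root.tips())

    def clusters(self) -> set[frozenset[str]]:
        """Nontrivial clusters: leaf sets of internal nodes, excluding
        singletons and the full leaf set."""
        all_leaves = self.leaf_names()
        out: set[frozenset[str]] = set()
        for node in self.root.non_tips(include_self=False):
            members = frozenset(tip.name for tip in node.tips())
            if 1 < len(members) < len(all_leaves):
                out.add(members)
        return out

    def splits(self) -> set[frozenset[str]]:
        """Nontrivial unrooted bipartitions, each normalised to the side not
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.root.non_tips(include_self=False):
            side = frozenset(tip.name for tip in node.tips())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def leaf_heights(self) -> dict[str, float]:
        """Root-to-leaf path lengths (missing branch lengths count as 0)."""
        heights: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            acc += node.length or 0.0
            if node.is_tip():
                heights[node.name] = acc
            else:
                for child in node.children:
                    walk(child, acc)

        walk(self.root, -(self.root.length or 0.0))
        return heights


def upgma(dm: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage hierarchical clustering of a dissimilarity matrix.

    At each step the closest cluster pair merges at height = distance / 2;
    the distance between clusters is the mean over all cross pairs. Ties are
    broken deterministically by the lexicographically smallest pair of
    cluster representative labels (the minimum original label per cluster).
    """
    if not dm.valid or np.isnan(dm.values).any():
        raise ParameterError(
            f"cannot cluster an NA matrix ({dm.measure}, k={dm.k}, order={dm.order})"
        )
    labels = list(dm.labels)
    n = len(labels)
    # cluster id -> (TreeNode, height, size, representative label)
    nodes = {i: TreeNode(name=labels[i]) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.values[i, j])
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                key = (dist[(i, j)], tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = (best[0], best[1], best[2])
        d_ij = dist[(i, j)]
        h = d_ij / 2.0
        if reps[j] < reps[i]:  # deterministic child order, input-order invariant
            i, j = j, i
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = h - heights[i]
        child_j.length = h - heights[j]
        parent = TreeNode(children=[child_i, child_j])
        nodes[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        reps[next_id] = min(reps[i], reps[j])
        active.discard(i)
        active.discard(j)
        for m in active:
            a, b = (min(i, m), max(i, m)), (min(j, m), max(j, m))
            d_new = (sizes[i] * dist[a] + sizes[j] * dist[b]) / (sizes[i] + sizes[j])
            dist[(min(m, next_id), max(m, next_id))] = d_new
        active.add(next_id)
        next_id += 1
    root = nodes[next_id - 1]
    root.length = None
    return Dendrogram(root=root)


def _needs_quotes(name: str) -> bool:
    return any(c in name for c in "(),:;'\" \t[]")


def to_newick(t: Dendrogram) -> str:
    """Serialise a tree to Newick (branch lengths included where present)."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
            if _needs_quotes(label):
                label = "'" + label.replace("'", "''") + "'"
            s = label
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if node.length is not None:
            s += f":{node.length:.12g}"
        return s

    return fmt(t.root) + ";"


def from_newick(text: str) -> Dendrogram:
    """Parse Newick text; multifurcations and absent branch lengths allowed."""
    try:
        root = TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc
    return Dendrogram(root=root)


def symmetric_difference(
    t1: Dendrogram, t2: Dendrogram, mode: str = "clusters"
) -> int:
    """Number of nontrivial clusters (or splits) present in exactly one tree.

    ``mode="clusters"`` treats each tree as the set of its nontrivial rooted
    clusters (each internal node denoted by its clustered leaves, singletons
    and the full set excluded); ``mode="splits"`` uses unrooted bipartitions.
    Branch lengths are ignored; the leaf sets must match.
    """
    l1, l2 = t1.leaf_names(), t2.leaf_names()
    if l1 != l2:
        raise LabelError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    if mode == "clusters":
        a, b = t1.clusters(), t2.clusters()
    elif mode == "splits":
        a, b = t1.splits(), t2.splits()
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return len(a ^ b)


@dataclass
class OrdinationResult:
    """PCoA output: eigenvalues (descending), coordinates, first-axis GOF."""

    labels: list[str]
    eigenvalues: np.ndarray  # all eigenvalues, descending, negatives included
    coordinates: np.ndarray  # n_samples x n_positive_axes, scaled by sqrt(eig)
    gof: float  # first-axis goodness of fit


def pcoa(dm: DissimilarityMatrix, gof_denominator: str = "positive") -> OrdinationResult:
    """Classical multidimensional scaling of a dissimilarity matrix.

    Double-centers -1/2 D^2, eigendecomposes, and scales eigenvectors of
    positive eigenvalues by sqrt(eigenvalue). Negative eigenvalues (a
    non-Euclidean matrix) are reported, not corrected. The first-axis GOF is
    lambda_1 / sum(max(lambda_i, 0)); ``gof_denominator="absolute"`` uses
    sum |lambda_i| instead.
    """
    if not dm.valid or np.isnan(dm.values).any():
        raise ParameterError("cannot ordinate an NA matrix")
    d = dm.values
    n = d.shape[0]
    if np.allclose(d, 0):
        raise DegenerateSampleError("all-zero dissimilarity matrix")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if gof_denominator == "positive":
        denom = float(np.clip(eigvals, 0, None).sum())
    elif gof_denominator == "absolute":
        denom = float(np.abs(eigvals).sum())
    else:
        raise ParameterError(f"unknown gof_denominator {gof_denominator!r}")
    gof = float(max(eigvals[0], 0.0) / denom) if denom > 0 else 0.0
    return OrdinationResult(
        labels=list(dm.labels), eigenvalues=eigvals, coordinates=coords, gof=gof
    )


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (ties get mean ranks); in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError(f"shape mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ParameterError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant vector has no rank correlation")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class GradientReport:
    """First-axis GOF and |SRCC| of axis 1 against an external covariate."""

    gof: float
    srcc_abs: float
    ordination: OrdinationResult


def gradient_report(
    dm: DissimilarityMatrix, covariate: np.ndarray
) -> GradientReport:
    """PCoA the matrix and correlate axis 1 with the covariate.

    The absolute SRCC is reported because the orientation of a principal
    coordinate axis is arbitrary.
    """
    covariate = np.asarray(covariate, dtype=float)
    if len(covariate) != len(dm.labels):
        raise LabelError(
            f"covariate length {len(covariate)} != {len(dm.labels)} samples"
        )
    ord_res = pcoa(dm)
    rho = spearman(ord_res.coordinates[:, 0], covariate)
    return GradientReport(gof=ord_res.gof, srcc_abs=abs(rho), ordination=ord_res)
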