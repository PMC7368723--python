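"""Nei genetic distance, UPGMA dendrogram with locus bootstrap, tree cut, PCoA.

The default distance is Nei's D_A (the 1983 frequency distance): per
individual and locus the within-individual allele frequencies are (1, 0),
(0.5, 0.5) or (0, 1) for dosages 0/1/2, and

    D_A(x, y) = 1 - (1/L_xy) * sum_{loci shared} sum_{alleles} sqrt(x_a y_a)

with L_xy the number of loci non-missing in both individuals
(pairwise-complete renormalisation, no imputation).  The sum over alleles
of sqrt-products is a dot product of per-locus sqrt-frequency vectors, so
the whole matrix is a single matrix product.  Nei's 1972 standard distance
is available as an alternative variant.

UPGMA merges the pair of clusters with the smallest average distance; the
merge height is half that average so leaf-to-leaf path heights reproduce
the distances (ultrametric convention).  Ties are broken by the
lexicographically smallest pair of cluster representative labels so runs
are bit-reproducible.  Bootstrap supports resample loci (columns) with
replacement; the support of a clade of the point-estimate tree is the
fraction of replicate trees containing that clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair shared-locus counts."""

    labels: list[str]
    values: np.ndarray
    pair_loci: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{lab}  {row}\n")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def _sqrt_freq_embedding(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual sqrt allele-frequency vectors (n, 2L) and observed mask."""
    n, m = calls.shape
    obs = calls != MISSING
    s = np.zeros((n, 2 * m))
    ref = np.select(
        [calls == 0, calls == 1, calls == 2], [1.0, np.sqrt(0.5), 0.0], default=0.0
    )
    alt = np.select(
        [calls == 0, calls == 1, calls == 2], [0.0, np.sqrt(0.5), 1.0], default=0.0
    )
    s[:, 0::2] = ref
    s[:, 1::2] = alt
    return s, obs


def _nei_da_from_calls(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s, obs = _sqrt_freq_embedding(calls)
    shared = obs.astype(float) @ obs.T.astype(float)
    sim = s @ s.T
    off = ~np.eye(len(calls), dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(f"individuals {i} and {j} share no genotyped loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - sim / np.maximum(shared, 1.0)
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T), shared


def nei_distance(g: GenotypeMatrix, variant: str = "da") -> DistanceMatrix:
    """Pairwise Nei genetic distance between individuals.

    variant="da" gives the bounded D_A frequency distance (default);
    variant="nei1972" gives Nei's standard distance -ln(I), unbounded.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    if variant == "da":
        d, shared = _nei_da_from_calls(g.calls)
    elif variant == "nei1972":
        d, shared = _nei1972_from_calls(g.calls)
    else:
        raise ValueError(f"unknown distance variant: {variant!r}")
    return DistanceMatrix(labels=list(g.individual_ids), values=d, pair_loci=shared)


def _nei1972_from_calls(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, m = calls.shape
    obs = (calls != MISSING).astype(float)
    x = np.zeros((n, 2 * m))
    ref = np.select([calls == 0, calls == 1, calls == 2], [1.0, 0.5, 0.0], default=0.0)
    alt = np.select([calls == 0, calls == 1, calls == 2], [0.0, 0.5, 1.0], default=0.0)
    x[:, 0::2] = ref
    x[:, 1::2] = alt
    shared = obs @ obs.T
    off = ~np.eye(n, dtype=bool)
    if (shared[off] == 0).any():
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(f"individuals {i} and {j} share no genotyped loci")
    jxy = x @ x.T  # sum over shared loci of sum_a x_a y_a
    jself = ref**2 + alt**2  # per locus sum of squared own frequencies
    jx = jself @ obs.T  # J_x restricted to loci shared with y
    ident = jxy / np.sqrt(jx * jx.T)
    ident = np.clip(ident, 1e-12, 1.0)
    d = -np.log(ident)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T), shared


# ------------------------------------------------------------------ UPGMA


@dataclass
class TreeNode:
    height: float
    children: list["TreeNode"] = field(default_factory=list)
    label: str | None = None  # leaf label
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return frozenset(out)


@dataclass
class Dendrogram:
    """Rooted binary ultrametric merge tree."""

    labels: list[str]
    root: TreeNode
    #: merge history in execution order: (height, leafset of the new cluster)
    merges: list[tuple[float, frozenset[str]]]

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def clades(self) -> set[frozenset[str]]:
        """Leafsets of all internal nodes (the root clade included)."""
        return {n.leaves() for n in self.internal_nodes()}

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k groups by undoing the k-1 highest (latest) merges.

        Groups are numbered 1..k by first appearance in the input label
        order.  A tie in merge height across the cut boundary is resolved
        by merge order and logged as a warning.
        """
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}")
        kept = self.merges[: n - k]
        if 0 < n - k < len(self.merges):
            if np.isclose(self.merges[n - k][0], kept[-1][0] if kept else np.nan):
                warnings.warn(
                    "tied merge heights at the cut; resolved by merge order",
                    stacklevel=2,
                )
        clusters: dict[str, set[str]] = {lab: {lab} for lab in self.labels}
        member: dict[str, str] = {lab: lab for lab in self.labels}
        for _, leafset in kept:
            parts = {member[l] for l in leafset}
            merged: set[str] = set()
            for p in parts:
                merged |= clusters.pop(p)
            rep = min(merged)
            clusters[rep] = merged
            for l in merged:
                member[l] = rep
        groups: dict[str, int] = {}
        next_id = 1
        for lab in self.labels:
            rep = member[lab]
            if rep not in groups:
                groups[rep] = next_id
                next_id += 1
        return {lab: groups[member[lab]] for lab in self.labels}

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, parent_height: float | None) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                sup = (
                    f"{node.support:.3f}"
                    if (with_support and node.support is not None)
                    else ""
                )
                s = f"({inner}){sup}"
            if parent_height is None:
                return s
            return f"{s}:{parent_height - node.height:.6f}"

        return fmt(self.root, None) + ";"


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie rule."""
    if not np.isfinite(d.values).all():
        raise ValueError("distance matrix contains non-finite entries")
    n = d.n
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(height=0.0, label=lab) for lab in d.labels
    }
    sizes: dict[str, int] = {lab: 1 for lab in d.labels}
    # representative label of a cluster = its smallest leaf label
    dist: dict[tuple[str, str], float] = {}
    labs = list(d.labels)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((labs[i], labs[j]))
            dist[(a, b)] = d.values[i, j]
    active = sorted(nodes)
    merges: list[tuple[float, frozenset[str]]] = []
    while len(active) > 1:
        best = min(
            ((dist[tuple(sorted((a, b)))], tuple(sorted((a, b))))
             for idx, a in enumerate(active) for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        dmin, (a, b) = best
        height = dmin / 2.0
        new = TreeNode(height=height, children=[nodes[a], nodes[b]])
        rep = min(a, b)
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            da = dist[tuple(sorted((a, c)))]
            db = dist[tuple(sorted((b, c)))]
            dnew = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            dist[tuple(sorted((rep, c)))] = dnew
        sizes[rep] = sizes[a] + sizes[b]
        nodes[rep] = new
        active.remove(other)
        del nodes[other]
        merges.append((height, new.leaves()))
    root = nodes[active[0]]
    return Dendrogram(labels=list(d.labels), root=root, merges=merges)


def cut_tree(t: Dendrogram, k: int) -> dict[str, int]:
    return t.cut(k)


def bootstrap_support(
    g: GenotypeMatrix, n_boot: int = 1000, seed: int | None = None
) -> Dendrogram:
    """UPGMA tree with clade supports from locus (column) bootstrap."""
    if g.n_individuals < 3:
        raise ValueError("bootstrap supports need at least three individuals")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = upgma(nei_distance(g))
    counts = {clade: 0 for clade in point.clades()}
    rng = np.random.default_rng(seed)
    m = g.n_markers
    labels = list(g.individual_ids)
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        dvals, _ = _nei_da_from_calls(g.calls[:, cols])
        rep_tree = upgma(DistanceMatrix(labels=labels, values=dvals))
        for clade in rep_tree.clades():
            if clade in counts:
                counts[clade] += 1
    all_leaves = frozenset(labels)
    for node in point.internal_nodes():
        leafset = node.leaves()
        node.support = 1.0 if leafset == all_leaves else counts[leafset] / n_boot
    return point


# -------------------------------------------------------------------- PCoA


@dataclass
class Ordination:
    """Principal-coordinate embedding of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray  # individuals x retained positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, % of positive total

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical (Gower) scaling of a distance matrix.

    Negative eigenvalues (from non-Euclidean distances) are reported but
    their axes are dropped without correction.
    """
    n = d.n
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0]))
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    pos_total = evals[pos].sum()
    prop = 100.0 * evals[:n_axes] / pos_total if pos_total > 0 else np.zeros(n_axes)
    return Ordination(
        labels=list(d.labels),
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=prop,
    )
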