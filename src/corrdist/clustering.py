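"""Clustering of items from a precomputed distance matrix.

Two clusterers operate directly on a :class:`~corrdist.distances.DistanceMatrix`:

* agglomerative hierarchical clustering with single, complete, or average
  (UPGMA) linkage, delegated to :func:`scipy.cluster.hierarchy.linkage`;
* PAM (partitioning around medoids), the classical BUILD + SWAP k-medoids
  of Kaufman & Rousseeuw, implemented here because it needs nothing beyond
  the distance matrix itself.

A useful structural fact exploited by the tests: single and complete
linkage only ever *select* existing distance values (min/max), so any
strictly increasing transform of the distances -- such as d_a -> d_r =
sqrt(d_a) -- yields a topologically identical dendrogram with transformed
heights.  Average linkage creates new values (means), so the transform can
reorder merges and change the topology.

The number of clusters is selected by the Calinski-Harabasz index
CH = (SS_B / SS_W) * ((N - k) / (k - 1)), computed on the original profile
vectors in Euclidean space; the peak over a candidate range is chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage

from .distances import DistanceMatrix
from .errors import CorrdistError, ValidationError

__all__ = [
    "Partition",
    "Dendrogram",
    "MedoidResult",
    "CHSelection",
    "hierarchical",
    "cut",
    "pam",
    "ch_index",
    "select_k",
]

LINKAGES = ("single", "complete", "average")


@dataclass
class Partition:
    """A flat clustering: item identifier -> cluster label."""

    assignment: dict[str, int]

    def __post_init__(self):
        self.assignment = {str(i): int(c) for i, c in self.assignment.items()}
        if not self.assignment:
            raise ValidationError("empty partition")

    @property
    def items(self) -> list[str]:
        return list(self.assignment)

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, items) -> np.ndarray:
        try:
            return np.array([self.assignment[str(i)] for i in items])
        except KeyError as e:
            raise ValidationError(f"item {e.args[0]!r} missing from partition") from None

    def classes(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for item, label in self.assignment.items():
            out.setdefault(label, set()).add(item)
        return out

    def canonicalize(self) -> "Partition":
        """Relabel clusters 0..k-1 in order of first appearance."""
        remap: dict[int, int] = {}
        for label in self.assignment.values():
            if label not in remap:
                remap[label] = len(remap)
        return Partition({i: remap[c] for i, c in self.assignment.items()})

    @classmethod
    def from_labels(cls, items, labels) -> "Partition":
        return cls(dict(zip(map(str, items), labels)))

    def write(self, path):
        pd.DataFrame(
            {"item": list(self.assignment), "label": list(self.assignment.values())}
        ).to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "Partition":
        df = pd.read_csv(path)
        return cls.from_labels(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int))


@dataclass
class Dendrogram:
    """An agglomerative merge tree over the items of a distance matrix.

    ``merges`` lists (left, right, height, new_id) in merge order; leaves
    are numbered 0..n-1 in item order, internal nodes n..2n-2 as in scipy's
    linkage encoding.
    """

    leaves: list[str]
    linkage_matrix: np.ndarray = field(repr=False)
    method: str = "average"

    def __post_init__(self):
        n = len(self.leaves)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValidationError("linkage matrix must have n - 1 rows")

    @property
    def n(self) -> int:
        return len(self.leaves)

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(l), int(r), float(h), self.n + step)
            for step, (l, r, h, _) in enumerate(self.linkage_matrix)
        ]

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def clades(self) -> set[frozenset]:
        """Leaf-label sets of all internal nodes; the dendrogram topology."""
        members: dict[int, frozenset] = {i: frozenset([name]) for i, name in enumerate(self.leaves)}
        out: set[frozenset] = set()
        for left, right, _, new_id in self.merges:
            clade = members[left] | members[right]
            members[new_id] = clade
            out.add(clade)
        return out

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["left", "right", "height", "new_id"])

    def to_newick(self) -> str:
        """Nested-parenthesis form with branch lengths (parent - child height)."""
        height: dict[int, float] = {i: 0.0 for i in range(self.n)}
        text: dict[int, str] = {i: name for i, name in enumerate(self.leaves)}
        for left, right, h, new_id in self.merges:
            height[new_id] = h
            text[new_id] = (
                f"({text[left]}:{h - height[left]:g},{text[right]}:{h - height[right]:g})"
            )
        return text[2 * self.n - 2] + ";"


def hierarchical(d: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    ``average`` is UPGMA: the distance between two clusters is the
    unweighted arithmetic mean of all cross-pair distances.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    d.validate()
    if d.n < 2:
        raise ValidationError("need at least 2 items")
    Z = scipy_linkage(d.condensed(), method=linkage)
    return Dendrogram(leaves=list(d.items), linkage_matrix=Z, method=linkage)


def cut(dend: Dendrogram, k: int) -> Partition:
    """Flatten a dendrogram into exactly k clusters by undoing the last k-1 merges."""
    if not 1 <= k <= dend.n:
        raise ValidationError(f"k={k} out of range 1..{dend.n}")
    labels = cut_tree(dend.linkage_matrix, n_clusters=k).ravel()
    return Partition.from_labels(dend.leaves, labels).canonicalize()


def _pam_cost(M: np.ndarray, medoids: list[int]) -> float:
    return float(M[:, medoids].min(axis=1).sum())


@dataclass
class MedoidResult:
    """PAM output: the partition, the medoid of each cluster, and the cost."""

    partition: Partition
    medoids: list[str]
    total_cost: float


def _pam_swap(M: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest-descent single exchanges until a local optimum."""
    k, n = len(medoids), M.shape[0]
    medoids = list(medoids)
    cost = _pam_cost(M, medoids)
    while True:
        best = None  # (new_cost, medoid_pos, candidate)
        in_set = set(medoids)
        for pos in range(k):
            trial = list(medoids)
            for h in range(n):
                if h in in_set:
                    continue
                trial[pos] = h
                c = _pam_cost(M, trial)
                if c < cost - 1e-12 and (best is None or c < best[0] - 1e-12):
                    best = (c, pos, h)
            trial[pos] = medoids[pos]
        if best is None:
            return medoids, cost
        cost, pos, h = best
        medoids[pos] = h


def pam(
    d: DistanceMatrix, k: int, seed: int | None = None, n_restarts: int = 0
) -> MedoidResult:
    """Partitioning around medoids on a precomputed distance matrix.

    BUILD greedily picks the k medoids with the largest cost reduction;
    SWAP then exchanges a medoid with a non-medoid as long as some exchange
    strictly lowers the total distance of items to their nearest medoid.
    Ties are broken toward the lowest item index, so the default result is
    deterministic.

    SWAP is a single-exchange descent and can stop in a local optimum even
    on small instances.  ``n_restarts`` extra seeded random initializations
    (each refined by SWAP, best result kept, off by default) make reaching
    the global optimum overwhelmingly likely on small problems; ``seed``
    only feeds these restarts.
    """
    d.validate()
    M, n = d.values, d.n
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    if k == n:
        part = Partition.from_labels(d.items, range(n))
        return MedoidResult(part, list(d.items), 0.0)

    # BUILD: first medoid minimizes total distance; then greedy additions.
    medoids = [int(np.argmin(M.sum(axis=0)))]
    while len(medoids) < k:
        dnear = M[:, medoids].min(axis=1)
        gains = np.maximum(0.0, dnear[:, None] - M).sum(axis=0)  # gain of adding c
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    medoids, cost = _pam_swap(M, medoids)
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            cand, c = _pam_swap(M, list(rng.choice(n, size=k, replace=False)))
            if c < cost - 1e-12:
                medoids, cost = cand, c

    medoids = sorted(medoids)
    labels = np.argmin(M[:, medoids], axis=1)  # nearest medoid; first wins ties
    labels[medoids] = np.arange(k)  # each medoid belongs to its own cluster
    part = Partition.from_labels(d.items, labels).canonicalize()
    return MedoidResult(part, [d.items[m] for m in medoids], _pam_cost(M, medoids))


def ch_index(matrix, p: Partition) -> float:
    """Calinski-Harabasz index of a partition of profile vectors.

    ``(SS_B / SS_W) * ((N - k) / (k - 1))`` with SS_W the pooled
    within-cluster sum of squared Euclidean deviations from cluster
    centroids and SS_B the between-cluster sum of squared centroid
    deviations, weighted by cluster size.  Computed on the profile vectors
    themselves, not on the correlation distances.
    """
    if isinstance(matrix, pd.DataFrame):
        items, X = [str(i) for i in matrix.index], matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        items = [str(i) for i in range(X.shape[0])]
    if X.ndim == 1:
        X = X[:, None]
    labels = p.labels_for(items)
    N, k = X.shape[0], len(set(labels.tolist()))
    if k < 2 or k >= N:
        raise ValidationError(f"CH index needs 2 <= k <= N - 1, got k={k}, N={N}")
    grand = X.mean(axis=0)
    ss_w = 0.0
    ss_b = 0.0
    for label in set(labels.tolist()):
        members = X[labels == label]
        centroid = members.mean(axis=0)
        ss_w += float(((members - centroid) ** 2).sum())
        ss_b += members.shape[0] * float(((centroid - grand) ** 2).sum())
    if ss_w == 0.0:
        raise CorrdistError("degenerate clustering: zero within-cluster variance")
    return (ss_b / ss_w) * ((N - k) / (k - 1))


@dataclass
class CHSelection:
    """CH index per candidate k, and the k at the peak."""

    candidate_ks: list[int]
    ch_values: list[float]
    chosen_k: int

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.candidate_ks, "ch": self.ch_values})


def select_k(
    matrix,
    d: DistanceMatrix,
    method: str = "hierarchical",
    k_range=range(2, 11),
    linkage: str = "average",
    seed: int | None = None,
) -> CHSelection:
    """Choose the number of clusters by the peak of the CH curve.

    Clusters the distance matrix at every k in ``k_range``, scores each
    partition with :func:`ch_index` on the profile vectors, and picks the
    argmax.  The full curve is returned so a user can instead look for an
    abrupt elbow.  A k whose partition is degenerate (zero within-cluster
    variance) is skipped with a warning.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValidationError("empty k_range")
    if method not in ("hierarchical", "pam"):
        raise ValidationError(f"unknown method {method!r}")
    dend = hierarchical(d, linkage=linkage) if method == "hierarchical" else None
    kept, values = [], []
    for k in ks:
        part = cut(dend, k) if dend is not None else pam(d, k, seed=seed).partition
        try:
            values.append(ch_index(matrix, part))
        except CorrdistError as e:
            warnings.warn(f"k={k} skipped: {e}")
            continue
        kept.append(k)
    if not kept:
        raise CorrdistError("no candidate k produced a scoreable partition")
    chosen = kept[int(np.argmax(values))]
    return CHSelection(candidate_ks=kept, ch_values=values, chosen_k=chosen)
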