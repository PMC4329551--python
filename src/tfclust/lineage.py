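"""Cell-type lineage inference from binary region presence.

Builds the presence matrix (cell types x reference elements), Euclidean
distances between cell types, a single-linkage ("nearest-neighbour")
dendrogram, Hungarian placement of precursor cell types onto internal
nodes, classical PCoA, column-bootstrap branch support, the
leave-category-out sensitivity ensemble, and the dendrogram-comparison
statistics Baker's Gamma and the Fowlkes-Mallows B_k curve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .genomic_io import GenomicInterval

__all__ = [
    "PresenceMatrix",
    "Dendrogram",
    "PrecursorAssignment",
    "BkCurve",
    "GammaResult",
    "presence_matrix",
    "distance_matrix",
    "cluster_nearest_neighbour",
    "place_precursors",
    "pcoa",
    "bootstrap_branch_support",
    "leave_category_out_ensemble",
    "bakers_gamma",
    "fowlkes_mallows_bk",
    "lineage_restricted_regions",
    "rf_distance",
]


@dataclass
class PresenceMatrix:
    """Binary cell-type x reference-element matrix."""

    cells: list[str]
    elements: list[GenomicInterval]
    matrix: np.ndarray  # shape (n_cells, n_elements), dtype uint8

    def row(self, cell: str) -> np.ndarray:
        return self.matrix[self.cells.index(cell)]


def presence_matrix(
    cell_region_sets: dict[str, list[GenomicInterval]],
    reference: list[GenomicInterval],
) -> PresenceMatrix:
    """Entry (cell, element) = 1 iff >= 1 of the cell's windows is fully
    contained in the element (100% containment, not partial overlap)."""
    if not reference:
        raise ValueError("empty reference element list")
    reference = sorted(reference)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    tmp: dict[str, tuple[list[int], list[int], list[int]]] = {}
    for idx, iv in enumerate(reference):
        lists = tmp.setdefault(iv.chrom, ([], [], []))
        lists[0].append(iv.start)
        lists[1].append(iv.end)
        lists[2].append(idx)
    by_chrom = {
        c: (np.array(s), np.array(e), np.array(i)) for c, (s, e, i) in tmp.items()
    }
    cells = sorted(cell_region_sets)
    mat = np.zeros((len(cells), len(reference)), dtype=np.uint8)
    for ci, cell in enumerate(cells):
        for w in cell_region_sets[cell]:
            if w.chrom not in by_chrom:
                continue
            starts, ends, idxs = by_chrom[w.chrom]
            j = int(np.searchsorted(starts, w.start, side="right")) - 1
            if j >= 0 and ends[j] >= w.end:
                mat[ci, idxs[j]] = 1
    return PresenceMatrix(cells, reference, mat)


def distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between rows (sqrt of Hamming distance
    for binary rows)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    return squareform(pdist(matrix, metric="euclidean"))


# ---------------------------------------------------------------------------
# dendrogram

@dataclass
class Dendrogram:
    """Agglomerative merge tree over named leaves.

    ``merges[t]`` records the two clusters (as frozensets of leaf indices)
    joined at step t and the linkage height; heights are non-decreasing.
    """

    leaves: list[str]
    merges: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.leaves)

    def clades(self) -> list[frozenset]:
        """Leaf-index sets created by each merge (last one is the root)."""
        return [a | b for a, b, _ in self.merges]

    def bipartitions(self) -> set[frozenset]:
        """Root-agnostic non-trivial splits as frozensets of two name-sets."""
        all_names = frozenset(self.leaves)
        out = set()
        for clade in self.clades():
            names = frozenset(self.leaves[i] for i in clade)
            other = all_names - names
            if len(names) >= 2 and len(other) >= 2:
                out.add(frozenset((names, other)))
        return out

    def cut(self, k: int) -> np.ndarray:
        """Cluster labels (0..k-1) after cutting the tree into k clusters."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k must be in [1, {self.n}]")
        parent = list(range(self.n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b, _ in self.merges[: self.n - k]:
            ra, rb = find(min(a)), find(min(b))
            parent[max(ra, rb)] = min(ra, rb)
        roots = {}
        labels = np.empty(self.n, dtype=np.int64)
        for i in range(self.n):
            r = find(i)
            labels[i] = roots.setdefault(r, len(roots))
        return labels

    def merge_stages(self) -> np.ndarray:
        """n x n matrix of the cluster count k at which each leaf pair first
        co-clusters (n-1 for the first merge, 1 for the root)."""
        n = self.n
        stages = np.zeros((n, n), dtype=np.int64)
        for t, (a, b, _) in enumerate(self.merges):
            k = n - t - 1
            for i in a:
                for j in b:
                    stages[i, j] = stages[j, i] = k
        return stages

    def to_newick(self, support: dict[frozenset, float] | None = None) -> str:
        """Newick string with merge heights as node heights; optional branch
        support labels keyed by clade name-sets."""
        node_str: dict[frozenset, str] = {
            frozenset((i,)): self.leaves[i] for i in range(self.n)
        }
        node_height: dict[frozenset, float] = {
            frozenset((i,)): 0.0 for i in range(self.n)
        }
        key = None
        for a, b, h in self.merges:
            key = a | b
            parts = []
            for child in (a, b):
                bl = max(h - node_height[child], 0.0)
                parts.append(f"{node_str[child]}:{bl:g}")
            label = ""
            if support is not None:
                names = frozenset(self.leaves[i] for i in key)
                if names in support:
                    label = f"{support[names]:g}"
            node_str[key] = f"({','.join(sorted(parts))}){label}"
            node_height[key] = h
        return node_str[key] + ";" if key is not None else f"({','.join(self.leaves)});"


def cluster_nearest_neighbour(
    dist: np.ndarray, leaf_names: list[str] | None = None
) -> Dendrogram:
    """Single-linkage agglomeration with a deterministic tie-break.

    Ties in the minimum linkage distance are broken by the smallest
    (i, j) pair of cluster positions, clusters being kept ordered by their
    smallest member leaf index.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix of size >= 2")
    if leaf_names is None:
        leaf_names = [f"L{i}" for i in range(n)]
    clusters: list[frozenset] = [frozenset((i,)) for i in range(n)]
    cd = dist.astype(float).copy()  # cluster-to-cluster single-linkage distances
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > 1:
        m = len(clusters)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or cd[i, j] < best[0]:
                    best = (cd[i, j], i, j)
        h, i, j = best
        merges.append((clusters[i], clusters[j], float(h)))
        merged = clusters[i] | clusters[j]
        # single-linkage update: d(new, k) = min(d(i,k), d(j,k))
        new_row = np.minimum(cd[i], cd[j])
        cd[i] = new_row
        cd[:, i] = new_row
        cd[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        cd = cd[np.ix_(keep, keep)]
        clusters[i] = merged
        del clusters[j]
    return Dendrogram(list(leaf_names), merges)


def rf_distance(t1: Dendrogram, t2: Dendrogram) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets."""
    if set(t1.leaves) != set(t2.leaves):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


# ---------------------------------------------------------------------------
# precursor placement

@dataclass
class PrecursorAssignment:
    """Injective precursor -> internal-node assignment of minimal total cost."""

    assignment: dict[str, frozenset]  # precursor name -> clade (leaf names)
    costs: dict[str, float]
    total_cost: float


def place_precursors(
    dendrogram: Dendrogram,
    precursor_vectors: dict[str, np.ndarray],
    leaf_matrix: np.ndarray,
) -> PrecursorAssignment:
    """Assign precursors to internal nodes by the Hungarian algorithm.

    The cost of placing precursor p at node v is the Euclidean distance
    between p's binary vector and the centroid of the leaf vectors under v.
    ``leaf_matrix`` rows align with ``dendrogram.leaves``.
    """
    clades = dendrogram.clades()
    names = sorted(precursor_vectors)
    if len(names) > len(clades):
        raise ValueError("more precursors than internal nodes")
    leaf_matrix = np.asarray(leaf_matrix, dtype=float)
    centroids = np.stack([leaf_matrix[sorted(c)].mean(axis=0) for c in clades])
    pvecs = np.stack([np.asarray(precursor_vectors[p], dtype=float) for p in names])
    cost = np.sqrt(((pvecs[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2))
    rows, cols = linear_sum_assignment(cost)
    assignment = {}
    costs = {}
    for r, c in zip(rows, cols):
        clade_names = frozenset(dendrogram.leaves[i] for i in clades[c])
        assignment[names[r]] = clade_names
        costs[names[r]] = float(cost[r, c])
    return PrecursorAssignment(assignment, costs, float(cost[rows, cols].sum()))


# ---------------------------------------------------------------------------
# PCoA

def pcoa(dist: np.ndarray, dims: int = 3) -> np.ndarray:
    """Classical multidimensional scaling of a distance matrix.

    Double-centres -0.5 * D^2, takes the top ``dims`` eigenpairs and scales
    eigenvectors by sqrt(eigenvalue). Negative eigenvalues are dropped with
    a warning; if fewer than ``dims`` positive eigenvalues exist the result
    is truncated (with a warning) to the positive ones.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals[0]), 1.0)
    if np.any(vals < -tol):
        warnings.warn("negative eigenvalues dropped (non-Euclidean distances)")
    pos = vals > tol
    if pos.sum() < dims:
        warnings.warn(f"only {int(pos.sum())} positive eigenvalues; truncating")
        dims = int(pos.sum())
    vals, vecs = vals[:dims], vecs[:, :dims]
    return vecs * np.sqrt(np.maximum(vals, 0.0))


# ---------------------------------------------------------------------------
# bootstrap support and sensitivity ensemble

def bootstrap_branch_support(
    matrix: np.ndarray,
    leaf_names: list[str],
    n_iter: int = 1000,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Column bootstrap support (%) for each internal branch of the tree
    built from the full matrix.

    Each iteration resamples element columns with replacement to the
    original count, recomputes distances, reclusters and records which
    reference bipartitions recur.
    """
    matrix = np.asarray(matrix)
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 element columns")
    ref = cluster_nearest_neighbour(distance_matrix(matrix), leaf_names)
    ref_bips = ref.bipartitions()
    counts = {b: 0 for b in ref_bips}
    rng = np.random.default_rng(seed)
    m = matrix.shape[1]
    for _ in range(n_iter):
        cols = rng.integers(0, m, size=m)
        tree = cluster_nearest_neighbour(distance_matrix(matrix[:, cols]), leaf_names)
        for b in tree.bipartitions() & ref_bips:
            counts[b] += 1
    return {b: 100.0 * c / n_iter for b, c in counts.items()}


def leave_category_out_ensemble(categories) -> list[tuple]:
    """All subsets of categories retaining >= 1 and excluding >= 1 member.

    Deterministic order: ascending binary mask over the sorted category
    list (bit i set = category i retained). With m categories the ensemble
    has 2^m - 2 members.
    """
    cats = sorted(set(categories))
    m = len(cats)
    if m < 2:
        raise ValueError("need >= 2 distinct categories")
    out = []
    for mask in range(1, 2 ** m - 1):
        out.append(tuple(cats[i] for i in range(m) if mask >> i & 1))
    return out


# ---------------------------------------------------------------------------
# dendrogram comparison

@dataclass
class GammaResult:
    """Baker's Gamma: Spearman rank correlation of pairwise merge stages."""

    gamma: float


def bakers_gamma(tree1: Dendrogram, tree2: Dendrogram) -> GammaResult:
    """Rank correlation between the cluster-count stages at which leaf pairs
    first co-cluster in the two trees. Invariant to leaf input order and to
    monotone transforms of merge heights."""
    if set(tree1.leaves) != set(tree2.leaves):
        raise ValueError("trees have different leaf sets")
    names = sorted(tree1.leaves)
    idx1 = [tree1.leaves.index(x) for x in names]
    idx2 = [tree2.leaves.index(x) for x in names]
    s1 = tree1.merge_stages()[np.ix_(idx1, idx1)]
    s2 = tree2.merge_stages()[np.ix_(idx2, idx2)]
    iu = np.triu_indices(len(names), k=1)
    v1, v2 = s1[iu], s2[iu]
    if np.all(v1 == v1[0]) and np.all(v2 == v2[0]):
        return GammaResult(1.0)  # both trees are stars at every stage
    rho = spearmanr(v1, v2).statistic
    return GammaResult(float(rho))


@dataclass
class BkCurve:
    """Fowlkes-Mallows B_k with permutation-null mean and 2-sigma limits."""

    ks: np.ndarray
    bk: np.ndarray
    e_bk: np.ndarray
    var_bk: np.ndarray
    lower: np.ndarray   # E(Bk) - 2 sqrt(var)
    upper: np.ndarray   # E(Bk) + 2 sqrt(var)
    defined: np.ndarray  # False where Pk or Qk vanished


def bk_statistics(labels1: np.ndarray, labels2: np.ndarray):
    """(Bk, E(Bk), var(Bk)) for two flat partitions of the same n objects.

    Uses the contingency-table forms: Tk = sum m_ij^2 - n,
    Pk = sum m_i.^2 - n, Qk = sum m_.j^2 - n, Bk = Tk / sqrt(Pk Qk), with
    the permutation-null mean and variance in closed form.
    """
    labels1 = np.asarray(labels1)
    labels2 = np.asarray(labels2)
    n = len(labels1)
    if len(labels2) != n:
        raise ValueError("partitions must cover the same objects")
    k1 = labels1.max() + 1
    k2 = labels2.max() + 1
    m = np.zeros((k1, k2))
    np.add.at(m, (labels1, labels2), 1.0)
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    tk = float((m ** 2).sum() - n)
    pk = float((row ** 2).sum() - n)
    qk = float((col ** 2).sum() - n)
    if pk == 0 or qk == 0:
        return float("nan"), float("nan"), float("nan")
    bk = tk / np.sqrt(pk * qk)
    e_bk = np.sqrt(pk * qk) / (n * (n - 1))
    pk2 = float((row * (row - 1) * (row - 2)).sum())
    qk2 = float((col * (col - 1) * (col - 2)).sum())
    var_tk = (
        2.0 * pk * qk / (n * (n - 1))
        + 4.0 * pk2 * qk2 / (n * (n - 1) * (n - 2))
        + (pk - 2 - 4 * pk2 / pk) * (qk - 2 - 4 * qk2 / qk)
        * pk * qk / (n * (n - 1) * (n - 2) * (n - 3))
        - pk * pk * qk * qk / (n * n * (n - 1) * (n - 1))
    )
    var_bk = var_tk / (pk * qk)
    return float(bk), float(e_bk), float(var_bk)


def fowlkes_mallows_bk(
    tree1: Dendrogram, tree2: Dendrogram, ks=None
) -> BkCurve:
    """B_k curve between two dendrograms over k = 2 .. n-1 (default)."""
    if set(tree1.leaves) != set(tree2.leaves):
        raise ValueError("trees have different leaf sets")
    n = tree1.n
    if ks is None:
        ks = range(2, n)
    names = sorted(tree1.leaves)
    idx1 = [tree1.leaves.index(x) for x in names]
    idx2 = [tree2.leaves.index(x) for x in names]
    ks = np.array(list(ks), dtype=np.int64)
    bk = np.empty(len(ks))
    e = np.empty(len(ks))
    v = np.empty(len(ks))
    defined = np.ones(len(ks), dtype=bool)
    for t, k in enumerate(ks):
        l1 = tree1.cut(int(k))[idx1]
        l2 = tree2.cut(int(k))[idx2]
        bk[t], e[t], v[t] = bk_statistics(l1, l2)
        defined[t] = np.isfinite(bk[t])
    sd = np.sqrt(np.maximum(v, 0.0))
    return BkCurve(ks, bk, e, v, e - 2 * sd, e + 2 * sd, defined)


# ---------------------------------------------------------------------------
# lineage-restricted region groups

def lineage_restricted_regions(
    pm: PresenceMatrix,
    tree: Dendrogram,
    branch_clades: list[frozenset] | None = None,
    alpha: float = 1.0,
    beta: float = 0.0,
) -> dict[frozenset, list[int]]:
    """Assign elements to the deepest branch whose descendant leaves carry
    them at fraction >= alpha while non-descendants carry them at <= beta.

    ``branch_clades`` are frozensets of leaf names (default: every internal
    node of the tree, including the root). Elements qualifying nowhere are
    omitted. Returns clade -> element column indices.
    """
    if alpha <= beta:
        raise ValueError("alpha must exceed beta")
    if branch_clades is None:
        branch_clades = [
            frozenset(tree.leaves[i] for i in c) for c in tree.clades()
        ]
    tree_names = set(tree.leaves)
    for clade in branch_clades:
        if not clade <= tree_names:
            raise ValueError(f"clade {sorted(clade)} not in the tree's leaf set")
    cell_idx = {c: i for i, c in enumerate(pm.cells)}
    mat = pm.matrix.astype(float)
    n_elem = mat.shape[1]
    # order candidate clades deepest-first (smallest first), deterministic
    ordered = sorted(branch_clades, key=lambda c: (len(c), tuple(sorted(c))))
    assigned = np.full(n_elem, -1, dtype=np.int64)
    for ci, clade in enumerate(ordered):
        inside = [cell_idx[c] for c in clade if c in cell_idx]
        outside = [i for c, i in cell_idx.items() if c not in clade]
        if not inside:
            continue
        in_frac = mat[inside].mean(axis=0)
        out_frac = mat[outside].mean(axis=0) if outside else np.zeros(n_elem)
        ok = (in_frac >= alpha) & (out_frac <= beta) & (assigned < 0)
        assigned[ok] = ci
    out: dict[frozenset, list[int]] = {}
    for e in range(n_elem):
        if assigned[e] >= 0:
            out.setdefault(ordered[assigned[e]], []).append(e)
    return out
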