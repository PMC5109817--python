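"""Manhattan dissimilarity, NJ/UPGMA trees, tree cutting, and PCoA.

Genotypes are encoded as per-allele dosage vectors (0/1/2 copies of each
allele at a marker).  The per-marker contribution to the distance between
two accessions is ``min(1, sum_alleles |dosage_i - dosage_j| / 4)`` — for
a biallelic marker this reduces to ``|minor-dosage difference| / 2`` —
and the dissimilarity is the mean contribution over markers where both
accessions are called (pairwise deletion), so values stay in [0, 1]
under missingness.

Tree construction and ordination are delegated to scikit-bio (Saitou-Nei
neighbor joining, classical metric PCoA) and SciPy (average-linkage
agglomeration); trees are carried as scikit-bio ``TreeNode`` objects with
a method tag, and UPGMA trees retain the linkage matrix so they can be
cut into exactly k groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio.tree import nj as _skbio_nj

from .model import GenotypeMatrix


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    d: np.ndarray  # (n, n) symmetric, zero diagonal
    n_shared: np.ndarray  # (n, n) co-non-missing marker counts

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("dissimilarity matrix not symmetric")

    def to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.d, self.ids)

    def subset(self, ids) -> "DissimilarityMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = [pos[a] for a in ids]
        return DissimilarityMatrix(
            list(ids), self.d[np.ix_(idx, idx)], self.n_shared[np.ix_(idx, idx)]
        )


@dataclass
class Tree:
    root: TreeNode
    method: str  # "nj" | "upgma"
    n_negative_clamped: int = 0
    linkage: np.ndarray | None = None  # retained for UPGMA tree cutting
    ids: list[str] | None = None

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.root.tips()]


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # accession -> 1..k
    k: int
    provenance: str  # "tree-cut" | "external"

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for a, c in self.labels.items():
            out.setdefault(int(c), []).append(a)
        return out


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # (n, n_axes)
    pct_variance: np.ndarray  # per retained axis, non-increasing


def _dosage_encoding(g: GenotypeMatrix):
    """Per-allele dosage array (n, total_slots), marker slot boundaries,
    and the valid (non-missing) mask (n, m)."""
    alleles = [g.marker_alleles(m) for m in g.marker_ids]
    starts = np.cumsum([0] + [max(len(a), 1) for a in alleles])[:-1]
    total = int(starts[-1] + max(len(alleles[-1]), 1)) if alleles else 0
    n = g.n_accessions
    D = np.zeros((n, total))
    valid = ~g.missing_mask()
    for j, mk_alleles in enumerate(alleles):
        index = {a: starts[j] + t for t, a in enumerate(mk_alleles)}
        for i in range(n):
            call = g.calls[i, j]
            if call is None:
                continue
            D[i, index[call[0]]] += 1
            D[i, index[call[1]]] += 1
    return D, starts, valid


def manhattan_dissimilarity(g: GenotypeMatrix) -> DissimilarityMatrix:
    """Pairwise Manhattan dissimilarity on allele dosages, in [0, 1].

    Raises if any pair of accessions shares no non-missing marker.
    """
    if g.n_accessions < 2:
        raise ValueError("need at least two accessions")
    D, starts, valid = _dosage_encoding(g)
    n, m = valid.shape
    d = np.zeros((n, n))
    n_shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        diffs = np.abs(D - D[i])  # (n, slots)
        per_marker = np.add.reduceat(diffs, starts, axis=1) / 4.0
        np.minimum(per_marker, 1.0, out=per_marker)
        shared = valid & valid[i]
        counts = shared.sum(axis=1)
        n_shared[i] = counts
        zero = np.flatnonzero(counts == 0)
        zero = zero[zero != i]
        if zero.size:
            raise ValueError(
                f"accessions {g.accession_ids[i]!r} and "
                f"{g.accession_ids[int(zero[0])]!r} share no non-missing marker"
            )
        with np.errstate(invalid="ignore"):
            d[i] = np.where(shared, per_marker, 0.0).sum(axis=1) / np.maximum(counts, 1)
    d = (d + d.T) / 2.0  # symmetric up to float noise
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(list(g.accession_ids), d, n_shared)


def nj_tree(D: DissimilarityMatrix) -> Tree:
    """Unweighted (Saitou-Nei) neighbor joining; negative branch lengths
    are clamped to zero with a count kept on the returned tree."""
    if len(D.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 accessions")
    if not np.all(np.isfinite(D.d)):
        raise ValueError("non-finite distances")
    root = _skbio_nj(D.to_skbio())
    clamped = 0
    for node in root.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    return Tree(root, "nj", n_negative_clamped=clamped, ids=list(D.ids))


def upgma_tree(D: DissimilarityMatrix) -> Tree:
    """Average-linkage (UPGMA) dendrogram; ultrametric, heights monotone."""
    if len(D.ids) < 2:
        raise ValueError("need at least two accessions")
    if not np.all(np.isfinite(D.d)):
        raise ValueError("non-finite distances")
    Z = hierarchy.linkage(squareform(D.d, checks=False), method="average")
    root = TreeNode.from_linkage_matrix(Z, list(D.ids))
    # scikit-bio labels internal nodes by linkage row; strip for clean Newick
    for node in root.non_tips(include_self=True):
        node.name = None
    return Tree(root, "upgma", linkage=Z, ids=list(D.ids))


def cut_tree(t: Tree, k: int) -> ClusterAssignment:
    """Cut a UPGMA dendrogram into exactly k groups (undo the k-1 highest
    merges).  NJ trees are unrooted and cannot be height-cut."""
    if t.method != "upgma":
        raise ValueError("cut_tree requires a UPGMA tree (NJ trees are unrooted)")
    ids = t.ids or t.leaf_names()
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    flat = hierarchy.cut_tree(t.linkage, n_clusters=k).ravel()
    # relabel deterministically: 1..k in order of first appearance
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for a, c in zip(ids, flat):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[a] = remap[c]
    return ClusterAssignment(labels, k, "tree-cut")


def pcoa(D: DissimilarityMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical metric scaling of the dissimilarity matrix.

    Keeps positive eigenvalues only; percentages are relative to the sum
    of positive eigenvalues.  Requests beyond the positive rank are
    truncated with a warning.
    """
    if len(D.ids) < 3:
        raise ValueError("PCoA needs at least 3 accessions")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(D.to_skbio(), method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(eig.max(), 1.0)
    rank = int(pos.sum())
    if n_axes > rank:
        warnings.warn(
            f"requested {n_axes} axes but only {rank} positive eigenvalues; truncated",
            stacklevel=2,
        )
        n_axes = rank
    coords = res.samples.to_numpy()[:, :n_axes]
    pct = 100.0 * eig[:n_axes] / eig[pos].sum()
    return PcoaResult(list(D.ids), coords, pct)


def export_newick(t: Tree, path) -> None:
    """Write the tree as Newick with branch lengths."""
    t.root.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
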