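"""Class construction and the greedy allele-coverage (M-strategy) selector.

Core-collection selection is cast as a set-cover problem.  Every variable
— SNP marker, qualitative trait, or Sturges-binned quantitative trait —
contributes a set of classes, and every accession carries the classes it
exhibits (a heterozygote carries both alleles of a marker; a missing
value carries nothing).  The maximization (M) strategy asks for a small
set of accessions that jointly carries *every* observed class.

The selector is a deterministic greedy maximum-coverage heuristic:

1. repeatedly pick the accession covering the most still-uncovered
   classes, breaking ties first in favour of accessions whose uncovered
   classes are rare (largest sum of 1/carrier-count), then by
   lexicographic accession id;
2. afterwards, revisit the selected accessions in selection order and
   drop any whose removal leaves all classes covered (backward
   redundancy elimination).

Full coverage is enforced unconditionally, so the core size is an output
— determined by the diversity of the collection — rather than an input.

Five sampling strategies wrap the selector: genotype-only (Gcc),
phenotype-only (Pcc), both (G+Pcc), and stratified variants (Ggcc,
Gg+Pcc) that run the selector within each cluster of a genotype-based
grouping and take the union of the per-cluster cores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance import ClusterAssignment
from .model import Collection

STRATEGIES = ("Gcc", "Ggcc", "Pcc", "G+Pcc", "Gg+Pcc")

#: strategy -> (variable basis, stratified?)
_STRATEGY_SPEC = {
    "Gcc": ("genotype", False),
    "Ggcc": ("genotype", True),
    "Pcc": ("phenotype", False),
    "G+Pcc": ("both", False),
    "Gg+Pcc": ("both", True),
}


@dataclass
class Variable:
    name: str
    source: str  # "marker" | "qual-trait" | "quant-trait"
    classes: list[str]
    bin_edges: np.ndarray | None = None


@dataclass
class ClassificationTable:
    """Boolean accession x class membership plus the variable layout."""

    accession_ids: list[str]
    variables: list[Variable]
    class_index: list[tuple[str, str]]  # (variable name, class label) per column
    membership: np.ndarray  # bool (n_accessions, n_classes)

    @property
    def n_classes(self) -> int:
        return self.membership.shape[1]

    def classes_of(self, variable_name: str) -> list[int]:
        return [i for i, (v, _) in enumerate(self.class_index) if v == variable_name]


@dataclass
class CoreSet:
    strategy: str
    selected_ids: list[str]
    classes_covered: int
    classes_total: int
    cluster_of: dict[str, int] = field(default_factory=dict)  # stratified provenance
    basis: str = ""

    @property
    def size(self) -> int:
        return len(self.selected_ids)


def sturges_bins(values) -> np.ndarray:
    """Equal-width bin edges with Sturges' class count k = ceil(1 + log2 n).

    Returns k+1 edges over [min, max].  A constant trait yields a single
    degenerate class (warned).  Values on internal edges belong to the
    lower bin; the maximum belongs to the top bin (see ``assign_bins``).
    """
    v = np.asarray([x for x in values if x is not None], dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("Sturges binning needs at least 2 non-missing values")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        warnings.warn("constant trait: single degenerate class", stacklevel=2)
        return np.array([lo, hi])
    k = int(np.ceil(1 + np.log2(v.size)))
    return np.linspace(lo, hi, k + 1)


def assign_bins(values, edges: np.ndarray) -> list[int | None]:
    """Bin index per value (None for missing / out of range).

    Internal-edge values go to the lower bin; min to bin 0, max to the
    top bin.  Values outside [min, max] (possible when edges come from a
    different subset) are unassigned.
    """
    k = len(edges) - 1
    out: list[int | None] = []
    for x in values:
        if x is None or not np.isfinite(x):
            out.append(None)
            continue
        if x < edges[0] or x > edges[-1]:
            out.append(None)
            continue
        if k == 0:
            out.append(0)
            continue
        idx = int(np.searchsorted(edges, x, side="left")) - 1
        out.append(min(max(idx, 0), k - 1))
    return out


def build_classification(
    collection: Collection, basis: str = "both", accession_ids=None
) -> ClassificationTable:
    """Build the accession x class membership table for a variable basis.

    ``basis`` is ``"genotype"`` (marker alleles: a biallelic marker
    contributes 2 classes and a heterozygote carries both),
    ``"phenotype"`` (qualitative categories + Sturges bins of
    quantitative traits, bins computed on the given subset), or
    ``"both"``.  Classes carried by no accession are pruned.
    """
    if basis not in ("genotype", "phenotype", "both"):
        raise ValueError(f"unknown basis {basis!r}")
    ids = list(accession_ids) if accession_ids is not None else list(collection.accession_ids)
    variables: list[Variable] = []
    columns: list[tuple[str, str]] = []
    member_cols: list[np.ndarray] = []
    n = len(ids)

    if basis in ("genotype", "both"):
        g = collection.genotypes.subset(accession_ids=ids)
        for j, mid in enumerate(g.marker_ids):
            alleles = sorted(
                {a for call in g.calls[:, j] if call is not None for a in call}
            )
            if not alleles:
                continue
            variables.append(Variable(mid, "marker", alleles))
            for a in alleles:
                col = np.zeros(n, dtype=bool)
                for i in range(n):
                    call = g.calls[i, j]
                    if call is not None and a in call:
                        col[i] = True
                columns.append((mid, a))
                member_cols.append(col)

    if basis in ("phenotype", "both"):
        if collection.phenotypes is None:
            raise ValueError(f"basis {basis!r} requires a phenotype table")
        p = collection.phenotypes
        for t in p.traits:
            vals = p.column(t.name, ids)
            if t.kind == "qualitative":
                observed = sorted({v for v in vals if v is not None})
                if not observed:
                    continue
                variables.append(Variable(t.name, "qual-trait", observed))
                for c in observed:
                    col = np.array([v == c for v in vals])
                    columns.append((t.name, c))
                    member_cols.append(col)
            else:
                finite = [v for v in vals if v is not None]
                if len(finite) < 2:
                    continue
                edges = sturges_bins(finite)
                bins = assign_bins(vals, edges)
                k = max(len(edges) - 1, 1)
                labels = [f"bin_{b + 1}" for b in range(k)]
                observed = sorted({b for b in bins if b is not None})
                if not observed:
                    continue
                variables.append(
                    Variable(t.name, "quant-trait", [labels[b] for b in observed], edges)
                )
                for b in observed:
                    col = np.array([x == b for x in bins])
                    columns.append((t.name, labels[b]))
                    member_cols.append(col)

    membership = (
        np.column_stack(member_cols) if member_cols else np.zeros((n, 0), dtype=bool)
    )
    return ClassificationTable(ids, variables, columns, membership)


def m_strategy_select(ct: ClassificationTable, strategy: str = "Gcc") -> CoreSet:
    """Greedy maximum-coverage core selection with backward elimination.

    Deterministic: ties on coverage gain break toward the accession whose
    uncovered classes are rarest (largest sum of 1/carrier-count over its
    uncovered classes), then toward the lexicographically smallest id.
    The returned core carries every class of the table.
    """
    M = ct.membership
    n, C = M.shape
    if n == 0 or C == 0:
        raise ValueError("empty classification table")
    carriers = M.sum(axis=0)
    if np.any(carriers == 0):
        bad = [ct.class_index[i] for i in np.flatnonzero(carriers == 0)]
        raise RuntimeError(f"classes carried by no accession (should be pruned): {bad}")
    inv_carriers = 1.0 / carriers
    # lexicographic order on ids, as a permutation rank
    order = np.argsort(np.array(ct.accession_ids, dtype=object))
    lex_rank = np.empty(n, dtype=int)
    lex_rank[order] = np.arange(n)

    uncovered = np.ones(C, dtype=bool)
    available = np.ones(n, dtype=bool)
    selected: list[int] = []
    while uncovered.any():
        gains = M[:, uncovered].sum(axis=1)
        gains[~available] = -1
        best_gain = gains.max()
        cand = np.flatnonzero(gains == best_gain)
        if len(cand) > 1:
            rare = (M[np.ix_(cand, np.flatnonzero(uncovered))] *
                    inv_carriers[uncovered]).sum(axis=1)
            cand = cand[np.isclose(rare, rare.max())]
        if len(cand) > 1:
            cand = cand[[int(np.argmin(lex_rank[cand]))]]
        pick = int(cand[0])
        selected.append(pick)
        available[pick] = False
        uncovered &= ~M[pick]

    # backward redundancy elimination, in selection order
    keep = list(selected)
    for idx in list(selected):
        others = [i for i in keep if i != idx]
        if others and M[others].any(axis=0).all():
            keep = others
    keep_ids = sorted(ct.accession_ids[i] for i in keep)
    return CoreSet(
        strategy=strategy,
        selected_ids=keep_ids,
        classes_covered=int(M[keep].any(axis=0).sum()),
        classes_total=C,
    )


def stratified_select(
    collection: Collection,
    clusters: ClusterAssignment | dict[str, object],
    basis: str = "genotype",
    strategy: str = "Ggcc",
) -> CoreSet:
    """Run the M-strategy selector within each cluster; union the cores.

    The classification (including Sturges bins for quantitative traits)
    is rebuilt from each cluster's own accessions, so the union covers
    every class observed in every cluster.  Singleton clusters contribute
    their sole accession (warned).
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else dict(clusters)
    missing = [a for a in collection.accession_ids if a not in labels]
    if missing:
        raise ValueError(f"accessions without a cluster label: {missing[:5]}")
    groups: dict[object, list[str]] = {}
    for a in collection.accession_ids:
        groups.setdefault(labels[a], []).append(a)
    union: list[str] = []
    cluster_of: dict[str, int] = {}
    covered = 0
    total = 0
    for lab in sorted(groups, key=str):
        ids = groups[lab]
        if len(ids) == 1:
            warnings.warn(f"singleton cluster {lab!r}: its accession selected", stacklevel=2)
            part = ids
            ct = build_classification(collection, basis, ids)
            covered += int(ct.membership.any(axis=0).sum())
            total += ct.n_classes
        else:
            ct = build_classification(collection, basis, ids)
            sub = m_strategy_select(ct, strategy)
            part = sub.selected_ids
            covered += sub.classes_covered
            total += sub.classes_total
        for a in part:
            if a not in cluster_of:  # first-cluster provenance on duplicates
                cluster_of[a] = lab
                union.append(a)
    return CoreSet(
        strategy=strategy,
        selected_ids=sorted(union),
        classes_covered=covered,
        classes_total=total,
        cluster_of=cluster_of,
        basis=basis,
    )


def run_strategy(
    collection: Collection,
    strategy: str,
    clusters: ClusterAssignment | dict[str, object] | None = None,
    accession_ids=None,
) -> CoreSet:
    """Dispatch one of the five sampling strategies.

    Stratified strategies (Ggcc, Gg+Pcc) require cluster labels.  An
    optional ``accession_ids`` restricts selection to a subset (e.g. the
    QC-retained accessions).
    """
    if strategy not in _STRATEGY_SPEC:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    basis, stratified = _STRATEGY_SPEC[strategy]
    coll = collection if accession_ids is None else collection.subset(accession_ids)
    if stratified:
        if clusters is None:
            raise ValueError(f"strategy {strategy} requires cluster labels")
        core = stratified_select(coll, clusters, basis, strategy)
    else:
        ct = build_classification(coll, basis)
        core = m_strategy_select(ct, strategy)
    core.basis = basis
    return core
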