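"""Allele-frequency and class-frequency diversity statistics, plus AMOVA.

Definitions used throughout (all denominators over non-missing data):

* allele frequencies: each non-missing diploid call contributes two
  allele copies;
* expected heterozygosity (gene diversity) per marker
  ``H_E = 1 - sum(p_i^2)`` — the plain uncorrected form;
* observed heterozygosity per marker: heterozygous / non-missing calls;
* PIC (Botstein form) ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``;
* Shannon index ``I = -sum f ln f`` with natural logs, ``I_max = ln(c)``
  over c classes, Pielou evenness ``J' = I / I_max``.

For SNP markers the Shannon "classes" are the observed genotype patterns
(``A/A``, ``A/B``, ...); allele-level classes are used only by the core
selector.  Per-cluster differentiation is a Wright-style proxy
``F_ST,k = mean_m (H_T - H_{S,k}) / H_T`` over polymorphic markers, and
AMOVA decomposes squared pairwise dissimilarities among/within groups
with a permutation test on Phi_ST.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import Collection, GenotypeMatrix, UndefinedValueError


@dataclass
class AlleleFrequencyTable:
    """Per-marker allele frequencies among non-missing allele copies."""

    marker_ids: list[str]
    freqs: dict[str, dict[str, float]]  # marker -> allele -> frequency
    n_copies: dict[str, int]  # marker -> number of non-missing allele copies

    def absent_markers(self) -> list[str]:
        return [m for m in self.marker_ids if self.n_copies[m] == 0]

    def vector(self, marker_id: str) -> np.ndarray:
        return np.array(list(self.freqs[marker_id].values()))


@dataclass
class DiversitySummary:
    label: str
    n: int
    H_O: float
    H_E: float
    PIC: float
    I: float
    I_max: float
    J_prime: float


@dataclass
class ClusterDiversitySummary:
    labels: list
    n: dict
    H_E: dict
    I: dict
    F_ST: dict


@dataclass
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    pct_among: float
    pct_within: float
    p_perm: float
    n_perm: int


# ---------------------------------------------------------------------------
# frequency substrate


def allele_frequencies(g: GenotypeMatrix, accession_ids=None) -> AlleleFrequencyTable:
    """Allele frequencies per marker over a subset of accessions.

    Markers with no non-missing call in the subset are flagged absent
    (``n_copies == 0``) and carry no frequencies.
    """
    if accession_ids is not None and len(list(accession_ids)) == 0:
        raise ValueError("empty accession subset")
    sub = g if accession_ids is None else g.subset(accession_ids=list(accession_ids))
    freqs: dict[str, dict[str, float]] = {}
    n_copies: dict[str, int] = {}
    for j, mid in enumerate(sub.marker_ids):
        counts: Counter = Counter()
        for call in sub.calls[:, j]:
            if call is not None:
                counts[call[0]] += 1
                counts[call[1]] += 1
        total = sum(counts.values())
        n_copies[mid] = total
        freqs[mid] = (
            {a: c / total for a, c in sorted(counts.items())} if total else {}
        )
    return AlleleFrequencyTable(list(sub.marker_ids), freqs, n_copies)


def expected_het(freqs: AlleleFrequencyTable) -> tuple[dict[str, float], float]:
    """Per-marker and mean gene diversity ``H_E = 1 - sum p_i^2``.

    The group value is the unweighted mean over markers with data.
    """
    per = {}
    for m in freqs.marker_ids:
        if freqs.n_copies[m] == 0:
            continue
        p = freqs.vector(m)
        per[m] = float(1.0 - np.sum(p**2))
    mean = float(np.mean(list(per.values()))) if per else float("nan")
    return per, mean


def observed_het(g: GenotypeMatrix, accession_ids=None) -> tuple[dict[str, float], float]:
    """Per-marker and mean observed heterozygosity (het / non-missing calls)."""
    sub = g if accession_ids is None else g.subset(accession_ids=list(accession_ids))
    if sub.n_accessions == 0:
        raise ValueError("empty accession subset")
    per = {}
    for j, mid in enumerate(sub.marker_ids):
        calls = [c for c in sub.calls[:, j] if c is not None]
        if not calls:
            continue
        per[mid] = sum(1 for c in calls if c[0] != c[1]) / len(calls)
    mean = float(np.mean(list(per.values()))) if per else float("nan")
    return per, mean


def pic(freqs: AlleleFrequencyTable) -> tuple[dict[str, float], float]:
    """Polymorphic information content per marker (Botstein form)."""
    per = {}
    for m in freqs.marker_ids:
        if freqs.n_copies[m] == 0:
            continue
        p = freqs.vector(m)
        p2 = p**2
        cross = np.sum(np.outer(p2, p2)) - np.sum(p2**2)  # 2 * sum_{i<j} p_i^2 p_j^2
        per[m] = float(1.0 - np.sum(p2) - cross)
    mean = float(np.mean(list(per.values()))) if per else float("nan")
    return per, mean


def shannon_index(class_freqs) -> float:
    """Shannon information index ``I = -sum f ln f`` (natural log)."""
    f = np.asarray(list(class_freqs), dtype=float)
    if f.size and not np.isclose(f.sum(), 1.0):
        raise ValueError("class frequencies must sum to 1")
    nz = f[f > 0]
    return float(-np.sum(nz * np.log(nz)))


def i_max(n_classes: int) -> float:
    """Maximum Shannon index over ``n_classes`` classes: ``ln(n_classes)``."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    return float(np.log(n_classes))


def pielou_evenness(I: float, n_classes: int) -> float:
    """Pielou evenness ``J' = I / ln(n_classes)``; undefined below 2 classes."""
    if n_classes < 2:
        raise UndefinedValueError("evenness undefined with fewer than 2 classes")
    return float(I / np.log(n_classes))


# ---------------------------------------------------------------------------
# grouped summaries


def _genotype_pattern_freqs(g: GenotypeMatrix, j: int) -> np.ndarray:
    counts = Counter(c for c in g.calls[:, j] if c is not None)
    total = sum(counts.values())
    if total == 0:
        return np.array([])
    return np.array([v / total for _, v in sorted(counts.items())])


def marker_shannon(g: GenotypeMatrix, accession_ids=None) -> tuple[dict[str, float], float]:
    """Shannon index per marker over observed genotype-pattern frequencies."""
    sub = g if accession_ids is None else g.subset(accession_ids=list(accession_ids))
    per = {}
    for j, mid in enumerate(sub.marker_ids):
        f = _genotype_pattern_freqs(sub, j)
        if f.size == 0:
            continue
        per[mid] = shannon_index(f)
    mean = float(np.mean(list(per.values()))) if per else float("nan")
    return per, mean


def _summarize_group(label: str, g: GenotypeMatrix, ids: list[str]) -> DiversitySummary:
    freqs = allele_frequencies(g, ids)
    _, he = expected_het(freqs)
    _, ho = observed_het(g, ids)
    _, p = pic(freqs)
    sub = g.subset(accession_ids=ids)
    i_vals, imax_vals, j_vals = [], [], []
    for j in range(sub.n_markers):
        f = _genotype_pattern_freqs(sub, j)
        if f.size == 0:
            continue
        I = shannon_index(f)
        i_vals.append(I)
        imax_vals.append(i_max(len(f)))
        if len(f) >= 2:
            j_vals.append(pielou_evenness(I, len(f)))
    I_mean = float(np.mean(i_vals)) if i_vals else float("nan")
    Imax_mean = float(np.mean(imax_vals)) if imax_vals else float("nan")
    J_mean = float(np.mean(j_vals)) if j_vals else float("nan")
    return DiversitySummary(label, len(ids), ho, he, p, I_mean, Imax_mean, J_mean)


def group_diversity(
    collection: Collection, grouping: str = "total", clusters: dict[str, object] | None = None
) -> list[DiversitySummary]:
    """Diversity summary rows per group plus a total row.

    ``grouping`` is ``"total"``, ``"species"`` (passport required) or
    ``"cluster"`` (a ``{accession: label}`` mapping required).  Shannon
    classes for markers are the observed genotype patterns.  Empty groups
    are skipped with a warning.
    """
    g = collection.genotypes
    groups: dict[str, list[str]] = {}
    if grouping == "total":
        pass
    elif grouping == "species":
        if collection.passport is None:
            raise ValueError("species grouping requires a passport table")
        for a in g.accession_ids:
            groups.setdefault(collection.passport.species.get(a, "UNKNOWN"), []).append(a)
    elif grouping == "cluster":
        if clusters is None:
            raise ValueError("cluster grouping requires cluster labels")
        for a in g.accession_ids:
            if a not in clusters:
                raise ValueError(f"no cluster label for accession {a!r}")
            groups.setdefault(str(clusters[a]), []).append(a)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out: list[DiversitySummary] = []
    for label in sorted(groups):
        ids = groups[label]
        if not ids:
            warnings.warn(f"group {label!r} is empty; skipped", stacklevel=2)
            continue
        out.append(_summarize_group(label, g, ids))
    out.append(_summarize_group("total", g, list(g.accession_ids)))
    return out


def fst_per_cluster(g: GenotypeMatrix, clusters: dict[str, object]) -> ClusterDiversitySummary:
    """Wright-style per-cluster differentiation from pooled vs cluster H_E.

    ``F_ST,k = mean over polymorphic markers of (H_T - H_{S,k}) / H_T``,
    with H_T from pooled allele frequencies.  Negative estimates are
    reported as-is, never clipped.
    """
    labels = sorted({str(v) for v in clusters.values()})
    if len(labels) < 2:
        raise ValueError("need at least two clusters")
    ids_of = {lab: [a for a in g.accession_ids if str(clusters[a]) == lab] for lab in labels}
    total_freqs = allele_frequencies(g)
    ht_per, _ = expected_het(total_freqs)
    poly = [m for m, h in ht_per.items() if h > 0]
    if not poly:
        raise ValueError("all markers monomorphic: F_ST undefined")
    he_d: dict[str, float] = {}
    i_d: dict[str, float] = {}
    fst_d: dict[str, float] = {}
    n_d: dict[str, int] = {}
    for lab in labels:
        ids = ids_of[lab]
        n_d[lab] = len(ids)
        fr = allele_frequencies(g, ids)
        hs_per, he_mean = expected_het(fr)
        he_d[lab] = he_mean
        _, i_d[lab] = marker_shannon(g, ids)
        ratios = [(ht_per[m] - hs_per[m]) / ht_per[m] for m in poly if m in hs_per]
        fst_d[lab] = float(np.mean(ratios)) if ratios else float("nan")
    return ClusterDiversitySummary(labels, n_d, he_d, i_d, fst_d)


# ---------------------------------------------------------------------------
# AMOVA


def _ss_from_d2(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squares of a group: sum_{i<j in group} d^2 / n_group."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2 * len(idx)))


def _phi_from_labels(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = len(codes)
    ss_total = float(d2.sum() / (2 * n))
    ss_within = 0.0
    sizes = []
    for gidx in range(n_groups):
        idx = np.flatnonzero(codes == gidx)
        sizes.append(len(idx))
        ss_within += _ss_from_d2(d2, idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = np.asarray(sizes)
    n0 = (n - np.sum(sizes**2) / n) / df_among
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    total = sigma_among + sigma_within
    phi = sigma_among / total if total != 0 else 0.0
    return phi, sigma_among, sigma_within


def amova(
    dissimilarity, clusters: dict[str, object], n_perm: int = 999, seed: int = 0
) -> AmovaResult:
    """Two-level AMOVA on squared dissimilarities with a permutation test.

    ``dissimilarity`` is a DissimilarityMatrix (``.ids``, ``.d``) or a
    square ndarray paired with cluster labels keyed by position.  The
    permutation p-value is ``(1 + #{permuted Phi >= observed}) / (n_perm + 1)``.
    """
    if hasattr(dissimilarity, "d"):
        ids = list(dissimilarity.ids)
        d = np.asarray(dissimilarity.d, dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    labels = [str(clusters[a]) for a in ids]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("AMOVA needs at least two clusters")
    codes = np.array([uniq.index(l) for l in labels])
    sizes = np.bincount(codes, minlength=len(uniq))
    if np.any(sizes < 2):
        small = [uniq[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"clusters of size < 2: {small}")
    d2 = d**2
    phi, s_among, s_within = _phi_from_labels(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        phi_p, _, _ = _phi_from_labels(d2, perm, len(uniq))
        if phi_p >= phi:
            n_ge += 1
    p_perm = (1 + n_ge) / (n_perm + 1)
    total = s_among + s_within
    pct_among = 100.0 * s_among / total if total != 0 else 0.0
    return AmovaResult(
        sigma2_among=s_among,
        sigma2_within=s_within,
        phi_st=phi,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        p_perm=p_perm,
        n_perm=n_perm,
    )
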