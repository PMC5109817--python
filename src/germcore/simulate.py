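"""Synthetic structured germplasm: a Balding-Nichols F-model generator.

The generator emulates the statistical shape of a large, highly structured
selfing-crop genebank collection: K latent clusters whose biallelic allele
frequencies diverge from a common ancestral frequency under the
Balding-Nichols model (divergence parameter ``F_div`` equals the expected
F_ST); strong within-accession inbreeding (``F_IS``) producing the
characteristic H_O << H_E excess-homozygosity of self-pollinating species;
a minority of planted F1 hybrids (first-generation crosses between
accessions of different clusters, hence strongly heterozygous); random
per-call missingness with a small fraction of "bad DNA" samples at an
elevated rate; cluster-correlated quantitative and qualitative traits;
and a few multi-allelic hold-out markers kept apart from anything used in
core selection.

A :class:`TruthRecord` accompanies every simulated collection so that
downstream stages (QC hybrid flagging, F_ST recovery, tree-cut cluster
recovery) can be scored against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    Collection,
    GenotypeMatrix,
    PassportTable,
    PhenotypeTable,
    TraitSpec,
    normalize_call,
)


class ConfigError(ValueError):
    """The simulation plan is internally inconsistent or infeasible."""


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults give a mid-size structured
    selfing-crop collection.

    ``F_div`` may be a scalar or a per-cluster sequence (the Balding-Nichols
    divergence of each cluster from the ancestral pool).  ``F_IS`` may be a
    scalar or a ``{species: value}`` mapping.  ``species_plan`` lists
    ``(species_label, count, cluster_mixture_weights)``; weights must sum
    to 1 and give the probability that an accession of that species is
    drawn from each latent cluster.
    """

    n_accessions: int = 600
    n_markers: int = 48
    K: int = 5
    F_div: float | list[float] = 0.3
    F_IS: float | dict[str, float] = 0.7
    species_plan: list[tuple[str, int, list[float]]] | None = None
    hybrid_fraction: float = 0.145
    missing_rate: float = 0.02
    bad_sample_fraction: float = 0.03
    bad_sample_missing_rate: float = 0.25
    n_traits_quant: int = 17
    n_traits_qual: int = 15
    trait_effect_sd: float = 1.0
    trait_noise_sd: float = 0.5
    trait_baseline_range: tuple[float, float] = (5.0, 50.0)
    trait_missing_rate: float = 0.02
    n_holdout_markers: int = 3
    holdout_allele_range: tuple[int, int] = (9, 16)
    seed: int = 0

    def f_div_per_cluster(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.F_div, dtype=float), (self.K,)).copy()
        if np.any((f <= 0) | (f >= 1)):
            raise ConfigError("F_div must lie in (0, 1)")
        return f

    def f_is_for(self, species: str) -> float:
        f = self.F_IS.get(species, 0.0) if isinstance(self.F_IS, dict) else float(self.F_IS)
        if not 0.0 <= f <= 1.0:
            raise ConfigError("F_IS must lie in [0, 1]")
        return f

    def validate(self) -> None:
        if self.n_accessions <= 0 or self.n_markers <= 0 or self.K <= 0:
            raise ConfigError("counts must be positive")
        if self.K > self.n_accessions:
            raise ConfigError("more clusters than accessions")
        for p, name in (
            (self.hybrid_fraction, "hybrid_fraction"),
            (self.missing_rate, "missing_rate"),
            (self.bad_sample_fraction, "bad_sample_fraction"),
            (self.bad_sample_missing_rate, "bad_sample_missing_rate"),
            (self.trait_missing_rate, "trait_missing_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.hybrid_fraction >= 1.0:
            raise ConfigError("hybrid_fraction must be < 1")
        self.f_div_per_cluster()
        plan = self.resolved_species_plan()
        total = sum(c for _, c, _ in plan)
        if total != self.n_accessions:
            raise ConfigError(
                f"species plan counts sum to {total}, expected {self.n_accessions}"
            )
        for name, _, w in plan:
            w = np.asarray(w, dtype=float)
            if len(w) != self.K or not np.isclose(w.sum(), 1.0):
                raise ConfigError(f"species {name!r}: cluster weights must sum to 1 over K")
        lo, hi = self.holdout_allele_range
        if not 2 <= lo <= hi:
            raise ConfigError("holdout_allele_range must satisfy 2 <= min <= max")

    def resolved_species_plan(self) -> list[tuple[str, int, list[float]]]:
        if self.species_plan is not None:
            return self.species_plan
        # single-species default, uniform over clusters
        return [("species_1", self.n_accessions, [1.0 / self.K] * self.K)]


def default_paper_like_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale stand-in for a large multi-species genebank collection.

    One strongly dominant cultivated species (~88% of accessions) spread
    over the first seven of ten clusters; ten minor species of very unequal
    sizes concentrated in the remaining clusters; per-cluster divergence
    spanning a wide range (0.08-0.78); heavy selfing in the dominant
    species; three multi-allelic hold-out markers.
    """
    K = 10

    def w(*clusters: int) -> list[float]:
        v = np.zeros(K)
        for c in clusters:
            v[c] = 1.0
        return list(v / v.sum())

    plan = [
        ("species_major", 880, w(0, 1, 2, 3, 4, 5, 6)),
        ("species_b", 40, w(7, 8, 9)),
        ("species_c", 25, w(7, 8)),
        ("species_d", 20, w(3, 8, 9)),
        ("species_e", 12, w(9)),
        ("species_f", 10, w(9)),
        ("species_g", 5, w(9)),
        ("species_h", 4, w(9)),
        ("species_i", 2, w(9)),
        ("species_j", 1, w(9)),
        ("species_k", 1, w(9)),
    ]
    return SimulationConfig(
        n_accessions=1000,
        n_markers=48,
        K=K,
        F_div=list(np.linspace(0.08, 0.78, K)),
        F_IS={"species_major": 0.75, "species_b": 0.6, "species_c": 0.7,
              "species_d": 0.6, "species_e": 0.3, "species_f": 0.7,
              "species_g": 0.2, "species_h": 0.3, "species_i": 0.2,
              "species_j": 0.2, "species_k": 0.2},
        species_plan=plan,
        hybrid_fraction=0.145,
        n_traits_quant=17,
        n_traits_qual=15,
        n_holdout_markers=3,
        holdout_allele_range=(9, 16),
        seed=seed,
    )


@dataclass
class TruthRecord:
    """Generating truth for a simulated collection."""

    cluster: dict[str, int]  # accession -> latent cluster (0-based)
    species: dict[str, str]
    hybrid: dict[str, bool]
    hybrid_parents: dict[str, tuple[str, str]]
    allele_freq: np.ndarray  # (K, n_markers) frequency of allele "A"
    ancestral_freq: np.ndarray  # (n_markers,)
    holdout_freq: list[np.ndarray] = field(default_factory=list)  # per marker (K, n_alleles)
    trait_cluster_means: np.ndarray | None = None  # (n_traits_quant, K)
    qual_class_probs: list[np.ndarray] = field(default_factory=list)  # per trait (K, n_classes)


def _draw_biallelic(rng: np.random.Generator, p: np.ndarray, f_is: float) -> np.ndarray:
    """Dosage of allele 'B' (the alternative) under inbreeding F_IS.

    P(hom A) = p^2 + pq F, P(het) = 2pq(1-F), P(hom B) = q^2 + pq F where
    p is the 'A' frequency.
    """
    q = 1.0 - p
    p_hom_a = p * p + p * q * f_is
    p_het = 2 * p * q * (1 - f_is)
    u = rng.random(p.shape)
    dosage = np.where(u < p_hom_a, 0, np.where(u < p_hom_a + p_het, 1, 2))
    return dosage


def simulate_collection(cfg: SimulationConfig) -> tuple[Collection, TruthRecord]:
    """Generate a collection plus its truth record; deterministic given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m, K = cfg.n_accessions, cfg.n_markers, cfg.K

    plan = cfg.resolved_species_plan()
    accession_ids = [f"ACC{i + 1:05d}" for i in range(n)]
    species = []
    clusters = np.empty(n, dtype=int)
    pos = 0
    for sp_name, count, weights in plan:
        species.extend([sp_name] * count)
        clusters[pos : pos + count] = rng.choice(K, size=count, p=np.asarray(weights, float))
        pos += count

    # Balding-Nichols cluster allele frequencies around ancestral p
    p_anc = rng.uniform(0.1, 0.9, size=m)
    f_div = cfg.f_div_per_cluster()
    p_cluster = np.empty((K, m))
    for k in range(K):
        f = f_div[k]
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_cluster[k] = rng.beta(a, b)

    # genotype dosages (count of allele "B")
    dosage = np.empty((n, m), dtype=int)
    for i in range(n):
        p = p_cluster[clusters[i]]
        dosage[i] = _draw_biallelic(rng, p, cfg.f_is_for(species[i]))

    # hold-out multi-allelic markers
    ho_ids = [f"HOLD{j + 1:02d}" for j in range(cfg.n_holdout_markers)]
    ho_freq: list[np.ndarray] = []
    ho_alleles: list[list[str]] = []
    ho_geno = np.empty((n, cfg.n_holdout_markers, 2), dtype=int)
    lo, hi = cfg.holdout_allele_range
    mean_f = float(np.mean(f_div))
    for j in range(cfg.n_holdout_markers):
        n_all = int(rng.integers(lo, hi + 1))
        base = rng.dirichlet(np.ones(n_all) * 2.0)
        conc = base * (1 - mean_f) / mean_f
        freq = np.vstack([rng.dirichlet(conc) for _ in range(K)])
        ho_freq.append(freq)
        ho_alleles.append([f"a{a + 1:02d}" for a in range(n_all)])
        for i in range(n):
            pk = freq[clusters[i]]
            a1 = rng.choice(n_all, p=pk)
            if rng.random() < cfg.f_is_for(species[i]):
                a2 = a1  # identical by descent under inbreeding
            else:
                a2 = rng.choice(n_all, p=pk)
            ho_geno[i, j] = (a1, a2)

    # planted F1 hybrids: cross two non-hybrid accessions from different clusters
    n_hyb = int(round(cfg.hybrid_fraction * n))
    hybrid_flags = np.zeros(n, dtype=bool)
    hybrid_parents: dict[str, tuple[str, str]] = {}
    if n_hyb > 0:
        hyb_idx = rng.choice(n, size=n_hyb, replace=False)
        hybrid_flags[hyb_idx] = True
        non_hyb = np.flatnonzero(~hybrid_flags)
        cl_of = clusters[non_hyb]
        for i in hyb_idx:
            p1 = int(rng.choice(non_hyb))
            other = non_hyb[cl_of != clusters[p1]]
            if len(other) == 0:  # single-cluster collection: any other parent
                other = non_hyb[non_hyb != p1]
            p2 = int(rng.choice(other))
            # one gamete from each parent per marker
            g1 = np.where(dosage[p1] == 1, rng.integers(0, 2, m), dosage[p1] // 2)
            g2 = np.where(dosage[p2] == 1, rng.integers(0, 2, m), dosage[p2] // 2)
            dosage[i] = g1 + g2
            for j in range(cfg.n_holdout_markers):
                ho_geno[i, j, 0] = ho_geno[p1, j, rng.integers(0, 2)]
                ho_geno[i, j, 1] = ho_geno[p2, j, rng.integers(0, 2)]
            hybrid_parents[accession_ids[i]] = (accession_ids[p1], accession_ids[p2])
            clusters[i] = clusters[p1]  # traits follow the seed parent

    # missingness: i.i.d. per call, with a few bad samples at an elevated rate
    bad = rng.random(n) < cfg.bad_sample_fraction
    rate = np.where(bad, cfg.bad_sample_missing_rate, cfg.missing_rate)
    miss = rng.random((n, m)) < rate[:, None]
    ho_miss = rng.random((n, cfg.n_holdout_markers)) < rate[:, None]

    marker_ids = [f"SNP{j + 1:02d}" for j in range(m)]
    geno_calls = np.empty((n, m), dtype=object)
    pair = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}
    for i in range(n):
        for j in range(m):
            geno_calls[i, j] = None if miss[i, j] else pair[dosage[i, j]]
    ho_calls = np.empty((n, cfg.n_holdout_markers), dtype=object)
    for i in range(n):
        for j in range(cfg.n_holdout_markers):
            if ho_miss[i, j]:
                ho_calls[i, j] = None
            else:
                labels = ho_alleles[j]
                ho_calls[i, j] = normalize_call(labels[ho_geno[i, j, 0]], labels[ho_geno[i, j, 1]])

    genotypes = GenotypeMatrix(accession_ids, marker_ids, geno_calls)
    holdouts = (
        GenotypeMatrix(accession_ids, ho_ids, ho_calls) if cfg.n_holdout_markers else None
    )

    # traits
    phenotypes = None
    traits: list[TraitSpec] = []
    trait_means = None
    qual_probs: list[np.ndarray] = []
    n_traits = cfg.n_traits_quant + cfg.n_traits_qual
    if n_traits:
        values = np.empty((n, n_traits), dtype=object)
        # morphological measurements are positive with a nonzero baseline
        # (lengths, weights, days); cluster effects shift around it
        baselines = rng.uniform(*cfg.trait_baseline_range, size=cfg.n_traits_quant)
        trait_means = baselines[:, None] + rng.normal(
            0.0, cfg.trait_effect_sd, size=(cfg.n_traits_quant, K)
        )
        col = 0
        for t in range(cfg.n_traits_quant):
            name = f"qt{t + 1:02d}"
            traits.append(TraitSpec(name, "quantitative"))
            vals = trait_means[t, clusters] + rng.normal(0.0, cfg.trait_noise_sd, size=n)
            for i in range(n):
                values[i, col] = float(vals[i])
            col += 1
        for t in range(cfg.n_traits_qual):
            n_classes = int(rng.integers(3, 13))
            labels = [f"class_{c + 1}" for c in range(n_classes)]
            name = f"ql{t + 1:02d}"
            traits.append(TraitSpec(name, "qualitative", labels))
            base = rng.dirichlet(np.ones(n_classes))
            probs = np.vstack([rng.dirichlet(base * 3.0 + 0.1) for _ in range(K)])
            qual_probs.append(probs)
            for i in range(n):
                values[i, col] = labels[int(rng.choice(n_classes, p=probs[clusters[i]]))]
            col += 1
        t_miss = rng.random((n, n_traits)) < cfg.trait_missing_rate
        values[t_miss] = None
        phenotypes = PhenotypeTable(accession_ids, traits, values)

    origins = [f"country_{c + 1:02d}" for c in range(12)]
    origin_of_cluster = rng.choice(len(origins), size=K)
    passport = PassportTable(
        accession_ids,
        {a: species[i] for i, a in enumerate(accession_ids)},
        {
            a: origins[origin_of_cluster[clusters[i]]]
            if rng.random() > 0.1
            else "UNKNOWN"
            for i, a in enumerate(accession_ids)
        },
        {a: ("genebank_A" if rng.random() < 0.75 else "genebank_B") for a in accession_ids},
    )

    truth = TruthRecord(
        cluster={a: int(clusters[i]) for i, a in enumerate(accession_ids)},
        species={a: species[i] for i, a in enumerate(accession_ids)},
        hybrid={a: bool(hybrid_flags[i]) for i, a in enumerate(accession_ids)},
        hybrid_parents=hybrid_parents,
        allele_freq=p_cluster,  # (K, m): frequency of allele "A" per cluster
        ancestral_freq=p_anc,
        holdout_freq=ho_freq,
        trait_cluster_means=trait_means,
        qual_class_probs=qual_probs,
    )
    return Collection(genotypes, phenotypes, passport, holdouts), truth
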