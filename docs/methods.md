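# Methods

This note documents the models, statistics, conventions and numerical
choices behind `germcore`, and what the synthetic-data tests do and do
not show about real collections.

## The synthetic germplasm model

The generator (`germcore.simulate`) emulates the statistical shape of a
large selfing-crop genebank collection, not any particular dataset.

**Genotypes.** Each of K latent clusters diverges from a common ancestral
pool under the Balding–Nichols F-model: ancestral allele frequency
p<sub>m</sub> ~ Uniform(0.1, 0.9) per marker, and cluster frequency
p<sub>m,k</sub> ~ Beta(p<sub>m</sub>(1−F)/F, (1−p<sub>m</sub>)(1−F)/F), where the
divergence F (`F_div`, scalar or per-cluster) equals the expected
F<sub>ST</sub> of that cluster against the pool. Within a cluster,
genotypes follow inbreeding-adjusted proportions:
P(het) = 2pq(1−F<sub>IS</sub>), P(hom) = p² + pqF<sub>IS</sub>. `F_IS` may vary by
species; heavily selfing species get values near 0.7–0.8, which produces
the H<sub>O</sub> ≪ H<sub>E</sub> signature of such collections.

**Hybrids.** A fraction of accessions (default 0.145) are first-generation
crosses of two non-hybrid accessions from different clusters — one gamete
from each parent per marker — so they are strongly heterozygous when the
parental clusters are divergent. This is exactly the contaminant the QC
heterozygosity filter exists to catch.

**Missingness.** Calls are dropped i.i.d. (default 2%), except for a
small fraction of "bad DNA" samples (default 3% of accessions at a 25%
missing rate), which gives the high-missing filter something realistic
to remove. Missing values are never imputed anywhere in the package;
every statistic defines its own denominator over non-missing data.

**Traits.** Quantitative trait t in cluster k has mean
μ<sub>t,k</sub> = b<sub>t</sub> + N(0, `trait_effect_sd`²) with a per-trait baseline
b<sub>t</sub> ~ Uniform(5, 50), and accession values add N(0, `trait_noise_sd`²)
noise. The positive baseline is a deliberate departure from a pure
zero-mean cluster-effect model: morphological traits (lengths, weights,
days to flowering) are positive quantities, and the evaluation statistics
MD% and CV are relative measures that degenerate around a zero mean.
Qualitative traits draw from cluster-specific multinomials (Dirichlet
around a shared base), with 3–12 classes per trait.

**Hold-out markers.** A few multi-allelic markers (default 3, with 9–16
alleles) are generated from cluster-specific Dirichlet frequencies and
kept in a separate matrix on the `Collection`, so they can never leak
into selection; they exist purely for independent validation of a core.

**Default scale.** `default_paper_like_config()` is a desk-scale stand-in
for a multi-thousand-accession collection: 1,000 accessions, 48 biallelic
markers, K = 10 clusters with per-cluster divergence spanning 0.08–0.78,
one dominant species holding 88% of accessions plus ten minor species of
very unequal sizes (some singletons), 17 quantitative + 15 qualitative
traits, 14.5% planted F1s. One full pipeline run at this scale takes a
few seconds.

**What passing tests do not show.** Traits are cluster-linked only (no
per-locus genetic architecture, no trait–trait correlation beyond shared
cluster structure); there is no linkage or recombination map; admixture
is modelled at the species level (each accession belongs to one cluster),
not per accession. Recovery results on this generator therefore bound
what the pipeline can do under its own assumptions, not under real
admixed data.

## QC filters

Hybrid flag: per-accession H<sub>O</sub> (heterozygous / non-missing calls)
strictly greater than 0.3. High-missing flag: strictly more than 7
missing calls. Both inequalities are strict — boundary accessions are
retained — and the flags are independent, so the partition
`retained + hybrid-only + missing-only + both = total` always holds, and
the filter is idempotent on its own output. Using non-missing calls as
the H<sub>O</sub> denominator is an assumption (the alternative, dividing by
the panel size, would penalize missingness twice on top of the missing
filter).

## Diversity statistics

All computed from allele frequencies where each non-missing diploid call
contributes two copies:

* H<sub>E</sub> = 1 − Σp<sub>i</sub>² per marker — the plain gene-diversity form with
  no small-sample correction; group value is the unweighted mean over
  markers with data.
* PIC (Botstein form) = 1 − Σp<sub>i</sub>² − Σ<sub>i&lt;j</sub>2p<sub>i</sub>²p<sub>j</sub>²; always
  ≤ H<sub>E</sub>, with equality only when monomorphic.
* Shannon I = −Σf ln f (natural log throughout; 0·ln 0 := 0). For SNP
  markers the classes are the **observed genotype patterns** (A/A, A/B,
  B/B), not alleles; allele-level classes appear only in core selection.
  I<sub>max</sub> = ln(class count); J′ = I/I<sub>max</sub>.
* Per-cluster differentiation is the Wright-style proxy
  F<sub>ST,k</sub> = mean over polymorphic markers of (H<sub>T</sub> − H<sub>S,k</sub>)/H<sub>T</sub>,
  with H<sub>T</sub> from pooled frequencies. Negative estimates are reported,
  never clipped. Note the estimator's expectation carries the finite-deme
  factor (K−1)/K relative to the Balding–Nichols divergence, so recovery
  is assessed at K = 10 where the factor is mild.
* AMOVA decomposes squared pairwise dissimilarities: SS<sub>total</sub> =
  Σ<sub>i&lt;j</sub>d²<sub>ij</sub>/N, SS<sub>within</sub> analogously per group; variance
  components via the standard expected-mean-square equations with the
  unequal-size coefficient n₀; Φ<sub>ST</sub> = σ²<sub>among</sub>/(σ²<sub>among</sub>+σ²<sub>within</sub>);
  p = (1 + #{permuted Φ ≥ observed})/(n<sub>perm</sub> + 1) with label
  permutations (library default 999; the pipeline uses 199). Groups must
  have ≥ 2 members; the pipeline drops accessions in singleton tree-cut
  clusters before AMOVA and records how many.

## Distances, trees, ordination

Genotypes are encoded as per-allele dosages; the per-marker contribution
to a pair's distance is min(1, Σ<sub>alleles</sub>|Δdosage|/4) — for biallelic
markers this is |Δ minor dosage|/2 — and the dissimilarity is the mean
contribution over markers where **both** accessions are called (pairwise
deletion), keeping values in [0, 1] under missingness. A pair sharing no
marker is an error, not a guess.

Neighbor joining is classic Saitou–Nei (scikit-bio's implementation);
negative branch lengths are clamped to zero with a count retained on the
tree. UPGMA is SciPy average-linkage; the resulting dendrogram is
ultrametric with monotone merge heights and keeps its linkage matrix so
`cut_tree(k)` can undo exactly the k−1 highest merges (cuts are nested:
the k-cut refines the (k−1)-cut). NJ trees are unrooted and refuse
height-cutting. Determinism: with continuous dissimilarities, linkage
ties have probability zero; SciPy's internal deterministic ordering
handles exact ties. PCoA is classical metric scaling (double-centred
−½D², eigendecomposition); only positive eigenvalues are kept and
percentages are relative to their sum.

Stratification clusters for core selection come from UPGMA tree cutting;
externally supplied labels (e.g. from a model-based structure analysis)
can be substituted anywhere a cluster mapping is accepted.

## Core selection (M strategy)

Selection maximizes the number of distinct classes retained:

* marker variables contribute one class per observed allele; a
  heterozygote carries both (so 48 biallelic markers yield 96 classes);
* qualitative traits contribute their observed categories;
* quantitative traits are discretized by Sturges' rule,
  k = ⌈1 + log₂ n⌉ equal-width bins over [min, max], with internal-edge
  values assigned to the lower bin and the maximum to the top bin; bins
  are recomputed within each stratum for stratified strategies, since a
  per-cluster run sees only its own data;
* missing values carry no class; unobserved classes are pruned.

The selector is greedy maximum coverage: repeatedly take the accession
carrying the most uncovered classes; break ties first by the largest sum
of 1/(carrier count) over its uncovered classes (preferring rare-class
carriers), then by lexicographic accession id; stop when everything is
covered; then revisit selections in order and drop any made redundant.
Full coverage is enforced unconditionally — core size is an output. The
published tool this emulates describes its heuristic only qualitatively,
so this deterministic variant is validated instead against an exhaustive
minimum-set-cover oracle on small instances (coverage always 100%, size
within +1 of the optimum on ≤ 12 × 10 instances).

The five strategies differ only in variable basis and stratification:
Gcc (genotype, whole collection), Ggcc (genotype, per cluster),
Pcc (phenotype), G+Pcc (both), Gg+Pcc (both, per cluster). Stratified
cores are deduplicated unions with first-cluster provenance.

## Evaluation

Continuous block over m usable quantitative traits (entire = e, core = c):

* MD% = (100/m)Σ|M<sub>e</sub> − M<sub>c</sub>|/|M<sub>e</sub>|, VD% = (100/m)Σ|V<sub>e</sub> − V<sub>c</sub>|/V<sub>e</sub>,
  CR% = (100/m)ΣR<sub>c</sub>/R<sub>e</sub>, VR% = (100/m)ΣCV<sub>c</sub>/CV<sub>e</sub>,
  with sample variance (n−1) and CV = sd/mean·100. Traits with a zero
  denominator are skipped (warned) and excluded from m. These are
  relative-difference forms; a variant counting significant Welch-t /
  Levene tests is available (`md_form="ttest"`) for comparability with
  the older literature. Verdict: representative iff MD% < 20 and CR% > 80.
* MD% and VD% are invariant to positive rescaling of a trait; CR% and
  VR%'s range/CV ratios cancel scale as well (CV, hence VR%, is not
  shift-invariant — that is a property of CV, not a defect).
* A full-coverage core must contain an accession in each outer Sturges
  bin of each trait, so per-trait CR ≥ 100·(k−2)/k is guaranteed (k =
  bin count); the extremes themselves need not be selected, so CR = 100
  is not. At n ≈ 850 (k = 11) realized CR is typically 90–95%.

Categorical block: per-variable Shannon I over markers (genotype-pattern
classes) and qualitative traits. I<sub>max</sub> is fixed at the
entire-collection class count for both core and entire, making J′
directly comparable (a core can legitimately score J′ above the entire
collection by evening out skewed class frequencies). The hold-out-marker
validation instead uses each column's own observed pattern count as its
I<sub>max</sub> (per-column convention); both conventions are implemented and
labelled.

Report rounding is half-up to 2 decimals for display; internal values
keep full precision.

## Problem sizes and seeds

Simulation-based checks use: F<sub>ST</sub> recovery at n = 800, 48 markers,
K = 10, F = 0.2, 3 seeds (tolerance ±0.05); cluster recovery at n = 300,
K = 5, F = 0.5 (Adjusted Rand ≥ 0.9); hybrid recall at n = 400, 5%
planted F1s, F = 0.5 (recall ≥ 0.9); AMOVA null calibration with 200
random labelings of 30 structureless points at 99 permutations each
(KS test of p-value uniformity at α = 0.01); and the five-strategy
comparison on five seeds of the 1,000-accession default collection.
All randomness flows from explicit integer seeds; rerunning any stage
with the same config and seed is bit-identical.

## Known limitations

* The greedy selector is a heuristic: on adversarial instances it can
  exceed the minimum core size (observed ≤ +1 on small instances, no
  guarantee at scale).
* The per-cluster F<sub>ST</sub> proxy is not comparable to model-based
  (Bayesian admixture) per-cluster divergences; values from such tools
  should not be expected to match numerically.
* Tree-cut clusters at small k can isolate single outlier accessions;
  downstream stages handle singletons explicitly (selection keeps the
  sole accession; AMOVA drops it).
* VCF import reads GT fields only and treats contig:pos as an opaque
  marker id; no coordinate arithmetic is done anywhere.
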