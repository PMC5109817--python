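import numpy as np
import pytest

from germcore import (
    DissimilarityMatrix,
    cut_tree,
    export_newick,
    manhattan_dissimilarity,
    nj_tree,
    pcoa,
    read_newick,
    upgma_tree,
)
from conftest import make_genotypes
import oracles


def _dm(d: np.ndarray, ids=None) -> DissimilarityMatrix:
    n = d.shape[0]
    ids = ids or [f"t{i}" for i in range(n)]
    return DissimilarityMatrix(ids, d, np.full((n, n), 1))


def _patristic(tree) -> dict[tuple[str, str], float]:
    tips = list(tree.root.tips())
    out = {}
    dm = tree.root.tip_tip_distances()
    for i, a in enumerate(dm.ids):
        for j, b in enumerate(dm.ids):
            if i < j:
                out[tuple(sorted((a, b)))] = dm[i, j]
    return out


# ---------------------------------------------------------------------------
# Manhattan dissimilarity


def test_identical_accessions_zero():
    g = make_genotypes({"a": ["A/A", "A/B"], "b": ["A/A", "A/B"]})
    D = manhattan_dissimilarity(g)
    assert D.d[0, 1] == 0.0


def test_opposite_homozygotes_one():
    g = make_genotypes({"a": ["A/A", "A/A"], "b": ["B/B", "B/B"]})
    D = manhattan_dissimilarity(g)
    assert D.d[0, 1] == 1.0


def test_half_step_at_one_of_two_markers():
    g = make_genotypes({"a": ["A/A", "A/A"], "b": ["A/B", "A/A"]})
    D = manhattan_dissimilarity(g)
    assert D.d[0, 1] == pytest.approx(0.25)


def test_pairwise_deletion_normalization():
    g = make_genotypes({"a": ["A/A", None], "b": ["B/B", "A/A"]})
    D = manhattan_dissimilarity(g)
    assert D.d[0, 1] == pytest.approx(1.0)  # only marker 1 shared
    assert D.n_shared[0, 1] == 1


def test_disjoint_missingness_rejected():
    g = make_genotypes({"a": ["A/A", None], "b": [None, "A/A"]})
    with pytest.raises(ValueError, match="share no non-missing"):
        manhattan_dissimilarity(g)


def test_multiallelic_contribution_capped():
    g = make_genotypes({"a": ["x/x"], "b": ["y/z"]})
    D = manhattan_dissimilarity(g)
    # dosage diff |2-0| + |0-1| + |0-1| = 4 -> 4/4 = 1.0
    assert D.d[0, 1] == pytest.approx(1.0)


def test_triangle_inequality_on_simulated_data(sim_small):
    coll, _ = sim_small
    sub = coll.genotypes.subset(accession_ids=coll.accession_ids[:40])
    D = manhattan_dissimilarity(sub)
    d = D.d
    n = d.shape[0]
    rng = np.random.default_rng(0)
    for _ in range(300):
        i, j, k = rng.choice(n, 3, replace=False)
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_recovers_four_taxon_tree_exactly():
    """Additive matrix from a known quartet: ((a:1,b:2):5,(c:3,d:4))."""
    d = np.array(
        [
            [0.0, 3.0, 9.0, 10.0],
            [3.0, 0.0, 10.0, 11.0],
            [9.0, 10.0, 0.0, 7.0],
            [10.0, 11.0, 7.0, 0.0],
        ]
    )
    t = nj_tree(_dm(d, ["a", "b", "c", "d"]))
    pat = _patristic(t)
    assert pat[("a", "b")] == pytest.approx(3.0, abs=1e-9)
    assert pat[("a", "c")] == pytest.approx(9.0, abs=1e-9)
    assert pat[("c", "d")] == pytest.approx(7.0, abs=1e-9)
    assert pat[("b", "d")] == pytest.approx(11.0, abs=1e-9)


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    t = nj_tree(_dm(d, ["a", "b", "c"]))
    pat = _patristic(t)
    assert pat[("a", "b")] == pytest.approx(3.0, abs=1e-9)
    assert pat[("a", "c")] == pytest.approx(4.0, abs=1e-9)
    assert pat[("b", "c")] == pytest.approx(5.0, abs=1e-9)


def test_nj_consistency_vs_topology_enumeration():
    """On random additive matrices (5-6 taxa) NJ reproduces the input
    distances exactly, and exhaustive least-squares over all unrooted
    topologies confirms a zero-residual fit exists and matches."""
    rng = np.random.default_rng(7)
    for n in (5, 6):
        for _ in range(3):
            D, edges, lengths = oracles.random_additive_matrix(n, rng)
            ids = [f"t{i}" for i in range(n)]
            t = nj_tree(_dm(D, ids))
            pat = _patristic(t)
            for i in range(n):
                for j in range(i + 1, n):
                    assert pat[tuple(sorted((ids[i], ids[j])))] == pytest.approx(
                        D[i, j], abs=1e-8
                    )
            best = min(
                oracles.ls_fit(e, D)[0] for e in oracles.enumerate_topologies(n)
            )
            assert best == pytest.approx(0.0, abs=1e-16)


def test_nj_input_order_invariance():
    rng = np.random.default_rng(1)
    D, _, _ = oracles.random_additive_matrix(6, rng)
    ids = [f"t{i}" for i in range(6)]
    t1 = nj_tree(_dm(D, ids))
    perm = [3, 0, 5, 1, 4, 2]
    Dp = D[np.ix_(perm, perm)]
    t2 = nj_tree(_dm(Dp, [ids[i] for i in perm]))
    assert _patristic(t1) == pytest.approx(_patristic(t2), abs=1e-9)


def test_nj_needs_three_and_finite():
    with pytest.raises(ValueError):
        nj_tree(_dm(np.zeros((2, 2))))
    d = np.full((3, 3), np.nan)
    np.fill_diagonal(d, 0)
    with pytest.raises(ValueError, match="finite"):
        nj_tree(_dm(d))


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_two_taxa_height():
    d = np.array([[0.0, 0.4], [0.4, 0.0]])
    t = upgma_tree(_dm(d, ["a", "b"]))
    depths = {tip.name: tip.accumulate_to_ancestor(t.root) for tip in t.root.tips()}
    assert depths["a"] == pytest.approx(0.2)
    assert depths["b"] == pytest.approx(0.2)


def test_upgma_is_ultrametric_and_recovers_ultrametric_input(sim_small):
    rng = np.random.default_rng(5)
    # random dendrogram -> ultrametric distances -> exact recovery
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    n = 12
    pts = rng.random((n, 4))
    Z = hierarchy.linkage(pts, method="average")
    ultra = hierarchy.cophenet(Z)
    D = squareform(ultra)
    t = upgma_tree(_dm(D))
    pat = _patristic(t)
    ids = [f"t{i}" for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            assert pat[tuple(sorted((ids[i], ids[j])))] == pytest.approx(
                D[i, j], abs=1e-9
            )
    # ultrametricity: equal root-to-tip depth
    depths = [tip.accumulate_to_ancestor(t.root) for tip in t.root.tips()]
    assert max(depths) - min(depths) < 1e-9


def test_upgma_merge_heights_monotone(sim_small):
    coll, _ = sim_small
    sub = coll.genotypes.subset(accession_ids=coll.accession_ids[:30])
    t = upgma_tree(manhattan_dissimilarity(sub))
    heights = t.linkage[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)


# ---------------------------------------------------------------------------
# tree cutting


def test_cut_tree_extremes(sim_small):
    coll, _ = sim_small
    sub = coll.genotypes.subset(accession_ids=coll.accession_ids[:20])
    t = upgma_tree(manhattan_dissimilarity(sub))
    assert set(cut_tree(t, 1).labels.values()) == {1}
    singletons = cut_tree(t, 20)
    assert sorted(singletons.labels.values()) == list(range(1, 21))


def test_cut_refines_previous_cut(sim_small):
    coll, _ = sim_small
    sub = coll.genotypes.subset(accession_ids=coll.accession_ids[:40])
    t = upgma_tree(manhattan_dissimilarity(sub))
    prev = cut_tree(t, 3).labels
    cur = cut_tree(t, 4).labels
    # every k=4 cluster maps into exactly one k=3 cluster
    mapping = {}
    for a, c in cur.items():
        mapping.setdefault(c, set()).add(prev[a])
    assert all(len(v) == 1 for v in mapping.values())


def test_cut_tree_rejects_nj(sim_small):
    coll, _ = sim_small
    sub = coll.genotypes.subset(accession_ids=coll.accession_ids[:10])
    t = nj_tree(manhattan_dissimilarity(sub))
    with pytest.raises(ValueError, match="UPGMA"):
        cut_tree(t, 3)


def test_cut_recovers_simulated_clusters():
    """UPGMA cut at the true K recovers clusters (ARI >= 0.9, F_div=0.5)."""
    from sklearn.metrics import adjusted_rand_score

    from germcore import SimulationConfig, simulate_collection

    cfg = SimulationConfig(
        n_accessions=300, K=5, F_div=0.5, hybrid_fraction=0.0,
        missing_rate=0.0, bad_sample_fraction=0.0, seed=1,
    )
    coll, truth = simulate_collection(cfg)
    D = manhattan_dissimilarity(coll.genotypes)
    ca = cut_tree(upgma_tree(D), 5)
    ari = adjusted_rand_score(
        [truth.cluster[a] for a in coll.accession_ids],
        [ca.labels[a] for a in coll.accession_ids],
    )
    assert ari >= 0.9


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_collinear_points_single_axis():
    d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    res = pcoa(_dm(d), n_axes=1)
    assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-6)


def test_pcoa_recovers_planar_configuration():
    rng = np.random.default_rng(0)
    pts = rng.random((10, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    res = pcoa(_dm(d), n_axes=2)
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(pts, res.coordinates)
    assert disparity < 1e-18


def test_pcoa_matches_pca_on_euclidean_embedding(sim_small):
    """PCoA of Euclidean distances of dosage-like vectors has the same
    positive eigenspectrum as PCA of those vectors."""
    rng = np.random.default_rng(2)
    X = rng.integers(0, 3, size=(15, 8)).astype(float)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    res = pcoa(_dm(d), n_axes=5)
    Xc = X - X.mean(axis=0)
    eig_pca = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
    eig_pca = eig_pca[eig_pca > 1e-9]
    pct_pca = 100.0 * eig_pca[:5] / eig_pca.sum()
    np.testing.assert_allclose(res.pct_variance, pct_pca, atol=1e-9)


def test_pcoa_pct_variance_non_increasing(sim_small):
    coll, _ = sim_small
    sub = coll.genotypes.subset(accession_ids=coll.accession_ids[:50])
    res = pcoa(manhattan_dissimilarity(sub), n_axes=5)
    assert np.all(np.diff(res.pct_variance) <= 1e-12)


def test_pcoa_truncates_beyond_rank():
    d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
    with pytest.warns(UserWarning, match="truncated"):
        res = pcoa(_dm(d), n_axes=3)
    assert res.coordinates.shape[1] < 3


# ---------------------------------------------------------------------------
# Newick round trip


def test_newick_round_trip(tmp_path, sim_small):
    coll, _ = sim_small
    sub = coll.genotypes.subset(accession_ids=coll.accession_ids[:12])
    t = upgma_tree(manhattan_dissimilarity(sub))
    path = tmp_path / "t.nwk"
    export_newick(t, path)
    back = read_newick(path)
    assert sorted(x.name for x in back.tips()) == sorted(
        x.name for x in t.root.tips()
    )
    orig = t.root.tip_tip_distances()
    re = back.tip_tip_distances(endpoints=list(orig.ids))
    np.testing.assert_allclose(orig.data, re.data, atol=1e-6)
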