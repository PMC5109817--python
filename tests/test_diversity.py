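import numpy as np
import pytest

from germcore import (
    SimulationConfig,
    allele_frequencies,
    amova,
    expected_het,
    fst_per_cluster,
    group_diversity,
    i_max,
    marker_shannon,
    merge_collection,
    observed_het,
    pic,
    pielou_evenness,
    shannon_index,
    simulate_collection,
)
from germcore.distance import DissimilarityMatrix
from germcore.model import UndefinedValueError
from conftest import make_genotypes
import oracles


def test_allele_frequencies_count_copies():
    g = make_genotypes({"a1": ["A/A"], "a2": ["A/B"]})
    f = allele_frequencies(g)
    assert f.freqs["m1"] == {"A": 0.75, "B": 0.25}
    assert f.n_copies["m1"] == 4


def test_all_missing_marker_flagged_absent():
    g = make_genotypes({"a1": [None, "A/A"], "a2": [None, "A/B"]})
    f = allele_frequencies(g)
    assert f.absent_markers() == ["m1"]
    assert f.freqs["m1"] == {}


def test_empty_subset_rejected():
    g = make_genotypes({"a1": ["A/A"]})
    with pytest.raises(ValueError):
        allele_frequencies(g, [])


@pytest.mark.parametrize(
    "calls,expected_he",
    [({"a": ["A/A"], "b": ["A/A"]}, 0.0),
     ({"a": ["A/A"], "b": ["B/B"]}, 0.5),
     # p(A) = (2 + 4)/20 = 0.3 -> H_E = 1 - 0.09 - 0.49 = 0.42
     ({"a": ["A/A"], "b": ["A/B"], "c": ["A/B"], "d": ["A/B"], "e": ["A/B"],
       "f": ["B/B"], "g": ["B/B"], "h": ["B/B"], "i": ["B/B"], "j": ["B/B"]}, 0.42)],
)
def test_expected_het_closed_forms(calls, expected_he):
    g = make_genotypes(calls)
    _, he = expected_het(allele_frequencies(g))
    assert he == pytest.approx(expected_he, abs=1e-12)


def test_observed_het_counts():
    g = make_genotypes({f"a{i}": ["A/B"] if i < 3 else ["A/A"] for i in range(10)})
    per, mean = observed_het(g)
    assert per["m1"] == pytest.approx(0.3)
    assert mean == pytest.approx(0.3)


def test_pic_closed_forms():
    g = make_genotypes({"a": ["A/A"], "b": ["B/B"]})  # p = (0.5, 0.5)
    _, val = pic(allele_frequencies(g))
    assert val == pytest.approx(0.375, abs=1e-12)
    g2 = make_genotypes({"a": ["A/A"], "b": ["A/A"]})  # monomorphic
    _, val2 = pic(allele_frequencies(g2))
    assert val2 == pytest.approx(0.0, abs=1e-12)


def test_pic_never_exceeds_expected_het():
    rng = np.random.default_rng(0)
    for _ in range(2000):
        k = int(rng.integers(2, 8))
        p = rng.dirichlet(np.ones(k))
        he = 1 - np.sum(p**2)
        p2 = p**2
        picv = he - (np.sum(np.outer(p2, p2)) - np.sum(p2**2))
        assert picv <= he + 1e-12


@pytest.mark.parametrize(
    "freqs,expected",
    [([1 / 9] * 9, np.log(9)), ([1.0], 0.0), ([0.5, 0.25, 0.25], 1.0397)],
)
def test_shannon_index_values(freqs, expected):
    assert shannon_index(freqs) == pytest.approx(expected, abs=1e-4)


def test_i_max_and_evenness():
    assert i_max(9) == pytest.approx(2.1972, abs=1e-4)
    assert i_max(16) == pytest.approx(2.7726, abs=1e-4)
    assert i_max(1) == 0.0
    assert pielou_evenness(shannon_index([0.25] * 4), 4) == pytest.approx(1.0)
    with pytest.raises(UndefinedValueError):
        pielou_evenness(0.0, 1)


def test_brute_force_equivalence_on_tiny_matrices():
    """Every statistic matches direct enumeration on <=5x4 instances."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        n = int(rng.integers(2, 6))
        m = int(rng.integers(1, 5))
        rows = {}
        for i in range(n):
            calls = []
            for j in range(m):
                if rng.random() < 0.15:
                    calls.append(None)
                else:
                    a = rng.choice(["A", "B", "C"])
                    b = rng.choice(["A", "B", "C"])
                    calls.append(f"{a}/{b}")
            rows[f"acc{i}"] = calls
        g = make_genotypes(rows)
        freqs = allele_frequencies(g)
        he_per, _ = expected_het(freqs)
        ho_per, _ = observed_het(g)
        pic_per, _ = pic(freqs)
        sh_per, _ = marker_shannon(g)
        for j, mid in enumerate(g.marker_ids):
            col = [g.calls[i, j] for i in range(n)]
            if all(c is None for c in col):
                assert mid not in he_per
                continue
            bf = oracles.brute_allele_freqs(col)
            for a, f in bf.items():
                assert freqs.freqs[mid][a] == pytest.approx(f, abs=1e-12)
            assert he_per[mid] == pytest.approx(oracles.brute_expected_het(bf), abs=1e-12)
            assert ho_per[mid] == pytest.approx(oracles.brute_observed_het(col), abs=1e-12)
            assert pic_per[mid] == pytest.approx(oracles.brute_pic(bf), abs=1e-12)
            assert sh_per[mid] == pytest.approx(
                oracles.brute_shannon(oracles.brute_genotype_pattern_freqs(col)),
                abs=1e-12,
            )


def test_statistics_invariant_to_ordering():
    rows = {"a1": ["A/A", "A/B"], "a2": ["A/B", None], "a3": ["B/B", "A/A"]}
    g1 = make_genotypes(rows)
    g2 = make_genotypes({k: rows[k] for k in ["a3", "a1", "a2"]})
    _, he1 = expected_het(allele_frequencies(g1))
    _, he2 = expected_het(allele_frequencies(g2))
    assert he1 == pytest.approx(he2, abs=1e-15)
    _, ho1 = observed_het(g1)
    _, ho2 = observed_het(g2)
    assert ho1 == pytest.approx(ho2, abs=1e-15)


def test_estimated_frequencies_recover_truth(sim_small):
    """Estimated allele frequencies fall within 3 binomial SE of truth."""
    coll, truth = sim_small
    g = coll.genotypes
    for k in range(truth.allele_freq.shape[0]):
        ids = [
            a for a in g.accession_ids
            if truth.cluster[a] == k and not truth.hybrid[a]
        ]
        if len(ids) < 10:
            continue
        freqs = allele_frequencies(g, ids)
        outside = 0
        checked = 0
        for j, mid in enumerate(g.marker_ids):
            p_true = truth.allele_freq[k, j]
            n_copies = freqs.n_copies[mid]
            if n_copies == 0:
                continue
            # inbred allele copies are correlated within an accession:
            # effective draws lie between n_copies/2 and n_copies
            se = np.sqrt(p_true * (1 - p_true) / (n_copies / 2))
            p_hat = freqs.freqs[mid].get("A", 0.0)
            checked += 1
            outside += abs(p_hat - p_true) > 3 * se
        assert outside <= max(1, 0.05 * checked)


def test_wahlund_effect_within_vs_total(sim_small):
    coll, truth = sim_small
    non_hyb = [a for a in coll.accession_ids if not truth.hybrid[a]]
    g = coll.genotypes.subset(accession_ids=non_hyb)
    _, he_total = expected_het(allele_frequencies(g))
    within = []
    for k in set(truth.cluster.values()):
        ids = [a for a in non_hyb if truth.cluster[a] == k]
        if len(ids) < 5:
            continue
        _, he_k = expected_het(allele_frequencies(g, ids))
        within.append(he_k)
    assert np.mean(within) < he_total


def test_group_diversity_species_rows(sim_small):
    coll, _ = sim_small
    rows = group_diversity(coll, "total")
    assert rows[-1].label == "total"
    assert rows[-1].n == coll.genotypes.n_accessions
    assert 0 <= rows[-1].H_O <= 1 and 0 <= rows[-1].H_E <= 1
    assert rows[-1].PIC <= rows[-1].H_E
    assert rows[-1].I <= rows[-1].I_max


def test_single_accession_group():
    g = make_genotypes({"a1": ["A/B", "A/A"], "a2": ["A/A", "B/B"]})
    coll = merge_collection(g)
    from germcore.diversity import _summarize_group

    s = _summarize_group("solo", g, ["a1"])
    assert s.n == 1
    assert s.H_E == pytest.approx(0.25)  # mean of 0.5 (het marker) and 0
    assert s.I >= 0


def test_fst_complete_differentiation_and_identity():
    g = make_genotypes(
        {"a1": ["A/A"], "a2": ["A/A"], "b1": ["B/B"], "b2": ["B/B"]}
    )
    s = fst_per_cluster(g, {"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    assert s.F_ST["1"] == pytest.approx(1.0)
    assert s.F_ST["2"] == pytest.approx(1.0)

    g2 = make_genotypes(
        {"a1": ["A/A"], "a2": ["B/B"], "b1": ["A/A"], "b2": ["B/B"]}
    )
    s2 = fst_per_cluster(g2, {"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    assert s2.F_ST["1"] == pytest.approx(0.0, abs=1e-12)

    mono = make_genotypes({"a1": ["A/A"], "b1": ["A/A"]})
    with pytest.raises(ValueError, match="monomorphic"):
        fst_per_cluster(mono, {"a1": 1, "b1": 2})


def test_fst_parameter_recovery():
    for seed in (1, 2, 3):
        cfg = SimulationConfig(
            n_accessions=800, K=10, F_div=0.2, hybrid_fraction=0.0,
            missing_rate=0.0, bad_sample_fraction=0.0, seed=seed,
        )
        coll, truth = simulate_collection(cfg)
        s = fst_per_cluster(coll.genotypes, truth.cluster)
        assert float(np.mean(list(s.F_ST.values()))) == pytest.approx(0.2, abs=0.05)


# ---------------------------------------------------------------------------
# AMOVA


def _point_cloud_distance(points: np.ndarray) -> DissimilarityMatrix:
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    return DissimilarityMatrix([f"s{i}" for i in range(n)], d, np.full((n, n), 1))


def test_amova_two_point_clouds_all_among():
    pts = np.array([[0.0, 0.0]] * 4 + [[3.0, 4.0]] * 4)
    D = _point_cloud_distance(pts)
    labels = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(8)}
    res = amova(D, labels, n_perm=99, seed=0)
    assert res.pct_among == pytest.approx(100.0)
    assert res.sigma2_within == pytest.approx(0.0, abs=1e-12)


def test_amova_percentages_sum_to_100():
    rng = np.random.default_rng(0)
    pts = rng.random((20, 3))
    D = _point_cloud_distance(pts)
    labels = {f"s{i}": i % 3 for i in range(20)}
    res = amova(D, labels, n_perm=49, seed=1)
    assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)
    assert 0 < res.p_perm <= 1


def test_amova_null_phi_near_zero_and_p_uniform():
    """Random labels on structureless data: Phi ~ 0 on average and the
    permutation p-value is uniform (KS at alpha = 0.01, 200 replicates)."""
    from scipy import stats

    rng = np.random.default_rng(3)
    pts = rng.random((30, 5))
    D = _point_cloud_distance(pts)
    pvals = []
    phis = []
    for rep in range(200):
        labels = {f"s{i}": int(v) for i, v in enumerate(rng.integers(0, 3, 30))}
        if min(np.bincount(list(labels.values()), minlength=3)) < 2:
            continue
        res = amova(D, labels, n_perm=99, seed=int(rng.integers(2**31)))
        pvals.append(res.p_perm)
        phis.append(res.phi_st)
    assert abs(float(np.mean(phis))) < 0.05
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_amova_degenerate_clusters_rejected():
    pts = np.arange(6, dtype=float)[:, None]
    D = _point_cloud_distance(pts)
    with pytest.raises(ValueError, match="size < 2"):
        amova(D, {f"s{i}": (0 if i else 1) for i in range(6)}, n_perm=9)
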