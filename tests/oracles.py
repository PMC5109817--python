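"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct enumeration and closed
forms with plain Python loops — and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# diversity statistics by direct enumeration
# genotypes given as {accession: [call, ...]} with call = (a, b) or None


def brute_allele_freqs(column):
    counts = {}
    for call in column:
        if call is None:
            continue
        for a in call:
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()} if total else {}


def brute_expected_het(freqs):
    return 1.0 - sum(p * p for p in freqs.values())


def brute_observed_het(column):
    calls = [c for c in column if c is not None]
    return sum(1 for c in calls if c[0] != c[1]) / len(calls)


def brute_pic(freqs):
    p = list(freqs.values())
    s = 1.0 - sum(x * x for x in p)
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            s -= 2.0 * p[i] ** 2 * p[j] ** 2
    return s


def brute_shannon(freqs):
    return -sum(f * math.log(f) for f in freqs if f > 0)


def brute_genotype_pattern_freqs(column):
    counts = {}
    n = 0
    for call in column:
        if call is None:
            continue
        n += 1
        counts[call] = counts.get(call, 0) + 1
    return [c / n for c in counts.values()]


# ---------------------------------------------------------------------------
# exhaustive minimum set cover


def min_cover_size(sets: list[set]) -> int:
    """Smallest number of sets whose union equals the union of all sets."""
    universe = set().union(*sets)
    for size in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), size):
            if set().union(*(sets[i] for i in combo)) == universe:
                return size
    raise AssertionError("unreachable: the full family always covers")


# ---------------------------------------------------------------------------
# unrooted tree topologies + least-squares branch fitting


def enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies on leaves 0..n-1, as edge lists.

    Internal nodes are negative ints.  3 leaves -> 1 topology, 4 -> 3,
    5 -> 15, 6 -> 105.
    """
    base = [(0, -1), (1, -1), (2, -1)]
    tops = [base]
    next_internal = -2
    for leaf in range(3, n_leaves):
        new_tops = []
        for edges in tops:
            for idx, (u, v) in enumerate(edges):
                w = next_internal
                ne = edges[:idx] + edges[idx + 1 :] + [(u, w), (w, v), (leaf, w)]
                new_tops.append(ne)
        tops = new_tops
        next_internal -= 1
    return tops


def _paths(edges, n_leaves):
    adj = {}
    for e, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, e))
        adj.setdefault(v, []).append((u, e))

    def path_edges(src, dst):
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, acc = stack.pop()
            if node == dst:
                return acc
            for nxt, e in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, acc + [e]))
        raise AssertionError("disconnected tree")

    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    for r, (i, j) in enumerate(pairs):
        for e in path_edges(i, j):
            A[r, e] = 1.0
    return pairs, A


def ls_fit(edges, D: np.ndarray):
    """Least-squares branch lengths for a fixed topology; returns
    (rss, fitted tip-distance matrix)."""
    n = D.shape[0]
    pairs, A = _paths(edges, n)
    d = np.array([D[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    fit = A @ x
    rss = float(np.sum((fit - d) ** 2))
    F = np.zeros_like(D)
    for (i, j), v in zip(pairs, fit):
        F[i, j] = F[j, i] = v
    return rss, F


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Patristic distances of a random binary tree with branch lengths
    in [0.1, 1.0]; returns (D, edges, lengths)."""
    tops = None
    # random topology by random leaf addition
    edges = [(0, -1), (1, -1), (2, -1)]
    next_internal = -2
    for leaf in range(3, n_leaves):
        idx = int(rng.integers(len(edges)))
        u, v = edges.pop(idx)
        w = next_internal
        edges += [(u, w), (w, v), (leaf, w)]
        next_internal -= 1
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    pairs, A = _paths(edges, n_leaves)
    d = A @ lengths
    D = np.zeros((n_leaves, n_leaves))
    for (i, j), v in zip(pairs, d):
        D[i, j] = D[j, i] = v
    return D, edges, lengths
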