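"""Shared fixtures and independent brute-force oracles.

The oracles reimplement the scoring definitions with plain Python loops and
hand-rolled ranking, deliberately sharing no code with the package, so tests
compare two independent routes to the same numbers.
"""

import numpy as np
import pytest

from evotsp import ExpressionMatrix, LabelVector


def make_random_dataset(p, m, seed, m1=None):
    """Random tie-free dataset with P genes, M samples, two classes."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=(p, m))
    m1 = m // 2 if m1 is None else m1
    labels = LabelVector(("A",) * m1 + ("B",) * (m - m1), ("A", "B"))
    gene_ids = tuple(f"g{k}" for k in range(p))
    sample_ids = tuple(f"s{k}" for k in range(m))
    return ExpressionMatrix(values, gene_ids, sample_ids), labels


@pytest.fixture
def toy5():
    """Hand-checkable 2-gene dataset: C1 samples (1,2),(3,4),(5,1); C2 (2,1),(4,3).

    Indicator x_0 < x_1 fires in 2 of 3 C1 samples and 0 of 2 C2 samples,
    so p1 = 2/3, p2 = 0, Δ = 2/3.
    """
    values = np.array([[1.0, 3.0, 5.0, 2.0, 4.0],
                       [2.0, 4.0, 1.0, 1.0, 3.0]])
    expr = ExpressionMatrix(values, ("gi", "gj"),
                            ("s1", "s2", "s3", "s4", "s5"))
    labels = LabelVector(("A", "A", "A", "B", "B"), ("A", "B"))
    return expr, labels


# ---------------------------------------------------------------- oracles

def oracle_pair_probabilities(values, y, i, j):
    n1 = d1 = n2 = d2 = 0
    for m in range(values.shape[1]):
        hit = 1 if values[i, m] < values[j, m] else 0
        if y[m] == 0:
            n1 += hit
            d1 += 1
        else:
            n2 += hit
            d2 += 1
    return n1 / d1, n2 / d2


def oracle_average_ranks(column):
    """Average ranks (1-based, ties averaged) of one sample's values."""
    order = sorted(range(len(column)), key=lambda g: column[g])
    ranks = [0.0] * len(column)
    pos = 0
    while pos < len(order):
        stop = pos
        while stop + 1 < len(order) and column[order[stop + 1]] == column[order[pos]]:
            stop += 1
        avg = (pos + stop) / 2 + 1
        for t in range(pos, stop + 1):
            ranks[order[t]] = avg
        pos = stop + 1
    return ranks


def oracle_secondary(values, y, i, j):
    diffs = {0: [], 1: []}
    for m in range(values.shape[1]):
        ranks = oracle_average_ranks(values[:, m])
        diffs[y[m]].append(ranks[i] - ranks[j])
    mean = lambda xs: sum(xs) / len(xs)
    return abs(mean(diffs[0]) - mean(diffs[1]))


def oracle_all_pair_deltas(values, y):
    """{(i, j): Δ} for all i < j via the plain double loop."""
    out = {}
    for i in range(values.shape[0]):
        for j in range(i + 1, values.shape[0]):
            p1, p2 = oracle_pair_probabilities(values, y, i, j)
            out[(i, j)] = abs(p1 - p2)
    return out


def oracle_best_pair(values, y, gene_ids):
    """Arg-max pair by (Δ, secondary, lexicographic id), fully enumerated."""
    best = None
    for i in range(values.shape[0]):
        for j in range(i + 1, values.shape[0]):
            p1, p2 = oracle_pair_probabilities(values, y, i, j)
            ids = sorted((gene_ids[i], gene_ids[j]))
            key = (-round(abs(p1 - p2), 12),
                   -round(oracle_secondary(values, y, i, j), 9),
                   ids[0], ids[1])
            if best is None or key < best[0]:
                best = (key, (i, j))
    return best[1]


def oracle_tst_best(values, y):
    """Full TST enumeration: best (score, triplet) over all gene triples."""
    from itertools import combinations, permutations
    m1 = int(np.sum(y == 0))
    m2 = int(np.sum(y == 1))
    perms = list(permutations(range(3)))
    best_score, best_trip = -1.0, None
    for trip in combinations(range(values.shape[0]), 3):
        counts = {0: [0] * 6, 1: [0] * 6}
        for m in range(values.shape[1]):
            vals = [(values[g, m], pos) for pos, g in enumerate(trip)]
            order = tuple(pos for _, pos in sorted(vals))
            counts[y[m]][perms.index(order)] += 1
        score = 0.5 * sum(abs(counts[0][o] / m1 - counts[1][o] / m2)
                          for o in range(6))
        if score > best_score + 1e-12:
            best_score, best_trip = score, trip
    return best_score, best_trip
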