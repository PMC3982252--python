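"""Rank-based scoring kernels shared by all relative-expression classifiers.

For a gene pair (i, j) and binary classes C1/C2, two class-conditional
probabilities of the event x_i < x_j are estimated as empirical fractions:

    p1 = (1/|C1|) Σ_{m∈C1} I(x_im < x_jm),   p2 = (1/|C2|) Σ_{m∈C2} I(...),

with the indicator giving 0 on equality (x_im ≥ x_jm counts against "<").
The pair score is Δ = |p1 − p2|; Δ ties are broken by a secondary score based
on within-sample ranks: genes are ranked inside each sample (average ranks on
ties) and the score is the absolute difference between the class means of the
rank difference R_i − R_j.

Everything here depends on the data only through within-sample orderings, so
all outputs are invariant under any strictly increasing per-sample transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.stats import rankdata

from .io_model import ExpressionMatrix, LabelVector


@dataclass(frozen=True)
class PairScore:
    """Scores for one unordered gene pair (i, j).

    ``count1``/``count2`` are the integer indicator counts behind p1/p2;
    together with the class sizes they allow exact Δ comparisons
    (Δ_a > Δ_b iff |c1_a·m2 − c2_a·m1| > |c1_b·m2 − c2_b·m1|), avoiding
    float round-off in tie detection.
    """

    i: int
    j: int
    p1: float
    p2: float
    delta: float
    secondary: float
    count1: int
    count2: int
    m1: int
    m2: int

    @property
    def delta_numerator(self) -> int:
        """|count1·m2 − count2·m1|: Δ scaled by m1·m2, exact integer."""
        return abs(self.count1 * self.m2 - self.count2 * self.m1)


def _check_pair(expr: ExpressionMatrix, i: int, j: int) -> None:
    p = expr.n_genes
    if not (0 <= i < p and 0 <= j < p):
        raise IndexError(f"gene index out of range: ({i}, {j}) with P={p}")
    if i == j:
        raise ValueError("a pair requires two distinct genes")


def _pair_counts(expr, labels, i, j):
    less = expr.values[i] < expr.values[j]
    y = labels.y
    return int(less[y == 0].sum()), int(less[y == 1].sum())


def pair_probabilities(expr: ExpressionMatrix, labels: LabelVector,
                       i: int, j: int) -> tuple:
    """Empirical class-conditional probabilities (p1, p2) of x_i < x_j."""
    _check_pair(expr, i, j)
    c1, c2 = _pair_counts(expr, labels, i, j)
    m1, m2 = labels.class_sizes
    return c1 / m1, c2 / m2


def rank_diff_means(expr: ExpressionMatrix, labels: LabelVector) -> np.ndarray:
    """Per-gene difference of class-mean within-sample ranks.

    Returns d of length P with d[g] = mean_{m∈C1} R_gm − mean_{m∈C2} R_gm,
    where R_gm is the rank of gene g within sample m (average ranks on ties).
    The secondary score of pair (i, j) is |d[i] − d[j]|.
    """
    ranks = rankdata(expr.values, axis=0)
    y = labels.y
    return ranks[:, y == 0].mean(axis=1) - ranks[:, y == 1].mean(axis=1)


def secondary_rank_score(expr: ExpressionMatrix, labels: LabelVector,
                         i: int, j: int) -> float:
    """Rank-difference tie-break score; larger is better when Δ ties."""
    _check_pair(expr, i, j)
    d = rank_diff_means(expr, labels)
    return float(abs(d[i] - d[j]))


def tsp_score(expr: ExpressionMatrix, labels: LabelVector,
              i: int, j: int) -> PairScore:
    """Full score record for one pair: Δ = |p1 − p2| plus the secondary score."""
    _check_pair(expr, i, j)
    c1, c2 = _pair_counts(expr, labels, i, j)
    m1, m2 = labels.class_sizes
    p1, p2 = c1 / m1, c2 / m2
    return PairScore(i=i, j=j, p1=p1, p2=p2, delta=abs(p1 - p2),
                     secondary=secondary_rank_score(expr, labels, i, j),
                     count1=c1, count2=c2, m1=m1, m2=m2)


def score_all_pairs(expr: ExpressionMatrix,
                    labels: LabelVector) -> Iterator[PairScore]:
    """Stream scores for all P·(P−1)/2 unordered pairs (i < j).

    Counts are computed one anchor gene at a time against all later genes,
    so memory stays O(P) per step; nothing quadratic is materialized.
    """
    values = expr.values
    y = labels.y
    m1, m2 = labels.class_sizes
    mask1, mask2 = y == 0, y == 1
    d = rank_diff_means(expr, labels)
    p = expr.n_genes
    for i in range(p - 1):
        less1 = values[i, mask1] < values[i + 1:, mask1]
        less2 = values[i, mask2] < values[i + 1:, mask2]
        counts1 = less1.sum(axis=1)
        counts2 = less2.sum(axis=1)
        for off in range(p - 1 - i):
            j = i + 1 + off
            c1, c2 = int(counts1[off]), int(counts2[off])
            p1, p2 = c1 / m1, c2 / m2
            yield PairScore(i=i, j=j, p1=p1, p2=p2, delta=abs(p1 - p2),
                            secondary=float(abs(d[i] - d[j])),
                            count1=c1, count2=c2, m1=m1, m2=m2)


def pair_sort_key(score: PairScore, gene_ids) -> tuple:
    """Descending-sort key: exact Δ, then secondary, then gene ids ascending.

    Sorting by this key descending yields the deterministic ranking used by
    the exhaustive classifiers; ties in both scores fall back to lexicographic
    gene-id order (smaller pair first).
    """
    ids = sorted((gene_ids[score.i], gene_ids[score.j]))
    return (-score.delta_numerator, -score.secondary, ids[0], ids[1])
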