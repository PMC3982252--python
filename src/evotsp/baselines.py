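"""Exhaustive relative-expression classifiers: TSP, k-TSP and TST.

These are the classical comparators the evolutionary search generalizes:

* TSP picks the single pair maximizing Δ (secondary score, then gene-id order,
  breaks ties) and votes by which class made the observed ordering more likely
  in training.
* k-TSP greedily collects the top gene-disjoint pairs and combines up to k of
  them by unweighted majority vote; k is chosen among odd values {1, 3, …,
  k_max} by internal cross-validation (ties prefer smaller k).
* TST scans all gene triplets, comparing the class-conditional distributions
  over the 6 within-sample orderings by total-variation distance (which
  reduces to Δ for pairs). O(P³) — intended for small P and oracle use.

All fits depend on the data only through within-sample orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io_model import ExpressionMatrix, LabelVector, stratified_kfold
from .rxa_core import PairScore, pair_sort_key, score_all_pairs


@dataclass(frozen=True)
class TspModel:
    gene_i: str
    gene_j: str
    less_votes_c1: bool          # True: observing x_i < x_j votes for C1
    pair: PairScore
    class_order: tuple

    @property
    def unique_genes(self) -> int:
        return 2

    def to_dict(self) -> dict:
        return {
            "method": "tsp",
            "class_order": list(self.class_order),
            "pairs": [{"gene_i": self.gene_i, "gene_j": self.gene_j,
                       "sign": "lt" if self.less_votes_c1 else "ge",
                       "weight": 1.0}],
        }


@dataclass(frozen=True)
class KTspModel:
    # (gene_i, gene_j, less_votes_c1, PairScore), sorted best-first
    pairs: tuple
    k: int
    class_order: tuple

    @property
    def unique_genes(self) -> int:
        genes = set()
        for gi, gj, _, _ in self.pairs:
            genes.update((gi, gj))
        return len(genes)

    def to_dict(self) -> dict:
        return {
            "method": "ktsp",
            "class_order": list(self.class_order),
            "pairs": [{"gene_i": gi, "gene_j": gj,
                       "sign": "lt" if lv else "ge", "weight": 1.0}
                      for gi, gj, lv, _ in self.pairs],
        }


@dataclass(frozen=True)
class TstModel:
    genes: tuple                 # three gene ids
    ordering_p1: tuple           # 6 probabilities, one per ordering code
    ordering_p2: tuple
    score: float
    class_order: tuple
    class_sizes: tuple

    @property
    def unique_genes(self) -> int:
        return 3

    def to_dict(self) -> dict:
        return {
            "method": "tst",
            "class_order": list(self.class_order),
            "genes": list(self.genes),
            "ordering_p1": list(self.ordering_p1),
            "ordering_p2": list(self.ordering_p2),
            "score": self.score,
            "class_sizes": list(self.class_sizes),
        }


def _orient(score: PairScore) -> bool:
    """Vote direction: x_i < x_j votes for the class where it was likelier."""
    if score.count1 * score.m2 >= score.count2 * score.m1:
        return True
    return False


def fit_tsp(expr: ExpressionMatrix, labels: LabelVector) -> TspModel:
    """Exhaustive scan for the single top-scoring pair."""
    best = None
    best_key = None
    for s in score_all_pairs(expr, labels):
        key = pair_sort_key(s, expr.gene_ids)
        if best_key is None or key < best_key:
            best, best_key = s, key
    return TspModel(gene_i=expr.gene_ids[best.i], gene_j=expr.gene_ids[best.j],
                    less_votes_c1=_orient(best), pair=best,
                    class_order=labels.class_order)


def greedy_disjoint_pairs(expr: ExpressionMatrix, labels: LabelVector,
                          k_max: int) -> list:
    """Top-scoring gene-disjoint pairs, best-first, at most k_max of them."""
    ranked = sorted(score_all_pairs(expr, labels),
                    key=lambda s: pair_sort_key(s, expr.gene_ids))
    chosen = []
    used = set()
    for s in ranked:
        if s.i in used or s.j in used:
            continue
        chosen.append(s)
        used.update((s.i, s.j))
        if len(chosen) == k_max:
            break
    return chosen


def _ktsp_from_scores(scores, expr, labels, k) -> KTspModel:
    pairs = tuple((expr.gene_ids[s.i], expr.gene_ids[s.j], _orient(s), s)
                  for s in scores[:k])
    return KTspModel(pairs=pairs, k=len(pairs), class_order=labels.class_order)


def fit_ktsp(expr: ExpressionMatrix, labels: LabelVector, k_max: int = 10,
             inner_folds: int = 3, seed: int = 0) -> KTspModel:
    """k-TSP: greedy disjoint top pairs; k chosen by internal cross-validation.

    Candidate k values are the odd numbers up to k_max (odd k avoids vote
    ties); among equally accurate candidates the smallest k wins.
    """
    if inner_folds > min(labels.class_sizes):
        raise ValueError(
            f"inner_folds={inner_folds} exceeds the smallest class "
            f"({min(labels.class_sizes)} samples)"
        )
    candidates = list(range(1, k_max + 1, 2))
    fold_acc = np.zeros((inner_folds, len(candidates)))
    folds = stratified_kfold(labels, inner_folds, seed)
    for f, (tr, te) in enumerate(folds):
        expr_tr, lab_tr = expr.subset_samples(tr), labels.subset(tr)
        expr_te, lab_te = expr.subset_samples(te), labels.subset(te)
        scores = greedy_disjoint_pairs(expr_tr, lab_tr, k_max)
        for c, k in enumerate(candidates):
            model = _ktsp_from_scores(scores, expr_tr, lab_tr, k)
            pred = predict(model, expr_te)
            fold_acc[f, c] = np.mean([p == t for p, t in zip(pred, lab_te.labels)])
    mean_acc = fold_acc.mean(axis=0)
    best_k = candidates[int(np.argmax(mean_acc))]  # argmax takes first → smallest k
    scores = greedy_disjoint_pairs(expr, labels, k_max)
    return _ktsp_from_scores(scores, expr, labels, best_k)


# ordering codes: bit pattern (x_i<=x_j, x_i<=x_l, x_j<=x_l), equality broken
# by gene position (earlier gene ranks lower), mapped to the sample's
# ascending ordering of the three genes; 2 of the 8 patterns are intransitive
# and cannot occur.
_CODE_TO_PERM = {
    0b111: (0, 1, 2),  # i <= j <= l
    0b110: (0, 2, 1),  # i <= l < j
    0b100: (2, 0, 1),  # l < i <= j
    0b011: (1, 0, 2),  # j < i <= l
    0b001: (1, 2, 0),  # j <= l < i
    0b000: (2, 1, 0),  # l < j < i
}
_VALID_CODES = sorted(_CODE_TO_PERM)
_CODE_SLOT = {c: s for s, c in enumerate(_VALID_CODES)}


def _ordering_slots(vi, vj, vl) -> np.ndarray:
    """Per-sample ordering slot (0..5) for three aligned value vectors."""
    code = ((vi <= vj).astype(int) << 2) | ((vi <= vl).astype(int) << 1) \
        | (vj <= vl).astype(int)
    slots = np.empty(code.shape, dtype=int)
    for c, s in _CODE_SLOT.items():
        slots[code == c] = s
    return slots


def fit_tst(expr: ExpressionMatrix, labels: LabelVector) -> TstModel:
    """Exhaustive top-scoring-triplet scan (O(P³); small-P / oracle use)."""
    p = expr.n_genes
    if p < 3:
        raise ValueError("TST requires at least 3 genes")
    values = expr.values
    y = labels.y
    mask1, mask2 = y == 0, y == 1
    m1, m2 = labels.class_sizes
    best = None
    best_num = -1  # score numerator, exact integer on denominator 2·m1·m2
    for i, j, l in combinations(range(p), 3):
        slots = _ordering_slots(values[i], values[j], values[l])
        c1 = np.bincount(slots[mask1], minlength=6)
        c2 = np.bincount(slots[mask2], minlength=6)
        num = int(np.abs(c1 * m2 - c2 * m1).sum())
        if num > best_num:
            best_num = num
            best = (i, j, l, c1, c2)
    i, j, l, c1, c2 = best
    return TstModel(
        genes=(expr.gene_ids[i], expr.gene_ids[j], expr.gene_ids[l]),
        ordering_p1=tuple((c1 / m1).tolist()),
        ordering_p2=tuple((c2 / m2).tolist()),
        score=best_num / (2 * m1 * m2),
        class_order=labels.class_order,
        class_sizes=labels.class_sizes,
    )


def _pair_votes_c1(expr, gene_i, gene_j, less_votes_c1) -> np.ndarray:
    vi = expr.values[expr.gene_index(gene_i)]
    vj = expr.values[expr.gene_index(gene_j)]
    less = vi < vj
    return less if less_votes_c1 else ~less


def predict(model, expr: ExpressionMatrix) -> list:
    """Predicted class symbols for every sample in ``expr``.

    TSP: the single pair's vote. k-TSP: unweighted majority; an even split
    falls back to the highest-Δ pair's vote. TST: the class whose training
    distribution gave the observed ordering higher probability; ties go to
    the larger training class, then C1.
    """
    c1, c2 = model.class_order
    if isinstance(model, TspModel):
        votes = _pair_votes_c1(expr, model.gene_i, model.gene_j,
                               model.less_votes_c1)
        return [c1 if v else c2 for v in votes]
    if isinstance(model, KTspModel):
        vote_stack = np.array([
            _pair_votes_c1(expr, gi, gj, lv) for gi, gj, lv, _ in model.pairs
        ])
        n_c1 = vote_stack.sum(axis=0)
        n_c2 = len(model.pairs) - n_c1
        out = []
        for m in range(expr.n_samples):
            if n_c1[m] > n_c2[m]:
                out.append(c1)
            elif n_c1[m] < n_c2[m]:
                out.append(c2)
            else:
                out.append(c1 if vote_stack[0, m] else c2)
        return out
    if isinstance(model, TstModel):
        gi, gj, gl = (expr.gene_index(g) for g in model.genes)
        slots = _ordering_slots(expr.values[gi], expr.values[gj],
                                expr.values[gl])
        p1 = np.asarray(model.ordering_p1)
        p2 = np.asarray(model.ordering_p2)
        tie_class = c1 if model.class_sizes[0] >= model.class_sizes[1] else c2
        out = []
        for s in slots:
            if p1[s] > p2[s]:
                out.append(c1)
            elif p1[s] < p2[s]:
                out.append(c2)
            else:
                out.append(tie_class)
        return out
    raise TypeError(f"unknown model type: {type(model).__name__}")
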