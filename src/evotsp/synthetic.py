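"""Synthetic expression data with planted rank-inversion signals.

The generator emulates the shape of two-class microarray studies: P genes
(10²–10⁵), M ≈ 100–200 samples, continuous positive expression values. A small
set of planted gene pairs carries the only class signal: within each sample
the two background draws are swapped so that x_i < x_j in class C1 and
x_i > x_j in class C2 (and the reverse with noise probability ε). Because
values are only permuted within the sample, the marginal distribution of each
planted gene is identical in both classes — the signal is invisible to
univariate differential-expression statistics and lives entirely in the pair
ordering, which is the setting relative-expression methods are built for.

For a planted pair the population pair score is Δ = (1−ε) − ε = 1 − 2ε.

Planted triplets fix one full ordering per class the same way (ascending in
C1, descending in C2, flipped with probability ε).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import ExpressionMatrix, LabelVector


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one synthetic dataset."""

    n_genes: int = 200
    n_samples: int = 100
    class_fraction: float = 0.5
    planted_pairs: tuple = ()
    planted_triplets: tuple = ()
    noise_eps: float = 0.05
    background_sd: float = 1.0
    seed: int = 0
    class_symbols: tuple = ("C1", "C2")

    def __post_init__(self):
        if not 0.0 < self.class_fraction < 1.0:
            raise ValueError("class_fraction must lie in (0, 1)")
        if not 0.0 <= self.noise_eps <= 0.5:
            raise ValueError("noise_eps must lie in [0, 0.5]")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        used = set()
        for unit in list(self.planted_pairs) + list(self.planted_triplets):
            if len(set(unit)) != len(unit):
                raise ValueError(f"planted unit {unit} repeats a gene")
            for g in unit:
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"planted gene index {g} out of range")
                if g in used:
                    raise ValueError(
                        f"gene index {g} appears in more than one planted unit"
                    )
                used.add(g)


def expected_pair_delta(eps: float) -> float:
    """Population Δ of a planted pair at noise rate ε: (1−ε) − ε = 1 − 2ε."""
    if not 0.0 <= eps <= 0.5:
        raise ValueError("eps must lie in [0, 0.5]")
    return 1.0 - 2.0 * eps


def generate(spec: PlantSpec):
    """Generate (ExpressionMatrix, LabelVector, ground-truth record).

    Background values are i.i.d. log-normal (log-mean log 100, log-sd
    ``background_sd``); planting permutes values within a sample only.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p, m = spec.n_genes, spec.n_samples
    m1 = int(round(spec.class_fraction * m))
    m1 = min(max(m1, 1), m - 1)
    y = np.array([0] * m1 + [1] * (m - m1))
    values = rng.lognormal(mean=np.log(100.0), sigma=spec.background_sd,
                           size=(p, m))
    eps = spec.noise_eps
    for (i, j) in spec.planted_pairs:
        flip = rng.random(m) < eps
        want_i_less = (y == 0) ^ flip        # C1 wants x_i < x_j
        lo = np.minimum(values[i], values[j])
        hi = np.maximum(values[i], values[j])
        values[i] = np.where(want_i_less, lo, hi)
        values[j] = np.where(want_i_less, hi, lo)
    for (i, j, l) in spec.planted_triplets:
        flip = rng.random(m) < eps
        ascending = (y == 0) ^ flip          # C1 wants x_i < x_j < x_l
        trio = np.sort(values[[i, j, l]], axis=0)
        asc = trio
        desc = trio[::-1]
        values[i] = np.where(ascending, asc[0], desc[0])
        values[j] = np.where(ascending, asc[1], desc[1])
        values[l] = np.where(ascending, asc[2], desc[2])
    gene_ids = tuple(f"g{k:05d}" for k in range(p))
    sample_ids = tuple(f"s{k:04d}" for k in range(m))
    c1, c2 = spec.class_symbols
    labels = LabelVector(tuple(c1 if cls == 0 else c2 for cls in y), (c1, c2))
    truth = {
        "planted_pairs": [[int(i), int(j)] for i, j in spec.planted_pairs],
        "planted_triplets": [[int(i), int(j), int(l)]
                             for i, j, l in spec.planted_triplets],
        "planted_pair_ids": [[gene_ids[i], gene_ids[j]]
                             for i, j in spec.planted_pairs],
        "planted_triplet_ids": [[gene_ids[i], gene_ids[j], gene_ids[l]]
                                for i, j, l in spec.planted_triplets],
        "noise_eps": eps,
        "seed": spec.seed,
        "class_sizes": [int(m1), int(m - m1)],
    }
    return ExpressionMatrix(values, gene_ids, sample_ids), labels, truth
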