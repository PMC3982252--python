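"""Containers for expression data and class labels, TSV I/O, and fold construction.

The canonical on-disk format is tab-separated text: genes in rows, samples in
columns, gene identifiers in the first column and sample identifiers in the
header row. Labels are a two-column (sample id, class symbol) TSV without a
header. Values are taken as-is — relative-expression methods use only
within-sample orderings, so no normalization is applied or needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold


class FormatError(ValueError):
    """An input file violates the expected TSV layout or data model invariants."""


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """A P×M matrix of continuous expression values with string identifiers.

    Parameters
    ----------
    values
        P×M array of finite reals (genes in rows, samples in columns).
    gene_ids
        P unique gene identifiers.
    sample_ids
        M unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        p, m = values.shape
        if p < 2 or m < 2:
            raise FormatError(f"need at least 2 genes and 2 samples, got {p}x{m}")
        if len(self.gene_ids) != p or len(self.sample_ids) != m:
            raise FormatError("identifier counts do not match matrix shape")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen = set()
            for x in ids:
                if x in seen:
                    raise FormatError(f"duplicate {name} id {x!r}")
                seen.add(x)
        if not np.all(np.isfinite(values)):
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[gi]!r}, "
                f"sample {self.sample_ids[si]!r}"
            )
        object.__setattr__(self, "_gene_index", {g: k for k, g in enumerate(self.gene_ids)})

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not present in matrix") from None

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            tuple(self.sample_ids[k] for k in idx),
        )


@dataclass(frozen=True, eq=False)
class LabelVector:
    """Binary class assignment per sample.

    ``class_order`` fixes which symbol is the "first" class C1: per-class
    probabilities and vote directions depend on it (the pair score Δ does not).
    """

    labels: tuple
    class_order: tuple

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        order = tuple(str(c) for c in self.class_order)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_order", order)
        present = set(labels)
        if len(order) != 2 or order[0] == order[1]:
            raise FormatError("class_order must name two distinct classes")
        if present != set(order):
            raise FormatError(
                f"labels contain classes {sorted(present)}, expected {sorted(order)}"
            )
        y = np.fromiter((0 if x == order[0] else 1 for x in labels), dtype=int)
        object.__setattr__(self, "_y", y)
        if (y == 0).sum() == 0 or (y == 1).sum() == 0:
            raise FormatError("each class must contain at least one sample")

    @property
    def y(self) -> np.ndarray:
        """0/1 encoding: 0 for C1 (class_order[0]), 1 for C2."""
        return self._y

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def class_sizes(self) -> tuple:
        return int((self._y == 0).sum()), int((self._y == 1).sum())

    @property
    def majority_class_index(self) -> int:
        """Index (0/1) of the larger class; ties go to C1."""
        m1, m2 = self.class_sizes
        return 0 if m1 >= m2 else 1

    def subset(self, indices: Sequence[int]) -> "LabelVector":
        idx = np.asarray(indices, dtype=int)
        return LabelVector(tuple(self.labels[k] for k in idx), self.class_order)


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a gene×sample TSV (header: sample ids; first column: gene ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed TSV ({exc})") from exc
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    for name, ids in (("gene", genes), ("sample", samples)):
        seen = set()
        for x in ids:
            if x in seen:
                raise FormatError(f"{path}: duplicate {name} id {x!r}")
            seen.add(x)
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for gi in range(raw.shape[0]):
        for si in range(raw.shape[1]):
            cell = raw[gi, si]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                v = np.nan
            if not np.isfinite(v):
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at gene {genes[gi]!r}, "
                    f"sample {samples[si]!r}"
                )
            values[gi, si] = v
    return ExpressionMatrix(values, tuple(genes), tuple(samples))


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.gene_ids),
                      columns=list(expr.sample_ids))
    df.to_csv(path, sep="\t", index_label="gene")


def read_labels_tsv(path, sample_ids: Sequence[str],
                    class_order: tuple | None = None) -> LabelVector:
    """Read a two-column (sample id, class symbol) TSV, reordered to sample_ids.

    class_order defaults to order of first appearance in the file. Samples in
    the file but absent from ``sample_ids`` are ignored; the reverse is an error.
    """
    path = Path(path)
    mapping: dict = {}
    first_seen: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, cls = parts
            if sid in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            mapping[sid] = cls
            if cls not in first_seen:
                first_seen.append(cls)
    if len(first_seen) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 classes, found {len(first_seen)}: {first_seen}"
        )
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise FormatError(f"{path}: no label for sample {missing[0]!r}")
    labels = tuple(mapping[s] for s in sample_ids)
    if class_order is None:
        class_order = tuple(first_seen)
    return LabelVector(labels, class_order)


def write_labels_tsv(labels: LabelVector, sample_ids: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for sid, cls in zip(sample_ids, labels.labels):
            fh.write(f"{sid}\t{cls}\n")


def stratified_kfold(labels: LabelVector, n_folds: int, seed: int,
                     stratify: bool = True) -> list:
    """Deterministic k-fold split; stratified by class unless disabled.

    Returns a list of (train_indices, test_indices) arrays partitioning all
    samples; per-fold class counts differ by at most 1 from proportional.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    m1, m2 = labels.class_sizes
    if stratify and min(m1, m2) < n_folds:
        raise ValueError(
            f"smallest class has {min(m1, m2)} samples, fewer than {n_folds} folds"
        )
    if not stratify and labels.n_samples < n_folds:
        raise ValueError("fewer samples than folds")
    if stratify:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y = labels.y
    return [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros(len(y)), y)]
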