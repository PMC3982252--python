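"""Repeated cross-validation benchmark harness for the four classifiers.

The protocol mirrors standard microarray benchmarking practice: repeated
stratified k-fold cross-validation (default 10 folds, 20 repeats), models
trained on the training split only, accuracy measured on the held-out fold,
reported as mean ± SD in percent together with the mean model size (number of
unique genes — the interpretability currency of relative-expression models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import baselines
from .evo import EvoConfig, fit_evotsp
from .io_model import ExpressionMatrix, LabelVector, stratified_kfold

METHODS = ("tsp", "ktsp", "tst", "evotsp")


@dataclass(frozen=True)
class CvReport:
    method: str
    folds: int
    repeats: int
    seed: int
    fold_accuracies: tuple     # percent, repeat-major order, folds*repeats long
    model_sizes: tuple         # unique genes per fitted model
    mean_accuracy: float       # percent
    sd_accuracy: float         # percent, sample SD over all folds
    mean_model_size: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "mean_accuracy_pct": self.mean_accuracy,
            "sd_accuracy_pct": self.sd_accuracy,
            "mean_model_size": self.mean_model_size,
            "fold_accuracies_pct": list(self.fold_accuracies),
            "model_sizes": list(self.model_sizes),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        return (
            f"method={self.method} folds={self.folds} repeats={self.repeats}\n"
            f"accuracy: {self.mean_accuracy:.1f} +/- {self.sd_accuracy:.1f} %\n"
            f"mean model size (unique genes): {self.mean_model_size:.1f}\n"
        )


def _fit(method: str, expr: ExpressionMatrix, labels: LabelVector,
         seed: int, **kw):
    if method == "tsp":
        return baselines.fit_tsp(expr, labels)
    if method == "ktsp":
        return baselines.fit_ktsp(
            expr, labels, k_max=kw.get("k_max", 10),
            inner_folds=kw.get("inner_folds", 3), seed=seed)
    if method == "tst":
        return baselines.fit_tst(expr, labels)
    if method == "evotsp":
        base = kw.get("evo_config") or EvoConfig()
        cfg = EvoConfig(
            population_size=kw.get("pop_size", base.population_size),
            alpha=kw.get("alpha", base.alpha),
            p_crossover=base.p_crossover, p_mutation=base.p_mutation,
            p_exchange_variant=base.p_exchange_variant,
            stall_generations=kw.get("stall", base.stall_generations),
            max_generations=kw.get("max_gen", base.max_generations),
            init_k_max=base.init_k_max,
            dipole_retry_limit=base.dipole_retry_limit, seed=seed)
        return fit_evotsp(expr, labels, cfg)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _predict(model, expr: ExpressionMatrix) -> list:
    if hasattr(model, "predict"):
        return model.predict(expr)
    return baselines.predict(model, expr)


def accuracy_pct(predicted, labels: LabelVector) -> float:
    hits = sum(p == t for p, t in zip(predicted, labels.labels))
    return 100.0 * hits / labels.n_samples


def cross_validate(expr: ExpressionMatrix, labels: LabelVector, method: str,
                   folds: int = 10, repeats: int = 20, seed: int = 0,
                   stratify: bool = True, refold: bool = True,
                   **method_kw) -> CvReport:
    """Repeated k-fold CV of one method; deterministic given ``seed``.

    With ``refold`` each repeat re-randomizes the folds (seed + repeat index);
    otherwise the folds are fixed and only method seeds vary across repeats.
    """
    accs = []
    sizes = []
    for rep in range(repeats):
        fold_seed = seed + rep if refold else seed
        method_seed = seed + 1000 * (rep + 1)
        for f, (tr, te) in enumerate(stratified_kfold(labels, folds, fold_seed,
                                                      stratify=stratify)):
            model = _fit(method, expr.subset_samples(tr), labels.subset(tr),
                         seed=method_seed + f, **method_kw)
            pred = _predict(model, expr.subset_samples(te))
            accs.append(accuracy_pct(pred, labels.subset(te)))
            sizes.append(model.unique_genes)
    accs_arr = np.asarray(accs)
    return CvReport(
        method=method, folds=folds, repeats=repeats, seed=seed,
        fold_accuracies=tuple(accs), model_sizes=tuple(sizes),
        mean_accuracy=float(accs_arr.mean()),
        sd_accuracy=float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_model_size=float(np.mean(sizes)),
    )
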