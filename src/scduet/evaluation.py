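"""Cross-validated benchmarking of decomposition methods.

Doublets are split into k folds (default five); for every fold each
method is trained on the remaining folds and asked to identify, for each
held-out doublet, the contributing reference cell of each type.  The
underlying single cells are shared across folds — only doublets are
split — mirroring how the artificial-doublet validation is defined (the
reference panel is the label space, so some memorization of reference
profiles is inherent to the task).

Metrics per (method, cell type):

* exact-cell accuracy — correct argmax predictions over all predictions
  (the headline number);
* micro-averaged one-vs-rest confusion metrics over all (doublet,
  reference cell) decisions, including both the false-positive rate as
  printed in the source method description, FP/(FP+FN), and the standard
  FP/(FP+TN) (the printed denominator is a probable typo, so both are
  reported);
* cell-type-level accuracy — whether the predicted reference cell carries
  the true component's type label (non-trivial only for mixed panels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .baselines import predict_baseline, train_baseline
from .decomposer import (
    DoubletDecomposer,
    NetworkSpec,
    TrainingConfig,
)
from .doublet_synthesis import (
    ArtificialDoubletSet,
    build_training_set,
    sample_recipes,
)
from .expr_data import ExpressionMatrix

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "kfold_split",
    "confusion_from_predictions",
    "metrics",
    "benchmark",
]


@dataclass
class ConfusionCounts:
    """Micro-aggregated one-vs-rest decision counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def kfold_split(n_doublets: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Shuffled k-fold partition of doublet indices; sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_doublets < k:
        raise ValueError("need at least k doublets")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.arange(n_doublets))]


def confusion_from_predictions(
    predicted: np.ndarray, truth: np.ndarray, n_references: int
) -> ConfusionCounts:
    """Tally one-vs-rest decisions over all reference cells.

    Each doublet contributes ``n_references`` binary decisions: a correct
    argmax yields one TP and K-1 TN; an incorrect one yields one FP (the
    predicted cell), one FN (the missed true cell), and K-2 TN.
    """
    predicted = np.asarray(predicted, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if predicted.size and max(predicted.max(), truth.max()) >= n_references:
        raise IndexError("reference index out of range")
    n = len(predicted)
    correct = int((predicted == truth).sum())
    wrong = n - correct
    return ConfusionCounts(
        tp=correct,
        fp=wrong,
        fn=wrong,
        tn=correct * (n_references - 1) + wrong * (n_references - 2),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, both false-positive rates, and the false-negative rate.

    ``fpr_printed`` uses the denominator FP+FN exactly as printed in the
    method description; ``fpr_standard`` uses FP+TN.  A metric whose
    denominator is zero is reported as NaN (undefined), never as 0.
    """
    if counts.total == 0:
        raise ValueError("all counts are zero")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "accuracy": ratio(counts.tp + counts.tn, counts.total),
        "fpr_printed": ratio(counts.fp, counts.fp + counts.fn),
        "fpr_standard": ratio(counts.fp, counts.fp + counts.tn),
        "fnr": ratio(counts.fn, counts.tp + counts.fn),
    }


@dataclass
class EvaluationReport:
    """Benchmark results: one row per (method, cell type)."""

    table: pd.DataFrame
    k: int
    seed: int
    n_doublets: int
    fold_sizes: list[int] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold cross-validation on {self.n_doublets} artificial "
            f"doublets (seed {self.seed})",
            "=" * 72,
        ]
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(self.table.to_string(index=False))
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "n_doublets": self.n_doublets,
            "fold_sizes": self.fold_sizes,
            "rows": self.table.to_dict(orient="records"),
        }


def _subset(dset: ArtificialDoubletSet, idx: np.ndarray) -> ArtificialDoubletSet:
    return ArtificialDoubletSet(
        mixtures=dset.mixtures[idx],
        recipes=[dset.recipes[i] for i in idx],
        gene_ids=dset.gene_ids,
    )


def benchmark(
    type_a: ExpressionMatrix,
    type_b: ExpressionMatrix,
    methods: list[str],
    n_doublets: int = 20000,
    k: int = 5,
    seed: int = 0,
    training_cfg: TrainingConfig | None = None,
    hidden_sizes: tuple[int, ...] = (256, 128, 64),
    types_to_run: tuple[str, ...] = ("A", "B"),
) -> EvaluationReport:
    """Cross-validate the listed methods on one shared artificial doublet set.

    ``methods`` may contain ``"twinnet"`` (the twin networks),
    ``"lr"`` (multinomial logistic regression), and ``"nb"`` (naive
    Bayes).  Every method sees identical folds, identical CPM inputs, and
    identical evaluation code.
    """
    if not methods:
        raise ValueError("at least one method is required")
    known = {"twinnet", "lr", "nb"}
    unknown = set(methods) - known
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    training_cfg = training_cfg or TrainingConfig(seed=seed)

    recipes = sample_recipes(type_a.n_cells, type_b.n_cells, n_doublets, seed)
    dset = build_training_set(type_a, type_b, recipes)
    folds = kfold_split(n_doublets, k=k, seed=seed)

    panel_sizes = {"A": type_a.n_cells, "B": type_b.n_cells}
    # per-reference-cell type labels; a pure panel defaults to its own type
    panel_types = {
        "A": np.asarray(
            type_a.cell_type
            if type_a.cell_type is not None
            else ["A"] * type_a.n_cells,
            dtype=object,
        ),
        "B": np.asarray(
            type_b.cell_type
            if type_b.cell_type is not None
            else ["B"] * type_b.n_cells,
            dtype=object,
        ),
    }
    acc: dict[tuple[str, str], dict] = {
        (m, t): {"correct": 0, "n": 0, "type_correct": 0, "conf": ConfusionCounts()}
        for m in methods
        for t in types_to_run
    }

    for fold_idx, test_idx in enumerate(folds):
        train_mask = np.ones(n_doublets, dtype=bool)
        train_mask[test_idx] = False
        train_set = _subset(dset, np.where(train_mask)[0])
        test_set = _subset(dset, test_idx)
        preds: dict[tuple[str, str], np.ndarray] = {}

        for method in methods:
            if method == "twinnet":
                d = dset.mixtures.shape[1]
                model = DoubletDecomposer(
                    train_set,
                    ref_ids_a=type_a.cell_ids,
                    ref_ids_b=type_b.cell_ids,
                    spec_a=NetworkSpec(d, panel_sizes["A"], hidden_sizes),
                    spec_b=NetworkSpec(d, panel_sizes["B"], hidden_sizes),
                )
                fitted = model.fit(training_cfg)
                scores = fitted.score_doublets(test_set)
                pa, pb = scores.predict_pair()
                preds[("twinnet", "A")] = pa
                preds[("twinnet", "B")] = pb
            else:
                sk_name = {
                    "lr": "logistic_regression",
                    "nb": "naive_bayes",
                }[method]
                for t in types_to_run:
                    bl = train_baseline(
                        sk_name,
                        train_set,
                        t,
                        n_references=panel_sizes[t],
                        seed=seed,
                    )
                    _, argmax = predict_baseline(bl, test_set)
                    preds[(method, t)] = argmax

        for t in types_to_run:
            true = test_set.targets(t.lower())
            for method in methods:
                key = (method, t)
                if key not in preds:
                    continue
                p = preds[key]
                entry = acc[key]
                entry["correct"] += int((p == true).sum())
                entry["n"] += len(true)
                entry["type_correct"] += int(
                    (panel_types[t][p] == panel_types[t][true]).sum()
                )
                entry["conf"] = entry["conf"] + confusion_from_predictions(
                    p, true, panel_sizes[t]
                )

    rows = []
    for (method, t), entry in acc.items():
        if entry["n"] == 0:
            continue
        m = metrics(entry["conf"])
        chance = 1.0 / panel_sizes[t]
        rows.append(
            {
                "method": method,
                "cell_type": t,
                "exact_accuracy": entry["correct"] / entry["n"],
                "type_accuracy": entry["type_correct"] / entry["n"],
                "micro_accuracy": m["accuracy"],
                "fpr_printed": m["fpr_printed"],
                "fpr_standard": m["fpr_standard"],
                "fnr": m["fnr"],
                "chance_level": chance,
                "n_predictions": entry["n"],
                "n_references": panel_sizes[t],
            }
        )
    table = pd.DataFrame(rows).sort_values(["method", "cell_type"]).reset_index(drop=True)
    return EvaluationReport(
        table=table,
        k=k,
        seed=seed,
        n_doublets=n_doublets,
        fold_sizes=[len(f) for f in folds],
    )
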