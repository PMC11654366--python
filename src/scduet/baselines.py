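"""Classical comparators for the decomposition benchmark.

Two baselines score a doublet against a reference panel through the same
CPM input representation as the networks: multinomial logistic regression
(scikit-learn, default multiclass settings pinned explicitly: L2 penalty,
C=1.0, tol=1e-4, up to 1000 lbfgs iterations) and naive Bayes.  The naive
Bayes variant defaults to multinomial on CPM values rounded to integer
pseudo-counts, which suits count-like data; a Gaussian-on-CPM variant is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB, MultinomialNB

from .doublet_synthesis import ArtificialDoubletSet
from .decomposer import SelectionResult, _prepare_inputs, TrainingConfig
from .expr_data import ExpressionMatrix, align_to_genes

__all__ = ["BaselineModel", "train_baseline", "predict_baseline", "score_baseline_pair"]

Method = Literal["logistic_regression", "naive_bayes"]


def _baseline_inputs(mixtures: np.ndarray, method: str, nb_variant: str) -> np.ndarray:
    """CPM inputs in the representation each estimator expects.

    Logistic regression (and Gaussian naive Bayes) share the networks'
    rescaled CPM representation; multinomial naive Bayes gets CPM rounded
    to integer pseudo-counts, the count-like form its likelihood assumes.
    """
    if method == "naive_bayes" and nb_variant == "multinomial":
        from .expr_data import cpm_matrix

        return np.round(cpm_matrix(mixtures))
    return _prepare_inputs(mixtures, TrainingConfig()).astype(np.float64)


@dataclass
class BaselineModel:
    """One fitted per-type comparator."""

    method: Method
    estimator: object
    target_type: Literal["A", "B"]
    gene_ids: np.ndarray
    ref_ids: np.ndarray
    classes_: np.ndarray  # reference indices seen in training
    nb_variant: str = "multinomial"

    def full_proba(self, x: np.ndarray) -> np.ndarray:
        """Probabilities over the full panel; unseen classes get 0."""
        proba = self.estimator.predict_proba(x)
        out = np.zeros((x.shape[0], len(self.ref_ids)), dtype=np.float64)
        out[:, self.classes_] = proba
        return out


def train_baseline(
    method: Method,
    doublets: ArtificialDoubletSet,
    target_type: Literal["A", "B"],
    *,
    n_references: int | None = None,
    ref_ids=None,
    nb_variant: Literal["multinomial", "gaussian"] = "multinomial",
    seed: int = 0,
) -> BaselineModel:
    """Fit one comparator to the CPM-normalized mixtures.

    Targets come from the recipes of ``doublets`` for the requested type.
    """
    which = target_type.lower()
    y = doublets.targets(which)
    x = _baseline_inputs(doublets.mixtures, method, nb_variant)
    if n_references is None:
        n_references = int(y.max()) + 1
    if ref_ids is None:
        ref_ids = [f"{target_type}_{i}" for i in range(n_references)]

    if method == "logistic_regression":
        # L2 penalty (the default), strength C=1.0, multinomial objective
        # (automatic for lbfgs with >2 classes)
        est = LogisticRegression(C=1.0, tol=1e-4, max_iter=1000, solver="lbfgs")
    elif method == "naive_bayes":
        if nb_variant == "multinomial":
            est = MultinomialNB()
        elif nb_variant == "gaussian":
            est = GaussianNB()
        else:
            raise ValueError(f"unknown naive Bayes variant: {nb_variant!r}")
    else:
        raise ValueError(f"unknown method: {method!r}")

    est.fit(x, y)
    return BaselineModel(
        method=method,
        estimator=est,
        target_type=target_type,
        gene_ids=np.asarray(doublets.gene_ids, dtype=object),
        ref_ids=np.asarray(ref_ids, dtype=object),
        classes_=np.asarray(est.classes_, dtype=np.int64),
        nb_variant=nb_variant,
    )


def _as_matrix(model: BaselineModel, doublets) -> np.ndarray:
    if isinstance(doublets, ArtificialDoubletSet):
        if list(doublets.gene_ids) != list(model.gene_ids):
            raise ValueError("doublet set gene list differs from the model's")
        return doublets.mixtures
    if isinstance(doublets, ExpressionMatrix):
        return align_to_genes(doublets, list(model.gene_ids))
    return np.asarray(doublets, dtype=np.float64)


def predict_baseline(
    model: BaselineModel, doublets
) -> tuple[np.ndarray, np.ndarray]:
    """Probability vectors (doublets x panel size) and argmax indices."""
    x = _baseline_inputs(_as_matrix(model, doublets), model.method, model.nb_variant)
    proba = model.full_proba(x)
    return proba, np.argmax(proba, axis=-1)


def score_baseline_pair(
    model_a: BaselineModel, model_b: BaselineModel, doublets
) -> SelectionResult:
    """Mirror the network scoring interface for a pair of baselines."""
    pa, _ = predict_baseline(model_a, doublets)
    pb, _ = predict_baseline(model_b, doublets)
    return SelectionResult(
        scores_a=pa,
        scores_b=pb,
        ref_ids_a=model_a.ref_ids,
        ref_ids_b=model_b.ref_ids,
    )
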