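"""Twin per-cell-type networks that decompose a doublet transcriptome.

One fully connected network is assigned to each of the two cell types in
a doublet.  Both receive the same counts-per-million (CPM) normalized
mixture profile and emit, through a softmax output layer, a probability
vector over that type's reference single cells; the highest-scoring cell
per type is the predicted component, and every reference cell scoring
above a small cutoff (default 0.01) in at least one doublet is retained
for the downstream differential-expression comparison.

The default architecture has three hidden rectified-linear layers of
2048, 1024, and 512 units.  Training minimizes categorical cross-entropy
with Adam over artificial doublets whose recipes supply the ground-truth
reference indices.

Usage follows the model/results idiom::

    model = DoubletDecomposer(doublets, ref_ids_a, ref_ids_b)
    result = model.fit(TrainingConfig(epochs=20, seed=0))
    scores = result.score_doublets(real_doublets)
    selected = scores.selected("a")
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import MLPClassifier, relu, softmax  # noqa: F401  (re-exported)
from .doublet_synthesis import ArtificialDoubletSet
from .expr_data import (
    ExpressionMatrix,
    align_to_genes,
    align_values_to_genes,
    cpm_matrix,
)

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "DoubletDecomposer",
    "TrainedDecomposer",
    "SelectionResult",
    "forward",
    "train",
    "score_doublets",
    "predict_pair",
    "select_cells",
]

DEFAULT_HIDDEN = (2048, 1024, 512)
SCORE_CUTOFF = 0.01


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one per-type network."""

    input_dim: int
    output_dim: int
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings shared by both networks.

    The loss is categorical cross-entropy and the optimizer Adam; learning
    rate and the exponential-decay coefficients are exposed here.  Inputs
    are CPM profiles; ``log_input`` optionally applies log1p on top (off
    by default).
    """

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 256
    epochs: int = 20
    validation_fraction: float = 0.0
    log_input: bool = False
    input_scale: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")


def forward(network: MLPClassifier, profile: np.ndarray) -> np.ndarray:
    """Apply a network to one CPM profile (or a batch); returns probabilities."""
    return network.predict_proba(profile)


def _prepare_inputs(mixtures: np.ndarray, cfg: TrainingConfig) -> np.ndarray:
    """CPM profiles, rescaled by a fixed constant for numerical conditioning.

    The constant (default 1e-4, i.e. per-cell sums of 100 instead of 1e6)
    carries no information — it is a units choice that keeps the first
    layer's pre-activations of order one under fan-in initialization.
    """
    x = cpm_matrix(mixtures, dtype=np.float32)
    if cfg.log_input:
        x = np.log1p(x)
    else:
        x = x * np.float32(cfg.input_scale)
    return x


class DoubletDecomposer:
    """Model object: artificial doublets plus the two reference panels.

    Parameters
    ----------
    doublets
        Training set whose recipes carry ground-truth indices into both
        reference panels.
    ref_ids_a, ref_ids_b
        Reference cell identifiers for type A and type B; their lengths
        fix the two output dimensions.
    spec_a, spec_b
        Optional architecture overrides (default three hidden layers of
        2048/1024/512 units).
    ref_types_a, ref_types_b
        Optional per-reference-cell type labels, carried through so that
        predictions can be checked at cell-type granularity.
    """

    def __init__(
        self,
        doublets: ArtificialDoubletSet,
        ref_ids_a,
        ref_ids_b,
        spec_a: NetworkSpec | None = None,
        spec_b: NetworkSpec | None = None,
        ref_types_a=None,
        ref_types_b=None,
    ) -> None:
        self.doublets = doublets
        self.ref_ids_a = np.asarray(ref_ids_a, dtype=object)
        self.ref_ids_b = np.asarray(ref_ids_b, dtype=object)
        d = doublets.mixtures.shape[1]
        self.spec_a = spec_a or NetworkSpec(d, len(self.ref_ids_a))
        self.spec_b = spec_b or NetworkSpec(d, len(self.ref_ids_b))
        self.ref_types_a = ref_types_a
        self.ref_types_b = ref_types_b
        for which, spec, ids in (
            ("a", self.spec_a, self.ref_ids_a),
            ("b", self.spec_b, self.ref_ids_b),
        ):
            if spec.input_dim != d:
                raise ValueError(f"spec_{which} input_dim {spec.input_dim} != {d}")
            if spec.output_dim != len(ids):
                raise ValueError(
                    f"spec_{which} output_dim {spec.output_dim} != "
                    f"{len(ids)} reference cells"
                )
            targets = doublets.targets(which)
            if targets.size and targets.max() >= spec.output_dim:
                raise ValueError(
                    f"recipe index {targets.max()} out of range for type "
                    f"{which} panel of size {spec.output_dim}"
                )

    def fit(self, cfg: TrainingConfig | None = None) -> "TrainedDecomposer":
        """Train both networks on the CPM-normalized mixtures."""
        cfg = cfg or TrainingConfig()
        x = _prepare_inputs(self.doublets.mixtures, cfg)
        n = x.shape[0]
        train_idx = np.arange(n)
        val_idx = np.arange(0)
        if cfg.validation_fraction > 0:
            rng = np.random.default_rng(cfg.seed)
            order = rng.permutation(n)
            n_val = int(round(cfg.validation_fraction * n))
            val_idx, train_idx = order[:n_val], order[n_val:]
        nets = {}
        for which, spec in (("a", self.spec_a), ("b", self.spec_b)):
            targets = self.doublets.targets(which)
            net = MLPClassifier(
                spec.input_dim,
                spec.hidden_sizes,
                spec.output_dim,
                seed=cfg.seed + (0 if which == "a" else 1),
            )
            net.fit(
                x[train_idx],
                targets[train_idx],
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                learning_rate=cfg.learning_rate,
                beta1=cfg.beta1,
                beta2=cfg.beta2,
                x_val=x[val_idx] if len(val_idx) else None,
                y_val=targets[val_idx] if len(val_idx) else None,
            )
            nets[which] = net
        return TrainedDecomposer(
            network_a=nets["a"],
            network_b=nets["b"],
            ref_ids_a=self.ref_ids_a,
            ref_ids_b=self.ref_ids_b,
            gene_ids=np.asarray(self.doublets.gene_ids, dtype=object),
            config=cfg,
            ref_types_a=self.ref_types_a,
            ref_types_b=self.ref_types_b,
        )


@dataclass
class TrainedDecomposer:
    """Fitted twin networks with frozen parameters and provenance."""

    network_a: MLPClassifier
    network_b: MLPClassifier
    ref_ids_a: np.ndarray
    ref_ids_b: np.ndarray
    gene_ids: np.ndarray
    config: TrainingConfig
    ref_types_a: np.ndarray | None = None
    ref_types_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.network_a.output_dim != len(self.ref_ids_a):
            raise ValueError("network A output dim != reference panel size")
        if self.network_b.output_dim != len(self.ref_ids_b):
            raise ValueError("network B output dim != reference panel size")

    @property
    def loss_history(self) -> dict[str, list[float]]:
        return {"a": self.network_a.loss_history_, "b": self.network_b.loss_history_}

    def _as_matrix(self, doublets) -> np.ndarray:
        if isinstance(doublets, ArtificialDoubletSet):
            if list(doublets.gene_ids) == list(self.gene_ids):
                return doublets.mixtures
            return align_values_to_genes(
                doublets.mixtures, doublets.gene_ids, list(self.gene_ids)
            )
        if isinstance(doublets, ExpressionMatrix):
            return align_to_genes(doublets, list(self.gene_ids))
        return np.asarray(doublets, dtype=np.float64)

    def score_doublets(self, doublets) -> "SelectionResult":
        """Score each doublet against both reference panels.

        CPM normalization (and the optional log transform the model was
        trained with) is applied internally; each returned score vector
        sums to one.
        """
        mat = self._as_matrix(doublets)
        x = _prepare_inputs(mat, self.config)
        return SelectionResult(
            scores_a=self.network_a.predict_proba(x),
            scores_b=self.network_b.predict_proba(x),
            ref_ids_a=self.ref_ids_a,
            ref_ids_b=self.ref_ids_b,
        )

    def predict_pair(self, doublets) -> tuple[np.ndarray, np.ndarray]:
        """Highest-scoring reference index per type for each doublet."""
        return self.score_doublets(doublets).predict_pair()

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Doublet decomposer (twin per-cell-type networks)",
            "=" * 48,
            f"genes: {len(self.gene_ids)}",
            f"type A panel: {len(self.ref_ids_a)} reference cells, "
            f"hidden {list(self.network_a.hidden_sizes)}",
            f"type B panel: {len(self.ref_ids_b)} reference cells, "
            f"hidden {list(self.network_b.hidden_sizes)}",
            f"training: {cfg.epochs} epochs, batch {cfg.batch_size}, "
            f"Adam(lr={cfg.learning_rate}, betas=({cfg.beta1}, {cfg.beta2})), "
            f"seed {cfg.seed}",
        ]
        for which, net in (("A", self.network_a), ("B", self.network_b)):
            if net.loss_history_:
                lines.append(
                    f"cross-entropy {which}: first epoch "
                    f"{net.loss_history_[0]:.4f} -> last {net.loss_history_[-1]:.4f}"
                )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Write a checkpoint archive (.npz) with gene list, ids, weights."""
        payload = {
            "gene_ids": np.asarray(self.gene_ids, dtype=str),
            "ref_ids_a": np.asarray(self.ref_ids_a, dtype=str),
            "ref_ids_b": np.asarray(self.ref_ids_b, dtype=str),
            "config_json": np.asarray(
                json.dumps(self.config.__dict__, default=list)
            ),
        }
        for which, net in (("a", self.network_a), ("b", self.network_b)):
            for key, val in net.state_dict().items():
                payload[f"{which}_{key}"] = np.asarray(val)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str) -> "TrainedDecomposer":
        with np.load(path, allow_pickle=False) as archive:
            data = {k: archive[k] for k in archive.files}
        cfg_raw = json.loads(str(data.pop("config_json")))
        cfg_raw["batch_size"] = int(cfg_raw["batch_size"])
        cfg = TrainingConfig(**cfg_raw)
        nets = {}
        for which in ("a", "b"):
            state = {
                k[len(which) + 1 :]: v
                for k, v in data.items()
                if k.startswith(which + "_")
            }
            state["hidden_sizes"] = state["hidden_sizes"].tolist()
            nets[which] = MLPClassifier.from_state_dict(state)
        return cls(
            network_a=nets["a"],
            network_b=nets["b"],
            ref_ids_a=data["ref_ids_a"].astype(object),
            ref_ids_b=data["ref_ids_b"].astype(object),
            gene_ids=data["gene_ids"].astype(object),
            config=cfg,
        )


@dataclass
class SelectionResult:
    """Per-doublet score vectors for both types plus the selection rule."""

    scores_a: np.ndarray  # doublets x K_a
    scores_b: np.ndarray  # doublets x K_b
    ref_ids_a: np.ndarray
    ref_ids_b: np.ndarray
    cutoff: float = SCORE_CUTOFF

    def __post_init__(self) -> None:
        for s in (self.scores_a, self.scores_b):
            sums = np.asarray(s).sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-5):
                raise ValueError("score vectors must each sum to 1")

    def scores(self, which: str) -> np.ndarray:
        return {"a": self.scores_a, "b": self.scores_b}[which]

    def ref_ids(self, which: str) -> np.ndarray:
        return {"a": self.ref_ids_a, "b": self.ref_ids_b}[which]

    def predict_pair(self) -> tuple[np.ndarray, np.ndarray]:
        """Argmax reference index per type; ties resolve to the lowest index."""
        return (
            np.argmax(self.scores_a, axis=-1),
            np.argmax(self.scores_b, axis=-1),
        )

    def selected(
        self,
        which: str,
        cutoff: float | None = None,
        mode: str = "union",
    ):
        """Reference cells scoring strictly above ``cutoff``.

        ``mode="union"`` (default) aggregates over the doublet set and
        returns the set of selected reference cell ids; ``mode="per_doublet"``
        returns one id list per doublet.
        """
        cutoff = self.cutoff if cutoff is None else cutoff
        if not 0.0 <= cutoff < 1.0:
            raise ValueError("cutoff must be in [0, 1)")
        s = self.scores(which)
        ids = self.ref_ids(which)
        hits = s > cutoff
        if mode == "union":
            return set(ids[hits.any(axis=0)])
        if mode == "per_doublet":
            return [list(ids[row]) for row in hits]
        raise ValueError(f"unknown selection mode: {mode!r}")

    def to_frame(self, which: str, floor: float = 1e-4):
        """Long-format score table (doublet, reference cell, score > floor)."""
        import pandas as pd

        s = self.scores(which)
        ids = self.ref_ids(which)
        d_idx, c_idx = np.where(s > floor)
        return pd.DataFrame(
            {
                "doublet": d_idx,
                "cell_type": which,
                "reference_cell": ids[c_idx],
                "score": s[d_idx, c_idx],
            }
        )


# ---------------------------------------------------------------------------
# Functional wrappers (thin aliases over the model/results API)
# ---------------------------------------------------------------------------

def train(
    doublets: ArtificialDoubletSet,
    spec_a: NetworkSpec,
    spec_b: NetworkSpec,
    cfg: TrainingConfig,
    ref_ids_a=None,
    ref_ids_b=None,
) -> TrainedDecomposer:
    """Train twin networks; reference ids default to panel indices."""
    if ref_ids_a is None:
        ref_ids_a = [f"A_{i}" for i in range(spec_a.output_dim)]
    if ref_ids_b is None:
        ref_ids_b = [f"B_{i}" for i in range(spec_b.output_dim)]
    model = DoubletDecomposer(doublets, ref_ids_a, ref_ids_b, spec_a, spec_b)
    return model.fit(cfg)


def score_doublets(model: TrainedDecomposer, doublets) -> SelectionResult:
    return model.score_doublets(doublets)


def predict_pair(scores: SelectionResult) -> tuple[np.ndarray, np.ndarray]:
    return scores.predict_pair()


def select_cells(
    scores: SelectionResult, cutoff: float = SCORE_CUTOFF, mode: str = "union"
) -> dict[str, object]:
    """Selected reference cells per type (see ``SelectionResult.selected``)."""
    return {
        "a": scores.selected("a", cutoff=cutoff, mode=mode),
        "b": scores.selected("b", cutoff=cutoff, mode=mode),
    }
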