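"""Artificial doublets: alpha-mixtures of single-cell UMI count vectors.

An artificial doublet is a convex combination of one cell of each type,

    mix = alpha * umi_a + (1 - alpha) * umi_b,

with the mixing factor drawn from the nine-point grid
{0.1, 0.2, ..., 0.9}.  Mixtures are kept real-valued: rounding is
immaterial once the downstream consumer applies counts-per-million
scaling, but an optional flag rounds for sensitivity checks.  Every
mixture carries its recipe (the two source cell indices and alpha) as
ground truth for training and evaluation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expr_data import ExpressionMatrix

__all__ = [
    "ALPHA_GRID",
    "DoubletRecipe",
    "ArtificialDoubletSet",
    "mix",
    "sample_recipes",
    "build_training_set",
    "write_doublet_set",
    "read_doublet_set",
]

ALPHA_GRID: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def _validate_alpha(alpha: float) -> float:
    matches = np.isclose(alpha, ALPHA_GRID, rtol=0, atol=1e-12)
    if not matches.any():
        raise ValueError(
            f"alpha={alpha} is not on the mixing grid {list(ALPHA_GRID)}"
        )
    return float(np.asarray(ALPHA_GRID)[matches][0])


@dataclass(frozen=True)
class DoubletRecipe:
    """Ground truth for one artificial doublet."""

    index_a: int
    index_b: int
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _validate_alpha(self.alpha))
        if self.index_a < 0 or self.index_b < 0:
            raise ValueError("cell indices must be non-negative")


@dataclass
class ArtificialDoubletSet:
    """Mixture matrix plus the per-row recipes that generated it."""

    mixtures: np.ndarray  # doublets x genes, real-valued
    recipes: list[DoubletRecipe]
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.mixtures = np.asarray(self.mixtures, dtype=np.float64)
        if self.mixtures.shape[0] != len(self.recipes):
            raise ValueError("row count must equal recipe count")
        if self.mixtures.size and self.mixtures.min() < 0:
            raise ValueError("mixtures must be non-negative")
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    @property
    def n_doublets(self) -> int:
        return self.mixtures.shape[0]

    def targets(self, which: str) -> np.ndarray:
        """Ground-truth reference indices for one type ('a' or 'b')."""
        if which == "a":
            return np.array([r.index_a for r in self.recipes], dtype=np.int64)
        if which == "b":
            return np.array([r.index_b for r in self.recipes], dtype=np.int64)
        raise ValueError("which must be 'a' or 'b'")

    def alphas(self) -> np.ndarray:
        return np.array([r.alpha for r in self.recipes])


def mix(umi_a: np.ndarray, umi_b: np.ndarray, alpha: float) -> np.ndarray:
    """Element-wise alpha-mixture of two count vectors, without rounding."""
    alpha = _validate_alpha(alpha)
    a = np.asarray(umi_a, dtype=np.float64)
    b = np.asarray(umi_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("count vectors must be non-negative")
    return alpha * a + (1.0 - alpha) * b


def sample_recipes(
    n_a: int, n_b: int, n_doublets: int, seed: int
) -> list[DoubletRecipe]:
    """Draw recipes uniformly and independently, with replacement.

    index_a ~ U{0..n_a-1}, index_b ~ U{0..n_b-1}, alpha ~ U(grid); a fixed
    seed reproduces the list exactly.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("need at least one cell of each type")
    if n_doublets < 1:
        raise ValueError("n_doublets must be positive")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, n_a, size=n_doublets)
    idx_b = rng.integers(0, n_b, size=n_doublets)
    alphas = rng.choice(ALPHA_GRID, size=n_doublets)
    return [
        DoubletRecipe(int(a), int(b), float(al))
        for a, b, al in zip(idx_a, idx_b, alphas)
    ]


def build_training_set(
    type_a: ExpressionMatrix,
    type_b: ExpressionMatrix,
    recipes: Sequence[DoubletRecipe],
    *,
    round_counts: bool = False,
) -> ArtificialDoubletSet:
    """Materialize the mixture matrix for a list of recipes.

    Both matrices must share the (already filtered) gene list, in order.
    """
    if list(type_a.gene_ids) != list(type_b.gene_ids):
        raise ValueError("type A and type B matrices must share the gene list")
    idx_a = np.array([r.index_a for r in recipes], dtype=np.int64)
    idx_b = np.array([r.index_b for r in recipes], dtype=np.int64)
    if idx_a.size and (idx_a.max() >= type_a.n_cells or idx_b.max() >= type_b.n_cells):
        raise IndexError("recipe cell index out of range")
    alphas = np.array([r.alpha for r in recipes])[:, None]
    mixtures = alphas * type_a.counts[idx_a] + (1.0 - alphas) * type_b.counts[idx_b]
    if round_counts:
        mixtures = np.round(mixtures)
    return ArtificialDoubletSet(
        mixtures=mixtures, recipes=list(recipes), gene_ids=type_a.gene_ids
    )


def write_doublet_set(dset: ArtificialDoubletSet, prefix: str) -> None:
    """Persist mixtures as a dense TSV and recipes as a companion TSV."""
    df = pd.DataFrame(
        dset.mixtures,
        index=[f"doublet_{i}" for i in range(dset.n_doublets)],
        columns=dset.gene_ids,
    )
    df.to_csv(prefix + ".mixtures.tsv", sep="\t")
    rec = pd.DataFrame(
        {
            "index_a": dset.targets("a"),
            "index_b": dset.targets("b"),
            "alpha": dset.alphas(),
        }
    )
    rec.to_csv(prefix + ".recipes.tsv", sep="\t", index=False)


def read_doublet_set(prefix: str) -> ArtificialDoubletSet:
    mix_path = prefix + ".mixtures.tsv"
    rec_path = prefix + ".recipes.tsv"
    for p in (mix_path, rec_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    df = pd.read_csv(mix_path, sep="\t", index_col=0)
    rec = pd.read_csv(rec_path, sep="\t")
    recipes = [
        DoubletRecipe(int(r.index_a), int(r.index_b), float(r.alpha))
        for r in rec.itertuples()
    ]
    return ArtificialDoubletSet(
        mixtures=df.to_numpy(),
        recipes=recipes,
        gene_ids=df.columns.astype(str).to_numpy(),
    )
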