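"""Synthetic two-cell-type scRNAseq data with a spiked interaction signature.

The generator emulates the salient structure of the hepatocyte / liver
endothelial cell (LEC) setting in which doublet decomposition was
developed: two cell types with distinct expression programs, a strongly
asymmetric sequencing depth (LEC-like cells carry an order of magnitude
fewer UMIs per cell than hepatocyte-like cells), and a subpopulation of
"interacting" type-A cells whose signature genes are upregulated — the
neighboring-cell-dependent expression that the downstream differential
test is meant to recover.

Counts follow a gamma-Poisson (negative binomial) model: gene g in a cell
of type t has expectation ``depth_t * rate_tg`` where the per-type rate
vectors sum to one, and a single shared dispersion parameter controls
overdispersion.  Marker genes are type-exclusive (near-zero rate in the
other type); everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doublet_synthesis import (
    ALPHA_GRID,
    ArtificialDoubletSet,
    DoubletRecipe,
    build_training_set,
)
from .expr_data import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_two_types",
    "spike_interaction_signature",
    "simulate_pc_doublets",
    "write_truth",
]

# rate attenuation of a marker gene in the non-marked type
_MARKER_LEAK = 0.01


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the two-type generator.

    Defaults put type A in the deep (hepatocyte-like, 20,000 UMI/cell)
    regime and type B in the shallow (LEC-like, 2,000 UMI/cell) regime,
    with 10% of genes type-exclusive markers, 20 signature genes spiked
    4-fold in half of the type-A cells.
    """

    n_cells_a: int = 200
    n_cells_b: int = 200
    n_genes: int = 2000
    depth_a: float = 20000.0
    depth_b: float = 2000.0
    marker_frac: float = 0.1
    dispersion: float = 0.3
    signature_genes: int = 20
    signature_fc: float = 4.0
    interacting_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells_a, self.n_cells_b, self.n_genes) < 1:
            raise ValueError("cell and gene counts must be positive")
        if min(self.depth_a, self.depth_b) <= 0:
            raise ValueError("depths must be positive")
        for name in ("marker_frac", "interacting_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.signature_fc < 1.0:
            raise ValueError("signature_fc must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated matrix."""

    cell_type: np.ndarray  # per cell: "A" or "B"
    interacting: np.ndarray  # boolean per cell; only type-A cells can be True
    signature_gene_ids: list[str]
    rates: dict = field(default_factory=dict)  # per-type base rate vectors


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_two_types(config: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw a combined two-type count matrix plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes

    # lognormal base expression program shared by both types
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    n_markers = int(round(config.marker_frac * n_genes))
    marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
    half = n_markers // 2
    markers_a = marker_idx[:half]
    markers_b = marker_idx[half:]

    rate_a = base.copy()
    rate_b = base.copy()
    rate_a[markers_b] *= _MARKER_LEAK
    rate_b[markers_a] *= _MARKER_LEAK
    rate_a /= rate_a.sum()
    rate_b /= rate_b.sum()

    counts_a = _nb_counts(
        rng, np.broadcast_to(config.depth_a * rate_a, (config.n_cells_a, n_genes)),
        config.dispersion,
    )
    counts_b = _nb_counts(
        rng, np.broadcast_to(config.depth_b * rate_b, (config.n_cells_b, n_genes)),
        config.dispersion,
    )

    gene_ids = np.array([f"gene_{i}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array(
        [f"A_{i}" for i in range(config.n_cells_a)]
        + [f"B_{i}" for i in range(config.n_cells_b)],
        dtype=object,
    )
    cell_type = np.array(
        ["A"] * config.n_cells_a + ["B"] * config.n_cells_b, dtype=object
    )
    matrix = ExpressionMatrix(
        np.vstack([counts_a, counts_b]),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_type=cell_type,
    )

    n_interacting = int(round(config.interacting_frac * config.n_cells_a))
    interacting_a = rng.choice(config.n_cells_a, size=n_interacting, replace=False)
    interacting = np.zeros(matrix.n_cells, dtype=bool)
    interacting[interacting_a] = True

    # signature genes: non-marker genes expressed in both types
    candidates = np.setdiff1d(np.arange(n_genes), marker_idx)
    sig_idx = rng.choice(candidates, size=config.signature_genes, replace=False)

    truth = SimulationTruth(
        cell_type=cell_type,
        interacting=interacting,
        signature_gene_ids=[str(gene_ids[i]) for i in np.sort(sig_idx)],
        rates={
            "A": rate_a,
            "B": rate_b,
            "markers_a": gene_ids[np.sort(markers_a)].tolist(),
            "markers_b": gene_ids[np.sort(markers_b)].tolist(),
        },
    )
    return matrix, truth


def spike_interaction_signature(
    matrix: ExpressionMatrix, truth: SimulationTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """Upregulate the signature genes in the interacting type-A cells.

    An independent negative-binomial component with expectation
    ``(signature_fc - 1) * depth_a * rate`` is added to the affected
    entries, so the expected expression is exactly ``signature_fc`` times
    the baseline and ``signature_fc = 1`` leaves the matrix untouched.
    All other entries are returned unchanged.
    """
    if not truth.interacting.any():
        raise ValueError("no interacting cells to spike")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    counts = matrix.counts.copy()
    gene_index = pd.Index(matrix.gene_ids)
    sig_locs = gene_index.get_indexer(truth.signature_gene_ids)
    if (sig_locs < 0).any():
        raise ValueError("signature genes missing from matrix")
    cells = np.where(truth.interacting)[0]
    extra_rate = (config.signature_fc - 1.0) * config.depth_a * truth.rates["A"][sig_locs]
    if config.signature_fc > 1.0:
        extra = _nb_counts(
            rng,
            np.broadcast_to(extra_rate, (len(cells), len(sig_locs))),
            config.dispersion,
        )
        counts[np.ix_(cells, sig_locs)] += extra
    return ExpressionMatrix(
        counts,
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        cell_type=matrix.cell_type,
    )


def simulate_pc_doublets(
    matrix: ExpressionMatrix,
    truth: SimulationTruth,
    n_doublets: int,
    seed: int,
) -> ArtificialDoubletSet:
    """Emulate paired-cell sequencing: mix interacting A cells with B cells.

    Every doublet pairs a uniformly drawn interacting type-A cell with a
    uniformly drawn type-B cell via the alpha-mixing equation; recipes
    record indices *within each type's matrix* as ground truth.
    """
    is_a = truth.cell_type == "A"
    is_b = truth.cell_type == "B"
    interacting_a = np.where(truth.interacting[is_a])[0]
    if interacting_a.size == 0 or not is_b.any():
        raise ValueError("need at least one interacting A cell and one B cell")
    mat_a = matrix.subset_cells(np.where(is_a)[0])
    mat_b = matrix.subset_cells(np.where(is_b)[0])
    rng = np.random.default_rng(seed)
    idx_a = rng.choice(interacting_a, size=n_doublets)
    idx_b = rng.integers(0, mat_b.n_cells, size=n_doublets)
    alphas = rng.choice(ALPHA_GRID, size=n_doublets)
    recipes = [
        DoubletRecipe(int(a), int(b), float(al))
        for a, b, al in zip(idx_a, idx_b, alphas)
    ]
    return build_training_set(mat_a, mat_b, recipes)


def write_truth(truth: SimulationTruth, matrix: ExpressionMatrix, prefix: str) -> None:
    """Emit the truth TSV (cell id, type, interacting flag) and gene list."""
    pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "cell_type": truth.cell_type,
            "interacting": truth.interacting.astype(int),
        }
    ).to_csv(prefix + ".truth.tsv", sep="\t", index=False)
    pd.Series(truth.signature_gene_ids).to_csv(
        prefix + ".signature_genes.txt", index=False, header=False
    )
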