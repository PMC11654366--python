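# scduet

Decompose the transcriptome of a two-cell clump (doublet) into the two
reference single cells that compose it, and find the genes whose
expression depends on having the other cell type as a physical neighbor.

Protocols such as paired-cell RNA sequencing deliberately capture
physically interacting cell pairs — for example hepatocytes attached to
liver endothelial cells — and sequence the pooled transcriptome of the
clump.  scduet answers two questions about such data:

1. **Which single cells made this doublet?**  One softmax network per
   cell type is trained on artificial doublets built by convex mixing of
   reference UMI profiles,

       mix = α · UMI_A + (1 − α) · UMI_B,   α ∈ {0.1, …, 0.9},

   and maps the CPM-normalized doublet profile to a probability
   distribution over that type's reference cells (hidden layers
   2048/1024/512 ReLU units by default, categorical cross-entropy, Adam).

2. **What does interaction do to expression?**  Reference cells scoring
   above 0.01 in at least one real doublet are treated as the interacting
   subpopulation; a per-gene two-sided Wilcoxon–Mann–Whitney test
   (Benjamini–Hochberg adjusted, log2 fold change with pseudo-count
   b = 1) contrasts them with the unselected cells of the same type.
   Genes with adjusted p < 0.05 and |logFC| > 0.5 are the
   neighboring-cell-dependent genes.

The package ships a negative-binomial synthetic-data generator that
reproduces the regime this method was designed for — two cell types with
a ten-fold per-cell depth asymmetry and a spiked interaction signature —
so the entire pipeline is testable without external data.  Comparators
(multinomial logistic regression, naive Bayes) and a five-fold
cross-validation benchmark are included.

## Worked example

```python
import numpy as np
from scduet import (
    SimulationConfig, simulate_two_types, spike_interaction_signature,
    simulate_pc_doublets, sample_recipes, build_training_set,
    DoubletDecomposer, NetworkSpec, TrainingConfig, neighboring_de,
)

cfg = SimulationConfig(seed=0)          # 200+200 cells, 2000 genes,
matrix, truth = simulate_two_types(cfg)  # depths 20000 vs 2000 UMI/cell
spiked = spike_interaction_signature(matrix, truth, cfg)
is_a = truth.cell_type == "A"
ref_a = spiked.subset_cells(np.where(is_a)[0])
ref_b = spiked.subset_cells(np.where(~is_a)[0])

# train the twin networks on 20,000 artificial doublets
recipes = sample_recipes(ref_a.n_cells, ref_b.n_cells, 20_000, seed=0)
doublets = build_training_set(ref_a, ref_b, recipes)
model = DoubletDecomposer(
    doublets, ref_a.cell_ids, ref_b.cell_ids,
    spec_a=NetworkSpec(2000, 200, (256, 128, 64)),
    spec_b=NetworkSpec(2000, 200, (256, 128, 64)),
)
fitted = model.fit(TrainingConfig(epochs=20, seed=0))

# decompose simulated paired-cell doublets and select interacting cells
pc = simulate_pc_doublets(spiked, truth, 2000, seed=1)
scores = fitted.score_doublets(pc)
pred_a, pred_b = scores.predict_pair()
selected = scores.selected("a", cutoff=0.01)

# neighboring-cell-dependent genes among the type-A reference cells
de = neighboring_de(ref_a, selected)
print(de.summary())
```

On this simulation the run prints (abridged):

```
Neighboring-cell-dependent differential expression
========================================================
selected cells: 107   unselected: 93
cutoffs: adjusted p < 0.05, |logFC| > 0.5 (b = 1.0)
upregulated genes: 19   downregulated: 0
     gene  mean_selected  mean_other   u_stat     pval  pval_adj  log_fc direction  pass
 gene_659             22        5.29  7.6e+03 1.41e-10   3.2e-09    1.87        up  True
 ...
```

The decomposer's selection captures all 100 truly interacting cells
(plus 7 false selections), and the differential test recovers 19 of the
20 spiked signature genes (4-fold upregulation in interacting cells) as
"up" with no spurious downregulated calls.  Exact counts vary slightly
with the seed.

A shell workflow covering the same chain is available as subcommands:

```bash
scduet simulate --out-prefix data --seed 0
scduet mix --type-a data.typeA.tsv --type-b data.typeB.tsv --out-prefix art
scduet train --doublets art --type-a data.typeA.tsv --type-b data.typeB.tsv \
             --out model.npz
scduet decompose --model model.npz --doublets data.pc --out scores.tsv
scduet select --scores scores.tsv --out selected.tsv
scduet de --matrix data.typeA.tsv --selected selected.tsv --out de.tsv
scduet evaluate --type-a data.typeA.tsv --type-b data.typeB.tsv --out report.tsv
```

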