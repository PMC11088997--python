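# clonoscope

Clone calling, lineage coupling, and perturbation statistics for joint
CRISPR-perturbation + lineage-barcode single-cell experiments.

In experiments that combine in vivo CRISPR perturbation (CROP-seq-style, one
guide per embryo) with heritable lineage barcoding (transposon-delivered
37-bp tags read out in scRNA-seq libraries), the analysis questions are
clonal: which cells descend from the same progenitor, whether clones span
cell classes (mitotic progenitors, GABAergic projection neurons, MGE/CGE
interneurons) more or less often than chance, and whether a perturbation
shifts the output of progenitors from one fate to another. `clonoscope`
provides that pipeline as a tested library with a thin CLI, plus a synthetic
data generator with known ground truth so every stage has a
parameter-recovery test without any external download.

## What it computes

- **Clone calling** — anchored extraction of the fixed-length lineage barcode
  from reads, mean-Phred ≥ 30 filtering, UMI collapsing, single-linkage
  Hamming clustering at distance ≤ 3, and per-batch bipartite
  cell↔barcode-cluster components as clones.
- **Clonal fate composition** — UpSet-style clone–class intersection counts
  and per-arm proportions; clone-size summaries.
- **Lineage coupling** — for cell states *i, j*, the observed count of clones
  shared between both states, O<sub>ij</sub>, against the independence
  expectation E<sub>ij</sub> = (Σ<sub>k</sub>O<sub>ik</sub> ·
  Σ<sub>k</sub>O<sub>kj</sub>) / Σ<sub>kl</sub>O<sub>kl</sub>; the score is
  the median O/E over 1,000 random 25% clone subsamples, with empirical
  p-values (direction consistency across trials, pseudo-counted) and BH-FDR.
  A score of 1 means coupling at random expectation.
- **Differential abundance** — per cell type, Poisson regression
  log E[count] = β₀ + β_arm + β_batch + log(total), so β_arm is the log
  proportion ratio perturbed vs control; Wald p, BH-FDR; plus
  log₁₀ proportion ratios and linear-model effects of perturbation on gene
  module scores (Bonferroni).
- **IN/PN fate classifier** — balanced, cross-validated L1 logistic
  regression on the 3,000 most variable genes (2/3 train, 1/3 validation);
  per-gene sigmoid fate scores in (0, 1) with 0.5 = uninformative.
- **Peak annotation** — signed nearest-TSS distances, ±5 kb promoter
  windows, shared/exclusive classification of two TF binding-site sets,
  Pearson Chi² enhancer enrichment, and promoter ∪ enhancer target-gene
  assignment (BED 0-based half-open throughout).

## Worked example

Simulate a two-arm, two-batch experiment (600 clones per arm, 15% of PN fate
probability moved to IN classes in the perturbed arm), call clones from the
synthetic reads, and test the composition shift:

```python
import clonoscope as cs
from sklearn.metrics import adjusted_rand_score

cfg = cs.SimConfig(n_progenitors=300, n_batches=2, fate_shift_delta=0.15, seed=1)
clone_truth, truth = cs.simulate_clones(cfg)
library = cs.generate_barcode_library(clone_truth["clone_id"].nunique(), seed=1)
reads, read_truth = cs.synthesize_fastq(clone_truth, library, cfg)

meta = clone_truth[["cell_id", "cell_class", "arm", "batch"]]
called, qc = cs.process_reads(reads, cell_metadata=meta)
m = clone_truth.merge(called, on="cell_id", suffixes=("_t", "_c"))
print(qc["reads_in"], qc["n_cells_assigned"],
      adjusted_rand_score(m["clone_id_t"], m["clone_id_c"]))

effects = cs.composition_poisson(cs.composition_table(called), control_label="gLacZ")
print(effects.round(4).to_string(index=False))
```

```
47560 2378 1.0
cell_type  effect     se      p  unstable      q
   IN-CGE  0.5309 0.0929 0.0000     False 0.0000
   IN-MGE  0.3539 0.0951 0.0002     False 0.0003
       PN -0.4202 0.0651 0.0000     False 0.0000
  mitotic -0.0229 0.0956 0.8110     False 0.8110
```

All 47,560 reads are called back into the true 1,200 clones exactly
(adjusted Rand index 1.0). The Poisson effects recover the simulated fate
shift: the PN proportion drops (effect −0.42, a rate ratio of e^−0.42 ≈ 0.66)
while both IN classes rise, and the untouched mitotic class is null
(p = 0.81). The same table drives `log_ratio_composition` for
log₁₀-proportion-ratio dot plots.

The CLI mirrors the library:

```
clonoscope simulate --out-dir sim --seed 1
clonoscope clones --fastq sim/reads.fastq --metadata meta.tsv --min-q 30 \
    --distance 3 --out-table clones.tsv
clonoscope coupling --clone-table clones.tsv --states mitotic,PN,IN-MGE,IN-CGE \
    --trials 1000 --frac 0.25 --seed 1 --out-prefix coupling/run1
clonoscope annotate-peaks --peaks peaks.bed --tss tss.bed --enhancers links.tsv \
    --half-width 5000 --out-prefix annot/run1
```

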