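# genefs

Feature selection for two-class gene-expression classification.

High-dimensional expression studies (microarray or RNA-seq, bulk or
single-cell pseudobulk) routinely face tens of thousands of genes against
at most a few hundred samples. `genefs` implements a complete selection
pipeline for the two-class (e.g. tumour vs. control) setting, aimed at
computational biologists who want a small, discriminative gene panel plus
an honest held-out evaluation of it:

1. **FDR screening** — a per-gene two-sided Welch *t*-test followed by
   Benjamini–Hochberg step-up adjustment; genes with *q* below a strict
   threshold become candidates.
2. **SVM-RFE with per-stage parameter optimization** — recursive feature
   elimination ranked by the squared SVM weight, with the RBF-kernel pair
   (C, γ) re-optimized during elimination by exhaustive **grid search**,
   **particle swarm optimization (PSO)**, or a real-coded **genetic
   algorithm (GA)**, each maximizing stratified cross-validated accuracy.
3. **Comparator selectors** — random-forest backward elimination
   (**RFFS**, and **RFFS-GS** with grid-tuned `max_features` /
   `n_estimators`) and **mRMR** with the Ω/n\* candidate-set-size rule.
4. **Nested-subset evaluation** — the smallest top-*k* subset maximizing
   training-set CV accuracy, scored on held-out samples with
   accuracy/precision/recall/F and the ROC/AUC of the continuous SVM
   decision values.
5. A **synthetic-data generator** with planted informative, redundant and
   noise genes, so every selector is testable without external downloads.

## The core algorithms

**SVM-RFE.** Train a soft-margin SVM on the surviving genes, score each
gene by the ranking criterion

```
c_k = ω_k²,     ω = Σ_i α_i y_i x_i
```

remove the argmin, and repeat until no gene survives; prepending removed
genes gives a total ranking (rank 1 = last survivor). Under the RBF kernel
ω is taken as the input-space pseudo-weight (a kernel-space criterion —
the change in the margin term αᵀdiag(y)·K·diag(y)α when a feature is
dropped — is available via `criterion="kernel"`).

**Parameter optimization.** All three optimizers work on (log₂C, log₂γ) in
the conventional box C ∈ 2^[−5,15], γ ∈ 2^[−15,3], with fitness =
stratified k-fold CV accuracy. PSO uses the canonical global-best update
`v ← wv + c₁r₁(pbest−x) + c₂r₂(gbest−x)`; the GA uses tournament
selection, BLX-0.5 blend crossover, Gaussian mutation and elitism of one.

**BH adjustment.** For sorted p₍₁₎ ≤ … ≤ p₍ₘ₎,
`q₍ᵢ₎ = min_{j≥i} min(1, p₍ⱼ₎·m/j)`, returned in the input gene order.

**mRMR (MID).** First pick argmax MI(gene, label); each later pick
maximizes `MI(gene, label) − mean_{s∈S} MI(gene, s)` over the unselected
genes, with mutual information computed in bits on three-level-coded
(z < −1 / |z| ≤ 1 / z > 1) expression.

## Worked example

`examples/05_full_pipeline.py` simulates a balanced 130-sample cohort
(200 genes, 10 informative at a 1.5 sd shift plus 10 redundant copies),
splits it in half, screens at q < 0.2, ranks with SVM-RFE-PSO, picks the
subset, and evaluates on the untouched half:

```
$ python examples/05_full_pipeline.py
genes selected: 3 (G0010, G0003, G0007)
confusion (TP FP FN TN): 32 1 0 31
test accuracy:  98.4375%
precision:      96.9697%
recall:         100.0000%
F-score:        98.4615%
AUC:            0.99805
```

Three planted genes suffice here: the selector found a subset whose SVM
misclassifies one control sample (FP = 1) on the 64-sample test half, and
whose decision values rank nearly every cancer sample above every control
(AUC ≈ 0.998). The other `examples/` scripts exercise each capability in
isolation (screening, SVM-RFE-PSO ranking, RFFS, mRMR/n\*).

A thin CLI wraps the same library calls:

```bash
genefs simulate --outdir sim --seed 1
genefs run --config config.yaml --outdir out
```

## Data formats

Delimited TSV/CSV expression tables with a header row, either
samples-by-genes or genes-by-samples (transposed on read); labels come
from a column of the table or a separate two-column file and are mapped to
{−1, +1} with +1 the positive (cancer) class. Values are used as given —
no log transform or imputation is applied, and missing values are
rejected.
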