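"""End-to-end run: split, FDR screen, SVM-RFE-PSO, subset choice, held-out
evaluation.

Emulates a balanced 130-sample cohort, splits it in half, screens genes at
q < 0.2 on the training half, ranks survivors by PSO-tuned SVM-RFE, picks
the smallest top-k subset maximizing training CV accuracy, and scores the
final SVM on the untouched test half.
"""

import tempfile

from genefs import PipelineConfig, SyntheticSpec, run_pipeline

with tempfile.TemporaryDirectory() as outdir:
    config = PipelineConfig(
        synthetic=SyntheticSpec(
            n_per_class=65, p=200, k_informative=10, k_redundant=10,
            delta=1.5, redundancy_noise=0.3, seed=42,
        ),
        seed=0,
        selector="svm-rfe-pso",
        reoptimize_every=25,
        optimizer_kwargs={"swarm_size": 8, "iterations": 10},
        eval_folds=5,
        outdir=outdir,
    )
    report = run_pipeline(config)

print(f"genes selected: {len(report.subset)} ({', '.join(report.subset)})")
print(f"confusion (TP FP FN TN): {report.tp} {report.fp} {report.fn} {report.tn}")
print(f"test accuracy:  {100 * report.accuracy:.4f}%")
print(f"precision:      {100 * report.precision:.4f}%")
print(f"recall:         {100 * report.recall:.4f}%")
print(f"F-score:        {100 * report.f_score:.4f}%")
print(f"AUC:            {report.auc:.5f}")
# Accuracy/precision/recall/F are computed from hard SVM labels on the
# held-out half; AUC integrates the ROC of the continuous decision values.
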