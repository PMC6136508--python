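"""Rank genes by SVM-RFE with particle-swarm-tuned RBF parameters.

Plants 10 informative genes (1.5 sd shift) among 190 others, runs the
recursive elimination with (C, gamma) re-optimized by PSO during the
elimination, and checks how many planted genes land in the top 20 ranks.
"""

from genefs import SyntheticSpec, generate, rfe_rank

expr, truth = generate(SyntheticSpec(
    n_per_class=30, p=200, k_informative=10, k_redundant=0, delta=1.5, seed=3,
))
ranked = rfe_rank(
    expr, optimizer="pso", kernel="rbf",
    reoptimize_every=50,          # re-tune (C, gamma) every 50 eliminations
    seed=0, cv_folds=3,
    optimizer_kwargs={"swarm_size": 8, "iterations": 10},
)
top20 = ranked.by_rank()[:20]
hits = len(set(top20) & set(truth.informative_ids))
last = ranked.per_iteration[-1]
print(f"top 20 of {expr.n_genes} ranks contain {hits}/10 planted genes")
print(f"rank-1 gene: {ranked.by_rank()[0]} "
      f"(planted: {ranked.by_rank()[0] in truth.informative_ids})")
print(f"(C, gamma) used at the final elimination: "
      f"({last.params.C:.4g}, {last.params.gamma:.4g})")
# Planted genes carry the class signal, so a working selector concentrates
# them at the top of the elimination ranking.
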