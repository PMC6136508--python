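"""mRMR gene selection and the omega/n* candidate-set size rule.

Selects genes greedily by relevance-minus-redundancy (mutual information on
three-level-coded expression), then picks the candidate-set size n* from
the cross-validation error curve over nested prefixes.
"""

from genefs import SyntheticSpec, generate, mrmr_rank, select_candidate_size

expr, truth = generate(SyntheticSpec(
    n_per_class=30, p=40, k_informative=5, k_redundant=5, delta=2.0, seed=7,
))
ranking = mrmr_rank(expr, n=15)
print("first five picks:", ", ".join(ranking.selection_order[:5]))
signal = set(truth.informative_ids) | set(truth.redundant_ids)
print(f"picks 1-10 contain {len(set(ranking.selection_order[:10]) & signal)} signal genes")

cand = select_candidate_size(ranking, expr, folds=5, tolerance=0.01, seed=0)
print(f"error curve e_k: {[round(float(e), 3) for e in cand.errors_by_k]}")
print(f"omega (stable low-error sizes): {cand.omega}")
print(f"n* = {cand.n_star} genes at CV error e* = {cand.e_star:.3f}")
# mRMR avoids picking redundant copies early; n* is the smallest prefix
# size whose CV error matches the best seen within the tolerance band.
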