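"""Annotate a target gene by guilt by association on a simulated cohort.

Simulates a 2,000-gene x 300-sample count cohort in which one planted
50-gene set is negatively coupled to the target and one positively, then
Spearman-correlates every gene with the target, selects the bottom 5% (the
most negatively correlated genes), and runs hypergeometric
over-representation analysis against the bundled toy gene sets.
"""

import lncannot as L

cfg = L.default_config(seed=1)
matrix, truth = L.generate_expression(cfg)
factors = L.estimate_size_factors(matrix)
logged = L.log_transform(L.normalize(matrix, factors))

ranking = L.correlate_all(logged, cfg.target_gene_id)
print(f"correlated {len(ranking)} genes with {cfg.target_gene_id}")
print(f"strongest positive: {ranking[0].gene_id} rho={ranking[0].rho:.3f}")
print(f"strongest negative: {ranking[-1].gene_id} rho={ranking[-1].rho:.3f}")

selected = L.select_top_fraction(ranking, 0.05, direction="bottom")
universe = {r.gene_id for r in ranking}
results = L.ora(selected, universe, truth.collection)

print(f"\nORA on the bottom 5% ({len(selected)} genes), top 3 sets:")
for r in results[:3]:
    print(f"  {r.set_name:18s} overlap {r.overlap:2d}/{r.set_size}  "
          f"p={r.p_value:.2e}  q={r.q_value:.2e}")
print("\nA tiny p/q for the negatively coupled planted set means the")
print("selection recovered the pathway the target suppresses; decoy sets")
print("should stay near q = 1.")
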