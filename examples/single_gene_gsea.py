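"""Single-gene GSEA: enrichment against a phenotype built from one gene.

Splits the simulated cohort into the top and bottom 10% of samples by the
target gene's expression, ranks all genes by signal-to-noise between the two
groups, and scores every gene set with the weighted KS statistic against a
1,000-draw gene-label permutation null.
"""

import lncannot as L

cfg = L.default_config(seed=1)
matrix, truth = L.generate_expression(cfg)
logged = L.log_transform(L.normalize(matrix, L.estimate_size_factors(matrix)))

results = L.gsea_collection(
    logged, cfg.target_gene_id, truth.collection,
    q=0.10, B=1000, seed=1,
)

print(f"{'set':18s} {'ES':>7s} {'NES':>7s} {'p_nom':>8s} {'FWER':>8s} {'FDR q':>8s}")
for r in results:
    print(f"{r.set_name:18s} {r.es:7.3f} {r.nes:7.3f} "
          f"{r.p_nominal:8.4f} {r.p_fwer:8.4f} {r.q_fdr:8.4f}")

neg = next(r for r in results if r.set_name == "CELL_CYCLE_LIKE")
print(f"\nleading edge of {neg.set_name}: {len(neg.leading_edge)} genes")
print("A strongly negative NES with tiny p/FWER/FDR says the planted")
print("'cell-cycle-like' set concentrates at the bottom of the ranking —")
print("the target behaves as a suppressor of that program. The positively")
print("coupled set mirrors it with a positive NES.")
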