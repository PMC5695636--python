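"""From geometry back to biology: project inferred vertices into gene
Z-score space, and call Bonferroni-significant genes.

Part 1 projects the vertices of a recovered mixture back through the PCA
loadings: each planted subpopulation perturbs its own block of genes, so a
vertex's largest-|Z| genes should land in its block.  (With uniformly mixed
cohorts the vertex Z-scores stay moderate -- column Z-scoring measures each
gene against the cohort's own mixing spread -- so block membership, not
genome-wide significance, is the check here.)

Part 2 applies the Bonferroni gene-list call to a strongly dysregulated
profile, the regime where significant lists are meaningful.
"""
import numpy as np

from scunmix.evaluation import gene_recovery_check, run_single_simplex

out = run_single_simplex(seed=2, g_features=60)
res = out["result"]
truth = out["truth"]

print("Part 1: vertex profiles recovered by projection")
for p in res.profiles:
    top = np.argsort(-np.abs(p.gene_z))[:20]
    blocks = np.bincount(top // 20, minlength=3)
    b = int(np.argmax(blocks))
    print(f"  vertex {p.vertex_id + 1}: top-20 |Z| genes, {blocks[b]}/20 in "
          f"planted block {b + 1} (genes g{20 * b:04d}..g{20 * b + 19:04d}), "
          f"max |Z| = {np.abs(p.gene_z).max():.2f}")

print()
print("Part 2: Bonferroni calling on a planted 50-gene dysregulated profile")
rec = gene_recovery_check(seed=2)
print(f"  genes with |Z| = 8 among 1000: recovered {rec['n_found']}/50, "
      f"exact = {rec['exact']} (alpha = 0.01 after correction)")
print()
print("These per-vertex gene lists are what one would submit to an"
      "\nontological term-enrichment service.")
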