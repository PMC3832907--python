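"""Functional-bin enrichment of a selected gene set.

One bin's membership odds are multiplied by 5 among the selected genes; the
Fisher exact test with Bonferroni and Benjamini-Hochberg correction should
flag exactly that bin.
"""

from estpipe.enrich import BinAnnotation, fisher_enrichment
from estpipe.synthetic_data import SimConfig, gen_annotations

cfg = SimConfig(seed=5, n_genes=2000, n_bins=20, planted_bin_odds=5.0)
genes = [f"g{i}" for i in range(cfg.n_genes)]
selected = genes[:200]
gene_bins, planted = gen_annotations(cfg, genes, selected)

results = fisher_enrichment(selected, genes, BinAnnotation(gene_bins))
print(f"planted bin: {planted}")
print("bin   k/n     K/N      dir    p_raw      p_bonf     p_bh")
for r in results[:5]:
    print(f"{r.bin_code:>3}  {r.k:>3}/{r.n}  {r.K:>4}/{r.N}  {r.direction:>5}  "
          f"{r.p_raw:.2e}  {r.p_bonferroni:.2e}  {r.p_bh:.2e}")
print()
print("The planted bin tops the list with a Bonferroni-corrected p far below")
print("0.05; all other bins are at chance level.")
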