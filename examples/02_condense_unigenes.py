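"""Condensing allelic contigs into IUPAC-ambiguity unigenes.

A non-homozygous source population yields near-identical contig pairs per
gene.  Contigs above 99 % identity and coverage are clustered and condensed
into one consensus whose disagreeing columns carry IUPAC ambiguity codes.
"""

from estpipe.condense import condense_assembly, condensation_summary
from estpipe.synthetic_data import SimConfig, gen_transcriptome

cfg = SimConfig(seed=4, n_genes=12, allele_pair_fraction=0.5, allele_identity=99.5)
_, _, contigs, truth = gen_transcriptome(cfg)
unigenes = condense_assembly(contigs)
summary = condensation_summary(contigs, unigenes)

print(f"input contigs:   {summary['n_contigs']}")
print(f"clusters:        {summary['n_clusters']} "
      f"({summary['n_clustered_members']} member contigs)")
print(f"unigenes:        {summary['n_unigenes']} "
      f"(= {summary['n_contigs']} - {summary['n_clustered_members']}"
      f" + {summary['n_clusters']})")
for u in unigenes:
    if len(u.members) > 1:
        print(f"  {u.id}: members {u.members}, "
              f"ambiguity codes at 1-based {[p + 1 for p in u.ambiguity_positions]}")
print()
print("Each planted allele pair collapses into one unigene; every ambiguity")
print("position marks exactly one planted inter-allele substitution.")
print(f"(planted: {[pos for _, pos in truth.allele_pairs.values()]})")
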