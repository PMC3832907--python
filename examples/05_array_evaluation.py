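"""Oligo-array evaluation: probe design, pre-selection, signal bimodality,
differential expression, and same- vs cross-species comparison.

Same-species hybridizations put most probes in a high-intensity specific
mode; cross-species hybridizations (70 % mismatched probes here) are
dominated by the low background mode, which costs differential-expression
sensitivity.
"""

from estpipe.array_eval import (build_kmer_index, classify_signal_modes,
                                cross_species_overlap, design_probes,
                                differential_expression, pss_select)
from estpipe.synthetic_data import SimConfig, gen_signals, gen_transcriptome

cfg = SimConfig(seed=6, n_genes=60)
_, unigenes, _, _ = gen_transcriptome(cfg)
seqs = {u.id: u.seq for u in unigenes if len(u.seq) >= 60}
kidx = build_kmer_index(seqs)
candidates = []
for uid, seq in seqs.items():
    candidates.extend(design_probes(uid, seq, target_count=4, kmer_index=kidx))
print(f"probe candidates: {len(candidates)} for {len(seqs)} unigenes")

probes = [(c.probe_id, c.unigene_id) for c in candidates]
same, meta, truth = gen_signals(cfg, probes, cross_species=False)
cross, _, _ = gen_signals(cfg, probes, cross_species=True)

selected, split = pss_select(candidates, same.median(axis=1).to_dict(),
                             cross.median(axis=1).to_dict(), n_target=100)
print(f"pre-selection kept {len(selected)} probes "
      f"({split['primary']} by cRNA-like signal, {split['secondary']} topped up)")

for label, mat in (("same-species", same), ("cross-species", cross)):
    fit, _ = classify_signal_modes(mat.to_numpy().ravel())
    print(f"{label}: background weight w_low = {fit.w_low:.2f}, "
          f"modes at log10 {fit.mu_low:.2f}/{fit.mu_high:.2f}, "
          f"effectively unimodal: {fit.effectively_unimodal}")

p2g = dict(probes)
de_same = differential_expression(same, meta, p2g)
de_cross = differential_expression(cross, meta, p2g)
n_same = sum(r.significant for r in de_same)
n_cross = sum(r.significant for r in de_cross)
rep = cross_species_overlap(de_same, de_cross)
print(f"DE genes (|log2FC| >= 1, FDR < 0.05): same {n_same}, cross {n_cross} "
      f"of {len(truth.de_genes)} planted")
print(f"overlap: both {rep.both}, same-only {rep.same_only}, "
      f"cross-only {rep.cross_only}")
print()
print("The dedicated (same-species) platform recovers the planted contrast;")
print("mismatch-attenuated cross-species signals miss most of it.")
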