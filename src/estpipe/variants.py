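"""Inter-accession SNP calling on consensus transcripts.

Each query unigene is assigned to its best reference gene model
(E < 1e-10), re-oriented if its best hit is on the minus strand, globally
aligned to the model, and every non-gap mismatch column yields a candidate
substitution on the reference (1-based).  Positions at which different
queries report different alternate bases are "ambiguous" and are filtered to
a sidecar, mirroring the common practice of dropping multi-allelic transcript
variants.  Because the inputs are consensus transcripts rather than reads,
a single supporting query suffices (no depth model).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .seq_core import IUPAC_TO_BASES, SeqRecord, reverse_complement
from .similarity import HitTable, Scoring, best_hit

logger = logging.getLogger(__name__)

FREQ_BINS = [str(i) for i in range(1, 10)] + [">=10"]


@dataclass
class SNPCall:
    gene_id: str
    pos: int  # 1-based on the reference gene model
    ref_base: str
    alt_base: str
    supporting_queries: list[str] = field(default_factory=list)
    ambiguous: bool = False
    iupac_alt: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("positions are 1-based")


@dataclass
class SNPFrequencyTable:
    rows: dict[str, int]
    total_genes: int

    def __post_init__(self) -> None:
        assert self.total_genes == sum(self.rows.values())


def _global_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    for attr in ("open_left_insertion_score", "extend_left_insertion_score",
                 "open_right_insertion_score", "extend_right_insertion_score",
                 "open_left_deletion_score", "extend_left_deletion_score",
                 "open_right_deletion_score", "extend_right_deletion_score"):
        setattr(a, attr, 0)  # free end gaps (semi-global)
    return a


def _mismatch_columns(ref_seq: str, qry_seq: str, aligner) -> list[tuple[int, str, str]]:
    """(0-based ref position, ref base, query base) for aligned substitution
    columns; gap columns are skipped (SNPs only)."""
    aln = aligner.align(ref_seq, qry_seq)[0]
    rblocks, qblocks = aln.aligned
    out = []
    for (r0, r1), (q0, q1) in zip(rblocks, qblocks):
        for k in range(r1 - r0):
            rb, qb = ref_seq[r0 + k], qry_seq[q0 + k]
            if rb != qb:
                out.append((r0 + k, rb, qb))
    return out


def call_snps(reference_models: Sequence[SeqRecord], query_unigenes: Sequence[SeqRecord],
              hits: HitTable, max_evalue: float = 1e-10,
              scoring: Scoring | None = None,
              ) -> tuple[list[SNPCall], list[SNPCall]]:
    """Call substitutions of every query against its best reference model.

    Returns ``(non_ambiguous, ambiguous)``: identical calls across queries are
    collapsed; positions with more than one distinct alternate base are
    ambiguous and reported separately.  Queries with no qualifying reference
    are skipped with a log entry.
    """
    scoring = scoring or Scoring()
    aligner = _global_aligner(scoring)
    refs = {r.id: r for r in reference_models}
    # (gene, pos0, ref) -> alt -> supporting query ids
    observed: dict[tuple, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for q in query_unigenes:
        h = best_hit(hits, q.id, max_evalue)
        if h is None or h.subject_id not in refs:
            logger.info("query %s has no qualifying reference model; skipped", q.id)
            continue
        ref = refs[h.subject_id]
        qseq = reverse_complement(q.seq) if h.strand == "-" else q.seq
        for pos0, rb, qb in _mismatch_columns(ref.seq, qseq, aligner):
            if qb in IUPAC_TO_BASES and len(IUPAC_TO_BASES[qb]) > 1:
                # ambiguity code in the query: call only if no resolution
                # matches the reference base (conservative)
                if rb in IUPAC_TO_BASES[qb]:
                    continue
            observed[(ref.id, pos0, rb)][qb].append(q.id)
    non_ambiguous, ambiguous = [], []
    for (gene, pos0, rb), alts in sorted(observed.items()):
        is_multi = len(alts) > 1
        for alt, supporters in sorted(alts.items()):
            call = SNPCall(
                gene_id=gene, pos=pos0 + 1, ref_base=rb, alt_base=alt,
                supporting_queries=sorted(set(supporters)), ambiguous=is_multi,
                iupac_alt=len(IUPAC_TO_BASES.get(alt, "X")) > 1,
            )
            (ambiguous if is_multi else non_ambiguous).append(call)
    return non_ambiguous, ambiguous


def snp_frequency_table(calls: Sequence[SNPCall]) -> SNPFrequencyTable:
    """Histogram of per-gene SNP counts binned 1..9 and >=10 (non-ambiguous
    calls only)."""
    if any(c.ambiguous for c in calls):
        raise ValueError("frequency table expects non-ambiguous calls only")
    per_gene = defaultdict(int)
    for c in calls:
        per_gene[c.gene_id] += 1
    rows = {b: 0 for b in FREQ_BINS}
    for n in per_gene.values():
        rows[str(n) if n < 10 else ">=10"] += 1
    return SNPFrequencyTable(rows=rows, total_genes=len(per_gene))


def write_frequency_table(table: SNPFrequencyTable, path) -> None:
    df = pd.DataFrame(
        [(b, n) for b, n in table.rows.items()] + [("Total", table.total_genes)],
        columns=["snp_frequency", "n_gene_models"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_vcf(calls: Sequence[SNPCall], path) -> None:
    """Minimal text VCF: CHROM = gene model id, POS 1-based, INFO carries the
    supporting query ids."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SUPP,Number=.,Type=String,Description="Supporting query ids">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.gene_id, c.pos, c.alt_base)):
            filt = "ambiguous" if c.ambiguous else "PASS"
            fh.write(f"{c.gene_id}\t{c.pos}\t.\t{c.ref_base}\t{c.alt_base}\t.\t{filt}\t"
                     f"SUPP={','.join(c.supporting_queries)}\n")
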