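"""Collapse near-identical allelic contigs into IUPAC-ambiguity unigenes.

A non-homozygous plant population yields several nearly identical contigs per
gene (alleles or very close paralogs differing at SNP sites).  Contigs
matching each other above 99 % identity *and* 99 % coverage are clustered by
single linkage; each cluster is star-aligned on its longest member and
condensed into one consensus in which disagreeing columns carry the minimal
IUPAC ambiguity code covering the observed bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align

from .seq_core import BASES_TO_IUPAC, IUPAC_TO_BASES, Contig, ProteinRecord, SeqRecord
from .similarity import HitRecord, HitTable, Scoring, search_local

GAP = "-"


@dataclass
class Cluster:
    member_ids: list[str]
    pairwise_evidence: list[HitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a cluster has at least two members")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class Unigene:
    id: str
    consensus: str
    members: list[str]
    orientation_known: bool = False

    @property
    def ambiguity_positions(self) -> list[int]:
        """0-based positions carrying an IUPAC ambiguity code."""
        return [i for i, b in enumerate(self.consensus) if len(IUPAC_TO_BASES.get(b, "")) > 1]


def symmetric_coverage(hit: HitRecord, len_q: int, len_s: int) -> float:
    """Alignment length over the shorter sequence, in % (symmetric in q/s)."""
    return 100.0 * hit.aln_length / min(len_q, len_s)


def cluster_near_identical(contigs: Sequence[Contig], hits: HitTable,
                           min_identity: float = 99.0,
                           min_coverage: float = 99.0) -> list[Cluster]:
    """Single-linkage clusters over hits strictly exceeding both thresholds.

    Coverage is symmetric (alignment length / shorter sequence).  Self-hits
    are ignored; connected components of size 1 are not clusters.
    """
    for t in (min_identity, min_coverage):
        if not (0 < t <= 100):
            raise ValueError("thresholds must lie in (0, 100]")
    lengths = {c.id: len(c) for c in contigs}
    g = nx.Graph()
    g.add_nodes_from(lengths)
    evidence: dict[frozenset, list[HitRecord]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in lengths or h.subject_id not in lengths:
            continue
        cov = symmetric_coverage(h, lengths[h.query_id], lengths[h.subject_id])
        if h.pct_identity > min_identity and cov > min_coverage:
            g.add_edge(h.query_id, h.subject_id)
            evidence.setdefault(frozenset((h.query_id, h.subject_id)), []).append(h)
    clusters = []
    order = {c.id: i for i, c in enumerate(contigs)}
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = sorted(comp, key=order.__getitem__)
        ev = [h for pair, hs in evidence.items() if pair <= comp for h in hs]
        clusters.append(Cluster(member_ids=members, pairwise_evidence=ev))
    clusters.sort(key=lambda c: order[c.member_ids[0]])
    return clusters


def consensus_iupac(aligned_members: Sequence[str]) -> str:
    """Column-wise IUPAC consensus of equal-length gapped sequences.

    Unanimous non-gap columns keep their base; disagreeing columns receive the
    minimal ambiguity code covering the observed base set.  A column is
    emitted only if non-gap in at least half of the members.
    """
    if len(aligned_members) < 2:
        raise ValueError("need at least two members")
    width = len(aligned_members[0])
    if any(len(m) != width for m in aligned_members):
        raise ValueError("aligned members differ in length")
    n = len(aligned_members)
    out = []
    for col in range(width):
        bases = [m[col].upper() for m in aligned_members if m[col] != GAP]
        if len(bases) * 2 < n:
            continue
        observed = frozenset().union(*(IUPAC_TO_BASES[b] for b in bases))
        out.append(BASES_TO_IUPAC[observed])
    return "".join(out)


def star_align(members: Sequence[SeqRecord], anchor: SeqRecord,
               scoring: Scoring | None = None) -> list[str]:
    """Project every member onto the anchor's coordinates via exact global
    alignment (zero end-gap penalty); insertions relative to the anchor are
    dropped.  Valid for near-identical clusters where insertions are absent or
    negligible."""
    scoring = scoring or Scoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    for attr in ("open_left_insertion_score", "extend_left_insertion_score",
                 "open_right_insertion_score", "extend_right_insertion_score",
                 "open_left_deletion_score", "extend_left_deletion_score",
                 "open_right_deletion_score", "extend_right_deletion_score"):
        setattr(aligner, attr, 0)  # free end gaps (semi-global)
    rows = []
    for m in members:
        if m.id == anchor.id:
            rows.append(anchor.seq)
            continue
        aln = aligner.align(anchor.seq, m.seq)[0]
        row = [GAP] * len(anchor.seq)
        ablocks, mblocks = aln.aligned
        for (a0, a1), (m0, m1) in zip(ablocks, mblocks):
            for k in range(a1 - a0):
                row[a0 + k] = m.seq[m0 + k]
        rows.append("".join(row))
    return rows


def condense_assembly(contigs: Sequence[Contig], hits: HitTable | None = None,
                      min_identity: float = 99.0, min_coverage: float = 99.0,
                      scoring: Scoring | None = None,
                      prefilter_kmer: int | None = 15) -> list[Unigene]:
    """One unigene per cluster (IUPAC consensus) plus one per unclustered
    contig.  Unigene count = n_contigs - n_clustered_members + n_clusters."""
    if hits is None:
        recs = [c.record for c in contigs]
        hits = search_local(recs, recs, scoring=scoring, prefilter_kmer=prefilter_kmer)
    clusters = cluster_near_identical(contigs, hits, min_identity, min_coverage)
    by_id = {c.id: c for c in contigs}
    cluster_of: dict[str, Cluster] = {}
    for cl in clusters:
        for mid in cl.member_ids:
            cluster_of[mid] = cl
    unigenes: list[Unigene] = []
    emitted: set[int] = set()
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"unigene_{counter:06d}"

    for contig in contigs:
        cl = cluster_of.get(contig.id)
        if cl is None:
            unigenes.append(Unigene(next_id(), contig.record.seq, [contig.id]))
            continue
        if id(cl) in emitted:
            continue
        emitted.add(id(cl))
        members = [by_id[m].record for m in cl.member_ids]
        anchor = max(members, key=lambda r: (len(r), r.id))
        aligned = star_align(members, anchor, scoring=scoring)
        unigenes.append(Unigene(next_id(), consensus_iupac(aligned), list(cl.member_ids)))
    return unigenes


def expected_unigene_count(n_contigs: int, n_clustered_members: int, n_clusters: int) -> int:
    """Bookkeeping identity: condensing m clustered contigs into c clusters
    leaves n - m + c unigenes."""
    if n_clustered_members > n_contigs or n_clusters > n_clustered_members:
        raise ValueError("inconsistent condensation counts")
    return n_contigs - n_clustered_members + n_clusters


def select_representative(protein_group: Sequence[ProteinRecord]) -> ProteinRecord:
    """Longest translated polypeptide in a group of near-identical proteins;
    ties resolved by lexicographically smallest id."""
    if not protein_group:
        raise ValueError("empty protein group")
    return min(protein_group, key=lambda p: (-len(p.aa_seq), p.id))


def write_membership(unigenes: Iterable[Unigene], path) -> None:
    rows = [(u.id, m) for u in unigenes for m in u.members]
    pd.DataFrame(rows, columns=["unigene_id", "member_id"]).to_csv(path, sep="\t", index=False)


def condensation_summary(contigs: Sequence[Contig], unigenes: Sequence[Unigene]) -> dict:
    clustered = [u for u in unigenes if len(u.members) > 1]
    return {
        "n_contigs": len(contigs),
        "n_clusters": len(clustered),
        "n_clustered_members": sum(len(u.members) for u in clustered),
        "n_unigenes": len(unigenes),
    }
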