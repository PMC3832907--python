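"""Pairwise similarity evidence: an exact local aligner for desk-scale data,
a reader/writer for 12-column tabular hit files, best-hit selection,
contaminant screening, and transcript orientation.

The internal aligner performs full dynamic programming (no heuristic seeding),
so it is only meant for small in-memory sets; large searches are supported by
importing standard 12-column tabular hit files (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore).

E-values follow the Karlin–Altschul form E = K*m*n*exp(-lambda*S).  lambda is
computed exactly for the ungapped scoring scheme by root finding; K is a
declared order-of-magnitude constant (0.1) — adequate because every decision
threshold in the pipeline spans many orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from scipy.optimize import brentq

from .seq_core import SeqRecord, reverse_complement

HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


@dataclass
class Scoring:
    """Ungapped-lattice scoring scheme with affine gaps for the local aligner."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 16
    K: float = 0.1

    @property
    def lam(self) -> float:
        return karlin_lambda(self.match, self.mismatch)


@lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int, p_match: float = 0.25) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0
    (uniform base composition: P(match) = 1/4)."""
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 > mismatch")

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1

    return float(brentq(f, 1e-9, 50.0))


@dataclass
class HitRecord:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int  # reversed (s_start > s_end) iff minus strand
    s_end: int
    evalue: float
    bitscore: float
    q_cov: float = float("nan")  # % of query covered by the alignment

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    def __post_init__(self) -> None:
        if not (0 <= self.pct_identity <= 100):
            raise ValueError("pct_identity out of [0, 100]")
        if self.q_end < self.q_start:
            raise ValueError("query coordinates must be ascending")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class HitTable:
    hits: list[HitRecord] = field(default_factory=list)
    provenance: str = "internal"

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def for_query(self, query_id: str) -> list[HitRecord]:
        return [h for h in self.hits if h.query_id == query_id]

    def filtered(self, max_evalue: float | None = None, min_qcov: float | None = None,
                 min_identity: float | None = None) -> "HitTable":
        hits = self.hits
        if max_evalue is not None:
            hits = [h for h in hits if h.evalue < max_evalue]
        if min_qcov is not None:
            hits = [h for h in hits if h.q_cov > min_qcov]
        if min_identity is not None:
            hits = [h for h in hits if h.pct_identity > min_identity]
        return HitTable(list(hits), provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(h, c) for c in HIT_COLUMNS] for h in self.hits],
            columns=HIT_COLUMNS,
        )


@dataclass
class TaxonomyMap:
    """subject id -> taxon label, taxon label -> inside-Streptophyta flag."""

    subject_taxon: dict[str, str]
    taxon_in_streptophyta: dict[str, bool]

    def is_plant_subject(self, subject_id: str) -> bool:
        if subject_id not in self.subject_taxon:
            raise KeyError(f"subject {subject_id!r} missing from taxonomy map")
        taxon = self.subject_taxon[subject_id]
        if taxon not in self.taxon_in_streptophyta:
            raise KeyError(f"taxon {taxon!r} missing from taxonomy map")
        return self.taxon_in_streptophyta[taxon]

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", names=["subject_id", "taxon", "in_streptophyta"],
                         comment="#")
        return cls(
            subject_taxon=dict(zip(df.subject_id, df.taxon)),
            taxon_in_streptophyta={t: bool(int(v)) for t, v in zip(df.taxon, df.in_streptophyta)},
        )


# ---------------------------------------------------------------------------
# internal exact aligner


def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


def _align_pair(aligner: Align.PairwiseAligner, qseq: str, sseq: str):
    alns = aligner.align(qseq, sseq)
    if len(alns) == 0 or alns.score <= 0:
        return None
    return alns[0]


def _hit_from_alignment(aln, query_id: str, subject_id: str, qlen: int, slen: int,
                        strand: str, scoring: Scoring) -> HitRecord:
    counts = aln.counts()
    gaps, identities, mismatches = counts.gaps, counts.identities, counts.mismatches
    columns = gaps + identities + mismatches
    qblocks, sblocks = aln.aligned
    q_start0, q_end0 = int(qblocks[0][0]), int(qblocks[-1][1])
    s_start0, s_end0 = int(sblocks[0][0]), int(sblocks[-1][1])
    gap_opens = max(len(qblocks), len(sblocks)) - 1
    score = float(aln.score)
    lam, K = scoring.lam, scoring.K
    evalue = K * qlen * slen * math.exp(-lam * score)
    bitscore = (lam * score - math.log(K)) / math.log(2)
    if strand == "+":
        s_start, s_end = s_start0 + 1, s_end0
    else:  # coordinates were on the reverse complement; map back, report reversed
        s_start, s_end = slen - s_start0, slen - s_end0 + 1
    return HitRecord(
        query_id=query_id, subject_id=subject_id,
        pct_identity=100.0 * identities / columns if columns else 0.0,
        aln_length=int(columns), mismatches=int(mismatches), gap_opens=int(gap_opens),
        q_start=q_start0 + 1, q_end=q_end0, s_start=s_start, s_end=s_end,
        evalue=evalue, bitscore=bitscore,
        q_cov=100.0 * (q_end0 - q_start0) / qlen,
    )


def _shared_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return True  # too short to prefilter; fall through to alignment
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def search_local(queries: Sequence[SeqRecord], subjects: Sequence[SeqRecord],
                 scoring: Scoring | None = None, both_strands: bool = True,
                 prefilter_kmer: int | None = None) -> HitTable:
    """Exact maximal-scoring local alignment for every query x subject pair.

    Reports one hit per pair (the better strand) when the raw score clears
    ``scoring.min_score``.  ``prefilter_kmer``, if set, skips pairs sharing no
    exact k-mer on either strand — a deterministic shortcut that cannot drop
    any near-identical pair.
    """
    if not queries or not subjects:
        raise ValueError("empty query or subject set")
    scoring = scoring or Scoring()
    aligner = _aligner(scoring)
    hits: list[HitRecord] = []
    for q in queries:
        for s in subjects:
            candidates = []
            s_rc = reverse_complement(s.seq) if both_strands else None
            if prefilter_kmer is not None:
                if not (_shared_kmer(q.seq, s.seq, prefilter_kmer)
                        or (s_rc is not None and _shared_kmer(q.seq, s_rc, prefilter_kmer))):
                    continue
            aln = _align_pair(aligner, q.seq, s.seq)
            if aln is not None:
                candidates.append(("+", aln))
            if both_strands:
                aln_rc = _align_pair(aligner, q.seq, s_rc)
                if aln_rc is not None:
                    candidates.append(("-", aln_rc))
            if not candidates:
                continue
            strand, best = max(candidates, key=lambda t: (t[1].score, t[0] == "+"))
            if best.score < scoring.min_score:
                continue
            hits.append(_hit_from_alignment(best, q.id, s.id, len(q), len(s), strand, scoring))
    return HitTable(hits, provenance="internal")


# ---------------------------------------------------------------------------
# hit-table consumers


def best_hit(table: HitTable, query_id: str, max_evalue: float) -> HitRecord | None:
    """Highest-bitscore qualifying hit; ties broken by lower E-value, then
    lexicographically smallest subject id."""
    cands = [h for h in table.for_query(query_id) if h.evalue < max_evalue]
    if not cands:
        return None
    return min(cands, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def screen_contaminants(reads: Sequence[SeqRecord], table: HitTable, tax: TaxonomyMap,
                        max_evalue: float = 1e-10) -> dict[str, bool]:
    """Flag a read as contaminant iff its best hit (E < threshold) falls
    outside Streptophyta.  Reads with no qualifying hit are not flagged."""
    flags: dict[str, bool] = {}
    for r in reads:
        hit = best_hit(table, r.id, max_evalue)
        flags[r.id] = (hit is not None) and not tax.is_plant_subject(hit.subject_id)
    return flags


def orient_by_best_hit(record: SeqRecord, table: HitTable,
                       max_evalue: float = 1e-3) -> tuple[SeqRecord, bool]:
    """Unify transcript orientation using the best hit's strand.

    Minus-strand best hit -> reverse complement (orientation known);
    plus-strand -> unchanged (known); no qualifying hit -> unchanged, unknown.
    """
    hit = best_hit(table, record.id, max_evalue)
    if hit is None:
        return record, False
    if hit.strand == "-":
        return SeqRecord(record.id, reverse_complement(record.seq), record.library), True
    return record, True


# ---------------------------------------------------------------------------
# 12-column tabular I/O


def read_hit_table(path, query_lengths: Mapping[str, int] | None = None) -> HitTable:
    """Read a BLAST outfmt-6 style table; q_cov is derived on load when query
    lengths are supplied (aligned query span / query length)."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        h = HitRecord(*row)
        if query_lengths is not None:
            h.q_cov = 100.0 * (h.q_end - h.q_start + 1) / query_lengths[h.query_id]
        hits.append(h)
    return HitTable(hits, provenance=str(path))


def write_hit_table(table: HitTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, header=False,
                            float_format="%.6g")
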