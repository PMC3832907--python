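"""Cross-set homology accounting.

Covers four related bookkeeping tasks performed after assembly:

* directional unique-vs-matched counts between two sequence sets (library
  vs library, species vs species) — reciprocal directions legitimately
  disagree, so both are reported and never merged into a fabricated consensus;
* classification of query-subject relationships (one-to-one, one-to-many,
  many-to-one, many-to-many) from the connected components of the filtered
  bipartite hit graph, which also yields putatively duplicated queries;
* full-length transcript calls (E < 1e-10 and > 90 % coverage of the
  reference gene-model length);
* screens of a sequence set against a reference database, optionally
  requiring reciprocal best hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .seq_core import SeqRecord
from .similarity import HitRecord, HitTable, Scoring, best_hit, search_local

RELATIONS = ("one_to_one", "one_to_many", "many_to_one", "many_to_many")


@dataclass
class CrossMapResult:
    n_query: int
    n_matched: int
    n_unique: int
    direction: str
    max_evalue: float

    def __post_init__(self) -> None:
        assert self.n_matched + self.n_unique == self.n_query


@dataclass
class HomologyComponent:
    query_ids: frozenset
    subject_ids: frozenset

    @property
    def relation(self) -> str:
        nq, ns = len(self.query_ids), len(self.subject_ids)
        if nq == 1 and ns == 1:
            return "one_to_one"
        if nq == 1:
            return "one_to_many"
        if ns == 1:
            return "many_to_one"
        return "many_to_many"


@dataclass
class FullLengthCall:
    query_id: str
    subject_id: str
    evalue: float
    q_cov: float
    full_length: bool


def crossmap(query_ids: Sequence[str], hits: HitTable, max_evalue: float,
             direction: str = "") -> CrossMapResult:
    """Directional matched/unique split: a query is matched iff it has at
    least one hit below the E-value threshold."""
    qualifying = {h.query_id for h in hits if h.evalue < max_evalue}
    n_matched = sum(1 for q in query_ids if q in qualifying)
    return CrossMapResult(
        n_query=len(query_ids), n_matched=n_matched,
        n_unique=len(query_ids) - n_matched,
        direction=direction, max_evalue=max_evalue,
    )


def classify_relationships(hits: HitTable, max_evalue: float = 1e-10,
                           min_qcov: float = 90.0,
                           ) -> tuple[list[HomologyComponent], set[str]]:
    """Connected components of the filtered bipartite query-subject graph.

    Returns the components (with their cardinality-based relation labels) and
    the set of putatively duplicated queries: members of many_to_one and
    many_to_many components, i.e. queries that share a subject with another
    query.
    """
    filt = hits.filtered(max_evalue=max_evalue, min_qcov=min_qcov)
    g = nx.Graph()
    for h in filt:
        g.add_edge(("q", h.query_id), ("s", h.subject_id))
    components = []
    for comp in nx.connected_components(g):
        qs = frozenset(n for side, n in comp if side == "q")
        ss = frozenset(n for side, n in comp if side == "s")
        components.append(HomologyComponent(qs, ss))
    components.sort(key=lambda c: min(c.query_ids))
    duplicated = set()
    for c in components:
        if c.relation in ("many_to_one", "many_to_many"):
            duplicated |= set(c.query_ids)
    return components, duplicated


def duplicated_component_count(components: Sequence[HomologyComponent]) -> int:
    """Number of components carrying duplication (many_to_one/many_to_many)."""
    return sum(1 for c in components if c.relation in ("many_to_one", "many_to_many"))


def classify_full_length(hits: HitTable, max_evalue: float = 1e-10,
                         min_cov: float = 90.0) -> list[FullLengthCall]:
    """Full-length call per query's best hit.

    ``hits`` must carry coverage measured against the reference gene-model
    length (use :func:`coverage_vs_subject` to derive it); a call is
    full-length iff E < max_evalue and coverage > min_cov (strict).
    """
    calls = []
    for qid in sorted({h.query_id for h in hits}):
        h = best_hit(hits, qid, max_evalue=float("inf"))
        calls.append(FullLengthCall(
            query_id=qid, subject_id=h.subject_id, evalue=h.evalue, q_cov=h.q_cov,
            full_length=(h.evalue < max_evalue and h.q_cov > min_cov),
        ))
    return calls


def full_length_fraction(calls: Sequence[FullLengthCall]) -> float:
    """Share of calls that are full length, in % (one decimal of precision is
    what reports print; the value itself is exact)."""
    if not calls:
        raise ValueError("no calls")
    return 100.0 * sum(c.full_length for c in calls) / len(calls)


def coverage_vs_subject(hits: HitTable, subject_lengths: Mapping[str, int]) -> HitTable:
    """Re-derive coverage with the reference (subject) length as denominator.

    The default q_cov uses the query length; full-length classification
    instead measures the aligned span against the published gene-model length.
    """
    out = []
    for h in hits:
        h2 = HitRecord(**{k: getattr(h, k) for k in (
            "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
            "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore")})
        span = abs(h.s_end - h.s_start) + 1
        h2.q_cov = 100.0 * span / subject_lengths[h.subject_id]
        out.append(h2)
    return HitTable(out, provenance=hits.provenance)


def screen_reference_db(unigenes: Sequence[SeqRecord], refdb: Sequence[SeqRecord],
                        max_evalue: float = 1e-10, reciprocal: bool = False,
                        scoring: Scoring | None = None,
                        hits_fwd: HitTable | None = None,
                        hits_rev: HitTable | None = None) -> dict[str, str]:
    """Unigenes matching a reference database (E < threshold), as a mapping
    unigene id -> best reference id.

    In reciprocal mode a unigene is retained only if it is also the best hit
    of its own best reference (reciprocal best hit).
    """
    if not refdb:
        raise ValueError("empty reference database")
    if hits_fwd is None:
        hits_fwd = search_local(list(unigenes), list(refdb), scoring=scoring)
    matched: dict[str, str] = {}
    for u in unigenes:
        h = best_hit(hits_fwd, u.id, max_evalue)
        if h is not None:
            matched[u.id] = h.subject_id
    if not reciprocal:
        return matched
    if hits_rev is None:
        hits_rev = search_local(list(refdb), list(unigenes), scoring=scoring)
    out = {}
    for uid, rid in matched.items():
        back = best_hit(hits_rev, rid, max_evalue)
        if back is not None and back.subject_id == uid:
            out[uid] = rid
    return out


def write_components(components: Sequence[HomologyComponent], path) -> None:
    rows = []
    for i, c in enumerate(components):
        for q in sorted(c.query_ids):
            rows.append((i, "query", q, c.relation))
        for s in sorted(c.subject_ids):
            rows.append((i, "subject", s, c.relation))
    pd.DataFrame(rows, columns=["component_id", "side", "member_id", "relation"]).to_csv(
        path, sep="\t", index=False)


def write_crossmap(results: Sequence[CrossMapResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
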