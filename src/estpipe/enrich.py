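"""Fisher's exact test for over/under-representation of functional bins.

Genes carry one or more hierarchical dotted bin codes (MapMan-style, e.g.
"29.2.1").  For a selected gene set against a universe, each bin's 2x2 table
(selected-in-bin, selected-out, unselected-in, unselected-out) is tested
two-sided by default; Bonferroni and Benjamini-Hochberg corrections are
computed over the bins large enough to be tested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BIN_CODE_RE = re.compile(r"^\d+(\.\d+)*$")


@dataclass
class BinAnnotation:
    """gene id -> set of bin codes, plus human-readable terms per code."""

    gene_bins: dict[str, set[str]]
    terms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bins in self.gene_bins.values():
            for code in bins:
                if not BIN_CODE_RE.match(code):
                    raise ValueError(f"malformed bin code {code!r}")

    def with_ancestors(self) -> "BinAnnotation":
        """Hierarchical mode: membership in a code implies membership in all
        ancestor codes ("29.2.1" -> also "29.2" and "29")."""
        expanded = {}
        for gene, bins in self.gene_bins.items():
            full = set()
            for code in bins:
                parts = code.split(".")
                full.update(".".join(parts[: i + 1]) for i in range(len(parts)))
            expanded[gene] = full
        return BinAnnotation(expanded, dict(self.terms))

    def genes_in_bin(self, code: str, among: Iterable[str]) -> set[str]:
        return {g for g in among if code in self.gene_bins.get(g, ())}

    def all_bins(self, among: Iterable[str]) -> set[str]:
        out = set()
        for g in among:
            out |= self.gene_bins.get(g, set())
        return out

    @classmethod
    def read_tsv(cls, path) -> "BinAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        gene_bins: dict[str, set[str]] = {}
        terms: dict[str, str] = {}
        for row in df.itertuples(index=False):
            gene_bins.setdefault(row.gene_id, set()).add(row.bin_code)
            if getattr(row, "term", ""):
                terms[row.bin_code] = row.term
        return cls(gene_bins, terms)

    def write_tsv(self, path) -> None:
        rows = [(g, c, self.terms.get(c, "")) for g in sorted(self.gene_bins)
                for c in sorted(self.gene_bins[g])]
        pd.DataFrame(rows, columns=["gene_id", "bin_code", "term"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    bin_code: str
    term: str
    k: int  # selected genes in bin
    n: int  # selected genes total
    K: int  # universe genes in bin
    N: int  # universe total
    direction: str  # over | under
    p_raw: float
    p_bonferroni: float = float("nan")
    p_bh: float = float("nan")


def p_adjust(pvalues: Sequence[float], method: str) -> np.ndarray:
    """Multiple-testing adjustment.

    bonferroni: min(1, m*p).  bh: step-up q_(i) = min_{j>=i} m*p_(j)/j with the
    original order restored.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, q)
        return out
    raise ValueError(f"unknown method {method!r}")


def fisher_enrichment(selected_genes: Iterable[str], universe: Iterable[str],
                      annotations: BinAnnotation, min_bin_size: int = 5,
                      alternative: str = "two-sided",
                      hierarchical: bool = False) -> list[EnrichmentResult]:
    """Per-bin Fisher exact test of the selected set against the universe.

    Bins with fewer than ``min_bin_size`` universe members are excluded from
    testing (and from the correction denominator m).  Direction is the sign of
    k/n - K/N.  Both Bonferroni and BH columns are filled.
    """
    selected = set(selected_genes)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    ann = annotations.with_ancestors() if hierarchical else annotations
    N, n = len(universe), len(selected)
    results = []
    for code in sorted(ann.all_bins(universe)):
        in_bin = ann.genes_in_bin(code, universe)
        K = len(in_bin)
        if K < min_bin_size:
            continue
        k = len(in_bin & selected)
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        direction = "over" if k * N > K * n else "under"
        results.append(EnrichmentResult(
            bin_code=code, term=ann.terms.get(code, ""), k=k, n=n, K=K, N=N,
            direction=direction, p_raw=float(p)))
    praw = [r.p_raw for r in results]
    for r, pb, pbh in zip(results, p_adjust(praw, "bonferroni"), p_adjust(praw, "bh")):
        r.p_bonferroni, r.p_bh = float(pb), float(pbh)
    results.sort(key=lambda r: (r.p_raw, r.bin_code))
    return results


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)
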