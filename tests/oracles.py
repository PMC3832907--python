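"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written from first principles (full matrices,
exact rational arithmetic, exhaustive scans) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

NEG_INF = float("-inf")


def smith_waterman_score(a: str, b: str, match: int = 1, mismatch: int = -2,
                         gap_open: int = -5, gap_extend: int = -2) -> float:
    """Full-matrix affine-gap local alignment score (Gotoh, three matrices).

    gap_open is the score of the first gapped position (open+extend combined
    convention used by the aligner under test: a gap of length L costs
    open + (L-1)*extend).
    """
    n, m = len(a), len(b)
    best = 0.0
    prev_m = [0.0] * (m + 1)
    prev_x = [NEG_INF] * (m + 1)  # gap in b (deletion)
    prev_y = [NEG_INF] * (m + 1)  # gap in a (insertion)
    for i in range(1, n + 1):
        cur_m = [0.0] * (m + 1)
        cur_x = [NEG_INF] * (m + 1)
        cur_y = [NEG_INF] * (m + 1)
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            cur_m[j] = max(0.0, diag + s)
            cur_x[j] = max(prev_m[j] + gap_open, prev_x[j] + gap_extend)
            cur_y[j] = max(cur_m[j - 1] + gap_open, cur_y[j - 1] + gap_extend)
            best = max(best, cur_m[j], cur_x[j], cur_y[j])
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


def fisher_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher p for the 2x2 table [[k, n-k], [K-k, N-K-n+k]].

    Exact rational enumeration: sum the hypergeometric probabilities of all
    outcomes no more probable than the observed one.
    """
    denom = comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    probs = {x: Fraction(comb(K, x) * comb(N - K, n - x), denom) for x in range(lo, hi + 1)}
    observed = probs[k]
    return float(sum(p for p in probs.values() if p <= observed))


def bipartite_components(edges: list[tuple[str, str]]) -> list[tuple[frozenset, frozenset, str]]:
    """Connected components of a bipartite edge list, with relation labels,
    by naive repeated expansion."""
    remaining = set(edges)
    comps = []
    while remaining:
        q, s = next(iter(remaining))
        qs, ss = {q}, {s}
        changed = True
        while changed:
            changed = False
            for (eq, es) in list(remaining):
                if eq in qs or es in ss:
                    if eq not in qs or es not in ss:
                        changed = True
                    qs.add(eq)
                    ss.add(es)
                    remaining.discard((eq, es))
        if len(qs) == 1 and len(ss) == 1:
            rel = "one_to_one"
        elif len(qs) == 1:
            rel = "one_to_many"
        elif len(ss) == 1:
            rel = "many_to_one"
        else:
            rel = "many_to_many"
        comps.append((frozenset(qs), frozenset(ss), rel))
    return comps


def orf_scan(seq: str, min_aa: int) -> set[tuple[int, int, int, int]]:
    """Exhaustive six-frame ORF scan via peptide-string inspection.

    Translates each frame codon by codon with a literal codon table and reads
    ORFs off the peptide string, mapping coordinates back to the forward
    strand.  Returns the same (frame, start, end, aa_len) tuples as the
    implementation under test is documented to produce.
    """
    table = _CODONS
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(seq))
    out = set()
    L = len(seq)
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq if frame > 0 else rc
        off = abs(frame) - 1
        pep = "".join(table.get(s[i : i + 3], "X") for i in range(off, len(s) - 2, 3))
        for i, aa in enumerate(pep):
            if aa != "M":
                continue
            j = pep.find("*", i)
            if j == -1:
                n_aa = len(pep) - i
                end_nt = off + 3 * len(pep)
            else:
                n_aa = j - i
                end_nt = off + 3 * (j + 1)
            if n_aa < min_aa:
                continue
            start_nt = off + 3 * i
            if frame > 0:
                out.add((frame, start_nt, end_nt, n_aa))
            else:
                out.add((frame, L - end_nt, L - start_nt, n_aa))
    return out


_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODONS = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
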