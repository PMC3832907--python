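"""Sequence records, FASTA I/O, ORF detection, translation, and assembly statistics.

The containers here are deliberately light: a transcriptome assembly at desk
scale is a list of contigs with read support, and everything downstream
(clustering, homology, SNP calling) consumes plain ``SeqRecord``/``Contig``
objects keyed by id.  Nucleotide alphabets follow the 15 IUPAC codes; protein
hydropathy uses the Kyte–Doolittle scale as implemented in ProtParam-style
tools.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from scipy import stats

IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

#: IUPAC ambiguity code -> set of bases it denotes
IUPAC_TO_BASES = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
BASES_TO_IUPAC = {v: k for k, v in IUPAC_TO_BASES.items()}

#: Kyte & Doolittle hydropathy values (the ProtParam GRAVY scale)
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class SeqRecord:
    """A named nucleotide sequence with library provenance."""

    id: str
    seq: str
    library: str = "none"  # normalized | non_normalized | external | none

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = self.seq.upper()
        bad = set(self.seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(f"sequence {self.id!r} contains non-IUPAC symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Contig:
    """An assembled contig: sequence plus read support."""

    record: SeqRecord
    n_reads: int = 1
    avg_coverage: float = 1.0
    contaminant: bool = False

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("a contig is supported by at least one read")
        if self.avg_coverage < 0:
            raise ValueError("average coverage must be non-negative")

    @property
    def id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record)


@dataclass
class ProteinRecord:
    id: str
    aa_seq: str
    frame: int
    gravy: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError("empty peptide")
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}")
        self.gravy = gravy(self.aa_seq)


@dataclass
class AssemblyStats:
    n_seqs: int
    mean_length: float
    n50: int
    total_bp: int
    coverage_length_r: float
    coverage_length_p: float


def reverse_complement(seq: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    return str(Seq(seq).reverse_complement())


def gravy(aa_seq: str) -> float:
    """Grand average of hydropathy (mean Kyte–Doolittle value).

    Residues outside the 20-letter scale (X, *) are excluded from the mean;
    a peptide with no scorable residue is an error.
    """
    vals = [KYTE_DOOLITTLE[a] for a in aa_seq.upper() if a in KYTE_DOOLITTLE]
    if not vals:
        raise ValueError("peptide has no residues on the hydropathy scale")
    return float(np.mean(vals))


def n50(lengths: Sequence[int]) -> int:
    """Contig length at which, walking longest-first, cumulative length first
    reaches half the total assembly length."""
    if not lengths:
        raise ValueError("no contigs")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assembly_stats(contigs: Iterable[Contig]) -> AssemblyStats:
    """Summary statistics for a contig collection, including the
    length-versus-coverage Pearson correlation."""
    contigs = list(contigs)
    if not contigs:
        raise ValueError("no contigs")
    lengths = np.array([len(c) for c in contigs])
    coverages = np.array([c.avg_coverage for c in contigs], dtype=float)
    total = int(lengths.sum())
    if len(contigs) >= 2 and np.std(lengths) > 0 and np.std(coverages) > 0:
        r, p = stats.pearsonr(lengths, coverages)
    else:
        r, p = float("nan"), float("nan")
    return AssemblyStats(
        n_seqs=len(contigs),
        mean_length=total / len(contigs),
        n50=n50([int(x) for x in lengths]),
        total_bp=total,
        coverage_length_r=float(r),
        coverage_length_p=float(p),
    )


def translate(seq: str, frame: int) -> str:
    """Six-frame translation with the standard code.

    Ambiguous codons translate to the amino acid if every resolution agrees,
    otherwise to ``X`` (Biopython's ambiguous translation semantics).
    Trailing partial codons are dropped.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}")
    s = seq if frame > 0 else reverse_complement(seq)
    offset = abs(frame) - 1
    sub = s[offset : offset + 3 * ((len(s) - offset) // 3)]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def translate_and_gravy(record: SeqRecord, frame: int) -> ProteinRecord:
    aa = translate(record.seq, frame).rstrip("*")
    # internal stops are kept as '*' (excluded from the hydropathy mean)
    if not aa:
        raise ValueError(f"frame {frame:+d} of {record.id!r} yields an empty peptide")
    return ProteinRecord(id=f"{record.id}|frame{frame:+d}", aa_seq=aa, frame=frame)


def find_orfs(record: SeqRecord, min_aa: int = 30) -> list[tuple[int, int, int, int]]:
    """All six-frame ORFs from ATG to the next stop (or sequence end).

    Every ATG opens its own ORF (nested starts included).  Returns tuples
    ``(frame, start, end, aa_length)`` with start/end 0-based half-open on the
    forward strand; ``aa_length`` counts residues including the initial Met and
    excluding any stop.
    """
    out: list[tuple[int, int, int, int]] = []
    L = len(record.seq)
    for frame in FRAMES:
        s = record.seq if frame > 0 else reverse_complement(record.seq)
        offset = abs(frame) - 1
        codons = [(i, s[i : i + 3]) for i in range(offset, L - 2, 3)]
        stops = {"TAA", "TAG", "TGA"}
        for idx, (pos, codon) in enumerate(codons):
            if codon != "ATG":
                continue
            end_pos = None
            n_aa = 0
            for pos2, codon2 in codons[idx:]:
                if codon2 in stops:
                    end_pos = pos2 + 3
                    break
                n_aa += 1
            if end_pos is None:
                end_pos = codons[-1][0] + 3
            if n_aa < min_aa:
                continue
            if frame > 0:
                start_f, end_f = pos, end_pos
            else:  # map back onto the forward strand
                start_f, end_f = L - end_pos, L - pos
            out.append((frame, start_f, end_f, n_aa))
    return sorted(out)


def has_orf(record: SeqRecord, min_aa: int = 30) -> bool:
    return bool(find_orfs(record, min_aa=min_aa))


def longest_orf(record: SeqRecord, min_aa: int = 1) -> tuple[int, int, int, int] | None:
    orfs = find_orfs(record, min_aa=min_aa)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o[3], -o[1], o[0]))


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path, library: str = "none") -> list[SeqRecord]:
    return [
        SeqRecord(id=r.id, seq=str(r.seq), library=library)
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def fasta_string(records: Iterable[SeqRecord]) -> str:
    buf = io.StringIO()
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.FastaIO.FastaWriter(buf, wrap=60).write_file(bio)
    return buf.getvalue()


def stats_report(contigs: Iterable[Contig], path) -> None:
    """Per-contig report: id, length, read support, coverage, longest ORF, GRAVY."""
    import pandas as pd

    rows = []
    for c in contigs:
        orf = longest_orf(c.record)
        if orf is not None:
            frame = orf[0]
            aa = translate(c.record.seq, frame)
            g = gravy(aa) if any(a in KYTE_DOOLITTLE for a in aa) else float("nan")
            longest_aa = orf[3]
        else:
            longest_aa, g = 0, float("nan")
        rows.append(
            dict(seq_id=c.id, length=len(c), n_reads=c.n_reads,
                 avg_coverage=c.avg_coverage, longest_orf_aa=longest_aa, gravy=g)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
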