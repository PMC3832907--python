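"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the pipeline is exercisable without any external download:

* a reference accession's gene-model set plus a second accession's
  transcripts carrying i.i.d. planted substitutions (SNP calling, homology);
* allelic contig variants at > 99 % identity (clustering/condensation);
* read populations from a non-normalized library (heavy-tailed abundance,
  long reads) and a normalized library (flattened abundance, short reads);
* functional bin annotations with one planted enriched category;
* probe intensities from a two-component background/signal log-normal
  mixture with planted differentially expressed genes, in same-species
  (mostly matched probes) and cross-species (mostly mismatched) variants.

Each generator is a pure function of its configuration: the seed fully
determines the output, byte for byte.  Ground truth for every planted event
is recorded so downstream recovery tests never re-derive randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_core import Contig, SeqRecord

BASES = np.array(list("ACGT"))


@dataclass
class ArrayConfig:
    n_probes_per_gene: int = 3
    w_low: float = 0.3          # background-mode weight in the signal mixture
    mu_low: float = 1.0         # log10 intensity of the background mode
    mu_high: float = 3.0        # log10 intensity of the specific mode
    sigma: float = 0.3          # log10 spread of both modes
    replicate_sigma: float = 0.1
    n_de: int = 100             # planted differentially expressed genes
    de_log2fc: float = 2.0
    n_reps: int = 3
    cross_mismatch_fraction: float = 0.7  # mismatched probes in cross-species mode


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 1500)
    snp_rate: float = 0.01           # substitutions/base between accessions
    allele_pair_fraction: float = 0.2
    allele_identity: float = 99.5    # % identity between planted allele pairs
    n_reads: int = 2000
    read_length_means: tuple[float, float] = (566.0, 257.0)  # non-normalized, normalized
    read_length_sds: tuple[float, float] = (150.0, 80.0)
    abundance_sigma: float = 1.5     # log-normal abundance spread
    normalization_beta: float = 0.2  # abundance^beta flattening for the normalized library
    error_rate: float = 0.0          # optional uniform sequencing-error rate
    n_bins: int = 20
    planted_bin_odds: float = 5.0
    array: ArrayConfig = field(default_factory=ArrayConfig)

    def __post_init__(self) -> None:
        for rate in (self.snp_rate, self.allele_pair_fraction, self.error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.gene_length_range[0] <= 0:
            raise ValueError("gene lengths must be positive")
        if not 0 < self.allele_identity <= 100:
            raise ValueError("allele identity is a percentage")


@dataclass
class GroundTruth:
    #: gene id -> list of (1-based position, ref base, alt base)
    snp_positions: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    #: gene id -> (contig ids of the planted allele pair, 1-based differing positions)
    allele_pairs: dict[str, tuple[list[str], list[int]]] = field(default_factory=dict)
    planted_bin: str | None = None
    de_genes: list[str] = field(default_factory=list)
    #: probe id -> True when the probe perfectly matches its target
    probe_matched: dict[str, bool] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _coverage(rng: np.random.Generator, length: int) -> float:
    """Per-contig read coverage: noisy but increasing with contig length,
    the pattern real assemblies show (long contigs draw more reads)."""
    return float(rng.uniform(0.8, 1.2) * (2 + length / 100))


def _substitute(rng: np.random.Generator, seq: str, positions: np.ndarray
                ) -> tuple[str, list[tuple[int, str, str]]]:
    """Substitute each 0-based position with a uniformly drawn different base."""
    chars = list(seq)
    events = []
    for pos in positions:
        ref = chars[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        chars[pos] = alt
        events.append((int(pos) + 1, ref, alt))
    return "".join(chars), events


def gen_transcriptome(config: SimConfig) -> tuple[
        list[SeqRecord], list[SeqRecord], list[Contig], GroundTruth]:
    """Reference gene models (accession A), query unigenes (accession B =
    A plus i.i.d. substitutions at ``snp_rate``), allelic contig variants for
    a fraction of genes, and the ground truth of every planted event."""
    rng = _rng(config, 1)
    truth = GroundTruth()
    lo, hi = config.gene_length_range
    models, unigenes, contigs = [], [], []
    n_allelic = int(round(config.allele_pair_fraction * config.n_genes))
    allelic_idx = set(range(n_allelic))  # deterministic: first genes carry allele pairs
    for i in range(config.n_genes):
        gid = f"gene_{i + 1:05d}"
        uid = f"uni_{i + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        a_seq = _random_seq(rng, length)
        n_sub = rng.binomial(length, config.snp_rate)
        positions = np.sort(rng.choice(length, size=n_sub, replace=False))
        b_seq, events = _substitute(rng, a_seq, positions)
        models.append(SeqRecord(gid, a_seq, library="external"))
        unigenes.append(SeqRecord(uid, b_seq, library="none"))
        truth.snp_positions[gid] = events
        if i in allelic_idx:
            n_allele_sub = max(1, int(round(length * (1 - config.allele_identity / 100))))
            apos = np.sort(rng.choice(length, size=n_allele_sub, replace=False))
            allele_seq, allele_events = _substitute(rng, b_seq, apos)
            c1, c2 = f"{uid}_allele1", f"{uid}_allele2"
            contigs.append(Contig(SeqRecord(c1, b_seq), n_reads=int(rng.integers(2, 30)),
                                  avg_coverage=_coverage(rng, length)))
            contigs.append(Contig(SeqRecord(c2, allele_seq), n_reads=int(rng.integers(2, 30)),
                                  avg_coverage=_coverage(rng, length)))
            truth.allele_pairs[gid] = ([c1, c2], [e[0] for e in allele_events])
        else:
            contigs.append(Contig(SeqRecord(f"{uid}_c1", b_seq),
                                  n_reads=int(rng.integers(2, 30)),
                                  avg_coverage=_coverage(rng, length)))
    return models, unigenes, contigs, truth


def gen_reads(config: SimConfig, models: Sequence[SeqRecord]
              ) -> dict[str, list[SeqRecord]]:
    """Reads for both library types.

    Non-normalized: per-gene abundance log-normal (heavy skew), read length
    normal around the long mean.  Normalized: abundance flattened as
    abundance**beta (duplex-specific-nuclease surrogate), shorter reads —
    the fragmentation cost of normalization.
    """
    if not models:
        return {"non_normalized": [], "normalized": []}
    rng = _rng(config, 2)
    raw_abund = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(models))
    out: dict[str, list[SeqRecord]] = {}
    for lib, mean_len, sd_len in (
        ("non_normalized", config.read_length_means[0], config.read_length_sds[0]),
        ("normalized", config.read_length_means[1], config.read_length_sds[1]),
    ):
        abund = raw_abund ** config.normalization_beta if lib == "normalized" else raw_abund
        probs = abund / abund.sum()
        picks = rng.choice(len(models), size=config.n_reads, p=probs)
        reads = []
        for r, gi in enumerate(picks):
            gene = models[gi]
            length = int(np.clip(rng.normal(mean_len, sd_len), 50, len(gene)))
            start = int(rng.integers(0, len(gene) - length + 1))
            seq = gene.seq[start : start + length]
            if config.error_rate > 0:
                n_err = rng.binomial(length, config.error_rate)
                if n_err:
                    epos = rng.choice(length, size=n_err, replace=False)
                    seq, _ = _substitute(rng, seq, np.sort(epos))
            # read ids carry the source gene, as read simulators usually do
            reads.append(SeqRecord(f"{lib}_read_{r + 1:06d}_{gene.id}", seq, library=lib))
        out[lib] = reads
    return out


def gen_annotations(config: SimConfig, gene_ids: Sequence[str],
                    selected_ids: Sequence[str]) -> tuple[dict[str, set[str]], str]:
    """Multinomial bin assignment with one planted enriched bin.

    Unselected genes draw a bin uniformly; selected genes draw the planted
    bin with its odds multiplied by ``planted_bin_odds`` (odds = 1 is the
    null fixture).  Returns (gene -> bin codes, planted bin code).
    """
    if config.n_bins < 2:
        raise ValueError("need at least two bins")
    rng = _rng(config, 3)
    bins = [f"{i + 1}" for i in range(config.n_bins)]
    planted = bins[0]
    selected = set(selected_ids)
    base = np.full(config.n_bins, 1.0 / config.n_bins)
    boosted = base.copy()
    # multiply the planted bin's odds: p/(1-p) -> odds * p/(1-p)
    odds = config.planted_bin_odds * base[0] / (1 - base[0])
    boosted[0] = odds / (1 + odds)
    boosted[1:] *= (1 - boosted[0]) / base[1:].sum()
    gene_ids = list(gene_ids)
    is_sel = np.array([g in selected for g in gene_ids])
    draws = np.empty(len(gene_ids), dtype=int)
    draws[is_sel] = rng.choice(config.n_bins, size=int(is_sel.sum()), p=boosted)
    draws[~is_sel] = rng.choice(config.n_bins, size=int((~is_sel).sum()), p=base)
    annotations = {g: {bins[d]} for g, d in zip(gene_ids, draws)}
    return annotations, planted


def gen_signals(config: SimConfig, probes: Sequence[tuple[str, str]],
                cross_species: bool = False,
                ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Probe-intensity matrix (probes x samples) with metadata and truth.

    ``probes`` is a sequence of (probe_id, gene_id).  log10 intensity of a
    matched probe ~ N(mu_high, sigma); mismatched (all cross-species
    attenuation is collapsed into mode membership) ~ N(mu_low, sigma).
    Planted DE genes move by de_log2fc * log10(2) in ACC samples — half up,
    half down, as stress contrasts regulate genes in both directions (and so
    that normalization sees no global shift); i.i.d. replicate noise is added
    on the log scale.
    """
    if not probes:
        raise ValueError("no probes")
    a = config.array
    if a.n_reps < 2:
        raise ValueError("need at least two replicates per condition")
    rng = _rng(config, 4 if not cross_species else 5)
    truth = GroundTruth()
    genes = sorted({g for _, g in probes})
    # never plant DE in more than 20 % of genes: a contrast that moves most of
    # the transcriptome would defeat normalization (and is not what arrays see)
    n_de = min(a.n_de, max(1, len(genes) // 5))
    de = [str(g) for g in rng.choice(genes, size=n_de, replace=False)] if n_de else []
    de_sign = {g: (1.0 if i % 2 == 0 else -1.0) for i, g in enumerate(de)}
    de = set(de)
    truth.de_genes = sorted(de)
    mismatch_p = a.cross_mismatch_fraction if cross_species else 0.0
    samples = [f"{cond}_rep{r + 1}" for cond in ("NA", "ACC") for r in range(a.n_reps)]
    meta = pd.DataFrame(
        {"treatment": [s.split("_")[0] for s in samples],
         "replicate": [int(s[-1]) for s in samples],
         "species": ["same" if not cross_species else "cross"] * len(samples)},
        index=pd.Index(samples, name="sample_id"))
    base = np.empty(len(probes))
    matched_mask = np.empty(len(probes), dtype=bool)
    for i, (pid, gene) in enumerate(probes):
        matched = rng.random() >= mismatch_p
        matched_mask[i] = matched
        truth.probe_matched[pid] = bool(matched)
        mu = a.mu_high if matched else a.mu_low
        base[i] = rng.normal(mu, a.sigma)
    mat = np.tile(base[:, None], (1, len(samples)))
    de_shift = a.de_log2fc * np.log10(2.0)
    is_acc = np.array([s.startswith("ACC") for s in samples])
    # only probes that actually hybridize to their target see the expression
    # change; mismatched probes report non-specific background
    row_shift = np.array([de_sign.get(g, 0.0) * de_shift for _, g in probes])
    row_shift[~matched_mask] = 0.0
    mat[:, is_acc] += row_shift[:, None]
    mat += rng.normal(0.0, a.replicate_sigma, size=mat.shape)
    intensities = pd.DataFrame(10.0 ** mat, index=[p for p, _ in probes], columns=samples)
    return intensities, meta, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True, default=list)
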