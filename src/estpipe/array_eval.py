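"""Oligo-array evaluation: probe design, empirical pre-selection, signal-mode
(bimodality) analysis, differential expression, and same- vs cross-species
comparison.

Raw hybridization intensities on a long-oligo array are well described on the
log10 scale by a two-component Gaussian mixture: a background/mismatch mode at
low intensity and a specific-hybridization mode at high intensity.  Same-
species hybridizations are dominated by the high mode; cross-species
hybridizations, attenuated by probe-target mismatches, by the low mode.  The
mixture fit drives both the "above background" probe call used during
pre-selection and the background estimate subtracted before normalization.

Differential expression uses quantile normalization of log2 intensities,
per-gene medians across a gene's probes, a two-sample t-test between
conditions with empirical-Bayes variance moderation (scaled-inverse-chi-
square shrinkage of per-gene variances toward a cross-gene prior, as
moderated linear models do), and Benjamini-Hochberg correction; a gene is
significant iff |log2FC| >= 1 and FDR-adjusted p < 0.05.  At the typical
three replicates per condition the moderation is what makes the test usable:
an unmoderated t at four residual degrees of freedom cannot produce p-values
small enough to survive the FDR step-up.  A plain Welch test is available as
``method="welch"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import p_adjust

PROBE_LEN = 60
UNIQUE_KMER = 50


@dataclass
class ProbeCandidate:
    probe_id: str
    unigene_id: str
    offset: int  # 0-based start on the unigene
    seq: str
    gc: float
    unique: bool = True
    below_minimum: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) != PROBE_LEN:
            raise ValueError("probes are 60-mers")


@dataclass
class MixtureFit:
    w_low: float
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    converged: bool
    n_iter: int
    log_likelihood: float
    effectively_unimodal: bool = False


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    p_raw: float
    p_fdr: float

    @property
    def significant(self) -> bool:
        return abs(self.log2fc) >= 1.0 and self.p_fdr < 0.05


@dataclass
class OverlapReport:
    both: int
    same_only: int
    cross_only: int
    signal_correlation: float = float("nan")

    @property
    def cross_missed_fraction(self) -> float:
        """Share of same-species DE genes not recovered cross-species."""
        total = self.both + self.same_only
        return self.same_only / total if total else float("nan")


# ---------------------------------------------------------------------------
# probe design


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def build_kmer_index(unigenes: Mapping[str, str], k: int = UNIQUE_KMER) -> dict[str, set[str]]:
    """k-mer -> set of unigene ids containing it (uniqueness screening)."""
    index: dict[str, set[str]] = {}
    for uid, seq in unigenes.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(uid)
    return index


def probe_offsets(length: int, target_count: int, span_cap: int = 900) -> list[int]:
    """Evenly spaced 0-based offsets biased toward the 3' end:
    round(linspace(L-60-span, L-60, k)) with span = min(L-60, span_cap)."""
    if length < PROBE_LEN:
        raise ValueError("unigene shorter than a probe")
    last = length - PROBE_LEN
    span = min(last, span_cap)
    raw = np.linspace(last - span, last, num=target_count)
    return sorted({int(round(x)) for x in raw})


def design_probes(unigene_id: str, seq: str, target_count: int = 12, min_count: int = 2,
                  gc_range: tuple[float, float] = (0.30, 0.70),
                  kmer_index: dict[str, set[str]] | None = None) -> list[ProbeCandidate]:
    """Tile up to ``target_count`` 60-mer probes over a unigene.

    Offsets are evenly spaced with a 3'-end bias; candidates outside the GC
    window or sharing a >= 50-nt exact match with another unigene are
    dropped.  If fewer than ``min_count`` survive, the survivors are flagged
    ``below_minimum`` (something is always emitted when the sequence allows).
    """
    if len(seq) < PROBE_LEN:
        raise ValueError(f"unigene {unigene_id!r} shorter than {PROBE_LEN} nt")
    candidates = []
    for i, off in enumerate(probe_offsets(len(seq), target_count)):
        probe_seq = seq[off : off + PROBE_LEN]
        gc = _gc(probe_seq)
        unique = True
        if kmer_index is not None:
            for j in range(PROBE_LEN - UNIQUE_KMER + 1):
                owners = kmer_index.get(probe_seq[j : j + UNIQUE_KMER], set())
                if owners - {unigene_id}:
                    unique = False
                    break
        if not (gc_range[0] <= gc <= gc_range[1]) or not unique:
            continue
        candidates.append(ProbeCandidate(
            probe_id=f"{unigene_id}:p{i:02d}", unigene_id=unigene_id,
            offset=off, seq=probe_seq, gc=gc, unique=unique))
    if len(candidates) < min_count:
        for c in candidates:
            c.below_minimum = True
    return candidates


# ---------------------------------------------------------------------------
# two-component Gaussian mixture (EM) on log10 intensities


def fit_mixture(log_intensities: np.ndarray, tol: float = 1e-8, max_iter: int = 500,
                ) -> tuple[MixtureFit, np.ndarray]:
    """EM fit of a two-Gaussian mixture in one dimension.

    Deterministic initialisation from the 10th/90th percentiles (a farthest-
    point seeding in 1-D); the log-likelihood is asserted non-decreasing at
    every step.  Returns the fit (components labelled so mu_low <= mu_high)
    and the posterior probability of the high component per observation.
    """
    x = np.asarray(log_intensities, dtype=float)
    mu = np.array([np.percentile(x, 10), np.percentile(x, 90)])
    sigma = np.array([x.std(ddof=0), x.std(ddof=0)])
    sigma = np.maximum(sigma, 1e-3)
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E step
        dens = np.stack([w[j] * stats.norm.pdf(x, mu[j], sigma[j]) for j in (0, 1)])
        total = dens.sum(axis=0)
        total = np.maximum(total, 1e-300)
        resp = dens / total
        ll = float(np.log(total).sum())
        assert ll >= ll_old - 1e-6, "EM log-likelihood decreased"
        if ll - ll_old < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp * x).sum(axis=1) / nk
        sigma = np.sqrt((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk)
        sigma = np.maximum(sigma, 1e-4)
    if mu[0] > mu[1]:
        mu, sigma, w = mu[::-1], sigma[::-1], w[::-1]
        resp = resp[::-1]
    pooled = float(np.sqrt((sigma**2).mean()))
    # Ashman's D: component separation in pooled-sigma units.  D < 2 means the
    # two fitted components do not describe separable modes (an EM fit forced
    # onto a single Gaussian settles near D ~ 1.2).
    ashman_d = abs(mu[1] - mu[0]) / pooled if pooled > 0 else float("inf")
    fit = MixtureFit(
        w_low=float(w[0]), mu_low=float(mu[0]), mu_high=float(mu[1]),
        sigma_low=float(sigma[0]), sigma_high=float(sigma[1]),
        converged=converged, n_iter=n_iter, log_likelihood=ll_old,
        effectively_unimodal=ashman_d < 2.0,
    )
    return fit, resp[1]


def classify_signal_modes(intensities: Sequence[float], tol: float = 1e-8,
                          max_iter: int = 500) -> tuple[MixtureFit, np.ndarray]:
    """Mixture fit of raw (positive) intensities on the log10 scale plus
    per-observation above-background flags (posterior of high mode > 0.5)."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 intensities for a stable mixture fit")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive")
    fit, post_high = fit_mixture(np.log10(x), tol=tol, max_iter=max_iter)
    return fit, post_high > 0.5


# ---------------------------------------------------------------------------
# pre-selection strategy


def pss_select(candidates: Sequence[ProbeCandidate],
               primary_signals: Mapping[str, float],
               secondary_signals: Mapping[str, float],
               n_target: int, max_per_unigene: int = 2,
               ) -> tuple[list[ProbeCandidate], dict[str, int]]:
    """Empirical probe pre-selection from hybridization signal strength.

    Stage 1 keeps candidates called above background on the primary
    (cRNA-like) channel, ranked by primary intensity; stage 2 tops up to
    ``n_target`` from the remainder ranked by the secondary (gDNA-like)
    channel.  At most ``max_per_unigene`` probes per unigene are retained,
    preferring the highest signal; ties break by probe id.
    """
    missing = [c.probe_id for c in candidates if c.probe_id not in primary_signals]
    if missing:
        raise ValueError(f"signals missing for probes {missing[:3]}...")
    if n_target > len(candidates):
        warnings.warn("n_target exceeds candidate count; selecting all")
    if len(candidates) >= 100:
        _, above = classify_signal_modes([primary_signals[c.probe_id] for c in candidates])
    else:
        # too few probes to estimate a background mode; every candidate is
        # treated as above background and ranking by signal decides
        above = [True] * len(candidates)
    above_map = {c.probe_id: bool(f) for c, f in zip(candidates, above)}

    per_unigene: dict[str, int] = {}
    selected: list[ProbeCandidate] = []
    counts = {"primary": 0, "secondary": 0}

    def take(pool: list[ProbeCandidate], stage: str) -> None:
        for c in pool:
            if len(selected) >= n_target:
                return
            if per_unigene.get(c.unigene_id, 0) >= max_per_unigene:
                continue
            selected.append(c)
            per_unigene[c.unigene_id] = per_unigene.get(c.unigene_id, 0) + 1
            counts[stage] += 1

    stage1 = sorted((c for c in candidates if above_map[c.probe_id]),
                    key=lambda c: (-primary_signals[c.probe_id], c.probe_id))
    take(stage1, "primary")
    chosen = {c.probe_id for c in selected}
    stage2 = sorted((c for c in candidates if c.probe_id not in chosen),
                    key=lambda c: (-secondary_signals.get(c.probe_id, 0.0), c.probe_id))
    take(stage2, "secondary")
    return selected, counts


# ---------------------------------------------------------------------------
# normalization and differential expression


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene sample variances.

    Assumes s2_g ~ s0^2 * F(df, d0) (scaled inverse chi-square prior) and
    estimates (d0, s0^2) by the method of moments on log s2, then returns the
    posterior variances (d0*s0^2 + df*s2) / (d0 + df) together with d0 and
    s0^2.  d0 = inf (coded as 1e8) when the observed spread of log s2 is no
    larger than expected from chi-square sampling alone.
    """
    from scipy.special import digamma, polygamma

    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - digamma(df / 2) + np.log(df / 2)
    excess = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2))
    if excess <= 1e-8:
        d0 = 1e8
    else:
        from scipy.optimize import brentq

        d0 = float(brentq(lambda d: float(polygamma(1, d / 2)) - excess, 1e-2, 1e8))
    s0_2 = float(np.exp(np.mean(e) + digamma(d0 / 2) - np.log(d0 / 2)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) to the same distribution: the mean of the
    sample-wise sorted vectors, assigned back by within-sample rank."""
    arr = matrix.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    return pd.DataFrame(mean_sorted[ranks], index=matrix.index, columns=matrix.columns)


def subtract_background(matrix: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Subtract the 5th percentile of the low-mode (background-like)
    intensities, flooring at a small positive constant before logs.

    When the mixture fit is effectively unimodal there is no separable
    background mode — a forced two-component split would subtract bulk
    signal and clip dim genes — so nothing is subtracted.
    """
    flat = matrix.to_numpy().ravel()
    fit, above = classify_signal_modes(flat)
    low = flat[~above]
    if fit.effectively_unimodal or not low.size:
        return matrix.clip(lower=floor)
    bg = float(np.percentile(low, 5))
    return (matrix - bg).clip(lower=floor)


def differential_expression(matrix: pd.DataFrame, metadata: pd.DataFrame,
                            probe_to_gene: Mapping[str, str],
                            condition_col: str = "treatment",
                            contrast: tuple[str, str] = ("ACC", "NA"),
                            background_subtract: bool = True,
                            exclude_samples: Sequence[str] = (),
                            method: str = "moderated",
                            ) -> list[DEResult]:
    """Per-gene differential expression between two conditions.

    ``matrix`` is probes x samples (raw positive intensities); ``metadata`` is
    indexed by sample id with a condition column.  Pipeline: optional
    background subtraction, log2, quantile normalization, per-gene median over
    the gene's probes, then either a moderated t-test (default; per-gene
    pooled variances shrunk toward a cross-gene prior) or a plain Welch
    t-test (``method="welch"``); BH correction in both cases.
    """
    if exclude_samples:
        matrix = matrix.drop(columns=list(exclude_samples))
        metadata = metadata.drop(index=list(exclude_samples))
    groups = {
        cond: [s for s in matrix.columns if metadata.loc[s, condition_col] == cond]
        for cond in contrast
    }
    for cond, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
    if background_subtract:
        matrix = subtract_background(matrix)
    logm = np.log2(matrix)
    norm = quantile_normalize(logm)
    gene_of = pd.Series({p: probe_to_gene[p] for p in norm.index if p in probe_to_gene})
    per_gene = norm.loc[gene_of.index].groupby(gene_of).median()
    a = per_gene[groups[contrast[0]]].to_numpy()
    b = per_gene[groups[contrast[1]]].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    if method == "welch":
        with np.errstate(invalid="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    elif method == "moderated":
        n1, n2 = a.shape[1], b.shape[1]
        df_res = n1 + n2 - 2
        pooled = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df_res
        post_var, d0, _ = moderate_variances(pooled, df_res)
        se = np.sqrt(post_var * (1 / n1 + 1 / n2))
        tstat = log2fc / np.maximum(se, 1e-12)
        df_total = min(df_res + d0, 1e8)
        pvals = 2 * stats.t.sf(np.abs(tstat), df_total)
    else:
        raise ValueError(f"unknown method {method!r}")
    fdr = p_adjust(pvals, "bh")
    return [
        DEResult(gene_id=g, log2fc=float(fc), p_raw=float(p), p_fdr=float(q))
        for g, fc, p, q in zip(per_gene.index, log2fc, pvals, fdr)
    ]


def cross_species_overlap(de_same: Sequence[DEResult], de_cross: Sequence[DEResult],
                          signals_same: Mapping[str, float] | None = None,
                          signals_cross: Mapping[str, float] | None = None,
                          ) -> OverlapReport:
    """Venn overlap of significant genes between a same-species and a
    cross-species platform, plus (optionally) the Pearson correlation of
    log10 median signals over the shared gene space."""
    genes_same = {r.gene_id for r in de_same}
    genes_cross = {r.gene_id for r in de_cross}
    shared = genes_same & genes_cross
    if not shared:
        raise ValueError("DE lists share no genes")
    sig_same = {r.gene_id for r in de_same if r.significant and r.gene_id in shared}
    sig_cross = {r.gene_id for r in de_cross if r.significant and r.gene_id in shared}
    corr = float("nan")
    if signals_same and signals_cross:
        common = sorted(set(signals_same) & set(signals_cross))
        if len(common) >= 3:
            corr, _ = stats.pearsonr(
                np.log10([signals_same[g] for g in common]),
                np.log10([signals_cross[g] for g in common]))
            corr = float(corr)
    return OverlapReport(
        both=len(sig_same & sig_cross),
        same_only=len(sig_same - sig_cross),
        cross_only=len(sig_cross - sig_same),
        signal_correlation=corr,
    )


def write_probes(candidates: Sequence[ProbeCandidate], path) -> None:
    pd.DataFrame(
        [(c.probe_id, c.unigene_id, c.offset, c.seq) for c in candidates],
        columns=["probe_id", "unigene_id", "offset", "seq"],
    ).to_csv(path, sep="\t", index=False)


def write_de_results(results: Sequence[DEResult], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in results])
    df["significant"] = [r.significant for r in results]
    df.to_csv(path, sep="\t", index=False)
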