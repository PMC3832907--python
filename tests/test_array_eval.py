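"""Probe design, pre-selection, mixture fits, and differential expression."""

import numpy as np
import pandas as pd
import pytest

from estpipe.array_eval import (
    DEResult,
    ProbeCandidate,
    build_kmer_index,
    classify_signal_modes,
    cross_species_overlap,
    design_probes,
    differential_expression,
    fit_mixture,
    pss_select,
    probe_offsets,
    quantile_normalize,
)
from estpipe.synthetic_data import ArrayConfig, SimConfig, gen_signals
from conftest import random_dna


class TestProbeDesign:
    def test_probe_sized_unigene_yields_single_flagged_probe(self, rng):
        seq = random_dna(rng, 60)
        (probe,) = design_probes("u1", seq, gc_range=(0.0, 1.0))
        assert probe.seq == seq and probe.offset == 0
        assert probe.below_minimum

    def test_offsets_match_direct_enumeration(self):
        L, k = 1000, 12
        got = probe_offsets(L, k)
        span = min(L - 60, 900)
        expected = sorted({int(round(x))
                           for x in np.linspace(L - 60 - span, L - 60, k)})
        assert got == expected
        assert max(got) == L - 60  # 3'-anchored

    def test_counts_bounded_by_contract(self, rng):
        for _ in range(20):
            L = int(rng.integers(60, 3000))
            probes = design_probes("u", random_dna(rng, L), gc_range=(0.0, 1.0))
            assert 1 <= len(probes) <= 12

    def test_shared_kmer_kills_uniqueness(self, rng):
        shared = random_dna(rng, 60)
        u1 = random_dna(rng, 100) + shared
        u2 = shared + random_dna(rng, 100)
        idx = build_kmer_index({"u1": u1, "u2": u2})
        probes = design_probes("u1", u1, gc_range=(0.0, 1.0), kmer_index=idx)
        # the 3'-terminal probe of u1 is exactly the shared 60-mer: dropped
        assert all(p.offset != len(u1) - 60 for p in probes)

    def test_too_short_unigene_is_an_error(self):
        with pytest.raises(ValueError):
            design_probes("u", "ACGT")


def synthetic_candidates(n, rng):
    cands = []
    for i in range(n):
        seq = random_dna(rng, 60)
        cands.append(ProbeCandidate(f"u{i:03d}:p00", f"u{i:03d}", 0, seq, 0.5))
    return cands


class TestPssSelect:
    def test_two_stage_split_counts(self, rng):
        cands = synthetic_candidates(150, rng)
        primary = {c.probe_id: (10 ** 3 if i < 40 else 10.0 ** 1) * rng.uniform(0.9, 1.1)
                   for i, c in enumerate(cands)}
        secondary = {c.probe_id: rng.uniform(10, 20) for c in cands}
        selected, counts = pss_select(cands, primary, secondary, n_target=50)
        assert len(selected) == 50
        assert counts == {"primary": 40, "secondary": 10}

    def test_target_beyond_candidates_selects_all_with_warning(self, rng):
        cands = synthetic_candidates(120, rng)
        sig = {c.probe_id: 10 ** rng.normal(3, 0.3) for c in cands}
        with pytest.warns(UserWarning):
            selected, _ = pss_select(cands, sig, sig, n_target=500)
        assert len(selected) == len(cands)

    def test_per_unigene_cap(self, rng):
        cands = []
        for i in range(200):
            cands.append(ProbeCandidate(f"u{i % 20:02d}:p{i // 20:02d}",
                                        f"u{i % 20:02d}", 0, random_dna(rng, 60), 0.5))
        sig = {c.probe_id: 10 ** rng.normal(3, 0.3) for c in cands}
        selected, _ = pss_select(cands, sig, sig, n_target=60)
        per_unigene = pd.Series([c.unigene_id for c in selected]).value_counts()
        assert per_unigene.max() <= 2

    def test_selection_is_deterministic(self, rng):
        cands = synthetic_candidates(150, rng)
        sig = {c.probe_id: float(10 ** (3 + 0.3 * np.sin(i))) for i, c in enumerate(cands)}
        sel1, c1 = pss_select(cands, sig, sig, n_target=80)
        sel2, c2 = pss_select(list(cands), dict(sig), dict(sig), n_target=80)
        assert [c.probe_id for c in sel1] == [c.probe_id for c in sel2] and c1 == c2


class TestMixture:
    def test_parameter_recovery_at_n_10000(self):
        rng = np.random.default_rng(42)
        n = 10_000
        low = rng.normal(1.0, 0.3, int(0.3 * n))
        high = rng.normal(3.0, 0.3, n - len(low))
        fit, post = fit_mixture(np.concatenate([low, high]))
        assert fit.converged
        assert fit.w_low == pytest.approx(0.3, abs=0.05)
        assert fit.mu_low == pytest.approx(1.0, abs=0.1)
        assert fit.mu_high == pytest.approx(3.0, abs=0.1)
        assert not fit.effectively_unimodal

    def test_single_tight_mode_flagged_unimodal(self):
        rng = np.random.default_rng(0)
        fit, _ = fit_mixture(rng.normal(3.0, 0.3, 5000))
        assert fit.effectively_unimodal

    def test_above_background_flags_follow_modes(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([10 ** rng.normal(1.0, 0.2, 500),
                            10 ** rng.normal(3.0, 0.2, 500)])
        fit, above = classify_signal_modes(x)
        assert above[500:].mean() > 0.99
        assert above[:500].mean() < 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            classify_signal_modes([1.0] * 50)
        with pytest.raises(ValueError):
            classify_signal_modes([-1.0] * 200)

    def test_matched_vs_mismatched_fixture_modes(self):
        cfg = SimConfig(seed=9)
        probes = [(f"p{i:04d}", f"g{i:04d}") for i in range(2000)]
        same, _, _ = gen_signals(cfg, probes, cross_species=False)
        cross, _, _ = gen_signals(cfg, probes, cross_species=True)
        fit_s, _ = classify_signal_modes(same.to_numpy().ravel())
        fit_c, _ = classify_signal_modes(cross.to_numpy().ravel())
        assert fit_c.w_low > 0.5          # cross-species dominated by background
        assert fit_s.effectively_unimodal or fit_s.w_low < 0.5


class TestQuantileNormalize:
    def test_sorted_columns_become_identical_exactly(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        q = quantile_normalize(m)
        ref = np.sort(q["a"].to_numpy())
        for c in "bcd":
            assert np.array_equal(np.sort(q[c].to_numpy()), ref)

    def test_preserves_within_sample_ranks(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 3)))
        q = quantile_normalize(m)
        for c in m.columns:
            assert np.array_equal(np.argsort(m[c].to_numpy(), kind="stable"),
                                  np.argsort(q[c].to_numpy(), kind="stable"))


def de_fixture(seed, **overrides):
    kwargs = dict(replicate_sigma=0.4 * np.log10(2), n_de=100)
    kwargs.update(overrides)
    cfg = SimConfig(seed=seed, array=ArrayConfig(**kwargs))
    probes = [(f"p{i:05d}", f"g{i:05d}") for i in range(2000)]
    mat, meta, truth = gen_signals(cfg, probes, cross_species=False)
    return mat, meta, dict(probes), truth


class TestDifferentialExpression:
    def test_null_data_yield_few_significant_genes(self):
        mat, meta, p2g, _ = de_fixture(1, n_de=0)
        results = differential_expression(mat, meta, p2g)
        assert sum(r.significant for r in results) / len(results) <= 0.01

    def test_planted_genes_recovered(self):
        mat, meta, p2g, truth = de_fixture(2)
        results = differential_expression(mat, meta, p2g)
        sig = {r.gene_id for r in results if r.significant}
        planted = set(truth.de_genes)
        assert len(sig & planted) / len(planted) >= 0.9

    def test_significance_invariant_to_replicate_relabeling(self):
        mat, meta, p2g, _ = de_fixture(3)
        res1 = differential_expression(mat, meta, p2g)
        perm = ["NA_rep3", "NA_rep1", "NA_rep2", "ACC_rep2", "ACC_rep3", "ACC_rep1"]
        res2 = differential_expression(mat[perm], meta.loc[perm], p2g)
        sig1 = {r.gene_id for r in res1 if r.significant}
        sig2 = {r.gene_id for r in res2 if r.significant}
        assert sig1 == sig2

    def test_single_replicate_condition_is_an_error(self):
        mat, meta, p2g, _ = de_fixture(4)
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(mat.drop(columns=["ACC_rep2", "ACC_rep3"]),
                                    meta.drop(index=["ACC_rep2", "ACC_rep3"]), p2g)

    def test_probe_pairs_give_correlated_fold_changes(self):
        """Two probes per gene must report near-identical fold changes."""
        cfg = SimConfig(seed=6, array=ArrayConfig(n_de=400, replicate_sigma=0.05))
        probes = [(f"p{i:05d}_{j}", f"g{i:05d}") for i in range(1000) for j in (0, 1)]
        mat, meta, _ = gen_signals(cfg, probes, cross_species=False)
        logm = np.log2(mat)
        acc = [s for s in mat.columns if s.startswith("ACC")]
        na = [s for s in mat.columns if s.startswith("NA")]
        fc = (logm[acc].mean(axis=1) - logm[na].mean(axis=1)).to_numpy()
        r = np.corrcoef(fc[0::2], fc[1::2])[0, 1]
        assert r > 0.9


class TestCrossSpeciesOverlap:
    def make(self, gene, fc, q):
        return DEResult(gene, fc, q, q)

    def test_identical_lists_have_empty_exclusive_sets(self):
        de = [self.make(f"g{i}", 2.0, 0.01) for i in range(10)]
        rep = cross_species_overlap(de, list(de))
        assert (rep.both, rep.same_only, rep.cross_only) == (10, 0, 0)

    def test_counts_equal_set_algebra_oracle(self):
        same = [self.make(f"g{i}", 2.0 if i < 6 else 0.0, 0.01) for i in range(10)]
        cross = [self.make(f"g{i}", 2.0 if i % 2 else 0.0, 0.01) for i in range(10)]
        sig_same = {r.gene_id for r in same if r.significant}
        sig_cross = {r.gene_id for r in cross if r.significant}
        rep = cross_species_overlap(same, cross)
        assert rep.both == len(sig_same & sig_cross)
        assert rep.same_only == len(sig_same - sig_cross)
        assert rep.cross_only == len(sig_cross - sig_same)

    def test_disjoint_gene_spaces_are_an_error(self):
        with pytest.raises(ValueError):
            cross_species_overlap([self.make("a", 2, 0.01)], [self.make("b", 2, 0.01)])

    def test_mismatch_attenuation_reduces_cross_platform_recall(self):
        cfg = SimConfig(seed=8, array=ArrayConfig(n_de=100, replicate_sigma=0.1))
        probes = [(f"p{i:05d}", f"g{i:05d}") for i in range(2000)]
        same, meta, truth = gen_signals(cfg, probes, cross_species=False)
        cross, _, _ = gen_signals(cfg, probes, cross_species=True)
        p2g = dict(probes)
        de_same = differential_expression(same, meta, p2g)
        de_cross = differential_expression(cross, meta, p2g)
        planted = set(truth.de_genes)
        recall_same = len({r.gene_id for r in de_same if r.significant} & planted)
        recall_cross = len({r.gene_id for r in de_cross if r.significant} & planted)
        assert recall_cross < recall_same
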