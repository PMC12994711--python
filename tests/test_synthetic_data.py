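"""Tests of the coalescent and proteome generators against closed forms."""

import json

import numpy as np
import pandas as pd
import pytest

from tescan import popgen_stats as ps
from tescan import sel_sites
from tescan.synthetic_data import (
    ConfigurationError,
    SimPopConfig,
    SimProteomeConfig,
    sample_site_counts,
    simulate_neutral_window,
    simulate_ortholog_proteins,
    simulate_populations,
    simulate_sweep_window,
    tile_genes,
    write_population_vcf,
)


def pop_config(**kw):
    base = dict(n_haplotypes=10, theta=5.0, n_windows=50, window_length_bp=2500, seed=0)
    base.update(kw)
    return SimPopConfig(**base)


class TestNeutralCoalescent:
    def test_zero_theta_gives_no_segregating_sites(self):
        cfg = pop_config(theta=0.0)
        assert simulate_neutral_window(cfg, 0).S == 0

    def test_two_haplotypes_only_singletons(self):
        cfg = pop_config(n_haplotypes=2, theta=20.0)
        for idx in range(5):
            w = simulate_neutral_window(cfg, idx)
            assert all(x == 1 for x in w.derived_counts)

    def test_identical_seed_reproduces_identical_windows(self):
        cfg = pop_config()
        w1 = simulate_neutral_window(cfg, 7)
        w2 = simulate_neutral_window(cfg, 7)
        assert w1 == w2

    def test_neutral_window_rejects_sweep_index(self):
        cfg = pop_config(sweep_windows={3})
        with pytest.raises(ConfigurationError):
            simulate_neutral_window(cfg, 3)

    def test_watterson_expectation(self):
        """Mean S matches theta * a1 within 3 Monte-Carlo standard errors."""
        cfg = pop_config(n_haplotypes=25, theta=5.0, n_windows=600)
        S = np.array([simulate_neutral_window(cfg, i).S for i in range(600)])
        expected = 5.0 * sum(1 / i for i in range(1, 25))
        se = S.std(ddof=1) / np.sqrt(S.size)
        assert abs(S.mean() - expected) < 3 * se


class TestSweepDistortion:
    def test_zero_strength_identical_to_neutral(self):
        neutral = pop_config()
        swept = pop_config(sweep_windows={5}, sweep_strength=0.0)
        w_n = simulate_neutral_window(neutral, 5)
        w_s = simulate_sweep_window(swept, 5)
        assert w_n.derived_counts == w_s.derived_counts

    def test_full_star_at_age_zero_polarizes_counts(self):
        # with full capture at time 0 only the star's upper branch and the
        # escaped lineage carry mutations: counts are 1 or n-1
        cfg = pop_config(n_haplotypes=12, theta=10.0, sweep_windows={0}, sweep_age=0.0, sweep_strength=1.0, sweep_escape=0.0)
        counts = []
        for seed in range(20):
            w = simulate_sweep_window(pop_config(
                n_haplotypes=12, theta=10.0, sweep_windows={0}, sweep_age=0.0,
                sweep_strength=1.0, sweep_escape=0.0, seed=seed), 0)
            counts.extend(w.derived_counts)
        assert counts
        assert set(counts) <= {1, 11}

    def test_sweep_window_requires_membership(self):
        with pytest.raises(ConfigurationError):
            simulate_sweep_window(pop_config(), 0)

    def test_hard_sweep_produces_negative_d_and_h(self):
        """Directional check of the hard-sweep signature (n=25, theta=5)."""
        D, H = [], []
        for seed in range(500):
            cfg = pop_config(
                n_haplotypes=25, theta=5.0, sweep_windows={0},
                sweep_age=0.05, sweep_strength=1.0, seed=seed,
            )
            w = simulate_sweep_window(cfg, 0)
            if w.S:
                D.append(ps.tajimas_d(w))
                H.append(ps.fay_wu_h(w))
        assert np.nanmean(D) < -0.5
        assert np.mean(H) < 0

    def test_sweep_monotonicity_in_strength(self):
        """Stronger sweeps never raise mean D or mean H (2-SE tolerance)."""
        means = {}
        for strength in (0.0, 0.5, 1.0):
            D, H = [], []
            for seed in range(300):
                cfg = pop_config(
                    n_haplotypes=25, theta=5.0, sweep_windows={0},
                    sweep_age=0.05, sweep_strength=strength, seed=seed,
                )
                w = simulate_sweep_window(cfg, 0) if strength > 0 else simulate_neutral_window(
                    pop_config(n_haplotypes=25, theta=5.0, seed=seed), 0
                )
                if w.S:
                    D.append(ps.tajimas_d(w))
                    H.append(ps.fay_wu_h(w))
            means[strength] = (
                np.nanmean(D), 2 * np.nanstd(D) / np.sqrt(len(D)),
                np.mean(H), 2 * np.std(H) / np.sqrt(len(H)),
            )
        for lo, hi in ((0.0, 0.5), (0.5, 1.0)):
            d_lo, d_se, h_lo, h_se = means[hi]
            d_hi, d_se2, h_hi, h_se2 = means[lo]
            assert d_lo <= d_hi + d_se + d_se2
            assert h_lo <= h_hi + h_se + h_se2

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            pop_config(sweep_strength=1.5)
        with pytest.raises(ConfigurationError):
            pop_config(n_haplotypes=1)
        with pytest.raises(ConfigurationError):
            pop_config(sweep_windows={999})


class TestPopulationOutputs:
    def test_vcf_bytes_deterministic(self, tmp_path):
        cfg = pop_config(n_windows=10)
        write_population_vcf(cfg, tmp_path / "a.vcf", "p")
        write_population_vcf(cfg, tmp_path / "b.vcf", "p")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_vcf_round_trip_recovers_counts(self, tmp_path):
        cfg = pop_config(n_windows=20)
        write_population_vcf(cfg, tmp_path / "t.vcf", "p")
        windows, tally = ps.windows_from_vcf(
            str(tmp_path / "t.vcf"), size=2500, step=2500
        )
        assert tally.get("aa_mismatch", 0) == 0
        simulated = [simulate_neutral_window(cfg, i) for i in range(20)]
        for sim, read in zip(simulated, windows):
            assert sorted(sim.derived_counts) == sorted(read.derived_counts)

    def test_manifest_bookkeeping_shared_sweeps(self, tmp_path):
        sweep_loci = frozenset(range(20, 40))  # covers gene_00001
        configs = {
            f"pop{i}": pop_config(n_windows=60, sweep_windows=sweep_loci, seed=i)
            for i in range(3)
        }
        genes = tile_genes(60 * 2500, gene_span=50_000, margin=10_000)
        manifest = simulate_populations(configs, tmp_path, genes=genes)
        for pop in configs:
            assert manifest["populations"][pop]["sweep_genes"] == ["gene_00001"]

    def test_manifest_empty_sweep_set(self, tmp_path):
        manifest = simulate_populations({"p": pop_config(n_windows=40)}, tmp_path)
        assert manifest["populations"]["p"]["sweep_genes"] == []
        assert json.loads((tmp_path / "manifest.json").read_text()) == manifest


class TestProteomeGenerator:
    def test_default_geometry_is_valid_and_deterministic(self):
        a = SimProteomeConfig.default(seed=3, n_proteins=10)
        b = SimProteomeConfig.default(seed=3, n_proteins=10)
        assert a == b
        assert a.n_proteins == 10

    def test_invalid_segment_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            SimProteomeConfig(protein_lengths=(100,), idr_segments=(((10, 120, 0.9),),))
        with pytest.raises(ConfigurationError):
            SimProteomeConfig(
                protein_lengths=(100,), idr_segments=(((10, 50, 0.9), (40, 80, 0.9)),)
            )

    def test_perfect_detection_recovers_planted_sites_exactly(self):
        cfg = SimProteomeConfig.default(
            seed=1, n_proteins=8, n_species=4,
            method_sensitivity=1.0, method_specificity=1.0,
        )
        bundle = simulate_ortholog_proteins(cfg)
        for protein, truth in bundle.truth["true_positive_sites"].items():
            calls = bundle.calls[bundle.calls["protein"] == protein]
            got = sel_sites.call_consensus_sites(calls)
            assert got == sorted(truth)

    def test_uniform_placement_mixture_fraction(self, rng):
        """At rho=5 and IDR fraction 0.4 the in-IDR site share is 10/13."""
        L = 1000
        cfg = SimProteomeConfig(
            protein_lengths=(L,),
            idr_segments=(((1, 400, 0.95),),),
            planted_site_enrichment=5.0,
            site_rate=0.02,
        )
        k = m = 0
        for _ in range(400):
            c = sample_site_counts(cfg, rng)
            k += c.k_in_idr
            m += c.m_total
        expected = (5 * 0.4) / (5 * 0.4 + 0.6)
        se = np.sqrt(expected * (1 - expected) / m)
        assert abs(k / m - expected) < 3 * se

    def test_bundle_deterministic_and_writable(self, tmp_path):
        cfg = SimProteomeConfig.default(seed=2, n_proteins=4, n_species=3)
        b1 = simulate_ortholog_proteins(cfg)
        b2 = simulate_ortholog_proteins(cfg)
        pd.testing.assert_frame_equal(b1.calls, b2.calls)
        pd.testing.assert_frame_equal(b1.disorder, b2.disorder)
        b1.write(tmp_path)
        assert (tmp_path / "truth.json").exists()
        msa = sel_sites.read_msa_fasta(tmp_path / "msa" / "prot_0000.fasta")
        assert msa[0][0] == cfg.reference_species
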