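"""Tests of IDR consensus calling, sequence descriptors and statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from tescan.idr_analysis import (
    FeatureConfig,
    IDRInterval,
    binomial_enrichment,
    compare_groups,
    consensus_idrs,
    constraint_feature_correlation,
    disorder_fraction_correlation,
    extract_ortholog_segment,
    fcr_ncpr,
    idr_feature_table,
    shd,
)

from conftest import kendall_tau_b_oracle


def disorder_table(entries, protein="p"):
    return pd.DataFrame(
        [(protein, sp, r, 1) for sp, r in entries],
        columns=["protein", "species", "residue", "disordered"],
    )


def uniform_msa(n_species, length, char="A"):
    return [(f"sp{i}", char * length) for i in range(n_species)]


class TestConsensusIdrs:
    def test_unanimous_run_becomes_interval(self):
        msa = uniform_msa(3, 80)
        entries = [(f"sp{i}", r) for i in range(3) for r in range(10, 61)]
        idrs = consensus_idrs(disorder_table(entries), msa, "sp0")
        assert [(i.start, i.end) for i in idrs] == [(10, 60)]

    def test_29_residue_run_is_dropped(self):
        msa = uniform_msa(2, 60)
        entries = [(f"sp{i}", r) for i in range(2) for r in range(10, 39)]
        assert consensus_idrs(disorder_table(entries), msa, "sp0") == []

    def test_half_species_boundary_is_inclusive(self):
        msa = uniform_msa(4, 50)
        entries = [(sp, r) for sp in ("sp0", "sp1") for r in range(1, 41)]
        idrs = consensus_idrs(disorder_table(entries), msa, "sp0")
        assert [(i.start, i.end) for i in idrs] == [(1, 40)]
        # below half: 1 of 4 species is not enough
        entries1 = [("sp0", r) for r in range(1, 41)]
        assert consensus_idrs(disorder_table(entries1), msa, "sp0") == []

    def test_invariant_to_species_order_and_all_gap_rows(self):
        base = [("sp0", "A" * 60), ("sp1", "A" * 60)]
        entries = [(sp, r) for sp, _ in base for r in range(5, 45)]
        table = disorder_table(entries)
        a = consensus_idrs(table, base, "sp0")
        b = consensus_idrs(table, list(reversed(base)), "sp0")
        c = consensus_idrs(table, base + [("sp2", "-" * 60)], "sp0")
        assert a == b == c

    def test_gap_aware_projection_to_reference(self):
        # reference has a gap; the aligned disordered block still projects
        # onto consecutive reference residues
        msa = [("sp0", "A" * 20 + "-" + "A" * 40), ("sp1", "A" * 61)]
        entries = [("sp0", r) for r in range(10, 55)] + [("sp1", r) for r in range(10, 56)]
        idrs = consensus_idrs(disorder_table(entries), msa, "sp0")
        assert len(idrs) == 1
        assert idrs[0].length >= 30

    def test_missing_reference_raises(self):
        with pytest.raises(KeyError):
            consensus_idrs(disorder_table([]), uniform_msa(2, 40), "nope")


class TestSequenceDescriptors:
    @pytest.mark.parametrize(
        "seq,fcr,ncpr",
        [("KKDD", 1.0, 0.0), ("KKKK", 1.0, 1.0), ("GGGG", 0.0, 0.0)],
    )
    def test_fcr_ncpr_hand_cases(self, seq, fcr, ncpr):
        assert fcr_ncpr(seq) == (fcr, ncpr)

    def test_histidine_flag(self):
        assert fcr_ncpr("HHHH")[0] == 0.0
        assert fcr_ncpr("HHHH", FeatureConfig(include_histidine=True))[0] == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fcr_ncpr("")

    def test_shd_smallest_case(self):
        # isoleucine has lambda = 1 on the normalized Kyte-Doolittle scale
        assert shd("II") == pytest.approx(1.0, abs=1e-12)

    def test_shd_hand_sum_three_residues(self):
        # lambda pattern [1, 0, 1]: pairs contribute 1, 1 and 1 -> 3/3
        assert shd("IRI") == pytest.approx(1.0, abs=1e-12)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=40))
    def test_shd_reversal_symmetry(self, seq):
        assert shd(seq) == pytest.approx(shd(seq[::-1]), abs=1e-10)

    def test_shd_needs_two_residues_and_known_scale(self):
        with pytest.raises(ValueError):
            shd("A")
        with pytest.raises(ValueError):
            shd("AX")


class TestFeatureTable:
    def test_identical_orthologs_have_zero_sd(self):
        msa = [("sp0", "KDGG" * 10), ("sp1", "KDGG" * 10), ("sp2", "KDGG" * 10)]
        idrs = [IDRInterval("p", 1, 40)]
        _, summary = idr_feature_table(idrs, msa, "sp0")
        assert (summary["sd"].abs() < 1e-12).all()

    def test_two_ortholog_sd_hand_case(self):
        msa = [("sp0", "KK" + "G" * 8), ("sp1", "KKKK" + "G" * 6)]
        _, summary = idr_feature_table([IDRInterval("p", 1, 10)], msa, "sp0")
        fcr_row = summary[summary["feature"] == "fcr"].iloc[0]
        assert fcr_row["mean"] == pytest.approx(0.3, abs=1e-12)
        assert fcr_row["sd"] == pytest.approx(0.1414, abs=5e-5)

    def test_ensemble_features_absent_without_external_table(self):
        msa = [("sp0", "KDGG" * 10), ("sp1", "KDGG" * 10)]
        per, summary = idr_feature_table([IDRInterval("p", 1, 40)], msa, "sp0")
        assert "sconf_per_n" not in per.columns
        assert "sconf_per_n" not in set(summary["feature"])

    def test_external_features_joined_by_overlap(self):
        msa = [("sp0", "KDGG" * 10), ("sp1", "KDGG" * 10)]
        ext = pd.DataFrame(
            {
                "protein": ["p", "p"],
                "species": ["sp0", "sp1"],
                "idr_start": [2, 2],
                "idr_end": [38, 38],
                "sconf_per_n": [2.5, 2.7],
                "nu": [0.5, 0.52],
            }
        )
        per, summary = idr_feature_table(
            [IDRInterval("p", 1, 40)], msa, "sp0", external=ext
        )
        sconf = summary[summary["feature"] == "sconf_per_n"].iloc[0]
        assert sconf["mean"] == pytest.approx(2.6, abs=1e-12)

    def test_gap_projection_extracts_ungapped_segment(self):
        msa = [("sp0", "MKV-W"), ("sp1", "M-VAW")]
        assert extract_ortholog_segment(msa, "sp0", "sp1", 1, 4) == "MVW"


class TestBinomialEnrichment:
    def test_zero_successes_greater_tail_is_one(self):
        assert binomial_enrichment(0, 10, 40, 100) == pytest.approx(1.0)

    def test_exact_tail_sum_hand_case(self):
        expected = sum(binom.pmf(j, 10, 0.3) for j in (9, 10))
        assert binomial_enrichment(9, 10, 30, 100) == pytest.approx(expected, rel=1e-12)

    def test_all_in_idr_near_unit_probability(self):
        m = 7
        assert binomial_enrichment(m, m, 999, 1000) == pytest.approx(0.999**m, rel=1e-12)

    def test_degenerate_probability_rejected(self):
        with pytest.raises(ValueError):
            binomial_enrichment(1, 2, 100, 100)
        with pytest.raises(ValueError):
            binomial_enrichment(1, 2, 0, 100)

    def test_zero_trials_returns_one(self):
        assert binomial_enrichment(0, 0, 40, 100) == 1.0


class TestGroupComparison:
    def test_exact_small_sample_p(self):
        out = compare_groups([1, 2, 3], [10, 20, 30])
        assert out["method"] == "exact"
        assert out["p"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_is_one(self):
        out = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["p"] == pytest.approx(1.0, abs=1e-9)

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=12)
        assert compare_groups(a, b)["p"] == pytest.approx(compare_groups(b, a)["p"], abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestCorrelations:
    def test_kendall_perfect_concordance(self):
        tau, _ = constraint_feature_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_kendall_perfect_discordance(self):
        x = [0.1, 0.4, 0.2, 0.9]
        tau, _ = constraint_feature_correlation(x, [-v for v in x])
        assert tau == pytest.approx(-1.0)

    def test_kendall_matches_pair_count_oracle(self, rng):
        x = rng.integers(0, 10, size=50).astype(float)  # ties included
        y = rng.integers(0, 10, size=50).astype(float)
        tau, _ = constraint_feature_correlation(x, y)
        assert tau == pytest.approx(kendall_tau_b_oracle(list(x), list(y)), abs=1e-12)

    def test_kendall_input_validation(self):
        with pytest.raises(ValueError):
            constraint_feature_correlation([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            constraint_feature_correlation([1, 2], [1, 2])

    def test_pearson_exact_cases(self, rng):
        a = rng.normal(size=30)
        r, _ = disorder_fraction_correlation(a, a)
        assert r == pytest.approx(1.0)
        r, _ = disorder_fraction_correlation(a, -a + 3.0)
        assert r == pytest.approx(-1.0)

    def test_pearson_matches_definition(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        r, _ = disorder_fraction_correlation(a, b)
        expected = float(
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_pearson_zero_variance_is_missing(self):
        r, p = disorder_fraction_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)
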