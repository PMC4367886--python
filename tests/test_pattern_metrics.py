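"""Profiles, entropy, paired comparisons, change calls, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linemeth import (
    call_change,
    cohort_change_calls,
    compare_entropy,
    compare_profiles,
    inter_locus_correlation,
    methylation_entropy,
    paired_wilcoxon,
    per_cpg_mean,
    simulate_marker_table,
    summarize_sample,
)
from linemeth.bisulfite_io import MISSING
from linemeth.validation import entropy_oracle, sign_flip_wilcoxon_p

from conftest import make_matrix


class TestPerCpgMean:
    def test_column_fractions_and_coverage(self):
        m = make_matrix([[1, 1], [1, 1], [0, 1], [0, 1]])
        prof = per_cpg_mean(m, min_coverage=1)
        np.testing.assert_allclose(prof.mean, [0.5, 1.0])
        np.testing.assert_array_equal(prof.coverage, [4, 4])

    def test_missing_calls_excluded_from_denominator(self):
        m = make_matrix([[1], [MISSING], [0]])
        prof = per_cpg_mean(m, min_coverage=1)
        np.testing.assert_allclose(prof.mean, [0.5])
        assert prof.coverage[0] == 2

    def test_low_coverage_flagged_nan(self):
        m = make_matrix([[1], [MISSING], [0]])
        prof = per_cpg_mean(m, min_coverage=10)
        assert np.isnan(prof.mean[0])


class TestMethylationEntropy:
    def test_single_epiallele_gives_zero(self):
        m = make_matrix(np.tile([1, 0, 1, 0], (20, 1)))
        assert methylation_entropy(m).entropy[0] == 0.0

    def test_all_sixteen_epialleles_equiprobable_gives_one(self):
        rows = [[(i >> k) & 1 for k in range(3, -1, -1)] for i in range(16)]
        m = make_matrix(rows)
        assert methylation_entropy(m).entropy[0] == 1.0

    def test_hand_worked_counts_4_2_1_1(self):
        rows = [[1, 1, 1, 1]] * 4 + [[0, 0, 0, 0]] * 2 + [[1, 0, 1, 0], [0, 1, 0, 1]]
        m = make_matrix(rows)
        assert methylation_entropy(m, min_reads=8).entropy[0] == pytest.approx(0.4375)

    def test_reads_with_missing_calls_dropped_per_window(self):
        rows = [[1, 1, 1, 1, 0]] * 12 + [[MISSING, 1, 1, 1, 1]] * 12
        m = make_matrix(rows)
        e = methylation_entropy(m, min_reads=10)
        assert e.n_reads[0] == 12  # first window loses the rows missing CpG 0
        assert e.n_reads[1] == 24

    def test_underpowered_window_is_nan(self):
        m = make_matrix(np.ones((5, 4), dtype=int))
        assert np.isnan(methylation_entropy(m, min_reads=10).entropy[0])

    def test_too_few_cpgs_rejected(self):
        with pytest.raises(ValueError):
            methylation_entropy(make_matrix(np.ones((10, 3), dtype=int)), b=4)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            n_reads = int(rng.integers(1, 13))
            n_cpg = int(rng.integers(4, 7))
            calls = rng.choice([1, 0, MISSING], size=(n_reads, n_cpg), p=[0.45, 0.45, 0.1])
            m = make_matrix(calls)
            got = methylation_entropy(m, min_reads=1).entropy
            expected = entropy_oracle(m, b=4, min_reads=1)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_permutation_invariant_over_reads(self, rng):
        calls = rng.choice([1, 0], size=(30, 6))
        m = make_matrix(calls)
        shuffled = make_matrix(calls[rng.permutation(30)])
        np.testing.assert_allclose(
            methylation_entropy(m).entropy, methylation_entropy(shuffled).entropy
        )


class TestPairedWilcoxon:
    def test_identical_profiles_give_p_one(self):
        x = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        assert paired_wilcoxon(x, x) == (0.0, 1.0)

    def test_six_concordant_differences_exact_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        _, p = paired_wilcoxon(x, x - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]))
        assert p == pytest.approx(2 / 64)

    def test_matches_sign_flip_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            x, y = rng.normal(size=n), rng.normal(size=n)
            _, p = paired_wilcoxon(x, y)
            assert p == pytest.approx(sign_flip_wilcoxon_p(x - y), abs=1e-12)


class TestCompareProfiles:
    def _profile(self, means, locus="L", sample="S"):
        m = make_matrix(np.ones((12, len(means)), dtype=int), locus_id=locus, sample_id=sample)
        prof = per_cpg_mean(m, min_coverage=1)
        prof.mean = np.asarray(means, dtype=float)
        return prof

    def test_identical_profiles_p_one(self):
        p1 = self._profile([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        _, p, n = compare_profiles(p1, p1)
        assert p == 1.0 and n == 6

    def test_concordant_shift_exact_p(self):
        t = self._profile([0.1, 0.2, 0.3, 0.4, 0.5, 0.62])
        n_ = self._profile([0.15, 0.26, 0.37, 0.48, 0.59, 0.72])
        _, p, _ = compare_profiles(t, n_)
        assert p == pytest.approx(2 / 64)

    def test_too_few_shared_cpgs_rejected(self):
        t = self._profile([0.1, np.nan, np.nan, 0.4, np.nan, 0.6])
        n_ = self._profile([0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            compare_profiles(t, n_)


class TestCompareEntropy:
    def test_identical_entropy_p_one(self, rng):
        calls = rng.choice([1, 0], size=(40, 10))
        e = methylation_entropy(make_matrix(calls))
        _, p, _ = compare_entropy(e, e)
        assert p == 1.0

    def test_patchy_tumor_vs_uniform_normal_is_significant(self, rng):
        from linemeth import canonical_model, simulate_matrix

        n_sig = 0
        reps = 20
        for _ in range(reps):
            t = simulate_matrix(canonical_model("patchy", n_cpg=20), 20, 500, rng)
            n = simulate_matrix(canonical_model("uniform_methylated"), 20, 500, rng)
            _, p, _ = compare_entropy(methylation_entropy(t), methylation_entropy(n))
            if p < 0.05:
                n_sig += 1
        assert n_sig >= 0.95 * reps

    def test_disjoint_window_sets_rejected(self, rng):
        calls = rng.choice([1, 0], size=(40, 10))
        e1 = methylation_entropy(make_matrix(calls))
        e2 = methylation_entropy(make_matrix(calls))
        e2.window_start = e2.window_start + 100
        with pytest.raises(ValueError, match="disjoint"):
            compare_entropy(e1, e2)


class TestCallChange:
    @pytest.mark.parametrize(
        "delta,label",
        [(-15, "hypomethylated"), (-10, "unchanged"), (0, "unchanged"),
         (10, "unchanged"), (15, "hypermethylated")],
    )
    def test_strict_ten_point_rule(self, delta, label):
        assert call_change(50.0 + delta, 50.0).label == label

    @given(t=st.floats(0, 100), n=st.floats(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_tumor_normal_swap(self, t, n):
        fwd, rev = call_change(t, n), call_change(n, t)
        assert fwd.delta == -rev.delta
        swap = {"hypomethylated": "hypermethylated",
                "hypermethylated": "hypomethylated", "unchanged": "unchanged"}
        assert rev.label == swap[fwd.label]

    def test_missing_mean_rejected(self):
        with pytest.raises(ValueError):
            call_change(np.nan, 50.0)


class TestSummarizeSample:
    @pytest.mark.parametrize(
        "labels,category",
        [(["hypomethylated", "hypomethylated"], "hypo_only"),
         (["hypermethylated"], "hyper_only"),
         (["hypomethylated", "hypermethylated"], "both"),
         (["unchanged", "unchanged"], "none")],
    )
    def test_categories(self, labels, category):
        calls = [call_change(50 + (-15 if l == "hypomethylated" else 15 if l == "hypermethylated" else 0), 50,
                             locus_id=f"L{i}", sample_pair_id="P1")
                 for i, l in enumerate(labels)]
        s = summarize_sample(calls)
        assert s.category == category

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample([])


class TestInterLocusCorrelation:
    def test_duplicated_marker_correlates_perfectly(self):
        table = simulate_marker_table(n_pairs=10, markers=["A", "B"], rng=0)
        table["B"] = table["A"]
        rho, p, sig = inter_locus_correlation(table, "tumor")
        assert rho.loc["A", "B"] == pytest.approx(1.0)

    def test_null_markers_rarely_significant(self):
        hits, total = 0, 0
        for rep in range(30):
            table = simulate_marker_table(n_pairs=20, markers=4, pair_sd=0.0, rng=rep)
            _, p, _ = inter_locus_correlation(table, "tumor")
            vals = p.to_numpy()[np.triu_indices(4, 1)]
            hits += int(np.sum(vals < 0.05))
            total += len(vals)
        assert hits / total < 0.12

    def test_too_few_samples_rejected(self):
        table = simulate_marker_table(n_pairs=4, markers=2, rng=0)
        with pytest.raises(ValueError):
            inter_locus_correlation(table, "tumor")

    def test_constant_marker_flagged_undefined(self):
        table = simulate_marker_table(n_pairs=10, markers=["A", "B"], rng=0)
        table["B"] = 50.0
        rho, _, sig = inter_locus_correlation(table, "tumor")
        assert np.isnan(rho.loc["A", "B"]) and not sig.loc["A", "B"]


def test_cohort_change_calls_match_planted_shifts():
    table = simulate_marker_table(
        n_pairs=30, markers=["A", "B"], tumor_shifts={"A": -30.0},
        marker_sd=1.0, pair_sd=1.0, rng=5,
    )
    calls = cohort_change_calls(table)
    a = calls[calls["locus_id"] == "A"]
    b = calls[calls["locus_id"] == "B"]
    assert (a["label"] == "hypomethylated").mean() > 0.95
    assert (b["label"] == "unchanged").mean() > 0.95
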