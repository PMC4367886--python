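"""Marker tests, FDR control, logistic scoring, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linemeth import (
    bh_fdr,
    fit_logistic,
    marker_test_groups,
    marker_test_paired,
    model_report,
    roc_auc,
    run_marker_cascade,
    simulate_marker_table,
    validate_marker_table,
)
from linemeth.validation import bh_stepup_oracle, kruskal_h_oracle


class TestMarkerTestPaired:
    def test_identical_values_give_p_one(self):
        table = simulate_marker_table(n_pairs=8, markers=["A"], rng=0)
        wide = table.pivot(index="pair_id", columns="group", values="A")
        table.loc[table["group"] == "tumor", "A"] = wide["normal"].to_numpy()
        _, p = marker_test_paired(table, "A")
        assert p == 1.0

    def test_six_concordant_pairs_exact_p(self):
        rows = []
        for i in range(6):
            rows.append({"sample_id": f"t{i}", "pair_id": f"P{i}", "group": "tumor", "A": 50.0 - i - 1})
            rows.append({"sample_id": f"n{i}", "pair_id": f"P{i}", "group": "normal", "A": 60.0 + i})
        _, p = marker_test_paired(pd.DataFrame(rows), "A")
        assert p == pytest.approx(2 / 64)

    def test_three_pairs_rejected(self):
        table = simulate_marker_table(n_pairs=3, markers=["A"], rng=0)
        with pytest.raises(ValueError):
            marker_test_paired(table, "A")


class TestMarkerTestGroups:
    def test_two_identical_groups_give_h_zero(self):
        rows = [{"sample_id": f"s{i}", "group": g, "A": v}
                for g in ("x", "y") for i, v in enumerate([1.0, 2.0, 3.0])]
        h, p = marker_test_groups(pd.DataFrame(rows), "A")
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_separated_groups_match_closed_form(self):
        rows = (
            [{"sample_id": f"a{i}", "group": "x", "A": v} for i, v in enumerate([1, 2, 3])]
            + [{"sample_id": f"b{i}", "group": "y", "A": v} for i, v in enumerate([10, 11, 12])]
        )
        h, _ = marker_test_groups(pd.DataFrame(rows), "A")
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_matches_rank_sum_oracle_with_ties(self, rng):
        for _ in range(20):
            sizes = rng.integers(3, 6, size=int(rng.integers(2, 4)))
            values = rng.integers(0, 6, size=int(sizes.sum())).astype(float)
            rows, start = [], 0
            groups = []
            for gi, sz in enumerate(sizes):
                chunk = values[start : start + sz]
                groups.append(chunk)
                rows += [{"sample_id": f"s{start + k}", "group": f"g{gi}", "A": v}
                         for k, v in enumerate(chunk)]
                start += sz
            if all(np.all(values == values[0]) for _ in [0]):
                continue
            try:
                h, _ = marker_test_groups(pd.DataFrame(rows), "A")
            except ValueError:
                continue  # scipy rejects all-identical data
            assert h == pytest.approx(kruskal_h_oracle(groups), abs=1e-9)

    def test_single_group_rejected(self):
        rows = [{"sample_id": f"s{i}", "group": "x", "A": float(i)} for i in range(5)]
        with pytest.raises(ValueError):
            marker_test_groups(pd.DataFrame(rows), "A")


class TestBhFdr:
    def test_step_up_hand_example(self):
        q, sel = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert sel.all()

    def test_single_p_passes_through(self):
        q, _ = bh_fdr([0.3])
        assert q[0] == pytest.approx(0.3)

    def test_all_ones_select_nothing(self):
        q, sel = bh_fdr([1.0, 1.0, 1.0])
        assert np.all(q == 1.0) and not sel.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_q_dominates_p_and_matches_oracle_under_permutation(self, pvals):
        p = np.asarray(pvals)
        q, _ = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm, _ = bh_fdr(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        _, auc = roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == 0.5

    def test_shuffled_labels_average_half(self, rng):
        scores = rng.random(30)
        aucs = [roc_auc(scores, rng.permutation([1] * 15 + [0] * 15))[1] for _ in range(200)]
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=30),
        st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_rank_formula_equals_trapezoidal_step_area(self, scores, data):
        n = len(scores)
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(labels) in (0, n):
            return
        roc, auc = roc_auc(scores, labels)
        trapezoid = float(np.trapezoid(roc["tpr"], roc["fpr"]))
        assert auc == pytest.approx(trapezoid, abs=1e-9)


class TestFitLogistic:
    def test_perfect_marker_pushes_probabilities_to_extremes(self):
        table = simulate_marker_table(
            n_pairs=10, markers=["A"], tumor_shifts={"A": -40.0},
            marker_sd=1.0, pair_sd=0.0, rng=0,
        )
        model = fit_logistic(table, ["A"], groups=table["pair_id"])
        y = (table["group"] == "tumor").to_numpy()
        pi = model.probabilities.to_numpy()
        assert np.all(pi[y] > 0.99) and np.all(pi[~y] < 0.01)
        assert model.auc_insample == 1.0

    def test_empty_selection_reports_skip(self):
        table = simulate_marker_table(n_pairs=6, markers=["A"], rng=0)
        model = fit_logistic(table, [])
        assert model.skipped_reason == "no marker passed FDR"
        assert np.isnan(model.auc_insample)

    def test_single_class_rejected(self):
        table = simulate_marker_table(n_pairs=6, markers=["A"], rng=0)
        tumors = table[table["group"] == "tumor"]
        with pytest.raises(ValueError):
            fit_logistic(tumors, ["A"])


class TestCascade:
    def test_shifted_marker_selected_and_model_separates(self):
        table = simulate_marker_table(
            n_pairs=20, markers=6, tumor_shifts={"M01": -15.0},
            marker_sd=3.5, pair_sd=3.5, rng=1,
        )
        model = run_marker_cascade(table, design="paired", rng_seed=0)
        assert "M01" in model.selected
        assert model.auc_oof > 0.85
        text = model_report(model)
        assert "M01" in text and "Out-of-fold AUC" in text

    def test_groups_design_runs_kruskal_screen(self):
        rng = np.random.default_rng(2)
        rows = []
        for g, shift in (("healthy_blood", 0.0), ("patient_blood", -12.0)):
            for i in range(10):
                rows.append({"sample_id": f"{g}{i}", "group": g,
                             "A": 70 + shift + rng.normal(0, 3),
                             "B": 70 + rng.normal(0, 3)})
        model = run_marker_cascade(pd.DataFrame(rows), design="groups")
        stats = model.marker_stats.set_index("marker")
        assert stats.loc["A", "q"] < 0.05
        assert stats.loc["B", "q"] > 0.05

    def test_pairing_violations_rejected(self):
        table = simulate_marker_table(n_pairs=6, markers=2, rng=0)
        broken = table.drop(index=0)
        with pytest.raises(ValueError, match="pairs"):
            validate_marker_table(broken, paired=True)
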