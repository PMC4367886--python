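"""Generator: epiallele draws, bisulfite conversion, samples, cohorts."""

import numpy as np
import pandas as pd
import pytest

from linemeth import (
    EpialleleModel,
    SimulationConfig,
    bisulfite_convert,
    canonical_model,
    config_from_yaml,
    config_to_yaml,
    default_loci,
    draw_epialleles,
    simulate_cohort,
    simulate_marker_table,
    simulate_sample,
)


class TestDrawEpialleles:
    def test_degenerate_probabilities_force_all_methylated(self, rng):
        uniform = EpialleleModel(kind="uniform", base_methylation=1.0)
        allelic = EpialleleModel(kind="allelic", base_methylation=1.0, allelic_fraction=1.0)
        for model in (uniform, allelic):
            states = draw_epialleles(model, 8, 50, rng)
            assert np.all(states == 1)

    def test_patchy_seed_demethylates_only_the_seed_without_spread(self, rng):
        model = EpialleleModel(
            kind="patchy", base_methylation=0.8, seed_cpg_indices=(3,),
            seed_demethylation_prob=1.0, spread_decay=0.0,
        )
        states = draw_epialleles(model, 10, 10_000, rng)
        emp = states.mean(axis=0)
        assert emp[3] == 0.0
        sd = np.sqrt(0.8 * 0.2 / 10_000)
        others = np.delete(emp, 3)
        assert np.all(np.abs(others - 0.8) < 3 * sd + 1e-9)

    @pytest.mark.parametrize("kind", ["uniform_methylated", "allelic", "patchy"])
    def test_empirical_mean_matches_analytic_within_binomial_error(self, kind, rng):
        n_cpg, n_reads = 12, 10_000
        model = canonical_model(kind, n_cpg=n_cpg)
        states = draw_epialleles(model, n_cpg, n_reads, rng)
        expected = model.analytic_mean(n_cpg)
        sd = np.sqrt(np.maximum(expected * (1 - expected), 1e-12) / n_reads)
        assert np.all(np.abs(states.mean(axis=0) - expected) < 4 * sd + 1e-9)

    def test_invalid_kind_and_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            EpialleleModel(kind="mosaic")
        with pytest.raises(ValueError):
            EpialleleModel(kind="uniform", base_methylation=1.5)
        with pytest.raises(ValueError):
            EpialleleModel(kind="uniform", seed_cpg_indices=(1,))
        model = EpialleleModel(kind="patchy", seed_cpg_indices=(99,), seed_demethylation_prob=0.5)
        with pytest.raises(ValueError):
            draw_epialleles(model, 5, 10, np.random.default_rng(0))


class TestBisulfiteConvert:
    def test_methylated_cpg_stays_c_other_cytosines_convert(self):
        assert bisulfite_convert("ACGTC", [1]) == "ACGTT"

    def test_unmethylated_cpg_converts(self):
        assert bisulfite_convert("ACGTC", [0]) == "ATGTT"

    def test_without_cpgs_every_cytosine_converts(self):
        assert bisulfite_convert("CCATCC", []) == "TTATTT"

    def test_state_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bisulfite_convert("ACGTC", [1, 0])

    def test_conversion_failure_retains_cytosines(self):
        rng = np.random.default_rng(3)
        seq = bisulfite_convert("CCCCCCCCCC", [], conversion_failure_rate=1.0, rng=rng)
        assert seq == "CCCCCCCCCC"


class TestSimulateSample:
    def test_identical_seed_gives_identical_reads(self, small_locus):
        model = canonical_model("allelic")
        config = SimulationConfig(
            loci=[small_locus],
            tumor_models={small_locus.locus_id: model},
            normal_models={small_locus.locus_id: model},
            n_reads=20, rng_seed=11,
        )
        reads_a, _ = simulate_sample(config, "tumor")
        reads_b, _ = simulate_sample(config, "tumor")
        assert reads_a == reads_b

    def test_zero_reads_rejected(self, small_locus):
        model = canonical_model("uniform_methylated")
        with pytest.raises(ValueError):
            SimulationConfig(
                loci=[small_locus],
                tumor_models={small_locus.locus_id: model},
                normal_models={small_locus.locus_id: model},
                n_reads=0,
            )

    def test_ground_truth_delta_matches_model_difference(self, small_locus):
        tumor = EpialleleModel(kind="uniform", base_methylation=0.40)
        normal = EpialleleModel(kind="uniform", base_methylation=0.80)
        config = SimulationConfig(
            loci=[small_locus],
            tumor_models={small_locus.locus_id: tumor},
            normal_models={small_locus.locus_id: normal},
            n_reads=500, rng_seed=5,
        )
        _, t_truth = simulate_sample(config, "tumor", sample_id="T")
        _, n_truth = simulate_sample(config, "normal", sample_id="N")
        key_t, key_n = ("T", small_locus.locus_id), ("N", small_locus.locus_id)
        delta = (t_truth.per_cpg_mean[key_t].mean() - n_truth.per_cpg_mean[key_n].mean()) * 100
        # binomial error on 500 reads x 12 CpGs
        assert abs(delta - (-40.0)) < 5.0


class TestSimulateCohort:
    def _config(self, loci, tumor_base, normal_base, n_pairs=20, seed=0):
        tumor = {l.locus_id: EpialleleModel(kind="uniform", base_methylation=tumor_base) for l in loci}
        normal = {l.locus_id: EpialleleModel(kind="uniform", base_methylation=normal_base) for l in loci}
        return SimulationConfig(loci=loci, tumor_models=tumor, normal_models=normal,
                                n_pairs=n_pairs, rng_seed=seed)

    def test_null_cohort_has_mean_delta_near_zero(self, small_locus):
        config = self._config([small_locus], 0.75, 0.75, n_pairs=50)
        table, _ = simulate_cohort(config)
        wide = table.pivot(index="pair_id", columns="group", values=small_locus.locus_id)
        delta = (wide["tumor"] - wide["normal"]).mean()
        assert abs(delta) < 3.0

    def test_planted_shift_recovers_in_mean_delta(self, small_locus):
        config = self._config([small_locus], 0.90, 0.75, n_pairs=50, seed=1)
        table, truth = simulate_cohort(config)
        wide = table.pivot(index="pair_id", columns="group", values=small_locus.locus_id)
        delta = (wide["tumor"] - wide["normal"]).mean()
        assert abs(delta - 15.0) < 3.0
        assert set(truth.cohort["expected_label"]) == {"hypermethylated"}

    def test_single_pair_table_has_two_rows_per_locus_column(self):
        loci = default_loci()
        config = self._config(loci, 0.8, 0.8, n_pairs=1)
        table, _ = simulate_cohort(config)
        assert len(table) == 2
        marker_cols = [c for c in table.columns if c.startswith("L1")]
        assert len(marker_cols) == len(loci)


class TestDefaultLoci:
    def test_eleven_loci_with_expected_chromosome_classes(self):
        loci = default_loci()
        assert len(loci) == 11
        classes = [l.chromosome_class for l in loci]
        assert classes.count("autosomal") == 5
        assert classes.count("X_linked") == 6

    def test_deterministic_across_calls(self):
        a, b = default_loci(), default_loci()
        assert [(l.locus_id, l.sequence, l.cpg_positions) for l in a] == [
            (l.locus_id, l.sequence, l.cpg_positions) for l in b
        ]

    def test_consensus_maps_are_strictly_increasing_subsets(self):
        for locus in default_loci():
            ci = locus.consensus_cpg_index
            assert ci is not None and len(ci) == locus.n_cpg
            assert all(b > a for a, b in zip(ci, ci[1:]))


class TestMarkerTable:
    def test_shape_and_pairing(self):
        table = simulate_marker_table(n_pairs=5, markers=3, rng=1)
        assert len(table) == 10
        assert set(table["group"]) == {"tumor", "normal"}
        assert table.groupby("pair_id").size().eq(2).all()

    def test_shift_applies_to_tumor_only(self):
        table = simulate_marker_table(
            n_pairs=200, markers=2, tumor_shifts={"M01": -15.0}, rng=2
        )
        wide = table.pivot(index="pair_id", columns="group", values="M01")
        assert abs((wide["tumor"] - wide["normal"]).mean() + 15.0) < 1.5


def test_config_yaml_round_trip(tmp_path, small_locus):
    model_t = canonical_model("patchy", n_cpg=small_locus.n_cpg)
    model_n = canonical_model("uniform_methylated")
    config = SimulationConfig(
        loci=[small_locus],
        tumor_models={small_locus.locus_id: model_t},
        normal_models={small_locus.locus_id: model_n},
        n_reads=33, n_pairs=7, rng_seed=42, conversion_failure_rate=0.01,
    )
    path = tmp_path / "config.yaml"
    config_to_yaml(config, path)
    loaded = config_from_yaml(path, loci=[small_locus])
    assert loaded.n_reads == 33 and loaded.n_pairs == 7 and loaded.rng_seed == 42
    assert loaded.tumor_models[small_locus.locus_id] == model_t
    assert loaded.normal_models[small_locus.locus_id] == model_n
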