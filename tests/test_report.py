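"""Dataset I/O, pipeline orchestration, subset filters, heatmap contract."""

import numpy as np
import pandas as pd
import pytest

from circadiff import (
    DatasetError,
    PipelineConfig,
    SimulationConfig,
    generate_expression_dataset,
    heatmap_normalize,
    load_expression,
    log2fc_screens,
    run_pipeline,
    subset_filters,
    write_expression,
)


@pytest.fixture(scope="module")
def small_dataset():
    config = SimulationConfig(n_genes=60, seed=11, amplitude_range=(0.6, 1.0),
                              noise_sd=0.2)
    return generate_expression_dataset(config)


@pytest.fixture(scope="module")
def small_report(small_dataset):
    dataset, _ = small_dataset
    return run_pipeline(dataset, PipelineConfig())


class TestDatasetIO:
    def test_write_load_round_trip(self, tmp_path, small_dataset):
        dataset, _ = small_dataset
        write_expression(dataset, tmp_path / "m.tsv", tmp_path / "a.tsv")
        loaded = load_expression(tmp_path / "m.tsv", tmp_path / "a.tsv")
        assert loaded.gene_ids == dataset.gene_ids
        np.testing.assert_allclose(loaded.values, dataset.values, rtol=1e-11)
        assert list(loaded.samples["sample_id"]) == list(dataset.samples["sample_id"])

    def test_shuffled_matrix_columns_reconciled_by_sample_id(self, tmp_path, small_dataset):
        dataset, _ = small_dataset
        write_expression(dataset, tmp_path / "m.tsv", tmp_path / "a.tsv")
        m = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        shuffled = m[["gene_id"] + list(np.random.default_rng(0).permutation(m.columns[1:]))]
        shuffled.to_csv(tmp_path / "m2.tsv", sep="\t", index=False)
        loaded = load_expression(tmp_path / "m2.tsv", tmp_path / "a.tsv")
        np.testing.assert_allclose(loaded.values, dataset.values, rtol=1e-11)

    def test_missing_annotation_row_names_sample(self, tmp_path, small_dataset):
        dataset, _ = small_dataset
        write_expression(dataset, tmp_path / "m.tsv", tmp_path / "a.tsv")
        ann = pd.read_csv(tmp_path / "a.tsv", sep="\t")
        dropped = ann["sample_id"].iloc[0]
        ann.iloc[1:].to_csv(tmp_path / "a2.tsv", sep="\t", index=False)
        with pytest.raises(DatasetError, match=dropped):
            load_expression(tmp_path / "m.tsv", tmp_path / "a2.tsv")

    def test_non_numeric_cell_names_gene(self, tmp_path, small_dataset):
        dataset, _ = small_dataset
        write_expression(dataset, tmp_path / "m.tsv", tmp_path / "a.tsv")
        m = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        m[m.columns[5]] = m[m.columns[5]].astype(object)
        m.iloc[2, 5] = "oops"
        m.to_csv(tmp_path / "m3.tsv", sep="\t", index=False)
        with pytest.raises(DatasetError, match=m.iloc[2, 0]):
            load_expression(tmp_path / "m3.tsv", tmp_path / "a.tsv")


class TestRunPipeline:
    def test_report_has_one_row_per_gene(self, small_dataset, small_report):
        dataset, _ = small_dataset
        assert len(small_report) == dataset.n_genes
        assert small_report.index.tolist() == dataset.gene_ids

    def test_classification_matches_truth_on_clear_signal(self, small_dataset, small_report):
        _, truth = small_dataset
        label_map = {
            "both": "rhythmic_both",
            "young_only": "rhythmic_young_only",
            "old_only": "rhythmic_old_only",
            "neither": "arrhythmic",
        }
        expected = truth.set_index("gene_id")["true_class"].map(label_map)
        agree = (small_report["rhythm_class"] == expected).mean()
        assert agree >= 0.9

    def test_permuting_sample_columns_changes_nothing(self, small_dataset):
        dataset, _ = small_dataset
        rng = np.random.default_rng(2)
        perm = rng.permutation(dataset.n_samples)
        from circadiff import ExpressionDataset

        permuted = ExpressionDataset(
            gene_ids=dataset.gene_ids,
            values=dataset.values[:, perm],
            samples=dataset.samples.iloc[perm].reset_index(drop=True),
        )
        a = run_pipeline(dataset)
        b = run_pipeline(permuted)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_groups_produce_no_difference_calls(self):
        config = SimulationConfig(n_genes=20, seed=13, noise_sd=0.0, donor_offset_sd=0.0,
                                  delta_mesor=0.0, delta_amplitude=0.0,
                                  delta_phase_hours=0.0)
        dataset, _ = generate_expression_dataset(config)
        # make old an exact copy of young
        idx_y = dataset.group_columns("young")
        idx_o = dataset.group_columns("old")
        dataset.values[:, idx_o] = dataset.values[:, idx_y]
        report = run_pipeline(dataset)
        subsets = subset_filters(report)
        for name in ("decreased_mesor", "increased_mesor", "phase_advance", "phase_delay"):
            assert subsets[name].sum() == 0

    def test_deterministic_given_dataset(self, small_dataset):
        dataset, _ = small_dataset
        pd.testing.assert_frame_equal(run_pipeline(dataset), run_pipeline(dataset))


class TestSubsetFilters:
    def _row(self, **kw):
        base = {
            "q_rhythm_young": 0.01, "q_rhythm_old": 0.01,
            "q_d_mesor": 0.5, "q_d_amplitude": 0.5, "q_d_phase": 0.5,
            "d_mesor": 0.0, "d_amplitude": 0.0, "d_phase": 0.0,
            "w_neither": 0.0, "w_young_only": 0.0, "w_old_only": 0.0, "w_both": 0.0,
            "log2fc_mesor": 0.0, "log2fc_amplitude": 0.0,
        }
        base.update(kw)
        return base

    def _report(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])

    def test_decreased_vs_increased_mesor_direction(self):
        report = self._report([
            self._row(q_d_mesor=0.03, d_mesor=-0.4),
            self._row(q_d_mesor=0.03, d_mesor=+0.4),
        ])
        s = subset_filters(report)
        assert s["decreased_mesor"].tolist() == [True, False]
        assert s["increased_mesor"].tolist() == [False, True]

    def test_rhythmicity_gate_blocks_mesor_call(self):
        report = self._report([
            self._row(q_rhythm_old=0.2, q_d_mesor=0.01, d_mesor=-0.4),
        ])
        assert subset_filters(report)["decreased_mesor"].sum() == 0

    def test_phase_advance_vs_delay(self):
        report = self._report([
            self._row(q_d_phase=0.01, d_phase=-1.5),
            self._row(q_d_phase=0.01, d_phase=+1.5),
        ])
        s = subset_filters(report)
        assert s["phase_advance"].tolist() == [True, False]
        assert s["phase_delay"].tolist() == [False, True]

    def test_bic_subsets_independent_of_qvalues(self):
        report = self._report([
            self._row(w_young_only=0.8, q_rhythm_young=0.9, q_rhythm_old=0.9),
            self._row(w_old_only=0.8),
            self._row(w_both=0.8),
        ])
        s = subset_filters(report)
        assert s["loss_of_rhythmicity"].tolist() == [True, False, False]
        assert s["gain_of_rhythmicity"].tolist() == [False, True, False]
        assert s["rhythmic_both"].tolist() == [False, False, True]

    def test_bic_threshold_boundary_is_strict(self):
        report = self._report([self._row(w_young_only=0.75)])
        assert subset_filters(report)["loss_of_rhythmicity"].sum() == 0

    def test_mesor_screen_boundary_is_strict(self):
        report = self._report([
            self._row(w_both=0.8, q_d_mesor=0.01, d_mesor=0.3, log2fc_mesor=0.25),
            self._row(w_both=0.8, q_d_mesor=0.01, d_mesor=0.3, log2fc_mesor=0.26),
        ])
        s = log2fc_screens(report)
        assert s["mesor_increased"].tolist() == [True, True]
        assert s["mesor_increased_screened"].tolist() == [False, True]

    def test_amplitude_screen_requires_q_call(self):
        report = self._report([
            self._row(w_both=0.8, q_d_amplitude=0.5, d_amplitude=-0.3, log2fc_amplitude=-0.5),
            self._row(w_both=0.8, q_d_amplitude=0.01, d_amplitude=-0.3, log2fc_amplitude=-0.5),
            self._row(w_both=0.8, q_d_amplitude=0.01, d_amplitude=-0.3, log2fc_amplitude=-0.1),
        ])
        s = log2fc_screens(report)
        assert s["amplitude_decreased_screened"].tolist() == [False, True, False]

    def test_negative_screen_threshold_rejected(self):
        report = self._report([self._row()])
        with pytest.raises(ValueError):
            log2fc_screens(report, mesor_threshold=-0.1)

    def test_flags_are_pure_functions_of_report_columns(self, small_report):
        a = subset_filters(small_report)
        b = subset_filters(small_report.copy())
        for name in a:
            pd.testing.assert_series_equal(a[name], b[name])


class TestHeatmapNormalize:
    def test_rows_have_zero_mean_unit_sd(self, small_dataset):
        dataset, _ = small_dataset
        hm = heatmap_normalize(dataset)
        for group in ("young", "old"):
            block = hm.values.xs(group, axis=1, level="group")
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-9)
            np.testing.assert_allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_invariant_to_per_donor_offsets(self, small_dataset):
        dataset, _ = small_dataset
        from circadiff import ExpressionDataset

        shifted = ExpressionDataset(
            gene_ids=dataset.gene_ids,
            values=dataset.values.copy(),
            samples=dataset.samples,
        )
        donor_cols = np.flatnonzero(
            ((dataset.samples["group"] == "young") & (dataset.samples["donor"] == "B")).to_numpy()
        )
        shifted.values[:, donor_cols] += 7.5
        a = heatmap_normalize(dataset)
        b = heatmap_normalize(shifted)
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-9)

    def test_constant_gene_flagged_all_zero(self, small_dataset):
        dataset, _ = small_dataset
        from circadiff import ExpressionDataset

        values = dataset.values.copy()
        values[0, :] = 2.0
        flat = ExpressionDataset(gene_ids=dataset.gene_ids, values=values,
                                 samples=dataset.samples)
        hm = heatmap_normalize(flat)
        assert hm.zero_variance.iloc[0].all()
        np.testing.assert_array_equal(hm.values.iloc[0].to_numpy(), 0.0)

    def test_missing_cell_raises(self, small_dataset):
        dataset, _ = small_dataset
        from circadiff import ExpressionDataset

        keep = ~(
            (dataset.samples["group"] == "old") & (dataset.samples["timepoint_hr"] == 40.0)
        ).to_numpy()
        trimmed = ExpressionDataset(
            gene_ids=dataset.gene_ids,
            values=dataset.values[:, keep],
            samples=dataset.samples.loc[keep].reset_index(drop=True),
        )
        with pytest.raises(ValueError, match="old"):
            heatmap_normalize(trimmed)
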