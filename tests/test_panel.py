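"""Expression-panel construction: CPM, TMM, aggregation, pseudobulk."""

import math

import numpy as np
import pandas as pd
import pytest

from dese import (
    CellAnnotation,
    CountsMatrix,
    ExpressionPanel,
    aggregate_bulk,
    cpm_normalize,
    filter_cells,
    map_homologs,
    pseudobulk_clusters,
    tmm_factors,
)
from dese.errors import (
    MissingAnnotation,
    MissingTissueLabel,
    NotEnoughSamples,
    ZeroLibrarySize,
)


class TestCpmNormalize:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([1, 3], [250_000.0, 750_000.0]),
            ([5, 5, 5, 5], [250_000.0] * 4),
        ],
    )
    def test_proportions_scaled_to_million(self, column, expected):
        df = pd.DataFrame({"s": column})
        np.testing.assert_allclose(cpm_normalize(df)["s"], expected)

    def test_zero_library_raises_and_names_column(self):
        df = pd.DataFrame({"ok": [1, 1], "empty": [0, 0]})
        with pytest.raises(ZeroLibrarySize, match="empty"):
            cpm_normalize(df)

    def test_column_sums_and_idempotence(self, toy_counts):
        cpm = cpm_normalize(toy_counts)
        np.testing.assert_allclose(cpm.sum(axis=0), 1e6, rtol=1e-12)
        np.testing.assert_allclose(cpm_normalize(cpm), cpm, rtol=1e-9)


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(tmm_factors(df), 1.0, atol=1e-12)

    def test_pure_depth_difference_gives_unit_factors(self):
        a = np.array([10, 20, 30, 40])
        df = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(tmm_factors(df), 1.0, atol=1e-12)

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.poisson(50, size=(40, 3)) + 1, columns=list("abc"))
        f1 = tmm_factors(df, reference_column="a")
        df2 = df.copy()
        df2["b"] = df2["b"] * 7
        f2 = tmm_factors(df2, reference_column="a")
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-10)

    def test_single_column_rejected(self):
        with pytest.raises(NotEnoughSamples):
            tmm_factors(pd.DataFrame({"a": [1, 2]}))

    def test_spiked_gene_matches_trimmed_mean_oracle(self):
        """Hand-evaluated doubly-trimmed mean of M on a 20-gene fixture."""
        rng = np.random.default_rng(7)
        base = rng.integers(50, 150, size=20).astype(float)
        spiked = base.copy()
        spiked[0] *= 10  # composition outlier in column b
        df = pd.DataFrame({"a": base, "b": spiked})

        # oracle: direct evaluation with trim 30% of M, 5% of A
        na, nb = base.sum(), spiked.sum()
        m = np.log2((spiked / nb) / (base / na))
        a_val = 0.5 * np.log2((spiked / nb) * (base / na))
        n = len(m)
        drop_m = int(np.floor(n * 0.30 / 2))  # 3 per tail
        drop_a = int(np.floor(n * 0.05 / 2))  # 0 per tail
        order = np.argsort(m)
        keep = set(order[drop_m : n - drop_m])
        if drop_a:
            order_a = np.argsort(a_val)
            keep &= set(order_a[drop_a : n - drop_a])
        f_raw = 2 ** np.mean(m[sorted(keep)])
        expected = np.array([1.0, f_raw]) / np.sqrt(f_raw)

        got = tmm_factors(df, reference_column="a")
        np.testing.assert_allclose(got.to_numpy(), expected, rtol=1e-10)


class TestAggregateBulk:
    def test_duplicate_samples_average_to_themselves(self):
        cpm = cpm_normalize(pd.DataFrame({"s1": [1, 3], "s2": [1, 3]}))
        panel = aggregate_bulk(cpm, {"s1": "liver", "s2": "liver"})
        np.testing.assert_allclose(panel.values["liver"], cpm["s1"])

    def test_equal_weight_mean(self):
        cpm = pd.DataFrame({"s1": [1e6, 0.0], "s2": [0.0, 1e6]})
        panel = aggregate_bulk(cpm, {"s1": "t", "s2": "t"})
        np.testing.assert_allclose(panel.values["t"], [5e5, 5e5])

    def test_unmapped_sample_raises(self):
        cpm = pd.DataFrame({"s1": [1e6], "s2": [1e6]})
        with pytest.raises(MissingTissueLabel, match="s2"):
            aggregate_bulk(cpm, {"s1": "t"})


class TestFilterCells:
    def test_strict_umi_boundary(self):
        df = pd.DataFrame([[299, 300, 500]], index=["g"], columns=["c1", "c2", "c3"])
        kept = filter_cells(CountsMatrix(df))
        assert kept.column_ids == ["c2", "c3"]

    def test_identity_when_all_pass(self):
        df = pd.DataFrame([[300, 400]], index=["g"], columns=["c1", "c2"])
        assert filter_cells(CountsMatrix(df)).column_ids == ["c1", "c2"]

    def test_empty_result_allowed_with_warning(self, caplog):
        df = pd.DataFrame([[10, 20]], index=["g"], columns=["c1", "c2"])
        with caplog.at_level("WARNING"):
            kept = filter_cells(CountsMatrix(df))
        assert kept.values.shape[1] == 0
        assert "removed every cell" in caplog.text


def _annotation(cells, cluster, label, condition="normal", dataset="ds1"):
    return [(c, cluster, label, condition, dataset) for c in cells]


def _make_annotation(rows):
    return CellAnnotation(
        pd.DataFrame(
            rows,
            columns=["cell_id", "cluster_id", "cell_type_label",
                     "sample_condition", "dataset_id"],
        )
    )


class TestPseudobulkClusters:
    def test_top_fraction_average_forced_value(self):
        """20-cell cluster, top ceil(0.1*20)=2 cells with counts 4 and 6 -> 5."""
        cells = [f"c{i}" for i in range(20)]
        other = np.full(20, 10.0)
        g = np.concatenate([[6, 4], np.zeros(18)])  # totals: 16, 14, 10 x 18
        df = pd.DataFrame([g, other], index=["g", "filler"], columns=cells)
        panel = pseudobulk_clusters(
            CountsMatrix(df), _make_annotation(_annotation(cells, "k", "T cell")),
            min_cells=15,
        )
        pre_cpm = np.array([5.0, 10.0])  # mean of the two deepest cells
        np.testing.assert_allclose(
            panel.values["T cell"], pre_cpm / pre_cpm.sum() * 1e6
        )

    def test_small_cluster_dropped(self):
        cells = [f"c{i}" for i in range(14)]
        df = pd.DataFrame(np.ones((2, 14)), index=["g1", "g2"], columns=cells)
        panel = pseudobulk_clusters(
            CountsMatrix(df), _make_annotation(_annotation(cells, "k", "B cell"))
        )
        assert panel.columns == []

    def test_same_label_clusters_merged_within_dataset(self):
        cells1 = [f"a{i}" for i in range(10)]
        cells2 = [f"b{i}" for i in range(10)]
        df = pd.DataFrame(
            np.ones((2, 20)), index=["g1", "g2"], columns=cells1 + cells2
        )
        rows = _annotation(cells1, "k1", "T cell") + _annotation(cells2, "k2", "T cell")
        panel = pseudobulk_clusters(CountsMatrix(df), _make_annotation(rows))
        assert panel.columns == ["T cell"]

    @pytest.mark.parametrize("label,condition", [("UNKNOWN", "normal"), ("X", "abnormal")])
    def test_unknown_and_abnormal_dropped(self, label, condition):
        cells = [f"c{i}" for i in range(20)]
        df = pd.DataFrame(np.ones((2, 20)), index=["g1", "g2"], columns=cells)
        panel = pseudobulk_clusters(
            CountsMatrix(df),
            _make_annotation(_annotation(cells, "k", label, condition=condition)),
        )
        assert panel.columns == []

    def test_missing_annotation_raises(self):
        df = pd.DataFrame(np.ones((1, 2)), index=["g"], columns=["c1", "c2"])
        with pytest.raises(MissingAnnotation):
            pseudobulk_clusters(
                CountsMatrix(df), _make_annotation(_annotation(["c1"], "k", "T"))
            )

    def test_identical_cells_equal_single_cell_cpm(self):
        cells = [f"c{i}" for i in range(16)]
        profile = np.array([3.0, 7.0])
        df = pd.DataFrame(
            np.tile(profile[:, None], 16), index=["g1", "g2"], columns=cells
        )
        panel = pseudobulk_clusters(
            CountsMatrix(df), _make_annotation(_annotation(cells, "k", "T"))
        )
        np.testing.assert_allclose(panel.values["T"], profile / profile.sum() * 1e6)


class TestMapHomologs:
    def _panel(self, genes):
        values = pd.DataFrame(
            np.arange(len(genes) * 2, dtype=float).reshape(len(genes), 2) + 1,
            index=genes, columns=["t1", "t2"],
        )
        return ExpressionPanel(values)

    def test_identity_mapping_keeps_panel(self):
        panel = self._panel(["A", "B"])
        mapping = pd.DataFrame({"source": ["A", "B"], "target": ["A", "B"]})
        out = map_homologs(panel, mapping)
        pd.testing.assert_frame_equal(out.values, panel.values)

    def test_unmapped_gene_dropped_without_renormalizing(self):
        panel = self._panel(["A", "B"])
        mapping = pd.DataFrame({"source": ["A"], "target": ["HGNC1"]})
        out = map_homologs(panel, mapping)
        assert out.genes == ["HGNC1"]
        np.testing.assert_allclose(out.values.loc["HGNC1"], panel.values.loc["A"])

    def test_many_to_one_both_dropped(self):
        panel = self._panel(["A", "B", "C"])
        mapping = pd.DataFrame(
            {"source": ["A", "B", "C"], "target": ["H1", "H1", "H2"]}
        )
        out = map_homologs(panel, mapping)
        assert out.genes == ["H2"]

    def test_one_to_many_dropped(self):
        panel = self._panel(["A", "B"])
        mapping = pd.DataFrame({"source": ["A", "A", "B"], "target": ["H1", "H2", "H3"]})
        out = map_homologs(panel, mapping)
        assert out.genes == ["H3"]
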