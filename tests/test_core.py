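"""Wilcoxon tissue enrichment, the DESE loop and the hierarchy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import dese
from dese import (
    DeseConfig,
    dese_iterate,
    hierarchical_estimate,
    rank_columns,
    wilcoxon_enrichment,
)
from dese.errors import DegenerateGroups, EmptyAnalysis, EmptySubset
from dese.panel import ExpressionPanel


def _series(values, assoc_count):
    s = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
    assoc = {f"g{i}" for i in range(assoc_count)}
    return s, assoc


class TestWilcoxonEnrichment:
    def test_most_extreme_labeling_exact_p(self):
        """3 associated genes holding the 3 largest z of 6: p = 1/C(6,3)."""
        s, assoc = _series([10.0, 9.0, 8.0, 1.0, 2.0, 3.0], 3)
        res = wilcoxon_enrichment(s, assoc)
        assert res.pvalue == pytest.approx(1 / 20)

    def test_all_ties_give_p_one(self):
        s, assoc = _series([5.0] * 8, 4)
        assert wilcoxon_enrichment(s, assoc).pvalue == pytest.approx(1.0)

    def test_exact_branch_matches_scipy_without_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=7)
            s = pd.Series(np.concatenate([x, y]),
                          index=[f"g{i}" for i in range(12)])
            got = wilcoxon_enrichment(s, {f"g{i}" for i in range(5)}).pvalue
            ref = mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
            assert got == pytest.approx(ref, rel=1e-12)

    def test_degenerate_groups_rejected(self):
        s, _ = _series([1.0, 2.0, 3.0], 0)
        with pytest.raises(DegenerateGroups):
            wilcoxon_enrichment(s, set())
        with pytest.raises(DegenerateGroups):
            wilcoxon_enrichment(s, {"g0", "g1", "g2"})

    def test_asymptotic_branch_detects_shift(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=200)
        z[:40] += 2.0
        s = pd.Series(z, index=[f"g{i}" for i in range(200)])
        res = wilcoxon_enrichment(s, {f"g{i}" for i in range(40)})
        assert res.pvalue < 1e-10


class TestRankColumns:
    def test_adjusted_not_below_raw_and_ranked(self):
        rng = np.random.default_rng(10)
        z = pd.DataFrame(
            rng.normal(size=(50, 4)),
            index=[f"g{i}" for i in range(50)],
            columns=list("abcd"),
        )
        table = rank_columns(z, {f"g{i}" for i in range(10)})
        assert list(table["rank"]) == [1, 2, 3, 4]
        assert (table["fdr_pvalue"] >= table["pvalue"] - 1e-15).all()
        assert (table["bonferroni_pvalue"] >= table["pvalue"] - 1e-15).all()
        assert table["pvalue"].is_monotonic_increasing


class TestDeseIterate:
    def test_driver_recovered_and_trace_converges(self, small_pipeline):
        z = dese.rez_scores(small_pipeline["tissue_panel"])
        run = dese_iterate(
            small_pipeline["results"], small_pipeline["gene_data"], z,
            small_pipeline["panel"],
        )
        assert run.converged
        assert run.top_column == small_pipeline["config"].driver
        assert run.iterations[-1].assoc_genes == run.iterations[-2].assoc_genes

    def test_causal_genes_dominate_associated_set(self, small_pipeline):
        z = dese.rez_scores(small_pipeline["tissue_panel"])
        run = dese_iterate(
            small_pipeline["results"], small_pipeline["gene_data"], z,
            small_pipeline["panel"],
        )
        final = run.iterations[-1].assoc_genes
        causal = set(small_pipeline["causal"])
        assert len(final & causal) >= 0.8 * len(causal)

    def test_max_iter_one_without_fixed_point(self, small_pipeline):
        cfg = DeseConfig(max_iter=1, min_assoc=3, assoc_alpha=1e-12)
        z = dese.rez_scores(small_pipeline["tissue_panel"])
        run = dese_iterate(
            small_pipeline["results"], small_pipeline["gene_data"], z,
            small_pipeline["panel"], cfg,
        )
        assert len(run.iterations) >= 1
        if not run.converged:
            assert len([r for r in run.iterations]) <= 2

    def test_rerun_is_deterministic(self, small_pipeline):
        z = dese.rez_scores(small_pipeline["tissue_panel"])
        args = (
            small_pipeline["results"], small_pipeline["gene_data"], z,
            small_pipeline["panel"],
        )
        r1, r2 = dese_iterate(*args), dese_iterate(*args)
        pd.testing.assert_frame_equal(r1.tissues, r2.tissues)
        assert [i.assoc_genes for i in r1.iterations] == [
            i.assoc_genes for i in r2.iterations
        ]

    def test_no_shared_genes_rejected(self, small_pipeline):
        z = pd.DataFrame(
            np.zeros((12, 3)), index=[f"x{i}" for i in range(12)],
            columns=list("abc"),
        )
        with pytest.raises(EmptyAnalysis):
            dese_iterate(
                small_pipeline["results"], small_pipeline["gene_data"], z,
                small_pipeline["panel"],
            )


class TestHierarchicalEstimate:
    def test_stage_two_restricted_to_significant_organs(self, small_pipeline):
        trun, crun = hierarchical_estimate(
            small_pipeline["results"], small_pipeline["gene_data"],
            small_pipeline["tissue_panel"], small_pipeline["celltype_panel"],
            small_pipeline["panel"],
        )
        cfg = small_pipeline["config"]
        sig = trun.tissues[trun.tissues["fdr_pvalue"] < 0.05]
        organs = {small_pipeline["tissue_panel"].organ[c] for c in sig["column"]}
        celltype_organs = {
            small_pipeline["celltype_panel"].organ[c]
            for c in crun.tissues["column"]
        }
        assert cfg.driver in set(sig["column"])
        assert celltype_organs <= organs
        assert crun.top_column == cfg.driver_celltype

    def test_manual_organ_override(self, small_pipeline):
        organs = ["O01", "O02"]
        _, crun = hierarchical_estimate(
            small_pipeline["results"], small_pipeline["gene_data"],
            small_pipeline["tissue_panel"], small_pipeline["celltype_panel"],
            small_pipeline["panel"], organs=organs,
        )
        got = {
            small_pipeline["celltype_panel"].organ[c]
            for c in crun.tissues["column"]
        }
        assert got == set(organs)

    def test_no_significant_tissue_falls_back_to_all(self, small_pipeline, caplog):
        cfg = DeseConfig(tissue_alpha=1e-300)
        with caplog.at_level("WARNING"):
            _, crun = hierarchical_estimate(
                small_pipeline["results"], small_pipeline["gene_data"],
                small_pipeline["tissue_panel"], small_pipeline["celltype_panel"],
                small_pipeline["panel"], cfg,
            )
        assert "all cell types" in caplog.text
        assert len(crun.tissues) == len(small_pipeline["celltype_panel"].columns)

    def test_empty_subset_rejected(self, small_pipeline):
        with pytest.raises(EmptySubset):
            hierarchical_estimate(
                small_pipeline["results"], small_pipeline["gene_data"],
                small_pipeline["tissue_panel"], small_pipeline["celltype_panel"],
                small_pipeline["panel"], organs=["no-such-organ"],
            )
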