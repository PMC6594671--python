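"""Pathway scores, fold-changes, heatmap scaling and sum-normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietsurv import (
    CohortSimSpec,
    ExpressionMatrix,
    GeneSet,
    MouseSimSpec,
    ValidationError,
    group_log2fc,
    heatmap_values,
    pathway_score,
    per_sample_sum_normalize,
    simulate_cohort,
    simulate_mouse_design,
)


def _matrix(values, genes, samples, scale="log2p1"):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)


class TestPathwayScore:
    def test_mean_of_two_values(self):
        m = _matrix([[2.0], [4.0]], ["g1", "g2"], ["s1"])
        scores = pathway_score(m, GeneSet("p", ["g1", "g2"]))
        assert scores.loc["s1", "p"] == pytest.approx(3.0)

    def test_constant_panel_gives_constant_score(self):
        m = _matrix(np.full((3, 4), 5.5), ["a", "b", "c"], list("wxyz"))
        scores = pathway_score(m, GeneSet("p", ["a", "b", "c"]))
        np.testing.assert_allclose(scores["p"], 5.5, atol=1e-12)

    def test_invariant_to_gene_order_and_outside_genes(self, rng):
        m = _matrix(rng.uniform(0, 8, (6, 5)), [f"g{i}" for i in range(6)],
                    [f"s{j}" for j in range(5)])
        s1 = pathway_score(m, GeneSet("p", ["g1", "g3"]))
        s2 = pathway_score(m, GeneSet("p", ["g3", "g1"]))
        pd.testing.assert_frame_equal(s1, s2)
        shuffled = ExpressionMatrix(m.values.sample(frac=1, random_state=0), "log2p1")
        s3 = pathway_score(shuffled, GeneSet("p", ["g1", "g3"]))
        pd.testing.assert_frame_equal(s1, s3)

    @given(c=st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=20, deadline=None)
    def test_constant_shift_moves_score_by_constant(self, c):
        base = np.array([[1.0, 2.0], [3.0, 4.0]])
        genes, samples = ["g1", "g2"], ["s1", "s2"]
        s0 = pathway_score(_matrix(base, genes, samples), GeneSet("p", genes))
        s1 = pathway_score(_matrix(base + c, genes, samples), GeneSet("p", genes))
        np.testing.assert_allclose(s1.to_numpy(), s0.to_numpy() + c, atol=1e-12)

    def test_zero_overlap_rejected(self):
        m = _matrix([[1.0]], ["g1"], ["s1"])
        with pytest.raises(ValidationError, match="missing"):
            pathway_score(m, GeneSet("missing", ["other"]))

    def test_simulation_scores_track_truth(self):
        spec = CohortSimSpec(n_samples=300, rho=0.5, baseline_sd=1.0, seed=21)
        m, _, truth = simulate_cohort(spec)
        scores = pathway_score(m, GeneSet("FAO", [f"FAO{i:03d}" for i in range(1, 16)]))
        slope, intercept = np.polyfit(truth["score_fao"], scores["FAO"], 1)
        # slope should match the shared-factor loading sqrt(rho)*sd
        assert slope == pytest.approx(np.sqrt(0.5), abs=0.1)
        resid = scores["FAO"] - (slope * truth["score_fao"] + intercept)
        predicted_sd = np.sqrt((1 - 0.5) / 15)  # averaging over 15 panel genes
        assert resid.std() == pytest.approx(predicted_sd, rel=0.5)


class TestGroupLog2FC:
    def _mouse(self):
        return simulate_mouse_design(MouseSimSpec(seed=31, n_rep=10))

    def test_simple_difference_of_means(self):
        m = _matrix([[4.0, 4.0, 2.0, 2.0]], ["g"], ["a1", "a2", "b1", "b2"])
        ann = pd.DataFrame(
            {"group": ["A", "A", "B", "B"]},
            index=pd.Index(["a1", "a2", "b1", "b2"], name="sample_id"),
        )
        fc = group_log2fc(m, ann, "A", "B")
        assert fc["g"] == pytest.approx(2.0)

    def test_identical_groups_give_zero(self, rng):
        vals = rng.uniform(0, 8, (5, 2))
        m = _matrix(np.hstack([vals, vals]), [f"g{i}" for i in range(5)],
                    ["a1", "a2", "b1", "b2"])
        ann = pd.DataFrame(
            {"group": ["A", "A", "B", "B"]},
            index=pd.Index(["a1", "a2", "b1", "b2"], name="sample_id"),
        )
        np.testing.assert_allclose(group_log2fc(m, ann, "A", "B"), 0.0, atol=1e-12)

    def test_planted_tumor_effect_recovered(self):
        m, ann, truth = self._mouse()
        fc = group_log2fc(m, ann, "tumor_NFD", "liver_NFD")
        dys = truth[truth.category == "dysregulated"]
        err = np.abs(fc[dys.index].to_numpy() - 2.0 * dys["direction"].to_numpy())
        assert (err <= 0.5).mean() >= 0.95

    def test_small_group_rejected(self):
        m = _matrix([[1.0, 2.0]], ["g"], ["a1", "b1"])
        ann = pd.DataFrame(
            {"group": ["A", "B"]}, index=pd.Index(["a1", "b1"], name="sample_id")
        )
        with pytest.raises(ValidationError):
            group_log2fc(m, ann, "A", "B")


class TestHeatmapValues:
    def test_direct_evaluation(self, small_fpkm, fao_panel):
        # sample s1 panel FPKM {1, 3}: mean 2 -> log2(1/2), log2(3/2)
        h = heatmap_values(small_fpkm, fao_panel)
        assert h.values.loc["g1", "s1"] == pytest.approx(-1.0)
        assert h.values.loc["g2", "s1"] == pytest.approx(np.log2(1.5))
        assert h.panel == "FAO"

    def test_equal_genes_give_zero(self):
        m = _matrix(np.full((3, 2), 4.0), ["a", "b", "c"], ["s1", "s2"], scale="fpkm")
        h = heatmap_values(m, GeneSet("p", ["a", "b", "c"]))
        np.testing.assert_allclose(h.values.to_numpy(), 0.0, atol=1e-12)

    def test_per_sample_power_mean_is_one(self, rng):
        m = _matrix(rng.uniform(0.1, 50, (8, 6)), [f"g{i}" for i in range(8)],
                    [f"s{j}" for j in range(6)], scale="fpkm")
        h = heatmap_values(m, GeneSet("p", [f"g{i}" for i in range(8)]))
        means = np.power(2.0, h.values).mean(axis=0)
        np.testing.assert_allclose(means, 1.0, atol=1e-9)

    def test_invariant_to_positive_column_rescaling(self, rng):
        vals = rng.uniform(0.1, 20, (5, 3))
        genes, samples = [f"g{i}" for i in range(5)], ["s1", "s2", "s3"]
        gs = GeneSet("p", genes)
        h0 = heatmap_values(_matrix(vals, genes, samples, "fpkm"), gs)
        scaled = vals * np.array([2.0, 0.5, 17.0])
        h1 = heatmap_values(_matrix(scaled, genes, samples, "fpkm"), gs)
        np.testing.assert_allclose(h0.values.to_numpy(), h1.values.to_numpy(), atol=1e-9)

    def test_zero_panel_mean_suggests_epsilon(self):
        m = _matrix([[0.0], [0.0]], ["g1", "g2"], ["s1"], scale="fpkm")
        with pytest.raises(ValidationError, match="epsilon"):
            heatmap_values(m, GeneSet("p", ["g1", "g2"]))


class TestSumNormalize:
    def test_column_halves(self):
        m = _matrix([[2.0], [2.0]], ["g1", "g2"], ["s1"], scale="fpkm")
        out = per_sample_sum_normalize(m)
        np.testing.assert_allclose(out.values["s1"], [0.5, 0.5])

    def test_idempotent_on_normalized_input(self, rng):
        vals = rng.uniform(0.1, 5, (4, 3))
        vals /= vals.sum(axis=0)
        m = _matrix(vals, [f"g{i}" for i in range(4)], ["a", "b", "c"], scale="fpkm")
        out = per_sample_sum_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), vals, atol=1e-12)

    def test_columns_sum_to_one(self, rng):
        m = _matrix(rng.uniform(0, 30, (10, 5)), [f"g{i}" for i in range(10)],
                    [f"s{j}" for j in range(5)], scale="fpkm")
        out = per_sample_sum_normalize(m)
        np.testing.assert_allclose(out.values.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_rejected(self):
        m = _matrix([[0.0, 1.0], [0.0, 2.0]], ["g1", "g2"], ["s1", "s2"], scale="fpkm")
        with pytest.raises(ValidationError, match="s1"):
            per_sample_sum_normalize(m)

    def test_log_scale_rejected(self, random_log2p1):
        with pytest.raises(ValidationError):
            per_sample_sum_normalize(random_log2p1)
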