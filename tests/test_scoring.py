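import numpy as np
import pandas as pd
import pytest

from crisprsel import (
    CountMatrix,
    ScalingAnchors,
    ScreenQualityError,
    ValidationError,
    classify_genes,
    compute_anchors,
    filter_genes,
    filter_sgrnas,
    gene_score,
    normalize_abundance,
    rank_plot_data,
    scale_scores,
    selective_essentiality,
    sgrna_lfc,
)
from crisprsel.scoring import (
    CATEGORY_ESSENTIAL_BOTH,
    CATEGORY_NEUTRAL,
    CATEGORY_SELECTIVE,
    CATEGORY_SENSITIZING,
)

from conftest import make_annotation


def single_sample_matrix(counts, genes=None):
    idx = pd.Index([f"s{i}" for i in range(len(counts))], name="sgrna")
    df = pd.DataFrame({"initial": counts}, index=idx)
    return CountMatrix(df, {"initial": "initial"})


class TestFilters:
    def test_initial_count_boundary(self, toy_counts):
        kept = filter_sgrnas(toy_counts, min_initial=100).counts
        assert "a1" in kept.index      # initial exactly 100 retained
        assert "b2" not in kept.index  # initial 99 removed
        assert "nt2" not in kept.index  # initial 50 removed

    def test_toy_tally(self, toy_counts):
        # 10 sgRNAs, 2 below the 100-count threshold by construction
        kept = filter_sgrnas(toy_counts, min_initial=100).counts
        assert len(kept) == len(toy_counts.counts) - 2

    def test_three_below_threshold_leaves_seven(self):
        cm = single_sample_matrix([100, 101, 99, 98, 97, 500, 1000, 200, 300, 400])
        assert len(filter_sgrnas(cm, min_initial=100).counts) == 7

    def test_min_initial_zero_is_identity(self, toy_counts):
        kept = filter_sgrnas(toy_counts, min_initial=0).counts
        assert kept.index.equals(toy_counts.counts.index)

    def test_gene_filter_boundary(self, toy_counts, toy_annotation):
        kept = filter_genes(
            filter_sgrnas(toy_counts), toy_annotation, min_sgrnas=6
        ).counts
        # GA keeps its 6 surviving sgRNAs; GB dropped (1 survivor); NT exempt
        assert set(kept.index) == {f"a{i}" for i in range(1, 7)} | {"nt1"}

    def test_gene_filter_never_removes_nontargeting(self, toy_counts, toy_annotation):
        kept = filter_genes(toy_counts, toy_annotation, min_sgrnas=100).counts
        assert set(kept.index) == {"nt1", "nt2"}

    def test_min_sgrnas_one_is_identity_on_targeting(self, toy_counts, toy_annotation):
        kept = filter_genes(toy_counts, toy_annotation, min_sgrnas=1).counts
        assert kept.index.equals(toy_counts.counts.index)

    def test_three_gene_enumeration(self):
        # genes with {6, 6, 4} surviving sgRNAs -> 12 targeting rows retained
        rows, counts = [], []
        for g, n in zip("XYZ", (6, 6, 4)):
            for i in range(n):
                rows.append((f"{g}{i}", g, "targeting", False))
                counts.append(200)
        ann = make_annotation(rows)
        cm = CountMatrix(
            pd.DataFrame({"initial": counts}, index=ann.sgrna_ids),
            {"initial": "initial"},
        )
        kept = filter_genes(cm, ann, min_sgrnas=6).counts
        assert len(kept) == 12


class TestNormalizeAndLfc:
    def test_pseudocount_normalization(self):
        cm = single_sample_matrix([1, 3])
        ab = normalize_abundance(cm)["initial"]
        np.testing.assert_allclose(ab.to_numpy(), [1 / 3, 2 / 3])

    def test_zero_counts_get_pseudocount(self):
        cm = single_sample_matrix([0, 0, 2])
        ab = normalize_abundance(cm)["initial"]
        np.testing.assert_allclose(ab.to_numpy(), [1 / 5, 1 / 5, 3 / 5])

    def test_equal_counts_uniform(self):
        cm = single_sample_matrix([7] * 4)
        np.testing.assert_allclose(normalize_abundance(cm)["initial"], 0.25)

    def test_empty_matrix_rejected(self):
        cm = single_sample_matrix([1])
        with pytest.raises(ValidationError):
            normalize_abundance(cm.restrict([]))

    @pytest.mark.parametrize(
        "a_final,a_init,expected", [(0.1, 0.1, 0.0), (0.4, 0.1, 2.0), (0.1, 0.4, -2.0)]
    )
    def test_lfc_arithmetic(self, a_final, a_init, expected):
        ab = pd.DataFrame({"initial": [a_init], "final": [a_final]})
        assert sgrna_lfc(ab, "final", "initial").iloc[0] == pytest.approx(expected)


class TestGeneScore:
    def ann_one_gene(self, n):
        return make_annotation([(f"g{i}", "G1", "targeting", False) for i in range(n)])

    def test_mean_of_lfcs(self):
        ann = self.ann_one_gene(3)
        lfc = pd.Series([-1.0, -2.0, -3.0], index=ann.sgrna_ids)
        out = gene_score(lfc, ann)
        assert out.loc["G1", "raw"] == pytest.approx(-2.0)
        assert out.loc["G1", "n_sgrnas_used"] == 3

    def test_outlier_sensitivity(self):
        ann = self.ann_one_gene(6)
        lfc = pd.Series([-1.0] * 5 + [5.0], index=ann.sgrna_ids)
        assert gene_score(lfc, ann).loc["G1", "raw"] == pytest.approx(0.0)


class TestAnchorsAndScaling:
    def two_class_lfcs(self, nt_vals, ce_vals):
        rows = [(f"nt{i}", "", "non_targeting", False) for i in range(len(nt_vals))]
        rows += [(f"ce{i}", "CE1", "targeting", True) for i in range(len(ce_vals))]
        ann = make_annotation(rows)
        lfc = pd.Series(list(nt_vals) + list(ce_vals), index=ann.sgrna_ids)
        return lfc, ann

    def test_reference_medians(self):
        lfc, ann = self.two_class_lfcs([0.1, 0.2, 0.3], [-2.0, -1.8, -1.6])
        a = compute_anchors(lfc, ann, min_reference=3)
        assert a.median_nontargeting == pytest.approx(0.2)
        assert a.median_core_essential == pytest.approx(-1.8)

    def test_even_length_median_is_midpoint(self):
        lfc, ann = self.two_class_lfcs([0.0, 1.0, 2.0, 3.0], [-3.0, -1.0])
        a = compute_anchors(lfc, ann, min_reference=2)
        assert a.median_nontargeting == pytest.approx(1.5)
        assert a.median_core_essential == pytest.approx(-2.0)

    def test_equal_anchors_rejected(self):
        with pytest.raises(ScreenQualityError, match="internal"):
            ScalingAnchors(0.5, 0.5)

    def test_too_few_reference_sgrnas(self):
        lfc, ann = self.two_class_lfcs([0.1, 0.2], [-2.0, -1.8, -1.6])
        with pytest.raises(ScreenQualityError, match="non-targeting"):
            compute_anchors(lfc, ann, min_reference=3)

    @pytest.mark.parametrize(
        "raw,expected", [(0.2, 0.0), (-1.8, -1.0), (-0.8, -0.5)]
    )
    def test_affine_map(self, raw, expected):
        anchors = ScalingAnchors(0.2, -1.8)
        assert scale_scores(raw, anchors) == pytest.approx(expected)


class TestSelectiveEssentiality:
    def test_z_of_symmetric_differences(self):
        control = pd.Series([0.0, 0.0, 0.0], index=list("abc"))
        treated = pd.Series([-2.0, 0.0, 2.0], index=list("abc"))
        z = selective_essentiality(treated, control)
        np.testing.assert_allclose(z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_identical_arms_degenerate(self):
        s = pd.Series([0.5, -0.3, 0.1], index=list("abc"))
        with pytest.raises(ScreenQualityError, match="degenerate"):
            selective_essentiality(s, s)

    def test_mismatched_gene_sets_rejected(self):
        a = pd.Series([0.0, 1.0], index=["g1", "g2"])
        b = pd.Series([0.0, 1.0], index=["g1", "g3"])
        with pytest.raises(ValidationError):
            selective_essentiality(a, b)

    def test_robust_variant_resists_outliers(self):
        rng = np.random.default_rng(0)
        control = pd.Series(np.zeros(101), index=[f"g{i}" for i in range(101)])
        treated = pd.Series(rng.normal(0, 0.1, 101), index=control.index)
        treated.iloc[0] = -50.0
        z = selective_essentiality(treated, control, robust=True)
        # the bulk keeps unit-scale spread instead of being crushed by the outlier
        assert z.iloc[1:].abs().max() > 1.0


class TestClassifyAndRank:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "scaled_control", "scaled_treated", "selective_z"]
        )

    def test_essential_both_takes_precedence(self):
        gt = self.frame([("g", -1.2, -1.1, -5.0)])
        assert classify_genes(gt).iloc[0] == CATEGORY_ESSENTIAL_BOTH

    def test_selective_and_sensitizing_tails(self):
        gt = self.frame([("g1", 0.0, -1.5, -3.0), ("g2", 0.0, 1.0, 3.0),
                         ("g3", 0.0, 0.1, 0.5)])
        cats = classify_genes(gt)
        assert list(cats) == [
            CATEGORY_SELECTIVE, CATEGORY_SENSITIZING, CATEGORY_NEUTRAL
        ]

    def test_rank_plot_orders_and_conserves(self):
        gt = self.frame(
            [("b", 0, 0, 1.0), ("a", 0, 0, -1.0), ("c", 0, 0, 0.0), ("d", 0, 0, 0.0)]
        )
        gt["category"] = CATEGORY_NEUTRAL
        rp = rank_plot_data(gt)
        assert len(rp) == 4
        assert list(rp["rank"]) == [1, 2, 3, 4]
        assert list(rp["gene"]) == ["a", "c", "d", "b"]  # tie c/d broken by gene id
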