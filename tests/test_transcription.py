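import numpy as np
import pandas as pd
import pytest

from usprok import transcription as tx


class TestModifiedTpm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [
            (1, 1000, 1_000_000, 1.0),
            (10, 500, 2_000_000, 10.0),
            (0, 750, 5_000_000, 0.0),
        ],
    )
    def test_formula(self, count, length, lib, expected):
        assert tx.modified_tpm(count, length, lib) == pytest.approx(expected, rel=1e-12)

    def test_zero_length_or_library_rejected(self):
        with pytest.raises(ValueError):
            tx.modified_tpm(1, 0, 1000)
        with pytest.raises(ValueError):
            tx.modified_tpm(1, 1000, 0)

    def test_linear_in_count_and_inverse_in_library(self, rng):
        c = rng.integers(1, 100)
        base = tx.modified_tpm(c, 900, 2_000_000)
        assert tx.modified_tpm(3 * c, 900, 2_000_000) == pytest.approx(3 * base)
        assert tx.modified_tpm(c, 900, 4_000_000) == pytest.approx(base / 2)

    def test_sum_identity_for_kb_genes(self, rng):
        """With every gene exactly 1000 bp, total tpm = 1e6 * mapped/library."""
        counts = pd.DataFrame(rng.integers(0, 50, (20, 3)), columns=list("abc"))
        lengths = pd.Series(1000, index=counts.index)
        libs = pd.Series([1e6, 2e6, 5e5], index=list("abc"))
        m = tx.modified_tpm_matrix(counts, lengths, libs)
        expected = 1e6 * counts.sum(axis=0) / libs
        assert np.allclose(m.sum(axis=0), expected, rtol=1e-12)

    def test_matrix_uses_column_library(self):
        counts = pd.DataFrame({"a": [1], "b": [1]}, index=["g1"])
        m = tx.modified_tpm_matrix(
            counts, pd.Series({"g1": 1000}), pd.Series({"a": 1e6, "b": 2e6})
        )
        assert m.at["g1", "a"] == pytest.approx(1.0)
        assert m.at["g1", "b"] == pytest.approx(0.5)


@pytest.fixture
def two_mag_setup():
    tpm = pd.DataFrame(
        {"s1": [4.0, 2.0, 6.0], "s2": [1.0, 1.0, 2.0]},
        index=["m1_g1", "m1_g2", "m2_g1"],
    )
    genes = pd.DataFrame(
        {"mag_id": ["m1", "m1", "m2"], "cog_category": ["E", None, "B"],
         "gene_name": [None, "cspA", "recA"]},
        index=tpm.index,
    )
    mags = pd.DataFrame(
        {"estimated_size": [1e6, 2e6]}, index=["m1", "m2"]
    )
    return tpm, genes, mags


class TestMagExpression:
    def test_single_mag_owns_all(self):
        tpm = pd.DataFrame({"s": [1.0, 2.0]}, index=["m_g1", "m_g2"])
        genes = pd.DataFrame({"mag_id": ["m", "m"]}, index=tpm.index)
        res = tx.mag_expression(tpm, genes)
        assert res.share.at["m", "s"] == pytest.approx(1.0)

    def test_size_normalized_shares(self, two_mag_setup):
        tpm, genes, mags = two_mag_setup
        res = tx.mag_expression(tpm, genes, mags, normalize_by_genome_size=True)
        # equal totals (6 each in s1), sizes 1 and 2 Mbp -> shares 2/3 vs 1/3
        assert res.share.at["m1", "s1"] == pytest.approx(2 / 3)
        assert res.share.at["m2", "s1"] == pytest.approx(1 / 3)

    def test_zero_expression_mag_flagged(self):
        tpm = pd.DataFrame({"s": [1.0, 0.0]}, index=["a_g1", "alti_g1"])
        genes = pd.DataFrame({"mag_id": ["a", "alti"]}, index=tpm.index)
        res = tx.mag_expression(tpm, genes)
        assert res.not_detected == ["alti"]
        assert res.share.at["alti", "s"] == 0.0

    def test_orphan_genes_excluded(self):
        tpm = pd.DataFrame({"s": [1.0, 5.0]}, index=["a_g1", "mystery"])
        genes = pd.DataFrame({"mag_id": ["a"]}, index=["a_g1"])
        res = tx.mag_expression(tpm, genes)
        assert res.orphan_genes == ["mystery"]
        assert res.total.at["a", "s"] == pytest.approx(1.0)


class TestCategoryProportions:
    def test_equal_means_give_fifty_fifty(self):
        tpm = pd.DataFrame({"o1": [2.0], "o2": [4.0], "d1": [3.0], "d2": [3.0]},
                           index=["g1"])
        genes = pd.DataFrame({"cog_category": ["E"]}, index=["g1"])
        labels = {"o1": "oxic", "o2": "oxic", "d1": "dysoxic", "d2": "dysoxic"}
        props = tx.category_condition_proportion(tpm, genes, labels)
        assert props.at["E", "pct_oxic"] == pytest.approx(50.0)

    def test_pairs_sum_to_hundred(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 10, (30, 4)),
                           columns=["o1", "o2", "d1", "d2"])
        genes = pd.DataFrame(
            {"cog_category": rng.choice(["E", "T", "B"], 30)}, index=tpm.index
        )
        labels = {"o1": "oxic", "o2": "oxic", "d1": "dysoxic", "d2": "dysoxic"}
        props = tx.category_condition_proportion(tpm, genes, labels)
        assert np.allclose(props["pct_oxic"] + props["pct_dysoxic"], 100.0)

    def test_invariant_to_sample_order_within_condition(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 10, (10, 4)),
                           columns=["o1", "o2", "d1", "d2"])
        genes = pd.DataFrame({"cog_category": ["E"] * 10}, index=tpm.index)
        labels = {"o1": "oxic", "o2": "oxic", "d1": "dysoxic", "d2": "dysoxic"}
        swapped = {"o2": "oxic", "o1": "oxic", "d2": "dysoxic", "d1": "dysoxic"}
        a = tx.category_condition_proportion(tpm, genes, labels)
        b = tx.category_condition_proportion(tpm, genes, swapped)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_condition_rejected(self):
        tpm = pd.DataFrame({"o1": [1.0]}, index=["g"])
        genes = pd.DataFrame({"cog_category": ["E"]}, index=["g"])
        with pytest.raises(ValueError):
            tx.category_condition_proportion(tpm, genes, {"o1": "oxic"})


class TestExclusiveDetection:
    def test_constructed_split(self):
        labels = {"o1": "oxic", "d1": "dysoxic", "d2": "dysoxic"}
        tpm = pd.DataFrame(
            {
                "o1": [1, 1, 0, 0, 0, 2, 0, 1, 3, 0],
                "d1": [0, 1, 2, 0, 0, 0, 1, 1, 0, 0],
                "d2": [0, 0, 1, 1, 0, 0, 0, 0, 0, 0],
            },
            index=[f"g{i}" for i in range(10)],
        )
        res = tx.exclusive_detection(tpm, labels)
        assert set(res.exclusive_a) == {"g0", "g5", "g8"}
        assert set(res.exclusive_b) == {"g2", "g3", "g6"}
        assert set(res.shared) == {"g1", "g7"}
        assert res.n_expressed == 8
        assert res.pct_exclusive_a == pytest.approx(100 * 3 / 8)

    def test_all_zero_feature_in_no_set(self):
        labels = {"o1": "oxic", "d1": "dysoxic"}
        tpm = pd.DataFrame({"o1": [0.0], "d1": [0.0]}, index=["g"])
        res = tx.exclusive_detection(tpm, labels)
        assert res.n_expressed == 0 and len(res.shared) == 0


class TestFoldChange:
    def test_ratio_values(self):
        labels = {"o1": "oxic", "o2": "oxic", "d1": "dysoxic", "d2": "dysoxic"}
        totals = pd.DataFrame(
            {"o1": [4.0, 1.0, 1.0, 0.0], "o2": [4.0, 1.0, 1.0, 0.0],
             "d1": [1.0, 1.0, 0.0, 0.0], "d2": [1.0, 1.0, 0.0, 0.0]},
            index=["up", "flat", "oxic_only", "silent"],
        )
        fc = tx.condition_fold_change(totals, labels)
        assert fc["up"] == pytest.approx(4.0)
        assert fc["flat"] == pytest.approx(1.0)
        assert np.isinf(fc["oxic_only"])
        assert "silent" not in fc.index


class TestZScore:
    def test_row_scaling_hand_value(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]])
        out = tx.zscore_scale(m, "row")
        assert out.iloc[0].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_zeroed(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        out = tx.zscore_scale(m, "row")
        assert out.iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_scaled_rows_standardized(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 8)))
        out = tx.zscore_scale(m, "row")
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_row_then_column_order(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 8)))
        manual = tx.zscore_scale(tx.zscore_scale(m, "row"), "column")
        pd.testing.assert_frame_equal(tx.zscore_scale(m, "row-then-column"), manual)


class TestAnnotatedFraction:
    def test_extremes(self):
        tpm = pd.DataFrame({"s": [1.0, 3.0]}, index=["g1", "g2"])
        annotated = pd.DataFrame({"mag_id": ["m", "m"], "cog_category": ["E", "T"]},
                                 index=tpm.index)
        none_at_all = pd.DataFrame({"mag_id": ["m", "m"],
                                    "cog_category": [None, None]}, index=tpm.index)
        assert tx.annotated_fraction(tpm, annotated).at["all", "s"] == pytest.approx(0.0)
        assert tx.annotated_fraction(tpm, none_at_all).at["all", "s"] == pytest.approx(100.0)

    def test_half_mass_and_group_split(self):
        tpm = pd.DataFrame({"s": [2.0, 2.0, 5.0]}, index=["g1", "g2", "g3"])
        genes = pd.DataFrame(
            {"mag_id": ["us1", "us1", "bg1"], "cog_category": ["E", None, None]},
            index=tpm.index,
        )
        out = tx.annotated_fraction(tpm, genes, ultrasmall_mags=["us1"])
        assert out.at["ultra-small", "s"] == pytest.approx(50.0)
        assert out.at["other", "s"] == pytest.approx(100.0)


class TestTopExpressed:
    def test_fixture_order_and_ties(self):
        tpm = pd.DataFrame(
            {"s1": [5.0, 3.0, 3.0, 1.0, 10.0]},
            index=["gB", "gC", "gA", "gD", "gE"],
        )
        genes = pd.DataFrame(
            {"mag_id": ["m"] * 5,
             "gene_name": ["nifH", None, "cspA", "recA", "rpoB"]},
            index=tpm.index,
        )
        top = tx.top_expressed(tpm, genes, k=4)
        # ties (gA, gC at 3.0) broken lexicographically
        assert list(top.index) == ["gE", "gB", "gA", "gC"]
        named = tx.top_expressed(tpm, genes, k=10, named_only=True)
        assert list(named.index) == ["gE", "gB", "gA", "gD"]
        assert bool(named.at["gA", "preservation_artifact"]) is True
        assert bool(named.at["gE", "preservation_artifact"]) is False

    def test_k_larger_than_gene_count(self):
        tpm = pd.DataFrame({"s1": [1.0]}, index=["g"])
        genes = pd.DataFrame({"mag_id": ["m"], "gene_name": [None]}, index=["g"])
        assert len(tx.top_expressed(tpm, genes, k=10)) == 1
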