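"""Relative quantification, I/O and design-matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sigselect as ss
from sigselect.expression import write_expression_csv


def _ct_table(ct_values, genes, samples, hk="HK", calibrator=None):
    df = pd.DataFrame(ct_values, index=genes, columns=samples)
    return ss.CtTable(ct=df, housekeeping_gene=hk, calibrator=calibrator)


class TestRelativeExpression:
    def test_forced_arithmetic(self):
        # Ct(g,s)=25, Ct(hk,s)=20, calibrator dCt(g)=3 -> ddCt=2 -> 0.25
        t = _ct_table(
            [[25.0], [20.0]], ["g", "HK"], ["s1"],
            calibrator=pd.Series({"g": 3.0}),
        )
        em = ss.compute_relative_expression(t)
        assert em.values.loc["g", "s1"] == pytest.approx(0.25)
        assert "HK" not in em.gene_ids

    def test_sample_matching_calibrator_gives_unity(self):
        rng = np.random.default_rng(0)
        ct = rng.uniform(20, 35, size=(3, 2))
        ct = np.vstack([ct, [[22.0, 22.0]]])  # housekeeping row
        t = _ct_table(ct, ["g1", "g2", "g3", "HK"], ["cal", "s"], calibrator="cal")
        em = ss.compute_relative_expression(t)
        np.testing.assert_allclose(em.values["cal"], 1.0)

    def test_matches_hand_computed_table(self):
        # independent spreadsheet-style recomputation on a 4-gene x 3-sample table
        rng = np.random.default_rng(3)
        genes = ["g1", "g2", "g3", "HK"]
        samples = ["s1", "s2", "s3"]
        ct = rng.uniform(18, 34, size=(4, 3))
        cal = pd.Series({"g1": 1.5, "g2": -0.5, "g3": 4.0})
        expected = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                dct = ct[i, j] - ct[3, j]
                ddct = dct - cal.iloc[i]
                expected[i, j] = 2.0 ** (-ddct)
        em = ss.compute_relative_expression(
            _ct_table(ct, genes, samples, calibrator=cal)
        )
        np.testing.assert_allclose(em.values.to_numpy(), expected, rtol=1e-12)

    def test_missing_ct_propagates(self):
        ct = [[25.0, np.nan], [20.0, 20.0]]
        t = _ct_table(ct, ["g", "HK"], ["s1", "s2"], calibrator=pd.Series({"g": 0.0}))
        em = ss.compute_relative_expression(t)
        assert np.isnan(em.values.loc["g", "s2"])
        assert np.isfinite(em.values.loc["g", "s1"])

    def test_missing_housekeeping_named_in_error(self):
        df = pd.DataFrame([[25.0]], index=["g"], columns=["s1"])
        with pytest.raises(ValueError, match="GUSB"):
            ss.CtTable(ct=df, housekeeping_gene="GUSB", calibrator="s1")

    def test_absent_calibrator_sample_rejected(self):
        with pytest.raises(ValueError, match="calibrator"):
            _ct_table([[25.0], [20.0]], ["g", "HK"], ["s1"], calibrator="nope")

    @given(shift=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_per_sample_ct_shift(self, shift):
        # adding a constant to every Ct of a sample cancels via housekeeping
        rng = np.random.default_rng(11)
        ct = rng.uniform(20, 32, size=(3, 2))
        cal = pd.Series({"g1": 1.0, "g2": 2.0})
        base = ss.compute_relative_expression(
            _ct_table(ct, ["g1", "g2", "HK"], ["s1", "s2"], calibrator=cal)
        )
        shifted = ct.copy()
        shifted[:, 0] += shift
        moved = ss.compute_relative_expression(
            _ct_table(shifted, ["g1", "g2", "HK"], ["s1", "s2"], calibrator=cal)
        )
        np.testing.assert_allclose(
            moved.values.to_numpy(), base.values.to_numpy(), rtol=1e-9
        )


class TestReadWrite:
    def test_well_formed_roundtrip(self, tmp_path, small_em):
        p = tmp_path / "m.csv"
        ann = tmp_path / "a.csv"
        write_expression_csv(small_em, p, ann)
        back = ss.read_expression_csv(p, annotation_path=ann)
        assert back.values.shape == (4, 6)
        np.testing.assert_array_equal(
            back.values.to_numpy(), small_em.values.to_numpy()
        )
        assert list(back.class_labels) == list(small_em.class_labels)

    def test_duplicated_gene_row_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,s1\ng1,1.0\ng1,2.0\n")
        with pytest.raises(ValueError, match="duplicated"):
            ss.read_expression_csv(p)

    def test_na_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,s1,s2\ng1,NA,2.0\n")
        em = ss.read_expression_csv(p)
        assert np.isnan(em.values.loc["g1", "s1"])
        assert em.values.loc["g1", "s2"] == 2.0

    def test_unlabeled_samples_listed_in_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("gene,s1,s2\ng1,1.0,2.0\n")
        ann = tmp_path / "a.csv"
        ann.write_text("sample_id,class\ns1,A\n")
        with pytest.raises(ValueError, match="s2"):
            ss.read_expression_csv(p, annotation_path=ann)


class TestDesignMatrix:
    def test_shapes_and_label_mapping(self, small_em):
        dm = ss.build_design_matrix(small_em, ("A", "B"))
        assert dm.X.shape == (6, 4)
        assert np.sum(dm.Y == -1) == 3 and np.sum(dm.Y == 1) == 3
        assert dm.class_map == {"A": -1, "B": 1}

    def test_empty_class_rejected(self, small_em):
        with pytest.raises(ValueError, match="no samples"):
            ss.build_design_matrix(small_em, ("A", "Z"))

    def test_constant_gene_flagged_and_zeroed(self, small_em):
        em = ss.ExpressionMatrix(
            values=small_em.values.copy(), class_labels=small_em.class_labels
        )
        em.values.loc["GA"] = 2.0
        dm = ss.build_design_matrix(em, ("A", "B"))
        j = dm.gene_ids.index("GA")
        assert "GA" in dm.zero_variance_genes
        np.testing.assert_allclose(dm.X[:, j], 0.0)

    def test_standardization_round_trip(self, small_em):
        dm = ss.build_design_matrix(small_em, ("A", "B"))
        transformed = np.log2(
            small_em.values[dm.sample_ids].to_numpy().T + dm.pseudocount
        )
        recovered = dm.X * dm.scale + dm.center
        np.testing.assert_allclose(recovered, transformed, atol=1e-12)

    def test_fit_samples_statistics_exclude_test_rows(self, small_em):
        fit = ["s0", "s1", "s3", "s4"]
        dm = ss.build_design_matrix(small_em, ("A", "B"), fit_samples=fit)
        rows = dm.rows(fit)
        np.testing.assert_allclose(dm.X[rows].mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(dm.X[rows].std(axis=0, ddof=1), 1.0, atol=1e-10)
        held_out = dm.X[dm.rows(["s2", "s5"])]
        assert not np.allclose(held_out.mean(axis=0), 0.0)

    def test_high_missingness_gene_dropped_and_rest_imputed(self, small_em):
        vals = small_em.values.copy()
        vals.loc["GA", ["s0", "s1"]] = np.nan  # 2/6 = 33% missing
        vals.loc["GB", "s0"] = np.nan  # 17%: kept, imputed
        em = ss.ExpressionMatrix(values=vals, class_labels=small_em.class_labels)
        dm = ss.build_design_matrix(em, ("A", "B"), max_missing_frac=0.2)
        assert "GA" not in dm.gene_ids
        assert np.isfinite(dm.X).all()


class TestHeatmapScaling:
    def test_row_scaled_to_unit_sample_sd(self):
        em = ss.ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                                columns=["a", "b", "c"])
        )
        scaled = ss.scale_for_heatmap(em)
        assert scaled.loc["g"].mean() == pytest.approx(0.0, abs=1e-12)
        assert scaled.loc["g"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_row_all_zeros_and_rows_centered(self, small_em):
        em = ss.ExpressionMatrix(
            values=small_em.values.copy(), class_labels=small_em.class_labels
        )
        em.values.loc["GA"] = 5.0
        scaled = ss.scale_for_heatmap(em)
        np.testing.assert_allclose(scaled.loc["GA"], 0.0)
        np.testing.assert_allclose(scaled.mean(axis=1), 0.0, atol=1e-12)

    def test_columns_grouped_by_class(self, small_em):
        scaled = ss.scale_for_heatmap(small_em, class_order=["B", "A"])
        assert list(scaled.columns) == ["s3", "s4", "s5", "s0", "s1", "s2"]

    def test_export_writes_sidecar(self, tmp_path, small_em):
        ss.export_heatmap(small_em, tmp_path / "h.tsv", tmp_path / "h.json")
        import json
        meta = json.loads((tmp_path / "h.json").read_text())
        assert meta["row_order"] == small_em.gene_ids
        assert set(meta["col_order"]) == set(small_em.sample_ids)
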