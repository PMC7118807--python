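import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netmods.coexpr import (
    EdgeWeightTable,
    ExpressionMatrix,
    collapse_probes,
    differential_expression,
    edge_weight,
    fisher_z_difference,
    read_expression,
)
from netmods.network import PPINetwork


def _mat(values: dict[str, list[float]], n_case: int, n_control: int) -> ExpressionMatrix:
    samples = [f"CASE{i}" for i in range(n_case)] + [f"CTRL{i}" for i in range(n_control)]
    condition = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=samples).T, condition=condition
    )


class TestExpressionMatrix:
    def test_sample_without_label_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="condition"):
            ExpressionMatrix(values=values, condition=pd.Series({"S1": "case"}))

    def test_unknown_label_rejected(self):
        values = pd.DataFrame([[1.0]], index=["G1"], columns=["S1"])
        with pytest.raises(ValueError, match="label"):
            ExpressionMatrix(values=values, condition=pd.Series({"S1": "tumour"}))

    def test_duplicate_genes_rejected(self):
        values = pd.DataFrame([[1.0], [2.0]], index=["G1", "G1"], columns=["S1"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(values=values, condition=pd.Series({"S1": "case"}))

    def test_scale_check_warns_on_unnormalized_input(self):
        mat = _mat({"G1": [1, 1, 1, 1, 9, 9, 9, 9], "G2": [1, 1, 1, 1, 9, 9, 9, 9]}, 4, 4)
        with pytest.warns(UserWarning, match="normalized"):
            assert not mat.check_scale()

    def test_tsv_roundtrip(self, tmp_path):
        mat = _mat({"G1": [1.0, 2.0, 3.0, 4.0], "G2": [0.5, 0.5, 0.5, 1.5]}, 2, 2)
        mat.to_tsv(tmp_path / "expr.tsv", tmp_path / "cond.tsv")
        back = read_expression(tmp_path / "expr.tsv", tmp_path / "cond.tsv")
        pd.testing.assert_frame_equal(back.values, mat.values)
        pd.testing.assert_series_equal(
            back.condition, mat.condition, check_names=False
        )


class TestCollapseProbes:
    def test_probe_mean_per_gene(self):
        df = pd.DataFrame({"S0": [2.0, 4.0], "S1": [1.0, 3.0]}, index=["p1", "p2"])
        cond = pd.Series({"S0": "case", "S1": "control"})
        mat = collapse_probes(df, {"p1": "G1", "p2": "G1"}, cond)
        assert mat.values.loc["G1"].tolist() == [3.0, 2.0]

    def test_single_probe_identity_and_three_probe_mean(self):
        df = pd.DataFrame(
            {"S0": [1.0, 2.0, 6.0, 5.0], "S1": [1.0, 2.0, 6.0, 5.0]},
            index=["a1", "a2", "a3", "b1"],
        )
        cond = pd.Series({"S0": "case", "S1": "control"})
        mat = collapse_probes(df, {"a1": "GA", "a2": "GA", "a3": "GA", "b1": "GB"}, cond)
        assert mat.values.loc["GA"].tolist() == [3.0, 3.0]
        assert mat.values.loc["GB"].tolist() == [5.0, 5.0]

    def test_unmapped_probes_dropped_with_warning(self):
        df = pd.DataFrame({"S0": [1.0, 2.0], "S1": [1.0, 2.0]}, index=["p1", "px"])
        cond = pd.Series({"S0": "case", "S1": "control"})
        with pytest.warns(UserWarning, match="1 unmapped"):
            mat = collapse_probes(df, {"p1": "G1"}, cond)
        assert mat.genes == ["G1"]

    def test_nothing_mapped_rejected(self):
        df = pd.DataFrame({"S0": [1.0]}, index=["p1"])
        with pytest.raises(ValueError):
            collapse_probes(df, {}, pd.Series({"S0": "case"}))

    def test_column_count_and_group_means_preserved(self):
        rng = np.random.default_rng(2)
        probes = [f"p{i}" for i in range(12)]
        gene_of = {p: f"G{i % 4}" for i, p in enumerate(probes)}
        df = pd.DataFrame(
            rng.normal(size=(12, 6)), index=probes, columns=[f"S{i}" for i in range(6)]
        )
        cond = pd.Series(["case"] * 3 + ["control"] * 3, index=df.columns)
        mat = collapse_probes(df, gene_of, cond)
        assert mat.values.shape == (4, 6)
        for g in mat.genes:
            members = [p for p in probes if gene_of[p] == g]
            np.testing.assert_allclose(
                mat.values.loc[g].to_numpy(), df.loc[members].mean(axis=0).to_numpy()
            )


class TestDifferentialExpression:
    def test_equal_means_give_zero_log2fc(self):
        mat = _mat({"G1": [1, 2, 1, 2, 1, 2, 1, 2]}, 4, 4)
        de = differential_expression(mat)
        assert de.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_two_fold_flag_is_strict(self):
        # exactly +1 on the log2 scale: flag must stay False
        mat = _mat({"G1": [3, 3, 3, 3, 2, 2, 2, 2], "G2": [1.1, 2, 3, 1, 2, 1, 3, 1.2]}, 4, 4)
        de = differential_expression(mat).set_index("gene")
        assert de.loc["G1", "log2fc"] == pytest.approx(1.0)
        assert not bool(de.loc["G1", "two_fold"])

    def test_clear_two_fold_change(self):
        mat = _mat({"G1": [5, 5, 5, 5, 3, 3, 3, 3], "G2": [1, 2, 1, 2, 1, 2, 1, 2]}, 4, 4)
        de = differential_expression(mat).set_index("gene")
        assert de.loc["G1", "log2fc"] == pytest.approx(2.0)
        assert bool(de.loc["G1", "two_fold"])

    def test_welch_pvalue_matches_direct_computation(self):
        rng = np.random.default_rng(0)
        case, ctrl = rng.normal(1, 1, 7), rng.normal(0, 2, 6)
        mat = _mat({"G1": list(case) + list(ctrl)}, 7, 6)
        de = differential_expression(mat)
        expected = stats.ttest_ind(case, ctrl, equal_var=False).pvalue
        assert de.loc[0, "p"] == pytest.approx(expected, rel=1e-12)

    def test_too_few_samples_rejected(self):
        mat = _mat({"G1": [1.0, 2.0, 3.0]}, 1, 2)
        with pytest.raises(ValueError, match="case"):
            differential_expression(mat)


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        assert fisher_z_difference(0.7, 0.7, 7, 6) == pytest.approx(0.0)

    def test_worked_example(self):
        # atanh(0.9) = 1.47222 twice, se = sqrt(1/4 + 1/3)
        z = fisher_z_difference(0.9, -0.9, 7, 6)
        assert z == pytest.approx(3.855, abs=1e-3)

    def test_antisymmetric_under_label_swap(self):
        a = fisher_z_difference(0.8, 0.1, 8, 9)
        b = fisher_z_difference(0.1, 0.8, 9, 8)
        assert a == pytest.approx(-b, abs=1e-12)

    def test_perfect_correlation_stays_finite(self):
        assert np.isfinite(fisher_z_difference(1.0, -1.0, 7, 6))

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(ValueError):
            fisher_z_difference(0.5, 0.5, 3, 6)


class TestEdgeWeight:
    def _random_mat(self, genes, n_case=7, n_control=6, seed=0):
        rng = np.random.default_rng(seed)
        return _mat(
            {g: list(rng.normal(size=n_case + n_control)) for g in genes},
            n_case,
            n_control,
        )

    def test_weights_are_nonnegative_with_zero_minimum(self):
        net = PPINetwork.from_edges(
            [("G0", "G1"), ("G1", "G2"), ("G2", "G3"), ("G3", "G0"), ("G0", "G2")]
        )
        mat = self._random_mat([f"G{i}" for i in range(4)])
        ew = edge_weight(mat, net)
        assert len(ew) == 5
        assert (ew.df["w"] >= 0).all()
        assert ew.df["w"].min() == pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(ew.df["z_raw"]).all()

    def test_correlations_match_numpy_oracle(self):
        net = PPINetwork.from_edges([("G0", "G1")])
        mat = self._random_mat(["G0", "G1"], seed=3)
        ew = edge_weight(mat, net)
        case = mat.submatrix("case")
        expected = np.corrcoef(case.loc["G0"], case.loc["G1"])[0, 1]
        assert ew.df.loc[0, "r_case"] == pytest.approx(expected, rel=1e-12)

    def test_label_swap_negates_z_raw(self):
        net = PPINetwork.from_edges([("G0", "G1"), ("G1", "G2")])
        mat = self._random_mat(["G0", "G1", "G2"], n_case=6, n_control=6, seed=4)
        swapped = ExpressionMatrix(
            values=mat.values.copy(),
            condition=mat.condition.map({"case": "control", "control": "case"}),
        )
        a = edge_weight(mat, net)
        b = edge_weight(swapped, net)
        np.testing.assert_allclose(a.df["z_raw"], -b.df["z_raw"], atol=1e-12)
        np.testing.assert_allclose(a.df["w"], b.df["w"], atol=1e-12)

    def test_zero_variance_gene_drops_its_edges(self):
        net = PPINetwork.from_edges([("G0", "G1"), ("G1", "G2")])
        mat = self._random_mat(["G0", "G1", "G2"])
        mat.values.loc["G0"] = 1.0  # flat profile
        with pytest.warns(UserWarning, match="zero-variance"):
            ew = edge_weight(mat, net)
        assert set(zip(ew.df["gene_a"], ew.df["gene_b"])) == {("G1", "G2")}

    def test_small_groups_rejected(self):
        net = PPINetwork.from_edges([("G0", "G1")])
        mat = self._random_mat(["G0", "G1"], n_case=3, n_control=6)
        with pytest.raises(ValueError, match=">= 4"):
            edge_weight(mat, net)

    def test_permuted_labels_give_near_zero_mean_z(self):
        """Null data: relabelling samples should not create systematic signal."""
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(12)]
        net = PPINetwork.from_edges(
            [(genes[i], genes[(i + 1) % 12]) for i in range(12)]
        )
        base = rng.normal(size=(12, 13))
        labels = np.array(["case"] * 7 + ["control"] * 6)
        zs = []
        for _ in range(200):
            perm = rng.permutation(13)
            cond = pd.Series(labels, index=[f"S{i}" for i in range(13)])
            values = pd.DataFrame(
                base[:, perm], index=genes, columns=[f"S{i}" for i in range(13)]
            )
            ew = edge_weight(ExpressionMatrix(values=values, condition=cond), net)
            zs.append(ew.df["z_raw"].to_numpy())
        assert abs(np.concatenate(zs).mean()) < 0.1

    def test_tsv_roundtrip(self, tmp_path):
        net = PPINetwork.from_edges([("G0", "G1")])
        ew = edge_weight(self._random_mat(["G0", "G1"]), net)
        ew.to_tsv(tmp_path / "ew.tsv")
        back = EdgeWeightTable.from_tsv(tmp_path / "ew.tsv")
        pd.testing.assert_frame_equal(back.df, ew.df)
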