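"""Filtering, DEG detection, gDNA-correlation screening, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gdnacontam.deg_analysis import (
    add_offset_and_filter,
    classify_degs,
    correlate_with_gdna,
    detect_degs,
)
from gdnacontam.expression import ExpressionMatrix, MatrixStateError


def _matrix(values: dict, offset_applied=False, **kw) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=pd.DataFrame(values), offset_applied=offset_applied, **kw
    )


class TestOffsetAndFilter:
    def test_gene_low_in_40_percent_of_libraries_removed(self):
        libs = {f"l{i}": [0.01 if i < 4 else 1.0, 5.0] for i in range(10)}
        matrix = ExpressionMatrix(
            values=pd.DataFrame(libs, index=["low", "high"])
        )
        filtered, removed = add_offset_and_filter(matrix)
        assert removed == ["low"]
        assert filtered.gene_ids == ["high"]
        assert filtered.values.loc["high", "l0"] == pytest.approx(5.01)

    def test_nothing_removed_when_all_expressed(self):
        matrix = _matrix({"l1": [0.02, 1.0], "l2": [0.5, 2.0], "l3": [1.0, 3.0]})
        filtered, removed = add_offset_and_filter(matrix)
        assert removed == [] and len(filtered.gene_ids) == 2

    def test_random_matrix_matches_enumeration_oracle(self, rng):
        values = pd.DataFrame(
            rng.uniform(0, 0.05, size=(50, 12)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"l{i}" for i in range(12)],
        )
        _, removed = add_offset_and_filter(ExpressionMatrix(values=values))
        expected = [
            g
            for g in values.index
            if (values.loc[g] < 0.02).sum() / 12 >= 0.30
        ]
        assert removed == expected

    def test_double_offset_refused(self):
        matrix = _matrix({"l1": [1.0]}, offset_applied=True)
        with pytest.raises(MatrixStateError):
            add_offset_and_filter(matrix)


class TestDetectDegs:
    def test_identical_groups_give_no_degs(self, rng):
        base = rng.uniform(0.1, 10, size=20)
        values = {f"t{i}": base for i in range(3)} | {f"c{i}": base for i in range(3)}
        matrix = ExpressionMatrix(
            values=pd.DataFrame(values, index=[f"g{i}" for i in range(20)]),
            offset_applied=True,
            offset=0.01,
        )
        degs = detect_degs(matrix, ["t0", "t1", "t2"], ["c0", "c1", "c2"])
        assert not degs["is_deg"].any()
        assert (degs["p_value"] == 1.0).all()

    def test_exact_twofold_change_is_not_a_deg(self):
        """|log2 FC| must strictly exceed 1: an exact doubling is excluded."""
        matrix = _matrix(
            {"t1": [1.9], "t2": [2.1], "c1": [0.9], "c2": [1.1]},
            offset_applied=True,
        )
        degs = detect_degs(matrix, ["t1", "t2"], ["c1", "c2"])
        assert degs["log2_fold_change"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert not degs["is_deg"].iloc[0]

    def test_pvalues_match_textbook_pooled_t_oracle(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            t_vals = rng.uniform(0.5, 20, size=(10, n1))
            c_vals = rng.uniform(0.5, 20, size=(10, n2))
            values = pd.DataFrame(
                np.hstack([t_vals, c_vals]),
                index=[f"g{i}" for i in range(10)],
                columns=[f"t{i}" for i in range(n1)] + [f"c{i}" for i in range(n2)],
            )
            matrix = ExpressionMatrix(values=values, offset_applied=True)
            degs = detect_degs(
                matrix, [f"t{i}" for i in range(n1)], [f"c{i}" for i in range(n2)]
            )
            lt, lc = np.log2(t_vals), np.log2(c_vals)
            sp2 = (
                (n1 - 1) * lt.var(axis=1, ddof=1) + (n2 - 1) * lc.var(axis=1, ddof=1)
            ) / (n1 + n2 - 2)
            t_stat = (lt.mean(axis=1) - lc.mean(axis=1)) / np.sqrt(
                sp2 * (1 / n1 + 1 / n2)
            )
            p_oracle = 2 * stats.t.sf(np.abs(t_stat), n1 + n2 - 2)
            np.testing.assert_allclose(degs["p_value"], p_oracle, rtol=0, atol=1e-10)

    def test_group_swap_negates_fold_change_preserves_p(self, rng):
        values = pd.DataFrame(
            rng.uniform(0.5, 10, size=(15, 6)),
            index=[f"g{i}" for i in range(15)],
            columns=list("abcdef"),
        )
        matrix = ExpressionMatrix(values=values, offset_applied=True)
        fwd = detect_degs(matrix, ["a", "b", "c"], ["d", "e", "f"])
        rev = detect_degs(matrix, ["d", "e", "f"], ["a", "b", "c"])
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-12
        )
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_requires_offset_and_group_sizes(self):
        matrix = _matrix({"a": [1.0], "b": [1.0], "c": [1.0], "d": [1.0]})
        with pytest.raises(MatrixStateError):
            detect_degs(matrix, ["a", "b"], ["c", "d"])
        matrix2 = _matrix(
            {"a": [1.0], "b": [1.0], "c": [1.0]}, offset_applied=True
        )
        with pytest.raises(ValueError):
            detect_degs(matrix2, ["a"], ["b", "c"])


class TestCorrelation:
    def _dna_a(self):
        return pd.Series(
            {"l0": 0.0, "l1": 0.0, "l2": 0.01, "l3": 0.01, "l4": 0.1, "l5": 0.1}
        )

    def test_perfectly_linear_gene_is_correlated(self):
        dna_a = self._dna_a()
        values = pd.DataFrame(
            {lib: [2.0 + 3.0 * a] for lib, a in dna_a.items()}, index=["g0"]
        )
        matrix = ExpressionMatrix(values=values, offset_applied=True)
        out = correlate_with_gdna(matrix, dna_a, log_scale=False)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert out["correlated"].iloc[0]

    def test_bonferroni_arithmetic_and_bound(self, rng):
        values = pd.DataFrame(
            rng.uniform(0.5, 5, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=self._dna_a().index,
        )
        matrix = ExpressionMatrix(values=values, offset_applied=True)
        out = correlate_with_gdna(matrix, self._dna_a())
        np.testing.assert_allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p_raw"] * 10), atol=1e-15
        )
        assert (out["p_bonferroni"] >= out["p_raw"]).all()

    def test_pvalues_match_scipy_pearsonr_oracle(self, rng):
        dna_a = self._dna_a()
        values = pd.DataFrame(
            rng.uniform(0.5, 5, size=(40, 6)),
            index=[f"g{i}" for i in range(40)],
            columns=dna_a.index,
        )
        matrix = ExpressionMatrix(values=values, offset_applied=True)
        out = correlate_with_gdna(matrix, dna_a)
        for gene in values.index:
            r_ref, p_ref = stats.pearsonr(
                np.log2(values.loc[gene]), dna_a.to_numpy()
            )
            assert out.loc[gene, "pearson_r"] == pytest.approx(r_ref, abs=1e-9)
            assert out.loc[gene, "p_raw"] == pytest.approx(p_ref, abs=1e-9)

    def test_constant_gene_flagged_never_correlated(self):
        dna_a = self._dna_a()
        values = pd.DataFrame({lib: [1.0] for lib in dna_a.index}, index=["g0"])
        matrix = ExpressionMatrix(values=values, offset_applied=True)
        out = correlate_with_gdna(matrix, dna_a)
        assert out["constant_expression"].iloc[0]
        assert not out["correlated"].iloc[0]
        assert np.isnan(out["pearson_r"].iloc[0])

    def test_unknown_dna_a_libraries_excluded(self):
        dna_a = self._dna_a()
        dna_a["l5"] = np.nan
        values = pd.DataFrame(
            {lib: [1.0 + 10 * (0 if np.isnan(a) else a)] for lib, a in dna_a.items()},
            index=["g0"],
        )
        matrix = ExpressionMatrix(values=values, offset_applied=True)
        out = correlate_with_gdna(matrix, dna_a, log_scale=False)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)


class TestClassification:
    def _degs(self, n_deg, n_total):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_total)],
                "p_value": 0.01,
                "log2_fold_change": 2.0,
                "is_deg": [i < n_deg for i in range(n_total)],
            }
        ).set_index("gene_id", drop=False)

    def _corr(self, correlated_genes, n_total):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_total)],
                "correlated": [f"g{i}" in correlated_genes for i in range(n_total)],
            }
        ).set_index("gene_id", drop=False)

    def test_no_degs_empty_partition(self):
        table, summary = classify_degs(self._degs(0, 5), self._corr(set(), 5))
        assert summary == {
            "n_deg": 0,
            "n_correlated": 0,
            "n_not_correlated": 0,
            "fraction_correlated": 0.0,
        }
        assert (table["deg_class"] == "NA").all()

    def test_fraction_correlated_arithmetic(self):
        table, summary = classify_degs(
            self._degs(10, 12), self._corr({"g0", "g1", "g2"}, 12)
        )
        assert summary["n_deg"] == 10
        assert summary["n_correlated"] == 3
        assert summary["fraction_correlated"] == pytest.approx(0.3)
        assert (table.loc["g0", "deg_class"]) == "Correlated"
        assert (table.loc["g5", "deg_class"]) == "NotCorrelated"

    def test_missing_deg_in_correlations_raises(self):
        with pytest.raises(KeyError):
            classify_degs(self._degs(3, 5), self._corr(set(), 2))


def test_clean_constant_data_yields_no_calls():
    """No contamination, no expression differences: zero DEGs and zero
    correlated genes."""
    dna_a = pd.Series({"l0": 0.0, "l1": 0.0, "l2": 0.01, "l3": 0.01})
    values = pd.DataFrame(
        {lib: [1.0, 4.0, 0.25] for lib in dna_a.index},
        index=["g0", "g1", "g2"],
    )
    matrix = ExpressionMatrix(values=values, offset_applied=True)
    degs = detect_degs(matrix, ["l2", "l3"], ["l0", "l1"])
    corr = correlate_with_gdna(matrix, dna_a)
    _, summary = classify_degs(degs, corr)
    assert summary["n_deg"] == 0
    assert not corr["correlated"].any()
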