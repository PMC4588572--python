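"""Expression quantification, differential calling and bias analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from polyevol import expr, syndata
from polyevol.expr import ExpressionMatrix, InvalidDesign


def _matrix(counts: dict, lengths: dict, libs: dict, tissues: dict | None = None):
    df = pd.DataFrame(counts).T
    samples = pd.DataFrame({"tissue": pd.Series(tissues or {s: "t" for s in df.columns})})
    return ExpressionMatrix(df, pd.Series(lengths), pd.Series(libs), samples)


class TestRpkm:
    def test_formula(self):
        mat = _matrix({"g": {"s": 10}}, {"g": 2000}, {"s": 10**6})
        assert expr.rpkm(mat).loc["g", "s"] == pytest.approx(5.0)

    def test_zero_count_and_library_scaling(self):
        mat = _matrix({"g": {"s1": 0, "s2": 100}}, {"g": 1000},
                      {"s1": 10**6, "s2": 2 * 10**6})
        r = expr.rpkm(mat)
        assert r.loc["g", "s1"] == 0.0
        mat2 = _matrix({"g": {"s1": 0, "s2": 100}}, {"g": 1000},
                       {"s1": 10**6, "s2": 4 * 10**6})
        assert expr.rpkm(mat2).loc["g", "s2"] == pytest.approx(
            r.loc["g", "s2"] / 2)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            _matrix({"g": {"s": -1}}, {"g": 100}, {"s": 10**6})
        with pytest.raises(ValueError):
            _matrix({"g": {"s": 10}}, {"g": 0}, {"s": 10**6})
        with pytest.raises(ValueError):
            _matrix({"g": {"s": 10}}, {"g": 100}, {"s": 5})  # lib < column sum


class TestCallDe:
    def test_balanced_gene_not_significant(self):
        mat = _matrix({"g": {"a": 50, "b": 50}}, {"g": 1000},
                      {"a": 10**6, "b": 10**6})
        res = expr.call_de(mat, ["a"], ["b"])
        assert res.loc["g", "log2_ratio"] == 0.0
        assert not res.loc["g", "significant"]

    def test_exact_binomial_extreme_case(self):
        mat = _matrix({"g": {"a": 100, "b": 0}}, {"g": 1000},
                      {"a": 10**6, "b": 10**6})
        res = expr.call_de(mat, ["a"], ["b"])
        assert res.loc["g", "p_value"] == pytest.approx(2 * 0.5**100)
        assert bool(res.loc["g", "significant"])

    def test_all_zero_gene_defined(self):
        mat = _matrix({"g": {"a": 0, "b": 0}}, {"g": 1000},
                      {"a": 10**6, "b": 10**6})
        res = expr.call_de(mat, ["a"], ["b"])
        assert res.loc["g", "p_value"] == 1.0
        assert res.loc["g", "log2_ratio"] == 0.0

    def test_empty_group_rejected(self):
        mat = _matrix({"g": {"a": 1, "b": 1}}, {"g": 1000},
                      {"a": 10**6, "b": 10**6})
        with pytest.raises(InvalidDesign):
            expr.call_de(mat, [], ["b"])

    def test_fdr_threshold_monotone(self):
        rng = np.random.default_rng(0)
        genes = {f"g{i}": {"a": int(rng.poisson(50)), "b": int(rng.poisson(50))}
                 for i in range(50)}
        genes["de"] = {"a": 500, "b": 20}
        mat = _matrix(genes, {g: 1000 for g in genes},
                      {"a": 10**6, "b": 10**6})
        loose = expr.call_de(mat, ["a"], ["b"], fdr_max=0.05)
        strict = expr.call_de(mat, ["a"], ["b"], fdr_max=0.001)
        assert set(strict.index[strict.significant]) <= set(
            loose.index[loose.significant])


class TestPreferential:
    def _mat(self):
        counts, tissues, libs = {}, {}, {}
        for s, t in [("f1", "fiber"), ("f2", "fiber"), ("o1", "ovule"),
                     ("o2", "ovule")]:
            tissues[s] = t
            libs[s] = 10**6
        counts["fiber_pref"] = {"f1": 400, "f2": 380, "o1": 10, "o2": 12}
        counts["uniform"] = {"f1": 100, "f2": 100, "o1": 100, "o2": 100}
        counts["ovule_pref"] = {"f1": 5, "f2": 8, "o1": 300, "o2": 320}
        return _matrix(counts, {g: 1000 for g in counts}, libs, tissues)

    def test_two_condition_rule(self):
        mat = self._mat()
        pref = expr.preferential_genes(mat, "fiber")
        assert pref == {"fiber_pref"}

    def test_single_tissue_rejected(self):
        mat = _matrix({"g": {"a": 1}}, {"g": 100}, {"a": 10**6}, {"a": "fiber"})
        with pytest.raises(InvalidDesign):
            expr.preferential_genes(mat, "fiber")


class TestHomoeologBias:
    def test_strong_imbalance_called_at_biased(self):
        counts = {"at": {"s1": 500, "s2": 520}, "dt": {"s1": 10, "s2": 12}}
        mat = _matrix(counts, {"at": 1000, "dt": 1000},
                      {"s1": 10**6, "s2": 10**6})
        res = expr.homoeolog_bias([("at", "dt")], mat)
        assert res.iloc[0]["call"] == "At_biased"

    def test_identical_counts_balanced(self):
        counts = {"at": {"s1": 100}, "dt": {"s1": 100}}
        mat = _matrix(counts, {"at": 1000, "dt": 1000}, {"s1": 10**6})
        res = expr.homoeolog_bias([("at", "dt")], mat)
        assert res.iloc[0]["call"] == "balanced"

    def test_missing_member_skipped(self):
        counts = {"at": {"s1": 100}}
        mat = _matrix(counts, {"at": 1000}, {"s1": 10**6})
        res = expr.homoeolog_bias([("at", "gone")], mat)
        assert len(res) == 0

    def test_truth_recovery_on_simulated_bias(self):
        genes = [f"at{i}" for i in range(40)] + [f"dt{i}" for i in range(40)]
        fcs = {f"at{i}": {"t": 6.0} for i in range(12)}  # 30% biased pairs
        groups = {g: f"pair{i}" for i in range(40) for g in (f"at{i}", f"dt{i}")}
        mat, _ = syndata.gen_counts(
            genes, {"s1": "t", "s2": "t"}, {"s1": 4 * 10**6, "s2": 4 * 10**6},
            fcs, seed=8, gene_lengths={g: 1500 for g in genes},
            baseline_groups=groups)
        pairs = [(f"at{i}", f"dt{i}") for i in range(40)]
        res = expr.homoeolog_bias(pairs, mat)
        called = set(res.index[res["call"] == "At_biased"].get_level_values(0))
        truth = {f"at{i}" for i in range(12)}
        recovered = len(called & truth) / len(truth)
        assert recovered >= 0.9


class TestLtrContrast:
    def test_constructed_suppression_detected(self):
        genes = [f"g{i}" for i in range(120)]
        flags = {g: i < 60 for i, g in enumerate(genes)}
        fcs = {g: {"t": 0.4} for g in genes[:60]}  # flagged at ~half expression
        mat, _ = syndata.gen_counts(genes, {"s1": "t", "s2": "t"},
                                    {"s1": 10**6, "s2": 10**6}, fcs, seed=4)
        m1, m0, p = expr.ltr_expression_contrast(mat, flags, n_perm=2000, seed=1)
        assert m1 < m0
        assert p < 0.05

    def test_empty_stratum_rejected(self):
        mat = _matrix({"g": {"s": 5}}, {"g": 100}, {"s": 10**6})
        with pytest.raises(InvalidDesign):
            expr.ltr_expression_contrast(mat, {"g": False})
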