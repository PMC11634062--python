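"""CNV-normalized expression differences, co-occurrence and CNV direction."""

import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_exact_enumeration
from pasnv import expression as X


def _expr(fpkm, cn=None):
    fpkm = pd.DataFrame(fpkm)
    if cn is None:
        cn = pd.DataFrame(2, index=fpkm.index, columns=fpkm.columns)
    else:
        cn = pd.DataFrame(cn, index=fpkm.index, columns=fpkm.columns)
    return X.ExpressionSet(fpkm, cn)


class TestExpressionSet:
    def test_nfpkm_equals_fpkm_at_diploid(self):
        es = _expr({"s1": {"g": 8.0}, "s2": {"g": 4.0}})
        pd.testing.assert_frame_equal(es.nfpkm, es.fpkm)

    def test_doubling_fpkm_and_cn_leaves_nfpkm_unchanged(self):
        base = _expr({"s1": {"g": 8.0}})
        doubled = _expr({"s1": {"g": 16.0}}, {"s1": {"g": 4}})
        pd.testing.assert_frame_equal(base.nfpkm, doubled.nfpkm)

    def test_zero_copy_number_masked(self):
        es = _expr({"s1": {"g": 8.0}}, {"s1": {"g": 0}})
        assert np.isnan(es.nfpkm.loc["g", "s1"])

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            _expr({"s1": {"g": -1.0}})


def _elig(mutant, wildtype):
    return X.Eligibility(mutant=mutant, wildtype=wildtype)


class TestDeltaExpression:
    def test_log2_arithmetic(self):
        es = _expr({"m": {"g": 4.0}, "w": {"g": 8.0}})
        result = X.delta_expression(es, _elig({"g": ["m"]}, {"g": ["w"]}))
        assert result["pooled_median"] == pytest.approx(-1.0)
        assert result["pooled_fold"] == pytest.approx(2.0)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(0)
        fpkm = pd.DataFrame(
            rng.lognormal(3, 0.5, (5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)],
        )
        es = X.ExpressionSet(fpkm, pd.DataFrame(2, index=fpkm.index, columns=fpkm.columns))
        mut = {g: ["s0", "s1"] for g in fpkm.index}
        wt = {g: ["s2", "s3", "s4"] for g in fpkm.index}
        fwd = X.delta_expression(es, _elig(mut, wt))
        rev = X.delta_expression(es, _elig(wt, mut))
        assert fwd["pooled_median"] == pytest.approx(-rev["pooled_median"])

    def test_nonpositive_pairs_dropped_and_counted(self):
        es = _expr({"m": {"g": 4.0}, "w": {"g": 8.0}, "w2": {"g": 0.0}})
        result = X.delta_expression(es, _elig({"g": ["m"]}, {"g": ["w", "w2"]}))
        assert result["n_pairs"] == 1
        assert result["n_dropped"] == 1

    def test_no_pairs_reports_missing(self):
        es = _expr({"m": {"g": 0.0}, "w": {"g": 8.0}})
        result = X.delta_expression(es, _elig({"g": ["m"]}, {"g": ["w"]}))
        assert result["pooled_median"] is None


class TestSelectEligible:
    def _inputs(self):
        genes = ["tsg1", "tsg2", "onc1"]
        samples = [f"s{i}" for i in range(5)]
        roles = pd.DataFrame(
            {"gene_id": genes, "role": ["TSG", "TSG", "oncogene"],
             "hallmark": False}
        )
        fpkm = pd.DataFrame(10.0, index=genes, columns=samples)
        cn = pd.DataFrame(2, index=genes, columns=samples)
        expr = X.ExpressionSet(fpkm, cn)
        damaging = pd.DataFrame(0, index=genes, columns=samples)
        return genes, samples, roles, expr, damaging

    def test_down_sample_with_damaging_is_not_mutant(self):
        genes, samples, roles, expr, damaging = self._inputs()
        damaging.loc["tsg1", "s0"] = 1
        down = pd.DataFrame({"gene_id": ["tsg1"], "sample_id": ["s0"]})
        elig = X.select_eligible(down, down, damaging, roles, expr)
        assert "tsg1" not in elig.mutant

    def test_clean_gene_is_eligible_with_disjoint_sets(self):
        genes, samples, roles, expr, damaging = self._inputs()
        down = pd.DataFrame({"gene_id": ["tsg1"], "sample_id": ["s0"]})
        elig = X.select_eligible(down, down, damaging, roles, expr)
        assert elig.mutant["tsg1"] == ["s0"]
        assert elig.wildtype["tsg1"] == ["s1", "s2", "s3", "s4"]
        assert not set(elig.mutant["tsg1"]) & set(elig.wildtype["tsg1"])

    def test_oncogene_excluded_by_role_filter(self):
        genes, samples, roles, expr, damaging = self._inputs()
        down = pd.DataFrame({"gene_id": ["onc1"], "sample_id": ["s0"]})
        elig = X.select_eligible(down, down, damaging, roles, expr)
        assert elig.genes == []

    def test_any_variant_disqualifies_wildtype_sample(self):
        genes, samples, roles, expr, damaging = self._inputs()
        down = pd.DataFrame({"gene_id": ["tsg1"], "sample_id": ["s0"]})
        all_events = pd.DataFrame(
            {"gene_id": ["tsg1", "tsg1"], "sample_id": ["s0", "s3"]}
        )
        elig = X.select_eligible(down, all_events, damaging, roles, expr)
        assert "s3" not in elig.wildtype["tsg1"]

    def test_low_expression_filtered(self):
        genes, samples, roles, expr, damaging = self._inputs()
        expr.fpkm.loc["tsg1"] = 0.5
        down = pd.DataFrame({"gene_id": ["tsg1"], "sample_id": ["s0"]})
        elig = X.select_eligible(down, down, damaging, roles, expr)
        assert elig.genes == []


def _events(down_cooccur, down_total, bg_cooccur, bg_total):
    rows = []
    genes, samples = [], []
    damaging_ones = []
    for i in range(down_total):
        rows.append({"gene_id": f"g{i}", "sample_id": f"s{i}", "category": "DOWN"})
        if i < down_cooccur:
            damaging_ones.append((f"g{i}", f"s{i}"))
    for i in range(bg_total):
        rows.append({"gene_id": f"g{i}", "sample_id": f"b{i}", "category": "BG"})
        if i < bg_cooccur:
            damaging_ones.append((f"g{i}", f"b{i}"))
    events = pd.DataFrame(rows)
    genes = sorted(events["gene_id"].unique())
    samples = sorted(events["sample_id"].unique())
    damaging = pd.DataFrame(0, index=genes, columns=samples)
    for g, s in damaging_ones:
        damaging.loc[g, s] = 1
    return events, damaging


class TestCooccurrence:
    def test_all_zero_damaging(self):
        events, damaging = _events(0, 10, 0, 10)
        damaging[:] = 0
        roles = pd.DataFrame({"gene_id": events["gene_id"].unique(),
                              "role": "TSG", "hallmark": False})
        result = X.cooccurrence_rate(events, damaging, roles)
        assert result["all_genes"]["down_rate"] == 0
        assert result["all_genes"]["odds_ratio"] is None

    def test_p_matches_enumeration(self):
        events, damaging = _events(8, 10, 2, 10)
        roles = pd.DataFrame({"gene_id": events["gene_id"].unique(),
                              "role": "non-census", "hallmark": False})
        result = X.cooccurrence_rate(events, damaging, roles)
        assert result["all_genes"]["p_value"] == pytest.approx(
            fisher_exact_enumeration([[8, 2], [2, 8]]), rel=1e-9
        )
        assert result["tsg_only"]["p_value"] is None  # no TSG events


class TestDamagingFrequencyCompare:
    def test_identical_groups(self):
        genes = [f"g{i}" for i in range(6)]
        damaging = pd.DataFrame(
            [[1, 0, 0]] * 6, index=genes, columns=["s0", "s1", "s2"]
        )
        roles = pd.DataFrame({"gene_id": genes, "role": "TSG", "hallmark": False})
        result = X.damaging_frequency_compare(roles, set(genes[:3]), damaging)
        assert result["p_value"] == pytest.approx(1.0)

    def test_disjoint_frequencies_significant(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{i}" for i in range(40)]
        damaging = pd.DataFrame(0, index=genes, columns=samples)
        for g in genes[:10]:  # DOWN-positive group: high frequency
            damaging.loc[g, rng.choice(samples, 20, replace=False)] = 1
        for g in genes[10:]:
            damaging.loc[g, rng.choice(samples, 2, replace=False)] = 1
        roles = pd.DataFrame({"gene_id": genes, "role": "TSG", "hallmark": False})
        result = X.damaging_frequency_compare(roles, set(genes[:10]), damaging)
        assert result["down_group_median"] > result["other_group_median"]
        assert result["p_value"] < 1e-4

    def test_single_gene_group_missing(self):
        genes = ["g0", "g1"]
        damaging = pd.DataFrame(0, index=genes, columns=["s0"])
        roles = pd.DataFrame({"gene_id": genes, "role": "TSG", "hallmark": False})
        assert X.damaging_frequency_compare(roles, {"g0"}, damaging)["p_value"] is None


class TestCnvDirection:
    def _calls(self, gains, losses, neutrals, category="DOWN", start=0):
        rows, calls = [], []
        i = start
        for call, n in (("gain", gains), ("loss", losses), ("neutral", neutrals)):
            for _ in range(n):
                rows.append({"gene_id": f"g{i}", "sample_id": f"s{i}",
                             "category": category})
                calls.append({"gene_id": f"g{i}", "sample_id": f"s{i}", "call": call})
                i += 1
        return rows, calls

    def test_ratio_arithmetic(self):
        d_rows, d_calls = self._calls(41, 10, 0)
        b_rows, b_calls = self._calls(10, 10, 0, category="BG", start=100)
        events = pd.DataFrame(d_rows + b_rows)
        cnv = pd.DataFrame(d_calls + b_calls)
        result = X.cnv_direction(events, cnv)
        assert result["down"]["gain_loss_ratio"] == pytest.approx(4.1)

    def test_all_neutral_missing_ratio(self):
        rows, calls = self._calls(0, 0, 5)
        result = X.cnv_direction(pd.DataFrame(rows), pd.DataFrame(calls))
        assert result["down"]["gain_loss_ratio"] is None

    def test_zero_losses_flagged_infinite(self):
        d_rows, d_calls = self._calls(5, 0, 0)
        b_rows, b_calls = self._calls(3, 3, 0, category="BG", start=100)
        result = X.cnv_direction(
            pd.DataFrame(d_rows + b_rows), pd.DataFrame(d_calls + b_calls)
        )
        assert result["down"]["gain_loss_ratio"] == np.inf
        assert result["down"]["ratio_flagged"]
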