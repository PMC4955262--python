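import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepthla.expression import (ExpressionError, SampleMeta, expressing_tissues,
                                gene_expression_for_peptide, is_cancer_specific,
                                offtarget_expressed, percentile, summarize)


def sort_interp_percentile(values, q):
    """Brute-force oracle: sort, interpolate at rank (n-1)q/100."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    r = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(r))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (r - lo) * (xs[hi] - xs[lo])


class TestPercentile:
    @pytest.mark.parametrize("values, q, expected", [
        ([1, 2, 3, 4], 75, 3.25),
        ([7, 7, 7], 40, 7.0),
        ([0, 10], 50, 5.0),
        ([3, 1, 2], 0, 1.0),
        ([3, 1, 2], 100, 3.0),
    ])
    def test_worked_examples(self, values, q, expected):
        assert percentile(values, q) == pytest.approx(expected, abs=1e-12)

    def test_empty_input_is_domain_error(self):
        with pytest.raises(ExpressionError):
            percentile([], 50)

    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=1, max_size=40),
           st.floats(min_value=0, max_value=100))
    @settings(derandomize=True, max_examples=1000)
    def test_agrees_with_sort_interpolate_oracle(self, values, q):
        assert percentile(values, q) == pytest.approx(
            sort_interp_percentile(values, q), abs=1e-9)


def make_matrix(rows: dict, groups: dict):
    """rows: gene -> {group: [values]}; groups: group -> (is_cancer, is_essential)."""
    samples, columns = [], []
    for group, (is_cancer, is_ess) in groups.items():
        n = max(len(v[group]) for v in rows.values())
        for k in range(n):
            sid = f"{group}_{k}"
            samples.append(SampleMeta(sid, "synthetic", group, is_cancer, is_ess))
            columns.append(sid)
    data = {
        gene: np.concatenate([np.asarray(per_group[g], float) for g in groups])
        for gene, per_group in rows.items()
    }
    return pd.DataFrame(data, index=columns).T, samples


GROUPS = {"SKCM": (True, False), "brain": (False, True),
          "liver": (False, True), "testis": (False, False)}


class TestSummarize:
    def test_cardinality_and_constant_gene(self):
        mat, samples = make_matrix(
            {"G1": {g: [7, 7, 7, 7] for g in GROUPS},
             "G2": {g: [0, 1, 2, 3] for g in GROUPS}},
            GROUPS)
        summ = summarize(mat, samples)
        assert len(summ.summaries) == 8
        s = summ.get("G1", "brain")
        assert s.p75 == s.p95 == 7
        assert summ.cancer_groups == {"SKCM"}
        assert summ.essential_normal_groups == {"brain", "liver"}

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        mat, samples = make_matrix(
            {"G1": {g: rng.uniform(0, 10, 6).tolist() for g in GROUPS}}, GROUPS)
        summ1 = summarize(mat, samples)
        perm = rng.permutation(len(samples))
        mat2 = mat.iloc[:, perm]
        summ2 = summarize(mat2, [samples[i] for i in perm])
        for key, s in summ1.summaries.items():
            assert summ2.summaries[key].p75 == pytest.approx(s.p75)
            assert summ2.summaries[key].p95 == pytest.approx(s.p95)

    def test_duplicate_gene_rows_aggregated_by_max(self):
        mat, samples = make_matrix({"G1": {g: [1, 1, 1, 1] for g in GROUPS}}, GROUPS)
        dup = pd.concat([mat, mat * 3])
        summ = summarize(dup, samples)
        assert summ.get("G1", "brain").p75 == 3


class TestSpecificityRules:
    def summ(self, tumor, brain, liver, testis):
        mat, samples = make_matrix(
            {"G1": {"SKCM": tumor, "brain": brain, "liver": liver, "testis": testis}},
            GROUPS)
        return summarize(mat, samples)

    def test_specific_when_tumor_high_normals_silent(self):
        s = self.summ([6.57] * 4, [0.1] * 4, [0.1] * 4, [50] * 4)
        # testis is non-essential: its huge expression must not block the call
        assert is_cancer_specific({"G1"}, "SKCM", s)

    def test_strict_boundaries(self):
        assert not is_cancer_specific(
            {"G1"}, "SKCM", self.summ([5.0] * 4, [0.1] * 4, [0.1] * 4, [0] * 4))
        assert not is_cancer_specific(
            {"G1"}, "SKCM", self.summ([9.0] * 4, [0.5] * 4, [0.1] * 4, [0] * 4))

    def test_unknown_cancer_type_is_lookup_error(self):
        with pytest.raises(ExpressionError):
            is_cancer_specific({"G1"}, "LUSC",
                               self.summ([9] * 4, [0] * 4, [0] * 4, [0] * 4))

    def test_offtarget_expression_rule(self):
        assert not offtarget_expressed({"G1"}, self.summ([0] * 4, [0] * 4, [0] * 4, [0] * 4))
        assert offtarget_expressed({"G1"}, self.summ([0] * 4, [0.6] * 4, [0] * 4, [0] * 4))
        # non-essential tissue expression alone never triggers the rule
        assert not offtarget_expressed({"G1"}, self.summ([0] * 4, [0] * 4, [0] * 4, [50] * 4))

    def test_expressing_tissues_sorted_by_p95(self):
        s = self.summ([0] * 4, [2.0] * 4, [5.0] * 4, [0] * 4)
        assert expressing_tissues({"G1"}, s) == [("liver", 5.0), ("brain", 2.0)]

    def test_monotonicity_in_cutoffs(self):
        s = self.summ([6.0] * 4, [0.3] * 4, [0.1] * 4, [0] * 4)
        assert is_cancer_specific({"G1"}, "SKCM", s)
        assert not is_cancer_specific({"G1"}, "SKCM", s, tumor_cut=7.0)
        assert not is_cancer_specific({"G1"}, "SKCM", s, normal_cut=0.2)


class TestMultiGenePeptides:
    def test_max_rule_over_source_genes(self):
        mat, samples = make_matrix(
            {"G1": {g: [2] * 4 for g in GROUPS}, "G2": {g: [8] * 4 for g in GROUPS}},
            GROUPS)
        summ = summarize(mat, samples)
        assert gene_expression_for_peptide({"G1", "G2"}, summ, "SKCM", "p75") == 8

    def test_absent_gene_falls_back_with_lookup_error_when_all_missing(self):
        mat, samples = make_matrix({"G1": {g: [2] * 4 for g in GROUPS}}, GROUPS)
        summ = summarize(mat, samples)
        assert gene_expression_for_peptide({"G1", "GX"}, summ, "SKCM", "p75") == 2
        with pytest.raises(ExpressionError):
            offtarget_expressed({"GX"}, summ)
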