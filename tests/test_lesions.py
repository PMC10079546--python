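"""TP53 allelic-state, SF3B1 subtype and feature-vector derivation."""

import pytest
from hypothesis import given, settings, strategies as st

from mdsrisk import CytogeneticsProfile, MutationCall, build_features, classify_sf3b1, classify_tp53

from .conftest import make_record


def _tp53_calls(pid, *vafs):
    return [MutationCall(pid, "TP53", v) for v in vafs]


def _cyto(del17p=False, cnloh=False):
    return CytogeneticsProfile(
        ipssr_cyto_category=1, del5q=False, minus7_or_del7q=False,
        del17p=del17p, complex_karyotype=False, tp53_cnloh=cnloh,
    )


class TestTp53:
    @pytest.mark.parametrize(
        "vafs,del17p,cnloh,mode,classification,mechanism",
        [
            # one mutation at 46% VAF plus CN-LOH: biallelic on full evidence,
            # but below the 55% surrogate threshold
            ((46.0,), False, True, "wgs", "multihit", "mutation_plus_cnloh"),
            ((46.0,), False, True, "vaf_surrogate", "monoallelic", "none"),
            # two mutations decide in either mode, regardless of CNV data
            ((30.0, 20.0), False, False, "wgs", "multihit", "two_mutations"),
            ((30.0, 20.0), False, False, "vaf_surrogate", "multihit", "two_mutations"),
            # mutation plus deletion
            ((40.0,), True, False, "wgs", "multihit", "mutation_plus_deletion"),
            ((40.0,), True, False, "vaf_surrogate", "multihit", "mutation_plus_deletion"),
            # high-VAF single mutation: only the surrogate calls it
            ((60.0,), False, False, "wgs", "monoallelic", "none"),
            ((60.0,), False, False, "vaf_surrogate", "multihit", "vaf_surrogate"),
            # boundary: VAF exactly at threshold is NOT above it
            ((55.0,), False, False, "vaf_surrogate", "monoallelic", "none"),
            # single mutation, clean flags
            ((30.0,), False, False, "wgs", "monoallelic", "none"),
        ],
    )
    def test_classification(self, vafs, del17p, cnloh, mode, classification, mechanism):
        state = classify_tp53(_tp53_calls("P", *vafs), _cyto(del17p, cnloh), mode)
        assert state.classification == classification
        assert state.mechanism == mechanism

    def test_deletion_alone_is_wildtype(self):
        state = classify_tp53([], _cyto(del17p=True), "wgs")
        assert state.classification == "wildtype"
        assert not state.is_multihit

    def test_unknown_flags_propagate_only_when_deciding(self):
        unknown_cnv = CytogeneticsProfile(ipssr_cyto_category=1)
        # single mutation, no CNV information at all: undecidable on WGS evidence
        assert classify_tp53(_tp53_calls("P", 30.0), unknown_cnv, "wgs").classification == "unknown"
        # two mutations: flags are irrelevant
        assert classify_tp53(_tp53_calls("P", 30.0, 10.0), unknown_cnv, "wgs").is_multihit

    def test_rejects_non_tp53_calls(self):
        with pytest.raises(ValueError, match="TP53"):
            classify_tp53([MutationCall("P", "ASXL1", 30.0)], _cyto())

    @given(
        n_mut=st.integers(0, 3),
        vaf=st.floats(5.0, 99.0),
        del17p=st.sampled_from([True, False, None]),
        cnloh=st.sampled_from([True, False, None]),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_wgs_without_cnloh_equals_surrogate_with_disabled_threshold(self, n_mut, vaf, del17p, cnloh):
        """With CN-LOH forced negative and the surrogate disabled (threshold 100),
        the two modes rest on identical evidence."""
        calls = _tp53_calls("P", *([vaf] * n_mut))
        cyto_no_cnloh = CytogeneticsProfile(ipssr_cyto_category=1, del17p=del17p, tp53_cnloh=False)
        wgs = classify_tp53(calls, cyto_no_cnloh, "wgs")
        sur = classify_tp53(calls, cyto_no_cnloh, "vaf_surrogate", vaf_threshold=100.0)
        assert wgs.classification == sur.classification

    @given(
        vaf=st.floats(5.0, 99.0),
        lo=st.floats(50.5, 99.0),
        hi=st.floats(50.5, 99.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_raising_threshold_never_creates_multihit(self, vaf, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        calls = _tp53_calls("P", vaf)
        low = classify_tp53(calls, _cyto(), "vaf_surrogate", vaf_threshold=lo)
        high = classify_tp53(calls, _cyto(), "vaf_surrogate", vaf_threshold=hi)
        if high.is_multihit:
            assert low.is_multihit


class TestSf3b1:
    def test_alpha_with_normal_karyotype(self):
        r = make_record(mutations=[("SF3B1", 40.0)])
        assert classify_sf3b1(r) == {"sf3b1_alpha"}

    def test_5q_with_isolated_del5q(self):
        r = make_record(mutations=[("SF3B1", 40.0)], del5q=True)
        assert classify_sf3b1(r) == {"sf3b1_5q"}

    def test_del5q_with_complex_karyotype_is_other(self):
        r = make_record(mutations=[("SF3B1", 40.0)], del5q=True, complex_k=True)
        assert classify_sf3b1(r) == {"sf3b1_other"}

    def test_srsf2_comutation_is_other(self):
        r = make_record(mutations=[("SF3B1", 40.0), ("SRSF2", 30.0)])
        assert classify_sf3b1(r) == {"sf3b1_other"}

    def test_unmutated_is_none(self):
        assert classify_sf3b1(make_record()) == {"none"}

    def test_unassessed_exclusion_gene_gives_range(self):
        panel = frozenset({"SF3B1", "TP53"})  # co-mutation genes not covered
        r = make_record(mutations=[("SF3B1", 40.0)], assessed=panel)
        assert classify_sf3b1(r) == {"sf3b1_alpha", "sf3b1_other"}

    def test_unknown_del5q_gives_range(self):
        r = make_record(mutations=[("SF3B1", 40.0)], del5q=None)
        assert classify_sf3b1(r) == {"sf3b1_5q", "sf3b1_alpha"}


class TestBuildFeatures:
    def test_all_wildtype(self, coeffs):
        f = build_features(make_record(), coeffs)
        assert all(v == 0.0 for v in f.values.values())
        assert f.nres2 == (0.0, 0.0, 0.0)

    def test_flt3_tkd_sets_flag(self, coeffs):
        f = build_features(make_record(mutations=[("FLT3", 20.0, "TKD")]), coeffs)
        assert f.values["FLT3"] == 1.0

    def test_flt3_plain_snv_does_not_set_flag(self, coeffs):
        f = build_features(make_record(mutations=[("FLT3", 20.0, "SNV")]), coeffs)
        assert f.values["FLT3"] == 0.0

    def test_kmt2a_ptd_sets_flag(self, coeffs):
        f = build_features(make_record(mutations=[("KMT2A", 20.0, "PTD")]), coeffs)
        assert f.values["MLL_PTD"] == 1.0

    def test_residual_count_caps_at_two(self, coeffs):
        r = make_record(mutations=[("BCOR", 10.0), ("STAG2", 20.0), ("WT1", 30.0)])
        f = build_features(r, coeffs)
        assert f.nres2 == (2.0, 2.0, 2.0)

    def test_residual_range_with_unassessed_genes(self, coeffs):
        panel = frozenset(set(coeffs.all_genes) - {"STAG2", "WT1"})
        r = make_record(mutations=[("BCOR", 10.0)], assessed=panel)
        f = build_features(r, coeffs)
        low, expected, high = f.nres2
        assert (low, high) == (1.0, 2.0)
        assert expected == pytest.approx(
            1.0 + coeffs.residual_prevalence["STAG2"] + coeffs.residual_prevalence["WT1"]
        )

    def test_row_order_invariance(self, coeffs):
        muts = [("SF3B1", 40.0), ("ASXL1", 30.0), ("BCOR", 10.0), ("TP53", 25.0)]
        f1 = build_features(make_record(mutations=muts), coeffs)
        f2 = build_features(make_record(mutations=list(reversed(muts))), coeffs)
        assert f1.values == f2.values
        assert f1.nres2 == f2.nres2
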