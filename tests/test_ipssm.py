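"""Molecular score: transforms, weighted sum, categories, scenarios."""

import json
import math
import random

import numpy as np
import pytest

from mdsrisk import assign_category, build_features, compute_score, score_patient, transform_variables
from mdsrisk.config import default_coefficients_path
from mdsrisk.ipssm import TransformedVector

from .conftest import make_record

LN2 = math.log(2.0)


def _transformed(record, coeffs):
    f = build_features(record, coeffs)
    return transform_variables(f, record.clinical, record.cytogenetics, coeffs)


class TestTransforms:
    def test_platelet_cap(self, coeffs):
        x = _transformed(make_record(platelets=400.0), coeffs)
        assert x.values["TRANSF_PLT100"] == 2.5

    def test_blast_cap_and_scale(self, coeffs):
        x = _transformed(make_record(blasts=30.0), coeffs)
        assert x.values["BLAST5"] == 4.0
        x = _transformed(make_record(blasts=10.0), coeffs)
        assert x.values["BLAST5"] == 2.0

    def test_unknown_anc_is_irrelevant(self, coeffs):
        a = score_patient(make_record(anc=2.0), coeffs)
        b = score_patient(make_record(anc=None), coeffs)
        assert a == b


class TestComputeScore:
    def test_centering_identity(self, coeffs):
        """A patient sitting exactly on every centering mean scores 0 -> ML."""
        values = {v.name: v.center for v in coeffs.variables if v.transform != "residual_count"}
        center_nres = coeffs.variable("NRES2").center
        x = TransformedVector(values=values, nres2=(center_nres,) * 3)
        for scenario in ("mean", "best", "worst"):
            assert compute_score(x, coeffs, scenario) == pytest.approx(0.0, abs=1e-12)
        assert assign_category(0.0, coeffs) == "ML"

    def test_single_deviation_linearity(self, coeffs):
        values = {v.name: v.center for v in coeffs.variables if v.transform != "residual_count"}
        spec = coeffs.variable("HB1")
        values["HB1"] = spec.center + 3.0
        x = TransformedVector(values=values, nres2=(coeffs.variable("NRES2").center,) * 3)
        assert compute_score(x, coeffs) == pytest.approx(3.0 * spec.log_hazard / LN2)

    def test_against_independent_hand_sum(self, coeffs):
        """Random complete patients vs a spreadsheet-style sum computed directly
        from the JSON file, bypassing the scoring code entirely."""
        raw = json.loads(default_coefficients_path().read_text())
        rng = random.Random(20240917)
        genes = list(coeffs.main_effect_genes) + list(coeffs.residual_genes)
        for _ in range(20):
            muts = [(g, rng.uniform(5, 60)) for g in genes if rng.random() < 0.2 and g not in ("FLT3", "KMT2A")]
            rec = make_record(
                blasts=rng.uniform(0, 25),
                hb=rng.uniform(6, 15),
                platelets=rng.uniform(10, 600),
                cyto_category=rng.randrange(5),
                del5q=rng.random() < 0.1,
                del17p=rng.random() < 0.1,
                cnloh=rng.random() < 0.1,
                mutations=muts,
            )
            got = score_patient(rec, coeffs).score_mean

            # independent oracle: re-derive inputs by hand from the raw JSON
            mutated = {g for g, _ in muts}
            n_tp53 = sum(1 for g in mutated if g == "TP53")
            tp53_multi = 1.0 if (n_tp53 >= 1 and (rec.cytogenetics.del17p or rec.cytogenetics.tp53_cnloh)) else 0.0
            excl = set(raw["sf3b1_alpha_exclusion"])
            sf5q = 1.0 if ("SF3B1" in mutated and rec.cytogenetics.del5q) else 0.0
            sfalpha = (
                1.0
                if ("SF3B1" in mutated and not rec.cytogenetics.del5q and not (mutated & excl))
                else 0.0
            )
            nres = min(2, sum(1 for g in raw["residual_genes"] if g in mutated))
            hand_inputs = {
                "CYTOVEC": float(rec.cytogenetics.ipssr_cyto_category),
                "BLAST5": min(rec.clinical.bm_blasts, 20.0) / 5.0,
                "TRANSF_PLT100": min(rec.clinical.platelets, 250.0) / 100.0,
                "HB1": rec.clinical.hemoglobin,
                "TP53multi": tp53_multi,
                "MLL_PTD": 0.0,
                "FLT3": 0.0,
                "SF3B1_5q": sf5q,
                "SF3B1_alpha": sfalpha,
                "NRES2": float(nres),
            }
            expected = 0.0
            for v in raw["variables"]:
                value = hand_inputs.get(v["name"], 1.0 if v.get("gene") in mutated else 0.0)
                expected += v["log_hazard"] * (value - v["center"]) / math.log(2)
            assert got == pytest.approx(expected, abs=1e-9)


class TestCategories:
    @pytest.mark.parametrize(
        "score,label",
        [(-2.0, "VL"), (-1.5, "VL"), (-1.4999, "L"), (-0.5, "L"), (0.0, "ML"),
         (0.3, "MH"), (0.5, "MH"), (1.5, "H"), (1.6, "VH"), (10.0, "VH")],
    )
    def test_boundaries_upper_inclusive(self, score, label, coeffs):
        assert assign_category(score, coeffs) == label

    def test_non_finite_rejected(self, coeffs):
        with pytest.raises(ValueError):
            assign_category(float("nan"), coeffs)
        with pytest.raises(ValueError):
            assign_category(float("inf"), coeffs)

    def test_monotone_in_score(self, coeffs):
        labels = list(coeffs.category_labels)
        grid = np.linspace(-4, 4, 400)
        cats = [labels.index(assign_category(s, coeffs)) for s in grid]
        assert cats == sorted(cats)


class TestScenarios:
    def test_complete_record_has_no_spread(self, coeffs):
        res = score_patient(make_record(mutations=[("ASXL1", 30.0)]), coeffs)
        assert res.score_best == res.score_mean == res.score_worst
        assert res.spread_consistent

    def test_masking_ptd_on_midrisk_carrier_splits_categories(self, coeffs):
        rec = make_record(mutations=[("KMT2A", 30.0, "PTD")], cyto_category=2, blasts=4.0, hb=9.5)
        res = score_patient(rec, coeffs, force_unknown={"MLL_PTD"})
        assert not res.spread_consistent
        assert res.score_worst - res.score_best == pytest.approx(
            coeffs.variable("MLL_PTD").weight, abs=1e-12
        )

    def test_very_high_risk_patient_consistent_despite_mask(self, coeffs):
        rec = make_record(
            mutations=[("TP53", 40.0), ("TP53", 30.0), ("ASXL1", 30.0)],
            cyto_category=4, blasts=18.0, hb=7.0, platelets=30.0, complex_k=True,
        )
        res = score_patient(rec, coeffs, force_unknown={"MLL_PTD"})
        assert res.category_best == res.category_worst == "VH"
        assert res.spread_consistent

    def test_masking_unknown_variable_rejected(self, coeffs):
        with pytest.raises(ValueError, match="NOPE"):
            score_patient(make_record(), coeffs, force_unknown={"NOPE"})

    def test_scenario_ordering_under_random_masks(self, coeffs):
        """best <= mean <= worst over many random records and random masks."""
        rng = random.Random(7)
        genes = list(coeffs.main_effect_genes) + list(coeffs.residual_genes)
        maskable = [v.name for v in coeffs.variables]
        for i in range(300):
            muts = [(g, rng.uniform(5, 60)) for g in genes if rng.random() < 0.15 and g not in ("FLT3", "KMT2A")]
            rec = make_record(
                blasts=rng.uniform(0, 25),
                hb=rng.uniform(6, 15),
                platelets=rng.uniform(10, 600),
                cyto_category=rng.randrange(5),
                del5q=rng.random() < 0.2,
                del17p=rng.random() < 0.1,
                cnloh=rng.random() < 0.1,
                mutations=muts,
            )
            mask = {name for name in maskable if rng.random() < 0.3}
            res = score_patient(rec, coeffs, force_unknown=mask)
            assert res.score_best <= res.score_mean + 1e-12
            assert res.score_mean <= res.score_worst + 1e-12

    def test_adverse_binary_monotonicity(self, coeffs):
        """Turning on any adverse gene lesion never lowers the score."""
        base = make_record()
        s0 = score_patient(base, coeffs).score_mean
        for gene, mtype in [("ASXL1", "SNV"), ("RUNX1", "SNV"), ("KMT2A", "PTD"), ("FLT3", "ITD"), ("BCOR", "SNV")]:
            s1 = score_patient(make_record(mutations=[(gene, 30.0, mtype)]), coeffs).score_mean
            assert s1 >= s0
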