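"""Continuous molecular risk score (IPSS-M) with missing-data scenarios.

The score is ``sum_j w_j * (x_j - center_j)`` over the configured variables,
with ``w_j`` on the log2-hazard scale, so one unit doubles the hazard and the
average patient scores 0.  Unknown variables are resolved three ways:

* ``mean``  — impute the centering mean (contribution 0); for the residual
  gene count, the expected count under the configured per-gene prevalences;
* ``best``  — the most favorable fill-in from the coefficient table;
* ``worst`` — the least favorable fill-in.

A patient with no unknowns gets three identical scores.  Categories are cut
from the unrounded score with upper-inclusive bounds (a score exactly on a
cutpoint falls in the more favorable category; 0 is "ML" by construction).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from .config import CoefficientTable
from .lesions import DEFAULT_VAF_THRESHOLD, MolecularFeatures, Tp53Mode, build_features
from .records import ClinicalPanel, CytogeneticsProfile, PatientRecord

Scenario = Literal["mean", "best", "worst"]
SCENARIOS: tuple[Scenario, ...] = ("mean", "best", "worst")

NRES2 = "NRES2"


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class TransformedVector:
    """Config-aligned numeric inputs: per-variable value or None (unknown),
    plus the residual-count triple (best, expected, worst)."""

    values: Mapping[str, float | None]
    nres2: tuple[float, float, float]


@dataclass(frozen=True)
class RiskResult:
    """Score and category per scenario for one patient and one system.

    Lower score = more favorable; ``score_best <= score_mean <= score_worst``.
    ``spread_consistent`` is True when the best- and worst-case categories
    agree (i.e. the unknowns do not matter for staging).
    """

    system: str
    score_mean: float
    score_best: float
    score_worst: float
    category_mean: str
    category_best: str
    category_worst: str
    spread_consistent: bool


def transform_variables(
    features: MolecularFeatures,
    clinical: ClinicalPanel,
    cyto: CytogeneticsProfile,
    config: CoefficientTable,
) -> TransformedVector:
    """Map raw inputs onto the numeric scale of each config variable.

    Blasts are capped at 20 % and divided by 5; platelets capped at 250 and
    divided by 100; hemoglobin enters as-is; cytogenetics as the 0-4 category
    index.  Gene variables come through from the feature vector unchanged.
    """
    values: dict[str, float | None] = {}
    for spec in config.variables:
        t = spec.transform
        if t == "hemoglobin":
            values[spec.name] = clinical.hemoglobin
        elif t == "blasts_cap20_div5":
            values[spec.name] = min(clinical.bm_blasts, 20.0) / 5.0
        elif t == "platelets_cap250_div100":
            values[spec.name] = min(clinical.platelets, 250.0) / 100.0
        elif t == "cyto_category":
            cat = cyto.ipssr_cyto_category
            values[spec.name] = None if cat is None else float(cat)
        elif t == "binary":
            values[spec.name] = features.values.get(spec.name)
        elif t == "residual_count":
            continue  # carried separately as a triple
        else:  # pragma: no cover - transform names are validated by config
            raise ScoringError(f"unknown transform {t!r} for {spec.name}")
    return TransformedVector(values=values, nres2=features.nres2)


def compute_score(
    x: TransformedVector,
    config: CoefficientTable,
    scenario: Scenario = "mean",
) -> float:
    """Centered weighted sum under one missing-data scenario."""
    if scenario not in SCENARIOS:
        raise ScoringError(f"unknown scenario {scenario!r}")
    total = 0.0
    for spec in config.variables:
        if spec.transform == "residual_count":
            low, expected, high = x.nres2
            value = {"best": low, "mean": expected, "worst": high}[scenario]
            total += spec.contribution(value)
            continue
        value = x.values.get(spec.name)
        if value is not None:
            total += spec.contribution(value)
        elif scenario == "best":
            total += spec.contribution(spec.best_value)
        elif scenario == "worst":
            total += spec.contribution(spec.worst_value)
        # mean: impute the centering mean -> contribution 0
    return total


def assign_category(score: float, config: CoefficientTable) -> str:
    """Bin a score into the six categories (upper bound inclusive)."""
    if not (score == score and abs(score) != float("inf")):
        raise ScoringError(f"non-finite score {score}")
    return config.category_labels[bisect_left(list(config.cutpoints), score)]


def score_patient(
    record: PatientRecord,
    config: CoefficientTable,
    tp53_mode: Tp53Mode = "wgs",
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
    force_unknown: Iterable[str] = (),
) -> RiskResult:
    """Full per-patient scoring: features -> transforms -> three scenarios.

    ``force_unknown`` masks config variables (by name) as if they had not
    been measured — the handle used by the missing-data sensitivity analyses.
    Masking ``NRES2`` discards all residual-gene information.
    """
    masked = frozenset(force_unknown)
    unknown_names = masked - set(config.variable_names)
    if unknown_names:
        raise ScoringError(f"cannot mask unknown variables: {sorted(unknown_names)}")

    features = build_features(record, config, tp53_mode, vaf_threshold)
    x = transform_variables(features, record.clinical, record.cytogenetics, config)

    values = dict(x.values)
    nres2 = x.nres2
    for name in masked:
        if name == NRES2:
            expected = min(2.0, sum(config.residual_prevalence.values()))
            nres2 = (0.0, expected, 2.0)
        else:
            values[name] = None
    x = TransformedVector(values=values, nres2=nres2)

    scores = {s: compute_score(x, config, s) for s in SCENARIOS}
    cats = {s: assign_category(scores[s], config) for s in SCENARIOS}
    return RiskResult(
        system="IPSSM",
        score_mean=scores["mean"],
        score_best=scores["best"],
        score_worst=scores["worst"],
        category_mean=cats["mean"],
        category_best=cats["best"],
        category_worst=cats["worst"],
        spread_consistent=cats["best"] == cats["worst"],
    )
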