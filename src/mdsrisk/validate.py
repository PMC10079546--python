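"""Cohort-level validation: category mix, restaging, concordance, sensitivity.

Reproduces, on any scored cohort, the analyses a score-validation study
reports: the distribution over the six molecular risk categories, the
cross-tabulation of clinical vs molecular staging (with the two moderate
molecular categories merged so both systems have five levels), Harrell's
c-index per system and endpoint on the common evaluable subset, the
missing-variable best/worst-case sensitivity, and the concordance between the
full (WGS-based) and the VAF-surrogate TP53 classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CoefficientTable, IPSSM_LABELS, IPSSR_LABELS
from .ipssm import RiskResult, score_patient
from .lesions import DEFAULT_VAF_THRESHOLD, classify_tp53
from .records import PatientRecord
from .survival import ConcordanceResult, harrell_c

#: Molecular categories with ML and MH merged, most to least favorable.
MERGED_IPSSM_LABELS = ("VL", "L", "Moderate", "H", "VH")

_MERGE = {"VL": "VL", "L": "L", "ML": "Moderate", "MH": "Moderate", "H": "H", "VH": "VH"}

ENDPOINTS = ("OS", "LFS", "LT")


def merge_moderate(category: str) -> str:
    return _MERGE[category]


def category_distribution(
    results: Iterable[RiskResult | str], labels: Sequence[str] = IPSSM_LABELS
) -> pd.Series:
    """Fraction of patients per category (mean scenario), in fixed label order."""
    cats = [r.category_mean if isinstance(r, RiskResult) else r for r in results]
    if not cats:
        raise ValueError("empty cohort")
    counts = pd.Series(cats).value_counts()
    frac = pd.Series([counts.get(lbl, 0) / len(cats) for lbl in labels], index=list(labels))
    return frac


@dataclass(frozen=True)
class RestagingTable:
    """Cross-tab of clinical (rows) vs merged molecular (columns) staging."""

    crosstab: pd.DataFrame
    n: int
    n_up: int
    n_down: int
    n_unchanged: int
    by_shift: dict[int, int]  # shift (molecular - clinical ordinal) -> count

    @property
    def n_up_gt1(self) -> int:
        return sum(c for s, c in self.by_shift.items() if s > 1)

    @property
    def n_down_gt1(self) -> int:
        return sum(c for s, c in self.by_shift.items() if s < -1)


def restage(ipssr_categories: Sequence[str], ipssm_categories: Sequence[str]) -> RestagingTable:
    """Compare per-patient staging between the two systems.

    The molecular ML and MH categories are merged into one "Moderate" level so
    both systems are 5-level ordinals; shift > 0 means up-staged by the
    molecular score.
    """
    if len(ipssr_categories) != len(ipssm_categories):
        raise ValueError("category vectors have different lengths")
    r_ord = {lbl: i for i, lbl in enumerate(IPSSR_LABELS)}
    m_ord = {lbl: i for i, lbl in enumerate(MERGED_IPSSM_LABELS)}
    merged = [merge_moderate(c) for c in ipssm_categories]

    table = pd.DataFrame(0, index=list(IPSSR_LABELS), columns=list(MERGED_IPSSM_LABELS))
    by_shift: dict[int, int] = {}
    for rc, mc in zip(ipssr_categories, merged):
        table.loc[rc, mc] += 1
        shift = m_ord[mc] - r_ord[rc]
        by_shift[shift] = by_shift.get(shift, 0) + 1
    n = len(merged)
    return RestagingTable(
        crosstab=table,
        n=n,
        n_up=sum(c for s, c in by_shift.items() if s > 0),
        n_down=sum(c for s, c in by_shift.items() if s < 0),
        n_unchanged=by_shift.get(0, 0),
        by_shift=dict(sorted(by_shift.items())),
    )


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    return {
        "OS": ("os_time", "os_event"),
        "LFS": ("lfs_time", "lfs_event"),
        "LT": ("lt_time", "lt_event"),
    }[endpoint]


def compare_c_index(
    scored: pd.DataFrame,
    endpoints: Sequence[str] = ENDPOINTS,
    predictor: str = "score",
) -> pd.DataFrame:
    """Harrell's c for both systems on the common evaluable subset.

    ``scored`` is the frame from :func:`mdsrisk.pipeline.score_cohort` with
    endpoint columns.  Patients without computable clinical points are dropped
    for *both* systems so the comparison is on the same patients.  For the
    transformation endpoint, death without transformation is treated as
    censoring (cause-specific concordance).  ``predictor`` selects the
    continuous score/points ("score") or the ordinal category index
    ("category").  A degenerate endpoint yields NaN with a note instead of
    failing the other endpoints.
    """
    if predictor not in ("score", "category"):
        raise ValueError(f"predictor must be 'score' or 'category', got {predictor!r}")
    sub = scored[scored["ipssr_points"].notna()].reset_index(drop=True)
    if predictor == "score":
        preds = {"IPSSM": sub["ipssm_score_mean"].to_numpy(), "IPSSR": sub["ipssr_points"].to_numpy()}
    else:
        m_ord = {lbl: i for i, lbl in enumerate(IPSSM_LABELS)}
        r_ord = {lbl: i for i, lbl in enumerate(IPSSR_LABELS)}
        preds = {
            "IPSSM": sub["ipssm_category_mean"].map(m_ord).to_numpy(float),
            "IPSSR": sub["ipssr_category"].map(r_ord).to_numpy(float),
        }
    rows = []
    for endpoint in endpoints:
        tcol, ecol = _endpoint_columns(endpoint)
        for system, p in preds.items():
            row = {"system": system, "endpoint": endpoint, "n": len(sub)}
            try:
                res = harrell_c(p, sub[tcol].to_numpy(), sub[ecol].to_numpy())
                row.update(
                    c=res.c,
                    n_comparable_pairs=res.n_comparable_pairs,
                    n_concordant=res.n_concordant,
                    n_tied_score=res.n_tied_score,
                    note="",
                )
            except ValueError as exc:
                row.update(c=np.nan, n_comparable_pairs=0, n_concordant=0, n_tied_score=0, note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_missing(
    records: Sequence[PatientRecord],
    config: CoefficientTable,
    masked_variables: Iterable[str],
    tp53_mode: str = "wgs",
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> tuple[float, pd.DataFrame]:
    """Re-score with the given variables forced unknown.

    Returns the fraction of patients whose best- and worst-case categories
    agree, plus the per-patient spread table.
    """
    masked = frozenset(masked_variables)
    rows = []
    for r in records:
        res = score_patient(r, config, tp53_mode, vaf_threshold, force_unknown=masked)
        rows.append(
            {
                "patient_id": r.patient_id,
                "category_best": res.category_best,
                "category_worst": res.category_worst,
                "consistent": res.spread_consistent,
            }
        )
    df = pd.DataFrame(rows)
    frac = float(df["consistent"].mean()) if len(df) else float("nan")
    return frac, df


def surrogate_concordance(
    records: Sequence[PatientRecord],
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> pd.DataFrame:
    """Patients whose definite-multihit TP53 status differs between the full
    (WGS) classification and the VAF-surrogate classification.

    Direction: ``missed`` — multihit by WGS evidence but not by the surrogate
    (typically CN-LOH with sub-threshold VAF); ``gained`` — multihit only
    under the surrogate (high VAF without documented second hit).
    """
    rows = []
    for r in records:
        calls = r.calls_for("TP53")
        wgs = classify_tp53(calls, r.cytogenetics, "wgs")
        sur = classify_tp53(calls, r.cytogenetics, "vaf_surrogate", vaf_threshold)
        if wgs.is_multihit == sur.is_multihit:
            continue
        rows.append(
            {
                "patient_id": r.patient_id,
                "direction": "missed" if wgs.is_multihit else "gained",
                "wgs_classification": wgs.classification,
                "surrogate_classification": sur.classification,
                "n_mutations": wgs.n_mutations,
                "max_vaf": wgs.max_vaf,
                "mechanism_wgs": wgs.mechanism,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "direction", "wgs_classification", "surrogate_classification",
            "n_mutations", "max_vaf", "mechanism_wgs",
        ],
    )


@dataclass
class CohortValidationReport:
    """Everything the validation emits, machine- and human-readable."""

    n_patients: int
    n_ipssr_evaluable: int
    n_spread_inconsistent: int
    distribution: pd.Series
    restaging: RestagingTable | None
    c_index: pd.DataFrame
    sensitivity: dict[str, float] = field(default_factory=dict)
    surrogate_discordance: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out: dict = {
            "n_patients": self.n_patients,
            "n_ipssr_evaluable": self.n_ipssr_evaluable,
            "n_spread_inconsistent": self.n_spread_inconsistent,
            "category_distribution": {k: round(float(v), 6) for k, v in self.distribution.items()},
        }
        if self.restaging is not None:
            rt = self.restaging
            out["restaging"] = {
                "n": rt.n,
                "up": rt.n_up,
                "down": rt.n_down,
                "unchanged": rt.n_unchanged,
                "up_more_than_one": rt.n_up_gt1,
                "down_more_than_one": rt.n_down_gt1,
                "by_shift": {str(k): v for k, v in rt.by_shift.items()},
                "crosstab": {r: rt.crosstab.loc[r].to_dict() for r in rt.crosstab.index},
            }
        else:
            out["restaging"] = None
        out["c_index"] = [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            for row in self.c_index.to_dict("records")
        ]
        out["sensitivity_consistent_fraction"] = self.sensitivity
        if self.surrogate_discordance is not None:
            out["tp53_surrogate_discordant"] = self.surrogate_discordance.to_dict("records")
        return out

    def to_text(self) -> str:
        lines = [
            f"cohort: {self.n_patients} patients "
            f"({self.n_ipssr_evaluable} with computable clinical score)",
            "",
            "molecular category distribution (mean scenario):",
        ]
        for lbl, frac in self.distribution.items():
            lines.append(f"  {lbl:>3}: {100 * frac:5.1f}%")
        if self.n_spread_inconsistent:
            lines.append(
                f"  ({self.n_spread_inconsistent} patients with scenario-dependent category; "
                "mean scenario used)"
            )
        if self.restaging is not None:
            rt = self.restaging
            lines += [
                "",
                f"restaging vs clinical score (n={rt.n}, moderate categories merged):",
                f"  up-staged:   {rt.n_up} ({100 * rt.n_up / rt.n:.1f}%), "
                f"of which >1 level: {rt.n_up_gt1}",
                f"  down-staged: {rt.n_down} ({100 * rt.n_down / rt.n:.1f}%), "
                f"of which >1 level: {rt.n_down_gt1}",
                f"  unchanged:   {rt.n_unchanged} ({100 * rt.n_unchanged / rt.n:.1f}%)",
            ]
        else:
            lines += ["", "restaging: clinical score not computable for this cohort"]
        lines += ["", "Harrell's c-index (common evaluable subset):"]
        for _, row in self.c_index.iterrows():
            c_txt = "n/a" if np.isnan(row["c"]) else f"{row['c']:.2f}"
            note = f"  [{row['note']}]" if row.get("note") else ""
            lines.append(f"  {row['system']:>5} {row['endpoint']:>3}: {c_txt}{note}")
        if self.sensitivity:
            lines += ["", "missing-variable sensitivity (fraction of consistent categories):"]
            for name, frac in self.sensitivity.items():
                lines.append(f"  {name}: {100 * frac:.1f}%")
        if self.surrogate_discordance is not None:
            lines += [
                "",
                f"TP53 surrogate vs WGS: {len(self.surrogate_discordance)} discordant patient(s)",
            ]
            for _, row in self.surrogate_discordance.iterrows():
                lines.append(
                    f"  {row['patient_id']}: {row['direction']} "
                    f"(VAF {row['max_vaf']}, WGS mechanism {row['mechanism_wgs']})"
                )
        return "\n".join(lines) + "\n"

    def write(self, json_path, text_path) -> None:
        from pathlib import Path

        Path(json_path).write_text(
            json.dumps(self.to_json_dict(), indent=2) + "\n", encoding="utf-8"
        )
        Path(text_path).write_text(self.to_text(), encoding="utf-8")


def build_report(
    records: Sequence[PatientRecord],
    scored: pd.DataFrame,
    config: CoefficientTable,
    endpoints: Sequence[str] = ENDPOINTS,
    predictor: str = "score",
    sensitivity_sets: Mapping[str, Iterable[str]] | None = None,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> CohortValidationReport:
    """Assemble the full validation report for a scored cohort.

    ``sensitivity_sets`` maps a label to the variable set to mask; the default
    probes the partial-tandem-duplication flag and the residual-gene count.
    """
    distribution = category_distribution(scored["ipssm_category_mean"].tolist())
    evaluable = scored[scored["ipssr_points"].notna()]
    restaging = None
    if len(evaluable):
        restaging = restage(
            evaluable["ipssr_category"].tolist(), evaluable["ipssm_category_mean"].tolist()
        )
    has_endpoints = "os_time" in scored.columns
    if has_endpoints:
        cidx = compare_c_index(scored, endpoints=endpoints, predictor=predictor)
    else:
        cidx = pd.DataFrame(
            columns=["system", "endpoint", "n", "c", "n_comparable_pairs", "n_concordant", "n_tied_score", "note"]
        )
    if sensitivity_sets is None:
        sensitivity_sets = {"MLL_PTD": ["MLL_PTD"], "residual_genes": ["NRES2"]}
    sens = {
        label: sensitivity_missing(records, config, variables)[0]
        for label, variables in sensitivity_sets.items()
    }
    return CohortValidationReport(
        n_patients=len(scored),
        n_ipssr_evaluable=len(evaluable),
        n_spread_inconsistent=int((~scored["spread_consistent"]).sum()),
        distribution=distribution,
        restaging=restaging,
        c_index=cidx,
        sensitivity=sens,
        surrogate_discordance=surrogate_concordance(records, vaf_threshold),
    )
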