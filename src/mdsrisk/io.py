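"""Cohort table I/O.

Four tab-separated inputs (clinical, cytogenetics, mutations, endpoints) keyed
by ``patient_id``, one output score table, all UTF-8 with '.' decimals and no
thousands separators.  Tri-state flags are encoded ``yes``/``no``/empty
(empty = unknown).  Gene symbols are upper-cased on ingest.

The optional ``assessed_genes`` column of the clinical table carries the
per-patient sequencing panel as a comma-separated gene list; an empty cell or
``*`` (or an absent column) means every gene was assessed.  Genes outside the
panel are *not assessed* — distinct from assessed-and-unmutated, which the
scenario logic of the molecular score relies on.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    ClinicalPanel,
    CytogeneticsProfile,
    EndpointData,
    MutationCall,
    PatientRecord,
    RecordError,
    Tri,
)

CLINICAL_COLUMNS = ("patient_id", "bm_blasts", "hemoglobin", "platelets", "anc")
CYTO_COLUMNS = (
    "patient_id",
    "ipssr_cyto_category",
    "del5q",
    "minus7_or_del7q",
    "del17p",
    "complex_karyotype",
    "tp53_cnloh",
)
MUTATION_COLUMNS = ("patient_id", "gene", "vaf", "mutation_type")
ENDPOINT_COLUMNS = (
    "patient_id",
    "os_time",
    "os_event",
    "lfs_time",
    "lfs_event",
    "lt_time",
    "lt_event",
    "death_without_lt",
)

SCORE_COLUMNS = (
    "patient_id",
    "ipssm_score_mean",
    "ipssm_score_best",
    "ipssm_score_worst",
    "ipssm_category_mean",
    "ipssm_category_best",
    "ipssm_category_worst",
    "ipssr_points",
    "ipssr_category",
)


class CohortReadError(ValueError):
    """Input tables are malformed; carries every collected row-level message."""

    def __init__(self, issues: Sequence[str]):
        self.issues = list(issues)
        super().__init__("cohort validation failed:\n" + "\n".join(self.issues))


def _read_tsv(path: str | Path, mandatory: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise CohortReadError([f"{path}: missing mandatory column(s) {missing}"])
    return df


def _parse_float(text: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    value = float(text)  # raises ValueError on locale-style separators
    if math.isnan(value):
        return None
    return value


def _parse_tri(text: str) -> Tri:
    text = text.strip().lower()
    if text in ("", "na", "unknown"):
        return None
    if text in ("yes", "1", "true"):
        return True
    if text in ("no", "0", "false"):
        return False
    raise ValueError(f"cannot parse tri-state value {text!r}")


def _format_tri(value: Tri) -> str:
    return "" if value is None else ("yes" if value else "no")


def read_cohort(
    clinical: str | Path,
    cytogenetics: str | Path,
    mutations: str | Path,
    endpoints: str | Path | None = None,
) -> list[PatientRecord]:
    """Read and cross-validate the cohort tables into one record per patient.

    Row-level problems are collected (with file and line numbers; the header
    is line 1) and raised together as :class:`CohortReadError`.
    """
    issues: list[str] = []
    clin = _read_tsv(clinical, CLINICAL_COLUMNS)
    cyto = _read_tsv(cytogenetics, CYTO_COLUMNS)
    muts = _read_tsv(mutations, MUTATION_COLUMNS)
    ends = _read_tsv(endpoints, ENDPOINT_COLUMNS) if endpoints is not None else None

    # -- clinical: defines the patient set --------------------------------
    panels: dict[str, ClinicalPanel] = {}
    assessed: dict[str, frozenset[str] | None] = {}
    for i, row in clin.iterrows():
        line = i + 2
        pid = row["patient_id"].strip()
        if not pid:
            issues.append(f"{clinical}:{line}: empty patient_id")
            continue
        if pid in panels:
            issues.append(f"{clinical}:{line}: duplicate patient id {pid}")
            continue
        try:
            blasts = _parse_float(row["bm_blasts"])
            hb = _parse_float(row["hemoglobin"])
            plt = _parse_float(row["platelets"])
            anc = _parse_float(row["anc"])
            if blasts is None or hb is None or plt is None:
                raise ValueError("blasts, hemoglobin and platelets are mandatory")
            panels[pid] = ClinicalPanel(bm_blasts=blasts, hemoglobin=hb, platelets=plt, anc=anc)
        except (ValueError, RecordError) as exc:
            issues.append(f"{clinical}:{line}: {exc}")
            continue
        panel_text = str(row.get("assessed_genes", "")).strip()
        if panel_text in ("", "*"):
            assessed[pid] = None
        else:
            assessed[pid] = frozenset(g.strip().upper() for g in panel_text.split(",") if g.strip())

    # -- cytogenetics ------------------------------------------------------
    cyto_by_pid: dict[str, CytogeneticsProfile] = {}
    for i, row in cyto.iterrows():
        line = i + 2
        pid = row["patient_id"].strip()
        if pid not in panels:
            issues.append(f"{cytogenetics}:{line}: patient {pid} not in clinical table")
            continue
        try:
            cat = _parse_float(row["ipssr_cyto_category"])
            cyto_by_pid[pid] = CytogeneticsProfile(
                ipssr_cyto_category=None if cat is None else int(cat),
                del5q=_parse_tri(row["del5q"]),
                minus7_or_del7q=_parse_tri(row["minus7_or_del7q"]),
                del17p=_parse_tri(row["del17p"]),
                complex_karyotype=_parse_tri(row["complex_karyotype"]),
                tp53_cnloh=_parse_tri(row["tp53_cnloh"]),
            )
        except (ValueError, RecordError) as exc:
            issues.append(f"{cytogenetics}:{line}: {exc}")

    # -- mutations ---------------------------------------------------------
    calls_by_pid: dict[str, list[MutationCall]] = {pid: [] for pid in panels}
    for i, row in muts.iterrows():
        line = i + 2
        pid = row["patient_id"].strip()
        if pid not in panels:
            issues.append(f"{mutations}:{line}: patient {pid} not in clinical table")
            continue
        try:
            mtype = row["mutation_type"].strip().upper() or "SNV"
            calls_by_pid[pid].append(
                MutationCall(
                    patient_id=pid,
                    gene=row["gene"].strip().upper(),
                    vaf=_parse_float(row["vaf"]),
                    mutation_type=mtype,
                )
            )
        except (ValueError, RecordError) as exc:
            issues.append(f"{mutations}:{line}: {exc}")

    # -- endpoints ---------------------------------------------------------
    ends_by_pid: dict[str, EndpointData] = {}
    if ends is not None:
        for i, row in ends.iterrows():
            line = i + 2
            pid = row["patient_id"].strip()
            if pid not in panels:
                issues.append(f"{endpoints}:{line}: patient {pid} not in clinical table")
                continue
            try:
                vals = {c: _parse_float(row[c]) for c in ENDPOINT_COLUMNS[1:]}
                if any(v is None for v in vals.values()):
                    raise ValueError("all endpoint columns are mandatory")
                ends_by_pid[pid] = EndpointData(
                    os_time=vals["os_time"],
                    os_event=int(vals["os_event"]),
                    lfs_time=vals["lfs_time"],
                    lfs_event=int(vals["lfs_event"]),
                    lt_time=vals["lt_time"],
                    lt_event=int(vals["lt_event"]),
                    death_without_lt=int(vals["death_without_lt"]),
                )
            except (ValueError, RecordError) as exc:
                issues.append(f"{endpoints}:{line}: {exc}")

    records: list[PatientRecord] = []
    for pid, panel in panels.items():
        try:
            records.append(
                PatientRecord(
                    patient_id=pid,
                    clinical=panel,
                    cytogenetics=cyto_by_pid.get(pid, CytogeneticsProfile()),
                    mutations=tuple(calls_by_pid[pid]),
                    endpoints=ends_by_pid.get(pid),
                    assessed_genes=assessed[pid],
                )
            )
        except RecordError as exc:
            issues.append(f"patient {pid}: {exc}")

    if issues:
        raise CohortReadError(issues)
    return records


# ---------------------------------------------------------------------------
# writing


def _fmt(value: float | None, decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def write_cohort(records: Iterable[PatientRecord], outdir: str | Path) -> dict[str, Path]:
    """Write the four cohort tables; returns the paths keyed by table name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = list(records)

    paths = {
        "clinical": outdir / "clinical.tsv",
        "cytogenetics": outdir / "cytogenetics.tsv",
        "mutations": outdir / "mutations.tsv",
        "endpoints": outdir / "endpoints.tsv",
    }

    clin_rows = []
    cyto_rows = []
    mut_rows = []
    end_rows = []
    for r in records:
        clin_rows.append(
            {
                "patient_id": r.patient_id,
                "bm_blasts": _fmt(r.clinical.bm_blasts, 1),
                "hemoglobin": _fmt(r.clinical.hemoglobin, 1),
                "platelets": _fmt(r.clinical.platelets, 0),
                "anc": _fmt(r.clinical.anc, 2),
                "assessed_genes": "" if r.assessed_genes is None else ",".join(sorted(r.assessed_genes)),
            }
        )
        c = r.cytogenetics
        cyto_rows.append(
            {
                "patient_id": r.patient_id,
                "ipssr_cyto_category": "" if c.ipssr_cyto_category is None else str(c.ipssr_cyto_category),
                "del5q": _format_tri(c.del5q),
                "minus7_or_del7q": _format_tri(c.minus7_or_del7q),
                "del17p": _format_tri(c.del17p),
                "complex_karyotype": _format_tri(c.complex_karyotype),
                "tp53_cnloh": _format_tri(c.tp53_cnloh),
            }
        )
        for m in r.mutations:
            mut_rows.append(
                {
                    "patient_id": r.patient_id,
                    "gene": m.gene,
                    "vaf": _fmt(m.vaf, 1),
                    "mutation_type": m.mutation_type,
                }
            )
        if r.endpoints is not None:
            e = r.endpoints
            end_rows.append(
                {
                    "patient_id": r.patient_id,
                    "os_time": _fmt(e.os_time, 2),
                    "os_event": str(e.os_event),
                    "lfs_time": _fmt(e.lfs_time, 2),
                    "lfs_event": str(e.lfs_event),
                    "lt_time": _fmt(e.lt_time, 2),
                    "lt_event": str(e.lt_event),
                    "death_without_lt": str(e.death_without_lt),
                }
            )

    pd.DataFrame(clin_rows, columns=list(CLINICAL_COLUMNS) + ["assessed_genes"]).to_csv(
        paths["clinical"], sep="\t", index=False
    )
    pd.DataFrame(cyto_rows, columns=list(CYTO_COLUMNS)).to_csv(paths["cytogenetics"], sep="\t", index=False)
    pd.DataFrame(mut_rows, columns=list(MUTATION_COLUMNS)).to_csv(paths["mutations"], sep="\t", index=False)
    pd.DataFrame(end_rows, columns=list(ENDPOINT_COLUMNS)).to_csv(paths["endpoints"], sep="\t", index=False)
    return paths


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the per-patient score table (fixed column order, 4-decimal scores).

    ``scores`` is the frame produced by :func:`mdsrisk.pipeline.score_cohort`;
    IPSS-R columns are left empty where the score was not computable.
    """
    out = pd.DataFrame()
    out["patient_id"] = scores["patient_id"]
    for col in ("ipssm_score_mean", "ipssm_score_best", "ipssm_score_worst"):
        out[col] = scores[col].map(lambda v: _fmt(v, 4))
    for col in ("ipssm_category_mean", "ipssm_category_best", "ipssm_category_worst"):
        out[col] = scores[col]
    out["ipssr_points"] = scores["ipssr_points"].map(
        lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.1f}"
    )
    out["ipssr_category"] = scores["ipssr_category"].fillna("")
    out = out[list(SCORE_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)
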