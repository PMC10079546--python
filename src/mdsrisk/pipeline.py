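"""Cohort-level scoring: one tidy row per patient with both systems."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CoefficientTable, IpssrPointTable
from .ipssm import score_patient
from .ipssr import ipssr_result
from .lesions import DEFAULT_VAF_THRESHOLD, Tp53Mode
from .records import PatientRecord


def score_cohort(
    records: Sequence[PatientRecord],
    config: CoefficientTable,
    ipssr_table: IpssrPointTable,
    tp53_mode: Tp53Mode = "wgs",
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
    force_unknown: Iterable[str] = (),
) -> pd.DataFrame:
    """Score every patient under both systems.

    Returns a DataFrame with the molecular score per scenario, its categories,
    the clinical points/category (NaN/None where not computable) and, when
    endpoints are present, the three endpoint columns used downstream.
    """
    rows = []
    for r in records:
        m = score_patient(r, config, tp53_mode, vaf_threshold, force_unknown)
        pts, cat = ipssr_result(r, ipssr_table)
        row = {
            "patient_id": r.patient_id,
            "ipssm_score_mean": m.score_mean,
            "ipssm_score_best": m.score_best,
            "ipssm_score_worst": m.score_worst,
            "ipssm_category_mean": m.category_mean,
            "ipssm_category_best": m.category_best,
            "ipssm_category_worst": m.category_worst,
            "spread_consistent": m.spread_consistent,
            "ipssr_points": np.nan if pts is None else pts,
            "ipssr_category": cat,
        }
        if r.endpoints is not None:
            e = r.endpoints
            row.update(
                os_time=e.os_time,
                os_event=e.os_event,
                lfs_time=e.lfs_time,
                lfs_event=e.lfs_event,
                lt_time=e.lt_time,
                lt_event=e.lt_event,
                death_without_lt=e.death_without_lt,
            )
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            {
                "patient_id": pd.Series(dtype=str),
                "ipssm_score_mean": pd.Series(dtype=float),
                "ipssm_score_best": pd.Series(dtype=float),
                "ipssm_score_worst": pd.Series(dtype=float),
                "ipssm_category_mean": pd.Series(dtype=str),
                "ipssm_category_best": pd.Series(dtype=str),
                "ipssm_category_worst": pd.Series(dtype=str),
                "spread_consistent": pd.Series(dtype=bool),
                "ipssr_points": pd.Series(dtype=float),
                "ipssr_category": pd.Series(dtype=str),
            }
        )
    return pd.DataFrame(rows)
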