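"""Clinical risk score (IPSS-R): point sums over five inputs, five categories.

IPSS-R needs the absolute neutrophil count, so a patient with unknown ANC (or
any other required input) gets a first-class "not computable" result rather
than an exception — validation analyses restrict themselves to the evaluable
subset exactly the way a registry analysis would.
"""

from __future__ import annotations

from bisect import bisect_left

from .config import IpssrPointTable
from .records import ClinicalPanel, CytogeneticsProfile, PatientRecord


def derive_cyto_category(cyto: CytogeneticsProfile) -> int | None:
    """Best-effort 0-4 category from the lesion flags.

    Only the abnormalities encoded in :class:`CytogeneticsProfile` can be
    mapped; anything else requires the precomputed category and yields None.
    Mapping used: no encoded abnormality -> good (normal karyotype bucket);
    isolated del(5q) -> good; -7/del(7q) -> poor; complex -> very poor;
    isolated del(17p) -> intermediate.
    """
    if cyto.ipssr_cyto_category is not None:
        return cyto.ipssr_cyto_category
    flags = (cyto.del5q, cyto.minus7_or_del7q, cyto.del17p, cyto.complex_karyotype)
    if any(f is None for f in flags):
        return None
    if cyto.complex_karyotype:
        return 4
    if cyto.minus7_or_del7q:
        return 3
    if cyto.del17p:
        return 2
    return 1  # normal or isolated del(5q): good


def ipssr_points(
    clinical: ClinicalPanel,
    cyto: CytogeneticsProfile,
    table: IpssrPointTable,
) -> float | None:
    """Total IPSS-R points, or None when a required input is unknown."""
    category = derive_cyto_category(cyto)
    if category is None or clinical.anc is None:
        return None
    return (
        table.cyto_points[category]
        + table.blasts.points(clinical.bm_blasts)
        + table.hemoglobin.points(clinical.hemoglobin)
        + table.platelets.points(clinical.platelets)
        + table.anc.points(clinical.anc)
    )


def ipssr_category(points: float, table: IpssrPointTable) -> str:
    """Bin total points into the five categories (upper bound inclusive)."""
    return table.category_labels[bisect_left(list(table.category_cutpoints), points)]


def ipssr_result(
    record: PatientRecord, table: IpssrPointTable
) -> tuple[float | None, str | None]:
    """(points, category) for one patient; (None, None) when not computable."""
    pts = ipssr_points(record.clinical, record.cytogenetics, table)
    if pts is None:
        return None, None
    return pts, ipssr_category(pts, table)
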