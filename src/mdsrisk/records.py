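"""Per-patient domain records: clinical panel, cytogenetics, mutations, endpoints.

Missingness is first-class throughout.  Tri-state flags are ``True``/``False``/
``None`` (yes / no / unknown), and gene mutation status distinguishes
*assessed-and-unmutated* from *not assessed* — the scenario logic of the
molecular score treats those very differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

Tri = Optional[bool]

MUTATION_TYPES = ("SNV", "ITD", "TKD", "PTD")


class RecordError(ValueError):
    """A per-patient record violates one of its invariants."""


@dataclass(frozen=True)
class MutationCall:
    """One oncogenic mutation call for one patient.

    ``vaf`` is the variant allele frequency in percent (0-100) or ``None``
    when not reported.  ``mutation_type`` is ``SNV`` for substitutions and
    indels; ``ITD``/``TKD`` are only valid on FLT3 and ``PTD`` only on KMT2A.
    """

    patient_id: str
    gene: str
    vaf: float | None = None
    mutation_type: str = "SNV"

    def __post_init__(self) -> None:
        if self.mutation_type not in MUTATION_TYPES:
            raise RecordError(
                f"{self.patient_id}/{self.gene}: unknown mutation type {self.mutation_type!r}"
            )
        if self.mutation_type == "PTD" and self.gene != "KMT2A":
            raise RecordError(f"{self.patient_id}: PTD call only valid for KMT2A, not {self.gene}")
        if self.mutation_type in ("ITD", "TKD") and self.gene != "FLT3":
            raise RecordError(
                f"{self.patient_id}: {self.mutation_type} call only valid for FLT3, not {self.gene}"
            )
        if self.vaf is not None and not (0.0 <= self.vaf <= 100.0):
            raise RecordError(f"{self.patient_id}/{self.gene}: VAF {self.vaf} outside [0,100]")


@dataclass(frozen=True)
class CytogeneticsProfile:
    """Cytogenetic inputs: IPSS-R category plus the lesion flags the molecular
    score needs (del(5q), -7/del(7q), del(17p), complex karyotype, TP53-locus
    copy-neutral LOH).  All flags are tri-state."""

    ipssr_cyto_category: int | None = None  # 0 very good .. 4 very poor
    del5q: Tri = None
    minus7_or_del7q: Tri = None
    del17p: Tri = None
    complex_karyotype: Tri = None
    tp53_cnloh: Tri = None

    def __post_init__(self) -> None:
        cat = self.ipssr_cyto_category
        if cat is not None and cat not in (0, 1, 2, 3, 4):
            raise RecordError(f"cytogenetic category {cat} outside 0-4")


@dataclass(frozen=True)
class ClinicalPanel:
    """Blood/marrow values: blasts %, hemoglobin g/dl, platelets and ANC x10^9/l.

    ANC is optional — it is required by the clinical score but not by the
    molecular one."""

    bm_blasts: float
    hemoglobin: float
    platelets: float
    anc: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bm_blasts <= 100.0:
            raise RecordError(f"bone-marrow blasts {self.bm_blasts}% outside [0,100]")
        if not 0.0 < self.hemoglobin <= 25.0:
            raise RecordError(f"hemoglobin {self.hemoglobin} g/dl outside (0,25]")
        if self.platelets < 0:
            raise RecordError(f"platelets {self.platelets} negative")
        if self.anc is not None and self.anc < 0:
            raise RecordError(f"ANC {self.anc} negative")


@dataclass(frozen=True)
class EndpointData:
    """Right-censored endpoints in months: overall survival (OS), leukemia-free
    survival (LFS) and leukemic transformation (LT).  LT carries an explicit
    death-without-transformation indicator for competing-risk analysis."""

    os_time: float
    os_event: int
    lfs_time: float
    lfs_event: int
    lt_time: float
    lt_event: int
    death_without_lt: int = 0

    def __post_init__(self) -> None:
        for name in ("os_time", "lfs_time", "lt_time"):
            if getattr(self, name) < 0:
                raise RecordError(f"{name} negative")
        for name in ("os_event", "lfs_event", "lt_event", "death_without_lt"):
            if getattr(self, name) not in (0, 1):
                raise RecordError(f"{name} must be 0 or 1")
        if self.lt_event and self.death_without_lt:
            raise RecordError("LT event and death-without-LT cannot both be 1")


@dataclass(frozen=True)
class PatientRecord:
    """All inputs for one patient.

    ``assessed_genes`` lists the genes covered by the sequencing panel;
    ``None`` means every gene was assessed.  A gene outside the panel has
    unknown mutation status and must not carry calls.
    """

    patient_id: str
    clinical: ClinicalPanel
    cytogenetics: CytogeneticsProfile
    mutations: tuple[MutationCall, ...] = ()
    endpoints: EndpointData | None = None
    assessed_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for call in self.mutations:
            if call.patient_id != self.patient_id:
                raise RecordError(
                    f"mutation call for {call.patient_id} attached to record {self.patient_id}"
                )
            if self.assessed_genes is not None and call.gene not in self.assessed_genes:
                raise RecordError(
                    f"{self.patient_id}: call in {call.gene} but gene marked not assessed"
                )

    # -- gene-level views -------------------------------------------------

    def calls_for(self, gene: str) -> tuple[MutationCall, ...]:
        return tuple(c for c in self.mutations if c.gene == gene)

    def is_assessed(self, gene: str) -> bool:
        return self.assessed_genes is None or gene in self.assessed_genes

    def gene_status(self, gene: str) -> Tri:
        """True = mutated, False = assessed and unmutated, None = not assessed."""
        if self.calls_for(gene):
            return True
        return False if self.is_assessed(gene) else None


def check_unique_ids(records: Iterable[PatientRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.patient_id in seen:
            raise RecordError(f"duplicate patient id {r.patient_id}")
        seen.add(r.patient_id)
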