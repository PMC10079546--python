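"""Lesion interpretation: derive the molecular feature vector from raw calls.

Three derivations carry the prognostic weight of the molecular score and are
implemented here:

* **TP53 allelic state** — *multihit* (biallelic) means >=2 mutations, or one
  mutation combined with del(17p) or with copy-neutral LOH at the TP53 locus.
  Panel assays often cannot see CN-LOH; a single mutation with a high VAF
  (default > 55 %) is the accepted surrogate, exposed as ``vaf_surrogate``
  mode.
* **SF3B1 subtypes** — SF3B1 with isolated del(5q) (``sf3b1_5q``), SF3B1
  without del(5q) and without co-mutations in a configured exclusion set
  (``sf3b1_alpha``), everything else mutated (``sf3b1_other``).
* **Residual-gene count** — number of mutated low-weight genes, capped at 2,
  carried as a [low, high] range plus an expected value when some residual
  genes were not assessed.

Unknown inputs never silently default: whenever an unknown flag or an
unassessed gene could change the answer, the classification itself becomes
unknown (or a set of possible classes) and is resolved downstream by the
best/worst-case scenario machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from .config import CoefficientTable
from .records import CytogeneticsProfile, MutationCall, PatientRecord, Tri

Tp53Mode = Literal["wgs", "vaf_surrogate"]

DEFAULT_VAF_THRESHOLD = 55.0

SF3B1_CLASSES = ("none", "sf3b1_5q", "sf3b1_alpha", "sf3b1_other")


@dataclass(frozen=True)
class Tp53State:
    """TP53 allelic state with the evidence trail.

    ``classification`` is ``wildtype``/``monoallelic``/``multihit`` or
    ``unknown`` when an unknown del(17p)/CN-LOH flag is the deciding factor.
    ``mechanism`` records how multihit status was reached, with precedence
    two_mutations > mutation_plus_deletion > mutation_plus_cnloh >
    vaf_surrogate (reporting only; classification is unaffected).
    """

    n_mutations: int
    max_vaf: float | None
    del17p: Tri
    cnloh: Tri
    classification: str  # wildtype | monoallelic | multihit | unknown
    mechanism: str  # none | two_mutations | mutation_plus_deletion | mutation_plus_cnloh | vaf_surrogate

    @property
    def is_multihit(self) -> bool:
        return self.classification == "multihit"


def classify_tp53(
    calls: Iterable[MutationCall],
    cyto: CytogeneticsProfile,
    mode: Tp53Mode = "wgs",
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> Tp53State:
    """Classify the TP53 locus as wildtype / monoallelic / multihit.

    ``wgs`` mode uses the full evidence (mutations, del(17p), CN-LOH).
    ``vaf_surrogate`` mode emulates a panel assay: CN-LOH is treated as
    unobservable and a single mutation with VAF strictly above
    ``vaf_threshold`` counts as multihit instead.
    """
    if not (50.0 < vaf_threshold <= 100.0):
        raise ValueError(f"vaf_threshold must be in (50, 100], got {vaf_threshold}")
    calls = [c for c in calls]
    if any(c.gene != "TP53" for c in calls):
        raise ValueError("classify_tp53 expects TP53 calls only")
    n = len(calls)
    vafs = [c.vaf for c in calls if c.vaf is not None]
    max_vaf = max(vafs) if vafs else None
    cnloh: Tri = None if mode == "vaf_surrogate" else cyto.tp53_cnloh
    del17p = cyto.del17p

    if n == 0:
        # deletion or CN-LOH alone is not multihit
        return Tp53State(0, None, del17p, cnloh, "wildtype", "none")

    if n >= 2:
        return Tp53State(n, max_vaf, del17p, cnloh, "multihit", "two_mutations")

    # single mutation: check the second-hit evidence in precedence order
    if del17p is True:
        return Tp53State(n, max_vaf, del17p, cnloh, "multihit", "mutation_plus_deletion")
    if cnloh is True:
        return Tp53State(n, max_vaf, del17p, cnloh, "multihit", "mutation_plus_cnloh")
    if mode == "vaf_surrogate" and max_vaf is not None and max_vaf > vaf_threshold:
        return Tp53State(n, max_vaf, del17p, cnloh, "multihit", "vaf_surrogate")

    # no positive second hit; unknown flags are deciding if they could flip this
    undecided = del17p is None or (mode == "wgs" and cnloh is None)
    if undecided:
        return Tp53State(n, max_vaf, del17p, cnloh, "unknown", "none")
    return Tp53State(n, max_vaf, del17p, cnloh, "monoallelic", "none")


def _sf3b1_concrete(del5q: bool, minus7: bool, complex_k: bool, comut: bool) -> str:
    if del5q and not minus7 and not complex_k:
        return "sf3b1_5q"
    if not del5q and not comut:
        return "sf3b1_alpha"
    return "sf3b1_other"


def classify_sf3b1(
    record: PatientRecord,
    exclusion: Iterable[str] = ("BCOR", "BCORL1", "NRAS", "RUNX1", "SRSF2", "STAG2"),
) -> frozenset[str]:
    """Return the set of possible SF3B1 subtypes for a patient.

    A singleton set means the class is determined.  Unknown del(5q)/-7/complex
    flags or unassessed exclusion-set genes widen the set to every class they
    could produce; scenario scoring consumes the ambiguity.
    """
    status = record.gene_status("SF3B1")
    if status is False:
        return frozenset({"none"})
    if status is None:
        return frozenset(SF3B1_CLASSES)

    cyto = record.cytogenetics
    statuses = [record.gene_status(g) for g in exclusion]
    if any(s is True for s in statuses):
        comut_opts: tuple[bool, ...] = (True,)
    elif all(s is False for s in statuses):
        comut_opts = (False,)
    else:
        comut_opts = (False, True)

    def options(flag: Tri) -> tuple[bool, ...]:
        return (False, True) if flag is None else (bool(flag),)

    possible = {
        _sf3b1_concrete(d5, m7, cx, cm)
        for d5, m7, cx, cm in itertools.product(
            options(cyto.del5q),
            options(cyto.minus7_or_del7q),
            options(cyto.complex_karyotype),
            comut_opts,
        )
    }
    return frozenset(possible)


@dataclass(frozen=True)
class MolecularFeatures:
    """Derived gene variables for the molecular score.

    ``values`` maps every gene-derived config variable to 0/1, or ``None``
    when unknown.  The residual-gene count is carried as
    ``(low, expected, high)``: best-case observed count, expected count under
    the configured per-gene prevalences, and worst-case count, all capped
    at 2.  The triple collapses to a single value when all residual genes
    were assessed.
    """

    values: Mapping[str, float | None]
    nres2: tuple[float, float, float]
    sf3b1_class: frozenset[str]
    tp53: Tp53State

    @property
    def nres2_known(self) -> bool:
        return self.nres2[0] == self.nres2[2]


def _binary_from_class(possible: frozenset[str], cls: str) -> float | None:
    """1 if the class is certain, 0 if impossible, None if ambiguous."""
    if possible == {cls}:
        return 1.0
    if cls not in possible:
        return 0.0
    return None


def build_features(
    record: PatientRecord,
    config: CoefficientTable,
    tp53_mode: Tp53Mode = "wgs",
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
) -> MolecularFeatures:
    """Derive every gene variable of the score from one patient record.

    Deterministic and independent of mutation-row order.
    """
    tp53 = classify_tp53(record.calls_for("TP53"), record.cytogenetics, tp53_mode, vaf_threshold)
    sf3b1 = classify_sf3b1(record, exclusion=config.sf3b1_alpha_exclusion)

    values: dict[str, float | None] = {}
    for spec in config.variables:
        if spec.kind != "gene_main":
            continue
        name = spec.name
        if name == "TP53multi":
            if tp53.classification == "unknown" or not record.is_assessed("TP53"):
                values[name] = None
            else:
                values[name] = 1.0 if tp53.is_multihit else 0.0
        elif name == "FLT3":
            if record.is_assessed("FLT3"):
                has = any(c.mutation_type in ("ITD", "TKD") for c in record.calls_for("FLT3"))
                values[name] = 1.0 if has else 0.0
            else:
                values[name] = None
        elif name == "MLL_PTD":
            if record.is_assessed("KMT2A"):
                has = any(c.mutation_type == "PTD" for c in record.calls_for("KMT2A"))
                values[name] = 1.0 if has else 0.0
            else:
                values[name] = None
        elif name == "SF3B1_5q":
            values[name] = _binary_from_class(sf3b1, "sf3b1_5q")
        elif name == "SF3B1_alpha":
            values[name] = _binary_from_class(sf3b1, "sf3b1_alpha")
        else:
            status = record.gene_status(spec.gene or name)
            values[name] = None if status is None else (1.0 if status else 0.0)

    observed = sum(1 for g in config.residual_genes if record.gene_status(g) is True)
    unassessed = [g for g in config.residual_genes if record.gene_status(g) is None]
    low = float(min(2, observed))
    high = float(min(2, observed + len(unassessed)))
    expected = min(2.0, observed + sum(config.residual_prevalence[g] for g in unassessed))

    return MolecularFeatures(values=values, nres2=(low, expected, high), sf3b1_class=sf3b1, tp53=tp53)
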