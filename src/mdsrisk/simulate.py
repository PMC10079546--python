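"""Synthetic MDS cohort generator.

Emulates the lesion structure of a single-center validation cohort of 626
newly diagnosed MDS patients: the TP53 allelic-state composition (67 carriers:
32 single-mutation, 7 two-mutation, 16 mutation+del(17p), 12
mutation+CN-LOH), 199 SF3B1 carriers with ~9 % isolated-del(5q) and ~82 %
no-co-mutation subtypes, 7 FLT3, 6 KMT2A-PTD and 4 NPM1 carriers, plus
background prevalences for the remaining score genes.  Clinical values come
from simple parametric families (truncated-normal hemoglobin, log-normal
platelets and neutrophils, a two-part blast distribution coupled to the
cytogenetic category); their parameters were tuned once so the scored cohort
reproduces the published six-category risk mix, and are bundled as data.

Survival is exponential with hazard ``h0 * 2**score`` (score = mean-scenario
molecular score), i.e. by construction one score unit doubles the hazard —
which makes discrimination testable and lets a null cohort (doubling
disabled) pin the c-index at 0.5.  Administrative censoring is uniform over a
configurable follow-up window.

Two modes: ``probabilistic`` draws every lesion independently;
``exact_marginals`` plants the configured lesion counts exactly (assignment
shuffled by the seed) so printed cohort counts are reproduced
deterministically.  One integer seed drives three independent sub-streams
(lesions / clinical / survival), so adding a later stage never perturbs
earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .config import CoefficientTable, load_coefficients
from .ipssm import score_patient
from .records import (
    ClinicalPanel,
    CytogeneticsProfile,
    EndpointData,
    MutationCall,
    PatientRecord,
)


class GeneratorError(ValueError):
    pass


class Tp53Mechanisms(BaseModel):
    """TP53 carrier composition (counts at the reference cohort size)."""

    model_config = ConfigDict(extra="forbid")

    single: int = Field(ge=0)
    two_mutations: int = Field(ge=0)
    mutation_deletion: int = Field(ge=0)
    mutation_cnloh: int = Field(ge=0)

    @property
    def total(self) -> int:
        return self.single + self.two_mutations + self.mutation_deletion + self.mutation_cnloh


class ClinicalModel(BaseModel):
    """Clinical-value distributions, conditioned on the cytogenetic category.

    The per-category arrays (index 0 = very good .. 4 = very poor) couple
    marrow failure to karyotype severity, which is what produces the compound
    low- and high-risk tails of the score distribution."""

    model_config = ConfigDict(extra="forbid")

    hb_mean_by_cyto: tuple[float, float, float, float, float]
    hb_sd: float = Field(gt=0)
    hb_min: float = 4.0
    hb_max: float = 18.0
    plt_log_mean_by_cyto: tuple[float, float, float, float, float]
    plt_log_sd: float = Field(gt=0)
    anc_log_mean: float
    anc_log_sd: float = Field(gt=0)
    anc_missing_frac: float = Field(ge=0, le=1)
    blasts_low_frac_by_cyto: tuple[float, float, float, float, float]
    blasts_low_max: float = 2.0
    blasts_tail_scale_by_cyto: tuple[float, float, float, float, float] = (3.0, 3.0, 4.0, 5.0, 6.0)
    blasts_max: float = 19.0


class VafModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(gt=0)
    beta: float = Field(gt=0)
    cnloh_mean: float = 66.0
    cnloh_sd: float = Field(default=9.0, gt=0)
    cnloh_min: float = 40.0
    cnloh_max: float = 95.0


class SurvivalModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    h0_os: float = Field(gt=0)  # monthly baseline hazard of death at score 0
    h0_lt: float = Field(gt=0)  # monthly baseline hazard of transformation
    hazard_doubling: bool = True
    censor_min: float = Field(ge=0)
    censor_max: float
    weibull_shape: float = Field(default=1.0, gt=0)


class GeneratorConfig(BaseModel):
    """All knobs of the cohort generator; see the bundled default for values."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    comment: str | None = None
    n: int = Field(ge=0)
    #: cohort size at which the lesion counts below were specified; carrier
    #: probabilities in probabilistic mode are count / reference_n, so n can
    #: be scaled without touching the counts
    reference_n: int = Field(default=626, gt=0)
    mode: Literal["probabilistic", "exact_marginals"] = "probabilistic"
    seed: int = 0
    tp53: Tp53Mechanisms
    sf3b1_count: int = Field(ge=0)
    sf3b1_5q_frac: float = Field(ge=0, le=1)
    sf3b1_comut_frac: float = Field(ge=0, le=1)
    flt3_count: int = Field(ge=0)
    flt3_itd_frac: float = Field(default=0.7, ge=0, le=1)
    kmt2a_ptd_count: int = Field(ge=0)
    npm1_count: int = Field(ge=0)
    gene_prevalence: dict[str, float]
    cyto_distribution: tuple[float, float, float, float, float]
    background_del5q: float = Field(ge=0, le=1)
    background_del17p: float = Field(ge=0, le=1)
    minus7_frac_poor: float = Field(ge=0, le=1)
    clinical: ClinicalModel
    vaf: VafModel
    survival: SurvivalModel

    @model_validator(mode="after")
    def _feasible(self) -> "GeneratorConfig":
        if self.n > 0 and self.mode == "exact_marginals":
            for label, count in (
                ("TP53 carriers", self.tp53.total),
                ("SF3B1 carriers", self.sf3b1_count),
                ("FLT3 carriers", self.flt3_count),
                ("KMT2A-PTD carriers", self.kmt2a_ptd_count),
                ("NPM1 carriers", self.npm1_count),
            ):
                if count > self.n:
                    raise ValueError(f"{label} ({count}) exceed cohort size n={self.n}")
        for g, p in self.gene_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {g} outside [0,1]: {p}")
        if abs(sum(self.cyto_distribution) - 1.0) > 1e-6:
            raise ValueError("cyto_distribution must sum to 1")
        if self.survival.censor_max <= self.survival.censor_min:
            raise ValueError("censoring window is empty")
        return self


def default_config() -> GeneratorConfig:
    """The bundled calibrated configuration (reference cohort size n=626)."""
    path = Path(str(resources.files("mdsrisk").joinpath("data/generator_default.json")))
    return GeneratorConfig.model_validate(json.loads(path.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# generation


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)  # lesions, clinical, survival


def _typical_vaf(rng: np.random.Generator, cfg: VafModel) -> float:
    return round(float(rng.beta(cfg.alpha, cfg.beta)) * 100.0, 1)


def _cnloh_vaf(rng: np.random.Generator, cfg: VafModel) -> float:
    a = (cfg.cnloh_min - cfg.cnloh_mean) / cfg.cnloh_sd
    b = (cfg.cnloh_max - cfg.cnloh_mean) / cfg.cnloh_sd
    return round(float(stats.truncnorm.rvs(a, b, loc=cfg.cnloh_mean, scale=cfg.cnloh_sd, random_state=rng)), 1)


def _assign_groups(
    rng: np.random.Generator, n: int, counts: list[int], mode: str, reference_n: int
) -> list[np.ndarray]:
    """Disjoint index groups of the given sizes.

    In exact mode the sizes are hit exactly (seed-shuffled assignment); in
    probabilistic mode each patient falls in group k with probability
    counts[k] / reference_n, and group sizes fluctuate.
    """
    if mode == "exact_marginals":
        if sum(counts) > n:
            raise GeneratorError(f"planted counts {counts} exceed n={n}")
        perm = rng.permutation(n)
        groups, start = [], 0
        for c in counts:
            groups.append(np.sort(perm[start : start + c]))
            start += c
        return groups
    # probabilistic: multinomial per patient
    probs = np.array([c / reference_n for c in counts], dtype=float)
    if probs.sum() > 1:
        raise GeneratorError("group probabilities exceed 1")
    u = rng.random(n)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    return [np.nonzero((u >= lo) & (u < hi))[0] for lo, hi in zip(edges[:-1], edges[1:])]


def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate lesion + clinical data (no endpoints) for ``config.n`` patients."""
    n = config.n
    lesion_rng, clinical_rng, _ = _streams(config.seed)
    if n == 0:
        return []
    coeffs = load_coefficients()
    exclusion = set(coeffs.sf3b1_alpha_exclusion)

    # -- TP53 mechanism groups -------------------------------------------
    t = config.tp53
    tp53_groups = _assign_groups(
        lesion_rng, n, [t.single, t.two_mutations, t.mutation_deletion, t.mutation_cnloh],
        config.mode, config.reference_n,
    )
    tp53_mechanism = np.full(n, "", dtype=object)
    for mech, idx in zip(("single", "two_mutations", "mutation_deletion", "mutation_cnloh"), tp53_groups):
        tp53_mechanism[idx] = mech

    # -- SF3B1 subtype groups --------------------------------------------
    n5q = int(round(config.sf3b1_5q_frac * config.sf3b1_count))
    nalpha = int(round((1 - config.sf3b1_5q_frac) * (1 - config.sf3b1_comut_frac) * config.sf3b1_count))
    nother = config.sf3b1_count - n5q - nalpha
    sf_groups = _assign_groups(lesion_rng, n, [n5q, nalpha, nother], config.mode, config.reference_n)
    sf3b1_group = np.full(n, "", dtype=object)
    for grp, idx in zip(("5q", "alpha", "other"), sf_groups):
        sf3b1_group[idx] = grp

    # -- rare high-weight lesions ----------------------------------------
    (flt3_idx,) = _assign_groups(lesion_rng, n, [config.flt3_count], config.mode, config.reference_n)
    (kmt2a_idx,) = _assign_groups(lesion_rng, n, [config.kmt2a_ptd_count], config.mode, config.reference_n)
    (npm1_idx,) = _assign_groups(lesion_rng, n, [config.npm1_count], config.mode, config.reference_n)
    flt3 = np.zeros(n, bool)
    flt3[flt3_idx] = True
    kmt2a = np.zeros(n, bool)
    kmt2a[kmt2a_idx] = True
    npm1 = np.zeros(n, bool)
    npm1[npm1_idx] = True

    # -- background gene mutations ---------------------------------------
    gene_mut: dict[str, np.ndarray] = {}
    for gene in sorted(config.gene_prevalence):
        mask = lesion_rng.random(n) < config.gene_prevalence[gene]
        if gene in exclusion:
            # the no-co-mutation SF3B1 subtype forbids these genes; the
            # "other" subtype requires at least one of them (planted below)
            mask[sf3b1_group == "alpha"] = False
        gene_mut[gene] = mask
    # ensure every "other"-subtype patient indeed carries a co-mutation
    exclusion_sorted = sorted(exclusion & set(gene_mut))
    weights = np.array([config.gene_prevalence[g] for g in exclusion_sorted])
    weights = weights / weights.sum()
    for i in np.nonzero(sf3b1_group == "other")[0]:
        if not any(gene_mut[g][i] for g in exclusion_sorted):
            forced = lesion_rng.choice(len(exclusion_sorted), p=weights)
            gene_mut[exclusion_sorted[forced]][i] = True

    # -- cytogenetics -----------------------------------------------------
    category = lesion_rng.choice(5, size=n, p=np.asarray(config.cyto_distribution))
    del5q = np.zeros(n, bool)
    minus7 = np.zeros(n, bool)
    del17p = np.zeros(n, bool)
    cnloh = np.zeros(n, bool)

    is_sf3b1 = sf3b1_group != ""
    bg5q = (lesion_rng.random(n) < config.background_del5q) & ~is_sf3b1
    del5q |= bg5q
    del5q[sf3b1_group == "5q"] = True
    category[sf3b1_group == "5q"] = 1  # isolated del(5q) is a "good" karyotype

    poor = category >= 3
    minus7 |= poor & (lesion_rng.random(n) < config.minus7_frac_poor)
    minus7[sf3b1_group == "5q"] = False

    # background del(17p) only outside the planted TP53 groups, so the
    # mechanism composition stays exactly as configured
    del17p |= (lesion_rng.random(n) < config.background_del17p) & (tp53_mechanism == "")
    mut_del = tp53_mechanism == "mutation_deletion"
    del17p |= mut_del
    # biallelic TP53 inactivation travels with high-risk karyotypes
    multihit = mut_del | (tp53_mechanism == "two_mutations") | (tp53_mechanism == "mutation_cnloh")
    category[multihit] = np.maximum(category[multihit], 3)

    cnloh[tp53_mechanism == "mutation_cnloh"] = True
    complex_k = category == 4

    # -- clinical panel ---------------------------------------------------
    cm = config.clinical
    hb_mean = np.asarray(cm.hb_mean_by_cyto)[category]
    a = (cm.hb_min - hb_mean) / cm.hb_sd
    b = (cm.hb_max - hb_mean) / cm.hb_sd
    hb = stats.truncnorm.rvs(a, b, loc=hb_mean, scale=cm.hb_sd, size=n, random_state=clinical_rng)
    plt_mean = np.asarray(cm.plt_log_mean_by_cyto)[category]
    plt = np.clip(np.exp(clinical_rng.normal(plt_mean, cm.plt_log_sd, size=n)), 5.0, 1500.0)
    anc = np.exp(clinical_rng.normal(cm.anc_log_mean, cm.anc_log_sd, size=n))
    anc_missing = clinical_rng.random(n) < cm.anc_missing_frac
    low_frac = np.asarray(cm.blasts_low_frac_by_cyto)[category]
    is_low = clinical_rng.random(n) < low_frac
    tail_scale = np.asarray(cm.blasts_tail_scale_by_cyto)[category]
    blasts = np.where(
        is_low,
        clinical_rng.uniform(0.0, cm.blasts_low_max, size=n),
        np.minimum(cm.blasts_low_max + clinical_rng.exponential(tail_scale), cm.blasts_max),
    )

    # -- assemble records -------------------------------------------------
    records: list[PatientRecord] = []
    width = max(4, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        calls: list[MutationCall] = []
        mech = tp53_mechanism[i]
        if mech == "single":
            calls.append(MutationCall(pid, "TP53", _typical_vaf(lesion_rng, config.vaf)))
        elif mech == "two_mutations":
            calls.append(MutationCall(pid, "TP53", _typical_vaf(lesion_rng, config.vaf)))
            calls.append(MutationCall(pid, "TP53", _typical_vaf(lesion_rng, config.vaf)))
        elif mech == "mutation_deletion":
            calls.append(MutationCall(pid, "TP53", _typical_vaf(lesion_rng, config.vaf)))
        elif mech == "mutation_cnloh":
            calls.append(MutationCall(pid, "TP53", _cnloh_vaf(lesion_rng, config.vaf)))
        if sf3b1_group[i]:
            calls.append(MutationCall(pid, "SF3B1", _typical_vaf(lesion_rng, config.vaf)))
        if flt3[i]:
            kind = "ITD" if lesion_rng.random() < config.flt3_itd_frac else "TKD"
            calls.append(MutationCall(pid, "FLT3", _typical_vaf(lesion_rng, config.vaf), kind))
        if kmt2a[i]:
            calls.append(MutationCall(pid, "KMT2A", _typical_vaf(lesion_rng, config.vaf), "PTD"))
        if npm1[i]:
            calls.append(MutationCall(pid, "NPM1", _typical_vaf(lesion_rng, config.vaf)))
        for gene in sorted(gene_mut):
            if gene_mut[gene][i]:
                calls.append(MutationCall(pid, gene, _typical_vaf(lesion_rng, config.vaf)))

        records.append(
            PatientRecord(
                patient_id=pid,
                clinical=ClinicalPanel(
                    bm_blasts=round(float(blasts[i]), 1),
                    hemoglobin=round(float(hb[i]), 1),
                    platelets=round(float(plt[i]), 0),
                    anc=None if anc_missing[i] else round(float(anc[i]), 2),
                ),
                cytogenetics=CytogeneticsProfile(
                    ipssr_cyto_category=int(category[i]),
                    del5q=bool(del5q[i]),
                    minus7_or_del7q=bool(minus7[i]),
                    del17p=bool(del17p[i]),
                    complex_karyotype=bool(complex_k[i]),
                    tp53_cnloh=bool(cnloh[i]),
                ),
                mutations=tuple(calls),
                assessed_genes=None,
            )
        )
    return records


def generate_survival(
    records: list[PatientRecord],
    config: GeneratorConfig,
    coefficients: CoefficientTable | None = None,
) -> list[PatientRecord]:
    """Attach score-linked exponential endpoints to a generated cohort.

    Death and transformation hazards are ``h0 * 2**score`` (mean-scenario
    molecular score) when hazard doubling is on, flat ``h0`` otherwise.
    Transformation competes with death; leukemia-free survival fails at the
    first of the two.  Administrative censoring is uniform on the follow-up
    window.
    """
    sm = config.survival
    coeffs = coefficients if coefficients is not None else load_coefficients()
    _, _, survival_rng = _streams(config.seed)
    out: list[PatientRecord] = []
    for r in records:
        score = score_patient(r, coeffs).score_mean
        mult = 2.0**score if sm.hazard_doubling else 1.0
        t_death = float(survival_rng.exponential(1.0 / (sm.h0_os * mult)))
        t_lt = float(survival_rng.exponential(1.0 / (sm.h0_lt * mult)))
        censor = float(survival_rng.uniform(sm.censor_min, sm.censor_max))

        os_time = min(t_death, censor)
        os_event = int(t_death <= censor)
        first = min(t_lt, t_death)
        lfs_time = min(first, censor)
        lfs_event = int(first <= censor)
        lt_event = int(t_lt <= censor and t_lt < t_death)
        death_wo_lt = int(t_death <= censor and t_death < t_lt)
        out.append(
            replace(
                r,
                endpoints=EndpointData(
                    os_time=os_time,
                    os_event=os_event,
                    lfs_time=lfs_time,
                    lfs_event=lfs_event,
                    lt_time=lfs_time,
                    lt_event=lt_event,
                    death_without_lt=death_wo_lt,
                ),
            )
        )
    return out


def simulate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Full simulation: lesions + clinical + endpoints."""
    return generate_survival(generate_cohort(config), config)
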