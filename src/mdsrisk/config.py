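"""Scoring-system parameter tables.

The molecular score (IPSS-M) is a centered weighted sum: each prognostic
variable ``x_j`` contributes ``w_j * (x_j - center_j)`` where ``w_j`` is the
published Cox log-hazard coefficient divided by ``ln 2``.  On that scale one
score unit corresponds to a doubling of hazard, and the cohort-average patient
scores exactly 0.  Six risk categories (VL..VH) are cut from the continuous
score at fixed thresholds.  The revised clinical score (IPSS-R) is a classic
point system over five inputs with five categories.

Both parameter sets ship as JSON under ``mdsrisk/data`` and are validated on
load; nothing numerical is hard-coded in scoring logic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

LN2 = math.log(2.0)

#: IPSS-M category labels, most to least favorable.
IPSSM_LABELS: tuple[str, ...] = ("VL", "L", "ML", "MH", "H", "VH")
#: IPSS-R category labels, most to least favorable.
IPSSR_LABELS: tuple[str, ...] = ("Very Low", "Low", "Intermediate", "High", "Very High")

VariableKind = Literal["clinical", "cytogenetic", "gene_main", "gene_residual_count"]
TransformName = Literal[
    "hemoglobin",
    "blasts_cap20_div5",
    "platelets_cap250_div100",
    "cyto_category",
    "binary",
    "residual_count",
]


class ConfigError(ValueError):
    """Raised when a parameter file cannot be parsed or violates an invariant."""


class VariableSpec(BaseModel):
    """One scoring variable: weight, centering mean and scenario fill-ins.

    ``log_hazard`` is the raw Cox coefficient as published; ``weight`` exposes
    it on the log2-hazard scale actually used by the score.  ``best_value``
    and ``worst_value`` are the values imputed for an unknown variable under
    the best-/worst-case scenarios and must map to the minimal and maximal
    contribution respectively.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    kind: VariableKind
    gene: str | None = None
    log_hazard: float
    center: float
    best_value: float
    worst_value: float
    transform: TransformName

    @property
    def weight(self) -> float:
        """Score units per unit of centered value (log2-hazard scale)."""
        return self.log_hazard / LN2

    def contribution(self, x: float) -> float:
        return self.weight * (x - self.center)

    @model_validator(mode="after")
    def _best_no_worse_than_worst(self) -> "VariableSpec":
        if self.contribution(self.best_value) > self.contribution(self.worst_value) + 1e-12:
            raise ValueError(
                f"variable {self.name!r}: best_value yields a larger contribution "
                f"than worst_value (weight sign inconsistent with fill-ins)"
            )
        return self


class CoefficientTable(BaseModel):
    """Validated IPSS-M parameter set (variables, cutpoints, gene lists)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    schema_version: int
    comment: str | None = None
    variables: tuple[VariableSpec, ...]
    cutpoints: tuple[float, float, float, float, float]
    category_labels: tuple[str, str, str, str, str, str] = IPSSM_LABELS
    residual_genes: tuple[str, ...]
    residual_prevalence: dict[str, float]
    sf3b1_alpha_exclusion: tuple[str, ...]

    @model_validator(mode="after")
    def _structural_invariants(self) -> "CoefficientTable":
        cuts = self.cutpoints
        if any(a >= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"cutpoints must be strictly ascending, got {cuts}")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in coefficient table")
        if set(self.residual_prevalence) != set(self.residual_genes):
            raise ValueError("residual_prevalence keys must match residual_genes")
        for g, p in self.residual_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"residual prevalence for {g} outside [0,1]: {p}")
        return self

    # -- lookups ---------------------------------------------------------

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def gene_variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.kind == "gene_main")

    @property
    def main_effect_genes(self) -> tuple[str, ...]:
        """Distinct genes behind the main-effect variables (SF3B1 counts once)."""
        seen: list[str] = []
        for v in self.variables:
            if v.kind == "gene_main" and v.gene and v.gene not in seen:
                seen.append(v.gene)
        return tuple(seen)

    @property
    def n_gene_variables(self) -> int:
        """Distinct gene-derived variables: main-effect genes plus residual genes."""
        return len(self.main_effect_genes) + len(self.residual_genes)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.main_effect_genes + tuple(self.residual_genes)

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class PointRule:
    op: str  # "le" | "lt"
    threshold: float
    points: float

    def matches(self, value: float) -> bool:
        return value <= self.threshold if self.op == "le" else value < self.threshold


@dataclass(frozen=True)
class PointBins:
    """Ordered threshold rules with a fallback; first matching rule wins."""

    rules: tuple[PointRule, ...]
    fallback: float

    def points(self, value: float) -> float:
        for rule in self.rules:
            if rule.matches(value):
                return rule.points
        return self.fallback

    @property
    def all_points(self) -> tuple[float, ...]:
        return tuple(r.points for r in self.rules) + (self.fallback,)


@dataclass(frozen=True)
class IpssrPointTable:
    """IPSS-R point assignments and category cutpoints."""

    cyto_points: tuple[float, ...]
    blasts: PointBins
    hemoglobin: PointBins
    platelets: PointBins
    anc: PointBins
    category_cutpoints: tuple[float, float, float, float]
    category_labels: tuple[str, ...] = IPSSR_LABELS

    def __post_init__(self) -> None:
        if len(self.cyto_points) != 5:
            raise ConfigError("cyto_points must have 5 entries (categories 0-4)")
        all_pts = (
            self.cyto_points
            + self.blasts.all_points
            + self.hemoglobin.all_points
            + self.platelets.all_points
            + self.anc.all_points
        )
        if any(p < 0 for p in all_pts):
            raise ConfigError("IPSS-R points must be non-negative")
        max_total = (
            max(self.cyto_points)
            + max(self.blasts.all_points)
            + max(self.hemoglobin.all_points)
            + max(self.platelets.all_points)
            + max(self.anc.all_points)
        )
        if max_total > 10.0 + 1e-9:
            raise ConfigError(f"maximal attainable IPSS-R total {max_total} exceeds 10")
        cuts = self.category_cutpoints
        if len(cuts) != 4 or any(a >= b for a, b in zip(cuts, cuts[1:])):
            raise ConfigError("IPSS-R category cutpoints must be 4 ascending values")
        if len(self.category_labels) != 5:
            raise ConfigError("IPSS-R needs exactly 5 category labels")


# ---------------------------------------------------------------------------
# loading


def default_coefficients_path() -> Path:
    return Path(str(resources.files("mdsrisk").joinpath("data/ipssm_coefficients.json")))


def default_ipssr_path() -> Path:
    return Path(str(resources.files("mdsrisk").joinpath("data/ipssr_points.json")))


def load_coefficients(path: str | Path | None = None) -> CoefficientTable:
    """Load and validate an IPSS-M coefficient table (bundled default if no path).

    Beyond the structural model invariants this enforces the gene-count
    contract: main-effect genes plus residual genes must total 31.
    """
    p = Path(path) if path is not None else default_coefficients_path()
    try:
        raw = json.loads(p.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse coefficient file {p}: {exc}") from exc
    try:
        table = CoefficientTable.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid coefficient table {p}: {exc}") from exc
    n = table.n_gene_variables
    if n != 31:
        raise ConfigError(
            f"coefficient table {p} defines {n} gene variables "
            f"({len(table.main_effect_genes)} main-effect + "
            f"{len(table.residual_genes)} residual); expected 31"
        )
    return table


def _bins_from_raw(raw: dict) -> PointBins:
    rules = tuple(PointRule(r["op"], float(r["threshold"]), float(r["points"])) for r in raw["rules"])
    return PointBins(rules=rules, fallback=float(raw["fallback"]))


def load_ipssr_table(path: str | Path | None = None) -> IpssrPointTable:
    """Load and validate the IPSS-R point table (bundled default if no path)."""
    p = Path(path) if path is not None else default_ipssr_path()
    try:
        raw = json.loads(p.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse IPSS-R point file {p}: {exc}") from exc
    known = {
        "schema_version", "comment", "cyto_points", "blasts", "hemoglobin",
        "platelets", "anc", "category_cutpoints", "category_labels",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown fields in IPSS-R point file {p}: {sorted(unknown)}")
    try:
        return IpssrPointTable(
            cyto_points=tuple(float(x) for x in raw["cyto_points"]),
            blasts=_bins_from_raw(raw["blasts"]),
            hemoglobin=_bins_from_raw(raw["hemoglobin"]),
            platelets=_bins_from_raw(raw["platelets"]),
            anc=_bins_from_raw(raw["anc"]),
            category_cutpoints=tuple(float(x) for x in raw["category_cutpoints"]),
            category_labels=tuple(raw.get("category_labels", IPSSR_LABELS)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing field in IPSS-R point file {p}: {exc}") from exc


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class ConfigReport:
    """Report-only diagnostics over a loaded parameter pair."""

    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["parameter diagnostics:"]
        for k, v in self.counts.items():
            lines.append(f"  {k}: {v}")
        for w in self.warnings:
            lines.append(f"  WARNING: {w}")
        return "\n".join(lines)


def validate_config(table: CoefficientTable, ipssr: IpssrPointTable) -> ConfigReport:
    """Count variables by class and sanity-check the gene lists (never raises)."""
    report = ConfigReport()
    kinds = {"clinical": 0, "cytogenetic": 0, "gene_main": 0, "gene_residual_count": 0}
    for v in table.variables:
        kinds[v.kind] += 1
    report.counts.update(
        {
            "clinical variables": kinds["clinical"],
            "cytogenetic variables": kinds["cytogenetic"],
            "main-effect gene variables": kinds["gene_main"],
            "main-effect genes (distinct)": len(table.main_effect_genes),
            "residual genes": len(table.residual_genes),
            "gene variables (distinct genes)": table.n_gene_variables,
            "risk categories": len(table.category_labels),
            "ipssr categories": len(ipssr.category_labels),
        }
    )
    if not table.residual_genes:
        report.warnings.append("residual gene list is empty")
    if len(table.main_effect_genes) != 16:
        report.warnings.append(
            f"expected 16 distinct main-effect genes, found {len(table.main_effect_genes)}"
        )
    if len(table.residual_genes) != 15:
        report.warnings.append(f"expected 15 residual genes, found {len(table.residual_genes)}")
    if table.n_gene_variables != 31:
        report.warnings.append(f"expected 31 gene variables in total, found {table.n_gene_variables}")
    return report
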