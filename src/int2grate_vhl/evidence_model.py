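"""Typed data model for the four VHL evidence axes.

Every case entering the variant evidence framework (VEF) is a
:class:`CaseRecord` holding the germline VHL variant, germline findings in
the differential-diagnosis gene panel, clinical-genetics information
(personal tumors/features, family history, age), and somatic VHL
alterations from tumor profiling.  Controlled vocabularies (the seven VHL
component tumor types, the three VHL-related features, the 13-gene
differential panel) live here so that every module agrees on them.

Raw case tables arrive as TSV (one row per case) or JSON (one object per
case); :func:`validate_case` turns a raw field mapping into a fully typed
record or a report listing every violated invariant.
"""

from __future__ import annotations

import csv
import json
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Union

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "VariantClassification",
    "Zygosity",
    "Sex",
    "FamilyHistory",
    "FamilyDegree",
    "VhlFeature",
    "AlterationType",
    "VHL_COMPONENT_TUMORS",
    "VHL_FEATURES",
    "DIFFERENTIAL_PANEL",
    "NON_VHL_PREFIX",
    "GermlineVariant",
    "DifferentialFinding",
    "TumorRecord",
    "ClinicalHistory",
    "SomaticAlteration",
    "CaseRecord",
    "Violation",
    "ValidationReport",
    "CaseValidationError",
    "validate_case",
    "case_to_row",
    "row_to_raw",
    "read_cases_tsv",
    "write_cases_tsv",
    "read_cases_json",
    "write_cases_json",
    "CASE_TABLE_COLUMNS",
]


class VariantClassification(str, Enum):
    """Reported germline classification; P_ECYT2 marks variants reported
    pathogenic only for the recessive erythrocytosis (ECYT2) allelic
    disorder, not for VHL syndrome."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    P_ECYT2 = "P_ECYT2"


class Zygosity(str, Enum):
    heterozygous = "heterozygous"
    homozygous = "homozygous"
    compound_heterozygous = "compound_heterozygous"
    hemizygous = "hemizygous"
    unknown = "unknown"


class Sex(str, Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class FamilyHistory(str, Enum):
    positive = "positive"
    negative = "negative"
    unknown = "unknown"


class FamilyDegree(str, Enum):
    first = "first"
    second = "second"
    other = "other"


class VhlFeature(str, Enum):
    multiple_kidney_cysts = "multiple_kidney_cysts"
    multiple_pancreatic_cysts = "multiple_pancreatic_cysts"
    epididymal_or_broad_ligament_cysts = "epididymal_or_broad_ligament_cysts"


class AlterationType(str, Enum):
    snv = "snv"
    indel = "indel"
    one_copy_deletion = "one_copy_deletion"
    two_copy_deletion = "two_copy_deletion"
    amplification = "amplification"
    sv = "sv"


#: The seven VHL component tumor types recognized by the VEF.
VHL_COMPONENT_TUMORS = frozenset(
    {
        "retinal_hemangioblastoma",
        "cns_hemangioblastoma",
        "rcc",
        "pheochromocytoma",
        "pancreatic_net",
        "endolymphatic_sac_tumor",
        "paraganglioma",
    }
)

#: The three VHL-related (non-tumor) features.
VHL_FEATURES = frozenset(f.value for f in VhlFeature)

#: Genes whose pathogenic germline findings indicate a VHL differential
#: condition (SDHx paraganglioma syndromes, HLRCC, BHD, MEN2, NF1, ...).
DIFFERENTIAL_PANEL = frozenset(
    {
        "FH",
        "FLCN",
        "MET",
        "BAP1",
        "SDHA",
        "SDHB",
        "SDHC",
        "SDHD",
        "SDHAF2",
        "TMEM127",
        "MAX",
        "RET",
        "NF1",
    }
)

#: Free-text, non-VHL tumor types are carried with this prefix; the VEF
#: only needs the VHL / non-VHL distinction.
NON_VHL_PREFIX = "non_vhl:"

#: Input spellings normalized at ingestion ("favor polymorphism" is a
#: laboratory downgrade from VUS and enters the model as LB).
_CLASSIFICATION_ALIASES = {
    "favor_polymorphism": "LB",
    "favor polymorphism": "LB",
    "pathogenic": "P",
    "likely_pathogenic": "LP",
    "likely pathogenic": "LP",
    "likely_benign": "LB",
    "likely benign": "LB",
    "benign": "B",
    "p_ecyt2": "P_ECYT2",
    "p (ecyt2)": "P_ECYT2",
}


def _norm_term(value: str) -> str:
    """Whitespace-normalized, case-insensitive vocabulary matching."""
    return "_".join(str(value).strip().lower().split())


def normalize_classification(value: str) -> str:
    term = str(value).strip()
    alias = _CLASSIFICATION_ALIASES.get(term.lower())
    if alias:
        return alias
    return term.upper()


class GermlineVariant(BaseModel):
    hgvs_c: Optional[str] = None
    reported_classification: VariantClassification
    zygosity: Zygosity = Zygosity.unknown
    is_copy_number: bool = False
    deleted_exons: Optional[frozenset[int]] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "GermlineVariant":
        if self.hgvs_c is not None and not self.hgvs_c.strip():
            raise ValueError("hgvs_c must be non-empty when present")
        if self.is_copy_number != bool(self.deleted_exons):
            raise ValueError("is_copy_number true iff deleted_exons non-empty")
        if self.deleted_exons and not set(self.deleted_exons) <= {1, 2, 3}:
            raise ValueError("deleted_exons must be a subset of {1, 2, 3}")
        if not self.is_copy_number and self.hgvs_c is None:
            raise ValueError("sequence variants require hgvs_c")
        return self


class DifferentialFinding(BaseModel):
    gene: str
    classification: VariantClassification

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "DifferentialFinding":
        if self.gene.upper() not in DIFFERENTIAL_PANEL:
            raise ValueError(
                f"unknown_term: gene {self.gene!r} is not in the differential panel"
            )
        object.__setattr__(self, "gene", self.gene.upper())
        if self.classification is VariantClassification.P_ECYT2:
            raise ValueError("P_ECYT2 applies only to VHL germline variants")
        return self


class TumorRecord(BaseModel):
    tumor_type: str
    laterality_count: int = Field(default=1, ge=1)
    age_at_dx: Optional[int] = Field(default=None, ge=0)
    sdh_deficient: bool = False

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "TumorRecord":
        t = self.tumor_type
        if not t.startswith(NON_VHL_PREFIX):
            t = _norm_term(t)
            if t not in VHL_COMPONENT_TUMORS:
                raise ValueError(
                    f"unknown_term: tumor type {self.tumor_type!r} is not a VHL "
                    f"component tumor (use '{NON_VHL_PREFIX}<text>' for others)"
                )
            object.__setattr__(self, "tumor_type", t)
        if self.sdh_deficient and self.tumor_type != "paraganglioma":
            raise ValueError("sdh_deficient may be true only for paraganglioma")
        return self

    @property
    def is_vhl_component(self) -> bool:
        return self.tumor_type in VHL_COMPONENT_TUMORS


class ClinicalHistory(BaseModel):
    evaluated_in_genetics: bool = False
    age_years: Optional[int] = Field(default=None, ge=0)
    sex: Sex = Sex.unknown
    personal_tumors: tuple[TumorRecord, ...] = ()
    personal_features: tuple[VhlFeature, ...] = ()
    family_history_vhl: FamilyHistory = FamilyHistory.unknown
    family_degree: Optional[FamilyDegree] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "ClinicalHistory":
        if (
            self.family_degree is not None
            and self.family_history_vhl is not FamilyHistory.positive
        ):
            raise ValueError("family_degree present only when family history positive")
        return self


class SomaticAlteration(BaseModel):
    hgvs_c: Optional[str] = None
    alteration_type: AlterationType
    vaf_percent: Optional[float] = Field(default=None, ge=0, le=100)
    log2_ratio: Optional[float] = None
    coverage: Optional[int] = Field(default=None, gt=0)
    unique_reads: Optional[int] = Field(default=None, ge=0)
    population_af_percent: Optional[float] = Field(default=None, ge=0)
    cosmic_count: Optional[int] = Field(default=None, ge=0)
    tumor_source: Optional[str] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "SomaticAlteration":
        small = self.alteration_type in (AlterationType.snv, AlterationType.indel)
        if small and not (self.hgvs_c or "").strip():
            raise ValueError("snv/indel records require hgvs_c")
        if not small and self.vaf_percent is not None:
            raise ValueError("vaf_percent applies only to snv/indel records")
        return self


class CaseRecord(BaseModel):
    subject_id: str
    germline: Optional[GermlineVariant] = None
    differential_findings: tuple[DifferentialFinding, ...] = ()
    clinical: ClinicalHistory = Field(default_factory=ClinicalHistory)
    somatic: tuple[SomaticAlteration, ...] = ()
    somatic_tested: bool = False

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "CaseRecord":
        if not self.subject_id.strip():
            raise ValueError("subject_id must be non-empty")
        if not self.somatic_tested and self.somatic:
            raise ValueError("somatic list must be empty when somatic_tested is false")
        return self


# ---------------------------------------------------------------------------
# validation entry point


class Violation(BaseModel):
    path: str
    code: str
    message: str

    model_config = {"frozen": True}


class ValidationReport(BaseModel):
    subject_id: Optional[str] = None
    violations: tuple[Violation, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"{v.path}: [{v.code}] {v.message}" for v in self.violations]
        return "; ".join(lines) or "ok"


class CaseValidationError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


def _violation_code(message: str) -> str:
    msg = message.lower()
    if "unknown_term" in msg:
        return "unknown_term"
    if "bad_hgvs" in msg or "hgvs" in msg:
        return "bad_hgvs"
    return "invariant"


def validate_case(
    raw: Union[Mapping[str, Any], CaseRecord],
    *,
    check_hgvs: bool = True,
) -> Union[CaseRecord, ValidationReport]:
    """Validate a raw field mapping (or re-validate a record).

    Returns the typed :class:`CaseRecord` when all invariants hold, else a
    :class:`ValidationReport` listing every violation with its field path.
    Validation is idempotent: a valid record round-trips unchanged.
    """
    if isinstance(raw, CaseRecord):
        raw = raw.model_dump()
    violations: list[Violation] = []
    try:
        case = CaseRecord.model_validate(raw)
    except Exception as exc:  # pydantic collects all field errors
        subject = None
        if isinstance(raw, Mapping):
            subject = str(raw.get("subject_id") or "") or None
        errors = getattr(exc, "errors", None)
        if callable(errors):
            for err in errors():
                path = ".".join(str(p) for p in err["loc"]) or "<root>"
                msg = err["msg"]
                violations.append(
                    Violation(path=path, code=_violation_code(msg), message=msg)
                )
        else:
            violations.append(
                Violation(path="<root>", code="invariant", message=str(exc))
            )
        return ValidationReport(subject_id=subject, violations=tuple(violations))

    if check_hgvs:
        from . import gene_annotation

        def _check_hgvs(value: Optional[str], path: str) -> None:
            if not value:
                return
            try:
                gene_annotation.parse_cdna(value)
            except gene_annotation.BadHgvsError as exc:
                violations.append(
                    Violation(path=path, code="bad_hgvs", message=str(exc))
                )

        if case.germline is not None and not case.germline.is_copy_number:
            _check_hgvs(case.germline.hgvs_c, "germline.hgvs_c")
        for i, alt in enumerate(case.somatic):
            if alt.alteration_type in (AlterationType.snv, AlterationType.indel):
                _check_hgvs(alt.hgvs_c, f"somatic.{i}.hgvs_c")

    if violations:
        return ValidationReport(subject_id=case.subject_id, violations=tuple(violations))
    return case


# ---------------------------------------------------------------------------
# case-table (TSV / JSON) serialization

CASE_TABLE_COLUMNS = [
    "subject_id",
    "vhl_hgvs_c",
    "vhl_classification",
    "zygosity",
    "deleted_exons",
    "differential_findings",
    "evaluated_in_genetics",
    "age_years",
    "sex",
    "personal_tumors",
    "personal_features",
    "non_vhl_tumors",
    "family_history_vhl",
    "family_degree",
    "somatic_tested",
    "somatic_alterations",
]

_SOMATIC_FIELDS = [
    "hgvs_c",
    "alteration_type",
    "vaf_percent",
    "log2_ratio",
    "coverage",
    "unique_reads",
    "population_af_percent",
    "cosmic_count",
    "tumor_source",
]


def _split_list(value: str) -> list[str]:
    value = (value or "").strip()
    if not value or value.lower() == "none":
        return []
    return [part.strip() for part in value.split(";") if part.strip()]


def _parse_bool(value: str) -> bool:
    return _norm_term(value) in {"true", "1", "yes", "y", "t"}


def _opt(value: str) -> Optional[str]:
    value = (value or "").strip()
    return value or None


def row_to_raw(row: Mapping[str, str]) -> dict[str, Any]:
    """Convert one TSV row (flat strings) into the nested raw mapping that
    :func:`validate_case` consumes."""
    raw: dict[str, Any] = {"subject_id": (row.get("subject_id") or "").strip()}

    hgvs = _opt(row.get("vhl_hgvs_c", ""))
    cls = _opt(row.get("vhl_classification", ""))
    exons = _opt(row.get("deleted_exons", ""))
    if hgvs or cls or exons:
        deleted = (
            frozenset(int(e) for e in exons.replace(";", ",").split(",") if e.strip())
            if exons
            else None
        )
        raw["germline"] = {
            "hgvs_c": hgvs,
            "reported_classification": normalize_classification(cls or "VUS"),
            "zygosity": _norm_term(row.get("zygosity") or "unknown"),
            "is_copy_number": bool(deleted),
            "deleted_exons": deleted,
        }

    findings = []
    for item in _split_list(row.get("differential_findings", "")):
        gene, _, klass = item.partition(":")
        findings.append(
            {
                "gene": gene.strip().upper(),
                "classification": normalize_classification(klass or "VUS"),
            }
        )
    raw["differential_findings"] = findings

    tumors: list[dict[str, Any]] = []
    for item in _split_list(row.get("personal_tumors", "")):
        parts = [p.strip() for p in item.split(":")]
        rec: dict[str, Any] = {"tumor_type": _norm_term(parts[0])}
        if len(parts) > 1 and parts[1]:
            rec["laterality_count"] = int(parts[1])
        if len(parts) > 2 and parts[2]:
            rec["sdh_deficient"] = _norm_term(parts[2]) in {"sdh_deficient", "true", "1"}
        tumors.append(rec)
    for item in _split_list(row.get("non_vhl_tumors", "")):
        tumors.append({"tumor_type": NON_VHL_PREFIX + item})

    raw["clinical"] = {
        "evaluated_in_genetics": _parse_bool(row.get("evaluated_in_genetics", "")),
        "age_years": int(row["age_years"]) if _opt(row.get("age_years", "")) else None,
        "sex": _norm_term(row.get("sex") or "unknown"),
        "personal_tumors": tumors,
        "personal_features": [
            _norm_term(f) for f in _split_list(row.get("personal_features", ""))
        ],
        "family_history_vhl": _norm_term(row.get("family_history_vhl") or "unknown"),
        "family_degree": _opt(row.get("family_degree", "")) and _norm_term(
            row["family_degree"]
        ),
    }

    alterations = []
    for item in _split_list(row.get("somatic_alterations", "")):
        fields = item.split("|")
        rec = {}
        for name, value in zip(_SOMATIC_FIELDS, fields):
            value = value.strip()
            if not value:
                continue
            if name in {"vaf_percent", "log2_ratio", "population_af_percent"}:
                rec[name] = float(value)
            elif name in {"coverage", "unique_reads", "cosmic_count"}:
                rec[name] = int(value)
            elif name == "tumor_source":
                rec[name] = _norm_term(value)
            else:
                rec[name] = value
        alterations.append(rec)
    raw["somatic"] = alterations
    raw["somatic_tested"] = _parse_bool(row.get("somatic_tested", ""))
    return raw


def case_to_row(case: CaseRecord) -> dict[str, str]:
    """Serialize a record back to the flat TSV representation."""
    g = case.germline
    vhl_tumors = [t for t in case.clinical.personal_tumors if t.is_vhl_component]
    non_vhl = [t for t in case.clinical.personal_tumors if not t.is_vhl_component]

    def _tumor_cell(t: TumorRecord) -> str:
        cell = t.tumor_type
        if t.laterality_count != 1 or t.sdh_deficient:
            cell += f":{t.laterality_count}"
        if t.sdh_deficient:
            cell += ":sdh_deficient"
        return cell

    def _somatic_cell(a: SomaticAlteration) -> str:
        vals = []
        for name in _SOMATIC_FIELDS:
            v = getattr(a, name)
            if v is None:
                vals.append("")
            elif isinstance(v, Enum):
                vals.append(v.value)
            elif isinstance(v, float):
                vals.append(f"{v:g}")
            else:
                vals.append(str(v))
        return "|".join(vals).rstrip("|")

    return {
        "subject_id": case.subject_id,
        "vhl_hgvs_c": (g.hgvs_c if g else "") or "",
        "vhl_classification": g.reported_classification.value if g else "",
        "zygosity": g.zygosity.value if g else "",
        "deleted_exons": ",".join(str(e) for e in sorted(g.deleted_exons)) if g and g.deleted_exons else "",
        "differential_findings": ";".join(
            f"{f.gene}:{f.classification.value}" for f in case.differential_findings
        ),
        "evaluated_in_genetics": str(case.clinical.evaluated_in_genetics).lower(),
        "age_years": "" if case.clinical.age_years is None else str(case.clinical.age_years),
        "sex": case.clinical.sex.value,
        "personal_tumors": ";".join(_tumor_cell(t) for t in vhl_tumors),
        "personal_features": ";".join(f.value for f in case.clinical.personal_features),
        "non_vhl_tumors": ";".join(
            t.tumor_type[len(NON_VHL_PREFIX):] for t in non_vhl
        ),
        "family_history_vhl": case.clinical.family_history_vhl.value,
        "family_degree": case.clinical.family_degree.value if case.clinical.family_degree else "",
        "somatic_tested": str(case.somatic_tested).lower(),
        "somatic_alterations": ";".join(_somatic_cell(a) for a in case.somatic),
    }


def _check_duplicates(rows: Iterable[Mapping[str, Any]]) -> None:
    seen: set[str] = set()
    for row in rows:
        sid = str(row.get("subject_id") or "")
        if sid in seen:
            report = ValidationReport(
                subject_id=sid,
                violations=(
                    Violation(
                        path="subject_id",
                        code="duplicate_subject",
                        message=f"duplicate subject_id {sid!r} in batch",
                    ),
                ),
            )
            raise CaseValidationError(report)
        seen.add(sid)


def read_cases_tsv(path: Union[str, Path]) -> list[Union[CaseRecord, ValidationReport]]:
    """Read a case table; each row becomes a CaseRecord or, if it violates
    the model, its ValidationReport.  Duplicate subject ids abort the read."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    _check_duplicates(rows)
    return [validate_case(row_to_raw(row)) for row in rows]


def write_cases_tsv(cases: Iterable[CaseRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CASE_TABLE_COLUMNS, delimiter="\t")
        writer.writeheader()
        for case in cases:
            writer.writerow(case_to_row(case))


def read_cases_json(path: Union[str, Path]) -> list[Union[CaseRecord, ValidationReport]]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    _check_duplicates(payload)
    return [validate_case(obj) for obj in payload]


def write_cases_json(cases: Iterable[CaseRecord], path: Union[str, Path]) -> None:
    payload = [case.model_dump(mode="json") for case in cases]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
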