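"""Scenario classification engine for the VHL variant evidence framework.

A validated :class:`~int2grate_vhl.evidence_model.CaseRecord` is reduced to
a discrete :class:`EvidenceVector` (tumor counts T and RCC counts R,
features, family history F, somatic allelic status S, age band) and
classified through a declarative :class:`ScenarioTable` into one of 17
codes across four actionability categories:

* ``I-*``   Positive — all evidence aligns conservatively with VHL syndrome;
* ``II-*``  Neutral  — evidence strong but insufficient for a complete
  assessment;
* ``III-*`` Negative — the evidence pattern does not support VHL syndrome;
* ``IV-*``  NOS      — a key piece of evidence is absent.

The table is data, not code: rules live in a YAML file whose loader
verifies totality and pairwise disjointness over the fully enumerated
discretized vector space before any classification, so the classification
is deterministic and priority never has to break a tie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Any, Iterator, Mapping, Optional, Sequence, Union

import yaml

from .evidence_model import (
    CaseRecord,
    FamilyDegree,
    FamilyHistory,
    VariantClassification,
    Zygosity,
)
from .somatic_analysis import (
    SomaticQCConfig,
    CopyCallConfig,
    SomaticStatus,
    allelic_status,
    qc_filter,
)

__all__ = [
    "Category",
    "AgeBand",
    "GateResult",
    "EvidenceVector",
    "Condition",
    "ScenarioRule",
    "ScenarioTable",
    "TableValidationError",
    "Classification",
    "EngineConfig",
    "load_scenario_table",
    "gate",
    "derive_vector",
    "classify",
    "classify_case",
    "enumerate_vector_space",
]


class Category(str, Enum):
    Positive = "Positive"
    Negative = "Negative"
    Neutral = "Neutral"
    NOS = "NOS"


#: Roman-prefix <-> category correspondence for the code families.
CODE_FAMILY = {"I": Category.Positive, "II": Category.Neutral,
               "III": Category.Negative, "IV": Category.NOS}

#: All 17 codes the default framework defines.
ALL_CODES = (
    ["I-I", "I-II", "I-III", "I-IV"]
    + ["II-I", "II-II", "II-III", "II-IV", "II-V", "II-VI", "II-VII"]
    + ["III-I", "III-II", "III-III"]
    + ["IV-I", "IV-II", "IV-III"]
)

#: Codes whose predicates require somatic genetic data.
SOMATIC_GATED_CODES = frozenset({"I-II", "I-III", "II-I", "II-II", "II-III", "III-I"})


class AgeBand(str, Enum):
    young = "young"
    adult = "adult"
    unknown = "unknown"


@dataclass(frozen=True)
class EngineConfig:
    """Tunable evidence-derivation parameters.

    ``age_young_threshold`` (years) splits the young/adult bands; component
    tumors in VHL syndrome have mean diagnosis ages in the twenties and
    thirties, so 30 is the default.  The heterozygous VAF band and somatic
    QC/copy thresholds are passed through to the somatic layer.
    """

    age_young_threshold: int = 30
    qc: SomaticQCConfig = field(default_factory=SomaticQCConfig)
    copy: CopyCallConfig = field(default_factory=CopyCallConfig)
    het_vaf_band: tuple[float, float] = (40.0, 60.0)


class GateResult:
    __slots__ = ("eligible", "reason")

    def __init__(self, eligible: bool, reason: Optional[str] = None):
        self.eligible = eligible
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover
        return f"GateResult(eligible={self.eligible}, reason={self.reason!r})"


def gate(case: CaseRecord) -> GateResult:
    """Eligibility gate applied before any scenario matching.

    The framework assesses heterozygous germline VHL variants only, in
    patients evaluated in a genetics clinic, and requires the absence of
    pathogenic / likely pathogenic germline findings in the differential
    gene panel.
    """
    if case.germline is None:
        return GateResult(False, "no_germline_variant")
    if case.germline.zygosity in (
        Zygosity.homozygous,
        Zygosity.compound_heterozygous,
        Zygosity.hemizygous,
    ):
        return GateResult(False, "non_heterozygous")
    if any(
        f.classification in (VariantClassification.P, VariantClassification.LP)
        for f in case.differential_findings
    ):
        return GateResult(False, "differential_positive")
    if not case.clinical.evaluated_in_genetics:
        return GateResult(False, "not_evaluated_in_genetics")
    return GateResult(True, None)


@dataclass(frozen=True)
class EvidenceVector:
    eligible: bool
    gate_reason: Optional[str]
    n_vhl_tumors: int
    n_rcc: int
    has_vhl_feature: bool
    has_non_vhl_tumor: bool
    family_history: FamilyHistory
    somatic_available: bool
    somatic_status: SomaticStatus
    age_band: AgeBand
    germline_class: Optional[VariantClassification]

    def __post_init__(self) -> None:
        if self.n_rcc > self.n_vhl_tumors:
            raise ValueError("n_rcc cannot exceed n_vhl_tumors")
        if not self.somatic_available and self.somatic_status is not SomaticStatus.uninformative:
            raise ValueError("somatic_status must be uninformative without somatic data")

    def discretized(self) -> dict[str, Any]:
        """The discrete fields the scenario table reasons over."""
        t = self.n_vhl_tumors
        r = self.n_rcc
        return {
            "eligible": self.eligible,
            "gate_reason": self.gate_reason or "",
            "t_band": min(t, 2),
            "rcc_band": min(r, 2),
            "all_rcc": t >= 1 and r == t,
            "has_vhl_feature": self.has_vhl_feature,
            "has_non_vhl_tumor": self.has_non_vhl_tumor,
            "family_history": self.family_history.value,
            "somatic_available": self.somatic_available,
            "somatic_status": self.somatic_status.value,
            "age_band": self.age_band.value,
            "germline_class": self.germline_class.value if self.germline_class else "",
        }

    def pattern(self) -> str:
        """Canonical, de-identified serialization of the discretized fields
        (the "evidence pattern" unit the quantifier counts)."""
        d = self.discretized()
        return ";".join(f"{k}={d[k]}" for k in sorted(d))


def derive_vector(case: CaseRecord, config: EngineConfig = EngineConfig()) -> EvidenceVector:
    """Reduce a case to the discrete evidence the scenario table consumes.

    T counts VHL component tumors only, per laterality (bilateral RCC
    counts twice); SDH-deficient paragangliomas are excluded because they
    indicate an SDHx differential etiology.  F is positive only for a
    first- or second-degree relative diagnosed with VHL syndrome.  S is the
    allelic status of the QC-retained somatic VHL alterations from
    component-tumor profiles.
    """
    g = gate(case)
    t = r = 0
    for tumor in case.clinical.personal_tumors:
        if not tumor.is_vhl_component:
            continue
        if tumor.tumor_type == "paraganglioma" and tumor.sdh_deficient:
            continue
        t += tumor.laterality_count
        if tumor.tumor_type == "rcc":
            r += tumor.laterality_count

    fh = case.clinical.family_history_vhl
    if fh is FamilyHistory.positive and case.clinical.family_degree not in (
        FamilyDegree.first,
        FamilyDegree.second,
    ):
        fh = FamilyHistory.negative  # distant relatives do not meet the criterion

    somatic_available = case.somatic_tested
    if somatic_available:
        retained = qc_filter(case.somatic, config.qc).retained
        status = allelic_status(retained, config.copy).status
    else:
        status = SomaticStatus.uninformative

    age = case.clinical.age_years
    if age is None:
        band = AgeBand.unknown
    elif age < config.age_young_threshold:
        band = AgeBand.young
    else:
        band = AgeBand.adult

    return EvidenceVector(
        eligible=g.eligible,
        gate_reason=g.reason,
        n_vhl_tumors=t,
        n_rcc=r,
        has_vhl_feature=bool(case.clinical.personal_features),
        has_non_vhl_tumor=any(
            not tu.is_vhl_component for tu in case.clinical.personal_tumors
        ),
        family_history=fh,
        somatic_available=somatic_available,
        somatic_status=status,
        age_band=band,
        germline_class=case.germline.reported_classification if case.germline else None,
    )


# ---------------------------------------------------------------------------
# declarative rules

_OPS = {
    "eq": lambda v, arg: v == arg,
    "ne": lambda v, arg: v != arg,
    "in": lambda v, arg: v in arg,
    "ge": lambda v, arg: v >= arg,
    "le": lambda v, arg: v <= arg,
}


@dataclass(frozen=True)
class Condition:
    op: str
    arg: Any

    def holds(self, value: Any) -> bool:
        return _OPS[self.op](value, self.arg)


@dataclass(frozen=True)
class ScenarioRule:
    id: str
    code: str
    category: Category
    when: tuple[tuple[str, Condition], ...]
    comment: str
    priority: int

    def matches(self, discretized: Mapping[str, Any]) -> bool:
        return all(cond.holds(discretized[field]) for field, cond in self.when)


class TableValidationError(ValueError):
    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("table_invalid: " + "; ".join(self.problems))


@dataclass(frozen=True)
class ScenarioTable:
    rules: tuple[ScenarioRule, ...]
    fallback_code: str
    fallback_comment: str
    metadata: Mapping[str, Any]

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(r.code for r in self.rules) | {self.fallback_code}


def _category_for_code(code: str) -> Category:
    return CODE_FAMILY[code.split("-", 1)[0]]


def enumerate_vector_space() -> Iterator[dict[str, Any]]:
    """Exhaustively enumerate the discretized evidence-vector space (the
    domain over which totality and disjointness are verified)."""
    tr_combos = [
        (0, 0, False),
        (1, 0, False),
        (1, 1, True),
        (2, 0, False),
        (2, 1, False),
        (2, 2, False),  # mixed: at least one non-RCC alongside >=2 RCC
        (2, 2, True),   # all tumors are RCC
    ]
    somatic_combos = [(False, SomaticStatus.uninformative.value)] + [
        (True, s.value) for s in SomaticStatus
    ]
    gate_states = [(True, "")] + [
        (False, reason)
        for reason in (
            "no_germline_variant",
            "non_heterozygous",
            "differential_positive",
            "not_evaluated_in_genetics",
        )
    ]
    for (eligible, reason), (t, r, allr), feat, nonvhl, fh, (sa, status), age in product(
        gate_states,
        tr_combos,
        [False, True],
        [False, True],
        [f.value for f in FamilyHistory],
        somatic_combos,
        [b.value for b in AgeBand],
    ):
        yield {
            "eligible": eligible,
            "gate_reason": reason,
            "t_band": t,
            "rcc_band": r,
            "all_rcc": allr,
            "has_vhl_feature": feat,
            "has_non_vhl_tumor": nonvhl,
            "family_history": fh,
            "somatic_available": sa,
            "somatic_status": status,
            "age_band": age,
            "germline_class": "",
        }


def validate_table(table: ScenarioTable) -> list[str]:
    """Structural and semantic validation; returns the list of problems."""
    problems: list[str] = []
    if table.codes != set(ALL_CODES):
        missing = set(ALL_CODES) - table.codes
        extra = table.codes - set(ALL_CODES)
        problems.append(f"code set mismatch (missing={sorted(missing)}, extra={sorted(extra)})")
    for rule in table.rules:
        if _category_for_code(rule.code) is not rule.category:
            problems.append(f"rule {rule.id}: code {rule.code} inconsistent with category {rule.category.value}")
    if _category_for_code(table.fallback_code) is not Category.NOS:
        problems.append("fallback code must be in the NOS family")
    for vec in enumerate_vector_space():
        hits = [r.id for r in table.rules if r.matches(vec)]
        if len(hits) > 1:
            problems.append(f"rules overlap on {vec}: {hits}")
            break
    return problems


def _load_rules(doc: Mapping[str, Any]) -> ScenarioTable:
    rules = []
    for spec in doc["rules"]:
        when = []
        for field_name, cond in spec["when"].items():
            (op, arg), = cond.items()
            when.append((field_name, Condition(op=op, arg=tuple(arg) if isinstance(arg, list) else arg)))
        rules.append(
            ScenarioRule(
                id=spec["id"],
                code=spec["code"],
                category=Category(spec["category"]),
                when=tuple(when),
                comment=" ".join(str(spec["comment"]).split()),
                priority=int(spec.get("priority", 100)),
            )
        )
    rules.sort(key=lambda r: r.priority)
    return ScenarioTable(
        rules=tuple(rules),
        fallback_code=doc.get("fallback_code", "IV-I"),
        fallback_comment=" ".join(str(doc.get("fallback_comment", "")).split()),
        metadata=dict(doc.get("metadata", {})),
    )


def load_scenario_table(
    path: Optional[Union[str, Path]] = None, *, validate: bool = True
) -> ScenarioTable:
    """Load a scenario table (the packaged default when ``path`` is None)
    and verify totality/disjointness/code-category consistency."""
    if path is None:
        text = (resources.files("int2grate_vhl") / "data" / "scenario_table_vhl.yaml").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    table = _load_rules(yaml.safe_load(text))
    if validate:
        problems = validate_table(table)
        if problems:
            raise TableValidationError(problems)
    return table


@dataclass(frozen=True)
class Classification:
    code: str
    category: Category
    comment: str
    matched_rule_id: Optional[str]
    evidence_pattern: str


def classify(vector: EvidenceVector, table: ScenarioTable) -> Classification:
    """Deterministic scenario assignment for one evidence vector."""
    d = vector.discretized()
    for rule in table.rules:
        if rule.matches(d):
            return Classification(
                code=rule.code,
                category=rule.category,
                comment=rule.comment,
                matched_rule_id=rule.id,
                evidence_pattern=vector.pattern(),
            )
    return Classification(
        code=table.fallback_code,
        category=_category_for_code(table.fallback_code),
        comment=table.fallback_comment,
        matched_rule_id=None,
        evidence_pattern=vector.pattern(),
    )


def classify_case(
    case: CaseRecord,
    table: Optional[ScenarioTable] = None,
    config: EngineConfig = EngineConfig(),
) -> Classification:
    if table is None:
        table = load_scenario_table()
    return classify(derive_vector(case, config), table)
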