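"""Deterministic synthetic case cohorts with exact scenario truth labels.

Generation is scenario-first: a scenario code is apportioned from the
requested mix (largest-remainder, so the realized counts match the mix
exactly), then a case is *constructed* to satisfy that scenario's
predicate, then decorated with a plausible VHL variant, age, and sex.
Truth labels are therefore exact by construction, and encoding a generated
cohort must reproduce them row for row.

Default marginals emulate a retrospective germline cohort evaluated in a
genetics clinic: ~74% female, median diagnosis age in the fifties, ~60%
VUS / ~22% P-LP / ~11% B-LB / ~7% ECYT2-only classifications, and somatic
profiling available for a small minority (~8%) of cases.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from random import Random
from typing import Optional, Union

from .evidence_model import CASE_TABLE_COLUMNS
from .vef_engine import ALL_CODES, SOMATIC_GATED_CODES

__all__ = [
    "CohortSpec",
    "InfeasibleSpecError",
    "generate",
    "write_cohort_tsv",
    "write_truth_tsv",
    "fixture",
    "FIXTURE_NAMES",
]


class InfeasibleSpecError(ValueError):
    """The requested mix cannot be constructed (e.g., a somatic-gated
    scenario requested in a cohort declared to have no somatic data)."""


def _uniform_mix() -> dict[str, float]:
    return {code: 1.0 / len(ALL_CODES) for code in ALL_CODES}


def _default_classification_mix() -> dict[str, float]:
    return {"P": 0.150, "LP": 0.068, "VUS": 0.602, "LB": 0.056, "B": 0.056, "P_ECYT2": 0.068}


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 100
    seed: int = 0
    scenario_mix: dict[str, float] = field(default_factory=_uniform_mix)
    classification_mix: dict[str, float] = field(default_factory=_default_classification_mix)
    somatic_fraction: float = 11 / 133
    sex_female_fraction: float = 0.74
    age_young_range: tuple[int, int] = (10, 29)
    age_adult_range: tuple[int, int] = (31, 85)

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        for name in ("scenario_mix", "classification_mix"):
            mix = getattr(self, name)
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        unknown = set(self.scenario_mix) - set(ALL_CODES)
        if unknown:
            raise ValueError(f"unknown scenario codes in mix: {sorted(unknown)}")


def _apportion(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so realized counts match the mix."""
    quotas = {code: n * p for code, p in mix.items()}
    counts = {code: int(q) for code, q in quotas.items()}
    remainder = n - sum(counts.values())
    order = sorted(mix, key=lambda c: (-(quotas[c] - counts[c]), c))
    for code in order[:remainder]:
        counts[code] += 1
    return counts


# Decoration pools: recurrent small variants observed for each reported
# classification class (SNVs, indels, and deep-intronic E1' variants).
_PLP_VARIANTS = [
    "c.208G>A", "c.341-1G>A", "c.464-1G>C", "c.506_509delinsCG",
    "c.217C>T", "c.227_229del", "c.371C>T",
]
_VUS_VARIANTS = [
    "c.340+578C>T", "c.340+691C>G", "c.340+705G>A", "c.340+742G>T",
    "c.340+694_340+711dup", "c.345C>A", "c.532C>G", "c.25G>A", "c.5C>T",
    "c.626A>G", "c.631A>C", "c.545G>A", "c.613C>T", "c.123_137del", "c.3G>A",
]
_BLB_VARIANTS = ["c.613C>T", "c.25G>A", "c.5C>T", "c.631A>C"]
_ECYT2_VARIANTS = ["c.598C>T", "c.562C>G", "c.388G>A", "c.429C>T"]

_NON_VHL_TUMORS = [
    "breast carcinoma", "colon adenocarcinoma", "melanoma",
    "prostate adenocarcinoma", "urothelial carcinoma", "cervical carcinoma",
]

_SECOND_HIT = "c.499C>T|snv|38||210|55|0|3|{src}"
_BIALLELIC = "c.263G>A|snv|72||160|80|0|2|{src};|one_copy_deletion||-0.85|||||{src}"


def _blank_row(sid: str) -> dict[str, str]:
    row = {col: "" for col in CASE_TABLE_COLUMNS}
    row.update(
        subject_id=sid,
        zygosity="heterozygous",
        evaluated_in_genetics="true",
        family_history_vhl="negative",
        somatic_tested="false",
        differential_findings="none",
    )
    return row


def _build_for_code(
    code: str, row: dict[str, str], rng: Random, young_range: tuple[int, int] = (10, 29)
) -> None:
    """Mutate a blank row so its evidence vector matches exactly `code`."""
    young = str(rng.randint(*young_range))
    if code == "I-I":
        row["personal_tumors"] = "cns_hemangioblastoma;retinal_hemangioblastoma"
    elif code == "I-II":
        row["personal_tumors"] = "cns_hemangioblastoma;rcc"
        row["somatic_tested"] = "true"
        row["somatic_alterations"] = _SECOND_HIT.format(src="rcc")
    elif code == "I-III":
        row["personal_tumors"] = "pheochromocytoma"
        row["family_history_vhl"] = "positive"
        row["family_degree"] = rng.choice(["first", "second"])
        row["somatic_tested"] = "true"
        row["somatic_alterations"] = _SECOND_HIT.format(src="pheochromocytoma")
    elif code == "I-IV":
        row["personal_tumors"] = "rcc:2;cns_hemangioblastoma"
        row["family_history_vhl"] = "positive"
        row["family_degree"] = "first"
    elif code == "II-I":
        row["personal_tumors"] = "cns_hemangioblastoma;rcc"
        row["somatic_tested"] = "true"
        row["somatic_alterations"] = _BIALLELIC.format(src="rcc")
    elif code == "II-II":
        row["personal_tumors"] = "pancreatic_net"
        row["somatic_tested"] = "true"
        row["somatic_alterations"] = _SECOND_HIT.format(src="pancreatic_net")
    elif code == "II-III":
        row["personal_tumors"] = "rcc"
        row["somatic_tested"] = "true"
        row["somatic_alterations"] = _SECOND_HIT.format(src="rcc")
    elif code == "II-IV":
        row["personal_tumors"] = "rcc:2"
    elif code == "II-V":
        row["personal_tumors"] = "retinal_hemangioblastoma"
        row["age_years"] = young
    elif code == "II-VI":
        row["family_history_vhl"] = "positive"
        row["family_degree"] = rng.choice(["first", "second"])
        row["age_years"] = young
    elif code == "II-VII":
        row["personal_tumors"] = "rcc:2"
        row["age_years"] = young
    elif code == "III-I":
        row["personal_tumors"] = "rcc"
        row["somatic_tested"] = "true"
        row["somatic_alterations"] = _BIALLELIC.format(src="rcc")
    elif code == "III-II":
        row["non_vhl_tumors"] = rng.choice(_NON_VHL_TUMORS)
    elif code == "III-III":
        pass  # no tumors at all
    elif code == "IV-I":
        row["zygosity"] = rng.choice(["homozygous", "compound_heterozygous"])
    elif code == "IV-II":
        row["personal_tumors"] = rng.choice(
            ["cns_hemangioblastoma", "paraganglioma", "pheochromocytoma"]
        )
    elif code == "IV-III":
        row["differential_findings"] = rng.choice(["SDHB:P", "FH:LP", "RET:P"])
        row["personal_tumors"] = "pheochromocytoma"
    else:  # pragma: no cover - guarded by CohortSpec validation
        raise InfeasibleSpecError(f"no builder for scenario code {code}")


#: Codes whose predicates ignore the somatic fields entirely; these may be
#: decorated with a negative somatic work-up without changing the label.
_SOMATIC_AGNOSTIC = frozenset({"I-I", "I-IV", "II-IV", "II-VI", "II-VII", "III-II", "III-III"})


def generate(spec: CohortSpec) -> tuple[list[dict[str, str]], list[dict[str, str]]]:
    """Generate a case table and its truth table (intended code per row).

    Same spec + seed gives byte-identical tables.  Raises
    :class:`InfeasibleSpecError` when a somatic-gated scenario is requested
    with ``somatic_fraction`` zero.
    """
    gated = [c for c in SOMATIC_GATED_CODES if spec.scenario_mix.get(c, 0) > 0]
    if gated and spec.somatic_fraction == 0:
        raise InfeasibleSpecError(
            f"infeasible_spec: scenarios {sorted(gated)} require somatic data "
            "but somatic_fraction is 0"
        )
    rng = Random(spec.seed)
    counts = _apportion(spec.scenario_mix, spec.n_cases)
    codes = [code for code in ALL_CODES for _ in range(counts.get(code, 0))]
    rng.shuffle(codes)

    cls_counts = _apportion(spec.classification_mix, spec.n_cases)
    classes = [c for c in sorted(cls_counts) for _ in range(cls_counts[c])]
    rng.shuffle(classes)

    pools = {
        "P": _PLP_VARIANTS, "LP": _PLP_VARIANTS, "VUS": _VUS_VARIANTS,
        "LB": _BLB_VARIANTS, "B": _BLB_VARIANTS, "P_ECYT2": _ECYT2_VARIANTS,
    }

    rows: list[dict[str, str]] = []
    truth: list[dict[str, str]] = []
    for i, code in enumerate(codes):
        sid = f"SYN{rng.getrandbits(40):010x}"
        row = _blank_row(sid)
        _build_for_code(code, row, rng, spec.age_young_range)

        cls = classes[i]
        row["vhl_classification"] = cls
        if cls in ("P", "LP") and rng.random() < 0.4:
            # germline copy-number deletion (multi-exon or whole gene)
            row["vhl_hgvs_c"] = ""
            row["deleted_exons"] = rng.choice(["1,2,3", "2,3", "1,2"])
        else:
            row["vhl_hgvs_c"] = rng.choice(pools[cls])
        row["sex"] = "female" if rng.random() < spec.sex_female_fraction else "male"
        if not row["age_years"]:
            row["age_years"] = str(rng.randint(*spec.age_adult_range))
        if (
            code in _SOMATIC_AGNOSTIC
            and row["somatic_tested"] == "false"
            and rng.random() < spec.somatic_fraction
        ):
            row["somatic_tested"] = "true"  # profiled, no VHL alteration found
        rows.append(row)
        truth.append({"subject_id": sid, "code": code})
    return rows, truth


def _write_rows(rows: list[dict[str, str]], columns: list[str], path: Union[str, Path]) -> None:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=columns, delimiter="\t", lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_cohort_tsv(rows: list[dict[str, str]], path: Union[str, Path]) -> None:
    _write_rows(rows, CASE_TABLE_COLUMNS, path)


def write_truth_tsv(truth: list[dict[str, str]], path: Union[str, Path]) -> None:
    _write_rows(truth, ["subject_id", "code"], path)


# ---------------------------------------------------------------------------
# packaged worked-example fixtures

FIXTURE_NAMES = {
    "patients_21_23": "patients_21_23.tsv",
    "portal_c340+578": "portal_c340plus578.tsv",
    "ecyt2_carriers": "ecyt2_carriers.tsv",
    "mixed_demo": "mixed_demo.tsv",
}


def fixture(name: str) -> list[dict[str, str]]:
    """Return a packaged worked-example case table as raw rows."""
    try:
        filename = FIXTURE_NAMES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_NAMES)}"
        ) from None
    text = (resources.files("int2grate_vhl") / "data" / "fixtures" / filename).read_text(
        encoding="utf-8"
    )
    return list(csv.DictReader(io.StringIO(text), delimiter="\t"))
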