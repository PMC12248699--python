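"""Batch encoder: case table in, coded table out.

Reads a case table (TSV or JSON), validates each row, derives the evidence
vector, classifies it through the scenario table, and appends the code,
category, comment, canonical evidence pattern, and gate reason to every
row.  Row count and subject ids are preserved; invalid rows are carried
through under the NOS fallback code with the validation message in the
comment (strict mode aborts instead).
"""

from __future__ import annotations

import logging
import secrets
from pathlib import Path
from random import Random
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import evidence_model as em
from . import pattern_quantifier as pq
from .vef_engine import (
    Classification,
    EngineConfig,
    ScenarioTable,
    derive_vector,
    load_scenario_table,
)

__all__ = [
    "ENCODED_COLUMNS",
    "encode_cases",
    "encode_table",
    "encode_file",
    "assign_subject_ids",
]

log = logging.getLogger(__name__)

ENCODED_COLUMNS = em.CASE_TABLE_COLUMNS + [
    "variant_key",
    "int2grate_code",
    "int2grate_category",
    "comment",
    "evidence_pattern",
    "gate_reason",
]


def _variant_key(case: em.CaseRecord) -> str:
    g = case.germline
    if g is None:
        return ""
    if g.is_copy_number:
        return pq.deletion_key(g.deleted_exons)
    return pq.normalize_variant_key(g.hgvs_c or "")


def _encoded_row(
    row: dict[str, str], classification: Optional[Classification], message: str = ""
) -> dict[str, str]:
    out = dict(row)
    if classification is None:
        out.update(
            int2grate_code="",
            int2grate_category="",
            comment=message,
            evidence_pattern="",
            gate_reason="invalid_record",
        )
    else:
        out.update(
            int2grate_code=classification.code,
            int2grate_category=classification.category.value,
            comment=classification.comment,
            evidence_pattern=classification.evidence_pattern,
            gate_reason=message,
        )
    return out


def encode_cases(
    cases: Sequence[Union[em.CaseRecord, em.ValidationReport]],
    table: Optional[ScenarioTable] = None,
    config: EngineConfig = EngineConfig(),
    *,
    strict: bool = False,
    raw_rows: Optional[Sequence[dict[str, str]]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Encode validated cases (or their validation reports).

    Returns the encoded table plus a run report with per-code and
    per-category counts.  ``raw_rows`` preserves original input columns;
    when omitted they are regenerated from the records.
    """
    if table is None:
        table = load_scenario_table()
    from .vef_engine import classify  # local to keep import graph simple

    rows: list[dict[str, str]] = []
    report: dict = {
        "n_rows": len(cases),
        "n_invalid": 0,
        "by_code": {},
        "by_category": {},
        "table_version": table.metadata.get("version", ""),
    }
    for i, item in enumerate(cases):
        raw = (
            dict(raw_rows[i])
            if raw_rows is not None
            else (em.case_to_row(item) if isinstance(item, em.CaseRecord) else {})
        )
        if isinstance(item, em.ValidationReport):
            if strict:
                raise em.CaseValidationError(item)
            report["n_invalid"] += 1
            raw.setdefault("subject_id", item.subject_id or "")
            out = dict(raw)
            out.update(
                variant_key="",
                int2grate_code=table.fallback_code,
                int2grate_category="NOS",
                comment=f"invalid record: {item}",
                evidence_pattern="",
                gate_reason="invalid_record",
            )
            code = table.fallback_code
            category = "NOS"
        else:
            vector = derive_vector(item, config)
            cls = classify(vector, table)
            out = dict(raw)
            out.update(
                variant_key=_variant_key(item),
                int2grate_code=cls.code,
                int2grate_category=cls.category.value,
                comment=cls.comment,
                evidence_pattern=cls.evidence_pattern,
                gate_reason=vector.gate_reason or "",
            )
            code, category = cls.code, cls.category.value
        report["by_code"][code] = report["by_code"].get(code, 0) + 1
        report["by_category"][category] = report["by_category"].get(category, 0) + 1
        rows.append(out)

    df = pd.DataFrame(rows, columns=ENCODED_COLUMNS, dtype=object)
    df = df.fillna("")
    return df, report


def encode_table(
    rows: Iterable[dict[str, str]],
    table: Optional[ScenarioTable] = None,
    config: EngineConfig = EngineConfig(),
    *,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Encode raw TSV-shaped rows (dicts of strings)."""
    rows = list(rows)
    em._check_duplicates(rows)
    cases = [em.validate_case(em.row_to_raw(r)) for r in rows]
    kept = [{k: r.get(k, "") for k in em.CASE_TABLE_COLUMNS} for r in rows]
    return encode_cases(cases, table, config, strict=strict, raw_rows=kept)


def encode_file(
    input_path: Union[str, Path],
    output_path: Optional[Union[str, Path]] = None,
    table: Optional[ScenarioTable] = None,
    config: EngineConfig = EngineConfig(),
    *,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Encode a TSV (or JSON) case table from disk; optionally write the
    coded TSV next to a JSON run report."""
    input_path = Path(input_path)
    if input_path.suffix.lower() == ".json":
        cases = em.read_cases_json(input_path)
        df, report = encode_cases(cases, table, config, strict=strict)
    else:
        import csv

        with open(input_path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        df, report = encode_table(rows, table, config, strict=strict)
    log.info(
        "encoded %d rows (%d invalid): %s",
        report["n_rows"],
        report["n_invalid"],
        report["by_category"],
    )
    if output_path is not None:
        df.to_csv(output_path, sep="\t", index=False)
    return df, report


def assign_subject_ids(
    rows: Sequence[dict[str, str]], seed: Optional[int] = None, prefix: str = "S"
) -> list[dict[str, str]]:
    """Assign fresh opaque subject ids (stable under a given seed, PHI-free).

    With no seed, ids are drawn from the system entropy source.
    """
    rng = Random(seed) if seed is not None else None
    seen: set[str] = set()
    out = []
    for row in rows:
        while True:
            token = (
                f"{rng.getrandbits(40):010x}" if rng is not None else secrets.token_hex(5)
            )
            sid = f"{prefix}{token}"
            if sid not in seen:
                break
        seen.add(sid)
        new = dict(row)
        new["subject_id"] = sid
        out.append(new)
    return out
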