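"""De-identified, shareable per-variant portal records.

Each record aggregates one variant across the cohort: its gene region, its
recurrence (distinct subjects), and its unique evidence patterns with
counts.  Records deliberately carry no subject ids, no exact ages (only
the young/adult band inside the pattern), and no free-text clinical notes,
so they are safe to publish.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import gene_annotation, pattern_quantifier as pq

__all__ = [
    "PortalPattern",
    "PortalRecord",
    "InconsistentInputsError",
    "build_portal",
    "query",
    "write_portal_json",
    "read_portal_json",
    "write_portal_tsv",
]


class InconsistentInputsError(ValueError):
    """Pattern summaries and encoded table describe different cohorts."""


@dataclass(frozen=True)
class PortalPattern:
    pattern: str
    code: str
    category: str
    count: int
    tumor_summary: str
    family_history: str
    age_band: str


@dataclass(frozen=True)
class PortalRecord:
    variant_key: str
    region: str
    recurrence: int
    patterns: tuple[PortalPattern, ...]
    table_version: str
    provenance: str


_PATTERN_FIELD_RE = re.compile(r"(\w+)=([^;]*)")


def _pattern_fields(pattern: str) -> dict[str, str]:
    return dict(_PATTERN_FIELD_RE.findall(pattern))


def _region_for_key(key: str, tmap: gene_annotation.TranscriptMap) -> str:
    if key.startswith("del:exons"):
        exons = frozenset(
            int(e) for e in key[len("del:exons"):].split(",") if e.strip()
        )
        return gene_annotation.region_for_deletion(exons, tmap).value
    try:
        parsed = gene_annotation.parse_cdna(key)
    except gene_annotation.BadHgvsError:
        return gene_annotation.Region.other.value
    return gene_annotation.map_region(parsed, tmap).value


def build_portal(
    encoded: pd.DataFrame,
    summaries: Sequence[pq.VariantPatternSummary],
    tmap: Optional[gene_annotation.TranscriptMap] = None,
    *,
    table_version: str = "",
    provenance: str = "default scenario table (reconstructed); see table metadata",
) -> list[PortalRecord]:
    """One de-identified record per distinct variant, ordered by key."""
    if tmap is None:
        tmap = gene_annotation.load_transcript_map()
    table_keys = {
        pq.normalize_variant_key(k)
        for k in encoded["variant_key"].astype(str)
        if k.strip()
    }
    records = []
    for summary in sorted(summaries, key=lambda s: s.variant_key):
        if summary.variant_key not in table_keys:
            raise InconsistentInputsError(
                f"inconsistent_inputs: {summary.variant_key!r} absent from encoded table"
            )
        patterns = []
        for pc in summary.patterns:
            f = _pattern_fields(pc.pattern)
            tumor_summary = (
                f"vhl_tumors={f.get('t_band', '?')};rcc={f.get('rcc_band', '?')};"
                f"features={f.get('has_vhl_feature', '?')};"
                f"non_vhl_tumors={f.get('has_non_vhl_tumor', '?')}"
            )
            patterns.append(
                PortalPattern(
                    pattern=pc.pattern,
                    code=pc.code,
                    category=pc.category,
                    count=pc.count,
                    tumor_summary=tumor_summary,
                    family_history=f.get("family_history", "unknown"),
                    age_band=f.get("age_band", "unknown"),
                )
            )
        records.append(
            PortalRecord(
                variant_key=summary.variant_key,
                region=_region_for_key(summary.variant_key, tmap),
                recurrence=summary.recurrence,
                patterns=tuple(patterns),
                table_version=table_version,
                provenance=provenance,
            )
        )
    return records


def query(records: Iterable[PortalRecord], variant_key: str) -> Optional[PortalRecord]:
    """Look up a variant (key normalized exactly as the quantifier does);
    returns None rather than raising when absent."""
    key = pq.normalize_variant_key(variant_key)
    for record in records:
        if record.variant_key == key:
            return record
    return None


def write_portal_json(records: Iterable[PortalRecord], path: Union[str, Path]) -> None:
    payload = [asdict(r) for r in records]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_portal_json(path: Union[str, Path]) -> list[PortalRecord]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        PortalRecord(
            variant_key=obj["variant_key"],
            region=obj["region"],
            recurrence=obj["recurrence"],
            patterns=tuple(PortalPattern(**p) for p in obj["patterns"]),
            table_version=obj["table_version"],
            provenance=obj["provenance"],
        )
        for obj in payload
    ]


def write_portal_tsv(records: Iterable[PortalRecord], path: Union[str, Path]) -> None:
    """Flat one-row-per-pattern view for spreadsheet users."""
    rows = []
    for r in records:
        for p in r.patterns:
            rows.append(
                {
                    "variant_key": r.variant_key,
                    "region": r.region,
                    "recurrence": r.recurrence,
                    "code": p.code,
                    "category": p.category,
                    "pattern_count": p.count,
                    "tumor_summary": p.tumor_summary,
                    "family_history": p.family_history,
                    "age_band": p.age_band,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
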