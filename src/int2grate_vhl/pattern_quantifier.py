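"""Variant recurrence and unique evidence patterns over an encoded cohort.

Recurrence is the number of distinct subjects carrying a variant; the
unique patterns are the distinct canonical evidence-pattern serializations
observed for that variant, each with its multiplicity.  Pattern counts for
a variant always sum to its recurrence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "normalize_variant_key",
    "deletion_key",
    "PatternCount",
    "VariantPatternSummary",
    "recurrence",
    "unique_patterns",
    "summarize_all",
    "write_patterns_json",
    "read_patterns_json",
]

_GENE_PREFIX_RE = re.compile(r"^vhl:", re.IGNORECASE)


def normalize_variant_key(hgvs_c: str) -> str:
    """Canonical variant key: whitespace stripped, optional gene prefix
    removed, case-folded ("VHL: c.340+578C>T" == "c.340+578c>t")."""
    key = re.sub(r"\s+", "", str(hgvs_c))
    key = _GENE_PREFIX_RE.sub("", key)
    return key.casefold()


def deletion_key(deleted_exons: Optional[Iterable[int]]) -> str:
    """Large germline deletions are keyed by the deleted-exon set."""
    exons = sorted(set(deleted_exons or ()))
    return "del:exons" + ",".join(str(e) for e in exons)


@dataclass(frozen=True)
class PatternCount:
    pattern: str
    code: str
    category: str
    count: int


@dataclass(frozen=True)
class VariantPatternSummary:
    variant_key: str
    recurrence: int
    patterns: tuple[PatternCount, ...]


def _subset(encoded: pd.DataFrame, variant_key: str) -> pd.DataFrame:
    key = normalize_variant_key(variant_key)
    keys = encoded["variant_key"].astype(str).map(normalize_variant_key)
    return encoded.loc[keys == key]


def recurrence(encoded: pd.DataFrame, variant_key: str) -> int:
    """Count of distinct subjects carrying the variant (a subject
    contributes once even with duplicate rows); unknown keys count 0."""
    sub = _subset(encoded, variant_key)
    return int(sub["subject_id"].nunique())


def unique_patterns(encoded: pd.DataFrame, variant_key: str) -> VariantPatternSummary:
    """Group the variant's subjects by canonical evidence pattern.

    Ordering is deterministic: descending count, then lexicographic
    pattern.  Duplicate rows for one subject collapse to that subject's
    single pattern entry.
    """
    key = normalize_variant_key(variant_key)
    sub = _subset(encoded, variant_key)
    sub = sub.drop_duplicates(subset=["subject_id"])
    groups: dict[tuple[str, str, str], int] = {}
    for _, row in sub.iterrows():
        k = (
            str(row["evidence_pattern"]),
            str(row["int2grate_code"]),
            str(row["int2grate_category"]),
        )
        groups[k] = groups.get(k, 0) + 1
    patterns = sorted(groups.items(), key=lambda kv: (-kv[1], kv[0][0]))
    return VariantPatternSummary(
        variant_key=key,
        recurrence=int(sub["subject_id"].nunique()),
        patterns=tuple(
            PatternCount(pattern=p, code=c, category=cat, count=n)
            for (p, c, cat), n in patterns
        ),
    )


def summarize_all(encoded: pd.DataFrame) -> list[VariantPatternSummary]:
    """One summary per distinct variant key, sorted by key."""
    keys = sorted(
        {
            normalize_variant_key(k)
            for k in encoded["variant_key"].astype(str)
            if k.strip()
        }
    )
    return [unique_patterns(encoded, k) for k in keys]


def write_patterns_json(
    summaries: Iterable[VariantPatternSummary], path: Union[str, Path]
) -> None:
    payload = [asdict(s) for s in summaries]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_patterns_json(path: Union[str, Path]) -> list[VariantPatternSummary]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [
        VariantPatternSummary(
            variant_key=obj["variant_key"],
            recurrence=obj["recurrence"],
            patterns=tuple(PatternCount(**p) for p in obj["patterns"]),
        )
        for obj in payload
    ]
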