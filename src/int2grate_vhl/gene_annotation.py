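"""Minimal HGVS cDNA parsing for VHL and mapping to gene regions.

The VHL coding sequence spans three exons; the canonical junctions are
fixed by the splice-acceptor variants c.341-1 (intron 1 / exon 2) and
c.464-1 (intron 2 / exon 3).  A cryptic exon E1' sits deep in intron 1 and
is exonized in erythrocytosis-associated alleles; its boundaries are not
standardized, so the window ships as configurable data and is echoed in
output metadata.

Only the cDNA dialect needed for this gene is supported: substitutions,
del / dup / ins / delins, and splice-offset positions such as c.341-1G>A or
c.340+578C>T.  Protein-level (p.) strings are inputs to effect
classification only, never parsed as positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = [
    "BadHgvsError",
    "AnnotationConflictError",
    "ParsedCdna",
    "TranscriptMap",
    "Region",
    "Effect",
    "RegionCall",
    "load_transcript_map",
    "parse_cdna",
    "map_region",
    "classify_effect",
]


class BadHgvsError(ValueError):
    """Raised for strings outside the supported cDNA dialect."""


class AnnotationConflictError(ValueError):
    """Raised when the c. and p. descriptions disagree structurally."""


class Region(str, Enum):
    exon1 = "exon1"
    intron1 = "intron1"
    intron1_E1prime = "intron1_E1prime"
    exon2 = "exon2"
    intron2 = "intron2"
    exon3 = "exon3"
    multi_exon_deletion = "multi_exon_deletion"
    whole_gene_deletion = "whole_gene_deletion"
    other = "other"


class Effect(str, Enum):
    missense = "missense"
    null = "null"
    synonymous = "synonymous"
    intronic = "intronic"
    copy_deletion = "copy_deletion"
    other = "other"


@dataclass(frozen=True)
class ParsedCdna:
    kind: str  # sub | del | dup | ins | delins
    start: int
    start_offset: int
    end: int
    end_offset: int
    ref: Optional[str] = None
    alt: Optional[str] = None

    @property
    def is_intronic(self) -> bool:
        return self.start_offset != 0


@dataclass(frozen=True)
class TranscriptMap:
    """Coding exon bounds in cDNA coordinates plus the E1' window given as
    intron-1 offsets from the exon-1 3' edge (c.340+min .. c.340+max)."""

    transcript_id: str
    cds_exon_bounds: tuple[tuple[int, int], ...]
    e1prime_window: tuple[int, int]
    utr_allowance: int = 200

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.cds_exon_bounds:
            if start != prev_end + 1 or end < start:
                raise ValueError("exon bounds must be contiguous and increasing")
            prev_end = end
        lo, hi = self.e1prime_window
        if not (0 < lo <= hi):
            raise ValueError("e1prime_window must be positive intron-1 offsets")

    @property
    def cds_end(self) -> int:
        return self.cds_exon_bounds[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.cds_exon_bounds)


_DATA = resources.files("int2grate_vhl") / "data"


def load_transcript_map(path: Optional[Union[str, Path]] = None) -> TranscriptMap:
    if path is None:
        text = (_DATA / "transcript_vhl.yaml").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    return TranscriptMap(
        transcript_id=doc["transcript_id"],
        cds_exon_bounds=tuple((int(a), int(b)) for a, b in doc["cds_exon_bounds"]),
        e1prime_window=tuple(int(v) for v in doc["e1prime_window"]),
        utr_allowance=int(doc.get("utr_allowance", 200)),
    )


_POS = r"(?P<{p}base>-?\*?\d+)(?P<{p}off>[+-]\d+)?"
_CDNA_RE = re.compile(
    r"^c\."
    + _POS.format(p="s")
    + r"(?:_" + _POS.format(p="e") + r")?"
    + r"(?:"
    r"(?P<ref>[ACGTacgt]+)>(?P<alt>[ACGTacgt]+)"
    r"|(?P<delins>delins)(?P<delins_seq>[ACGTacgt]*)"
    r"|(?P<del>del)(?P<del_seq>[ACGTacgt]*)"
    r"|(?P<dup>dup)(?P<dup_seq>[ACGTacgt]*)"
    r"|(?P<ins>ins)(?P<ins_seq>[ACGTacgt]+)"
    r")$"
)


def _strip(hgvs: str) -> str:
    s = re.sub(r"\s+", "", str(hgvs))
    s = re.sub(r"^\(|\)$", "", s)
    if ":" in s:
        s = s.rsplit(":", 1)[1]
    return s


def parse_cdna(hgvs_c: str) -> ParsedCdna:
    """Parse the c.-prefixed cDNA subset used for VHL variants.

    Raises :class:`BadHgvsError` for protein-level strings, UTR-star
    coordinates, and anything else outside the dialect.
    """
    s = _strip(hgvs_c)
    if s.startswith("p."):
        raise BadHgvsError(f"bad_hgvs: protein-level description {hgvs_c!r}")
    m = _CDNA_RE.match(s)
    if not m or "*" in s:
        raise BadHgvsError(f"bad_hgvs: cannot parse {hgvs_c!r}")
    start = int(m.group("sbase"))
    start_off = int(m.group("soff") or 0)
    if m.group("ebase") is not None:
        end = int(m.group("ebase"))
        end_off = int(m.group("eoff") or 0)
    else:
        end, end_off = start, start_off
    if (end, end_off) < (start, start_off):
        raise BadHgvsError(f"bad_hgvs: inverted range in {hgvs_c!r}")
    if m.group("ref"):
        kind, ref, alt = "sub", m.group("ref").upper(), m.group("alt").upper()
        if len(ref) != 1 or len(alt) != 1:
            raise BadHgvsError(f"bad_hgvs: multi-base substitution {hgvs_c!r}")
    elif m.group("delins"):
        kind, ref, alt = "delins", None, m.group("delins_seq").upper() or None
    elif m.group("del"):
        kind, ref, alt = "del", m.group("del_seq").upper() or None, None
    elif m.group("dup"):
        kind, ref, alt = "dup", m.group("dup_seq").upper() or None, None
    else:
        kind, ref, alt = "ins", None, m.group("ins_seq").upper()
    return ParsedCdna(kind, start, start_off, end, end_off, ref, alt)


@dataclass(frozen=True)
class RegionCall:
    region: Region
    effect: Effect

    def __post_init__(self) -> None:
        deletion_regions = {Region.multi_exon_deletion, Region.whole_gene_deletion}
        if (self.effect is Effect.copy_deletion) != (self.region in deletion_regions):
            raise ValueError("effect=copy_deletion iff region is a deletion region")


def _exon_of(base: int, tmap: TranscriptMap) -> Optional[int]:
    for i, (start, end) in enumerate(tmap.cds_exon_bounds, start=1):
        if start <= base <= end:
            return i
    return None


def map_region(pos: ParsedCdna, tmap: TranscriptMap) -> Region:
    """Deterministic region assignment; every parseable position maps to
    exactly one region (a range is placed by its start)."""
    base, offset = pos.start, pos.start_offset
    if base < 1 or base > tmap.cds_end:
        if -tmap.utr_allowance <= base < 0 or tmap.cds_end < base <= tmap.cds_end + tmap.utr_allowance:
            return Region.other
        return Region.other
    if offset == 0:
        exon = _exon_of(base, tmap)
        return {1: Region.exon1, 2: Region.exon2, 3: Region.exon3}.get(exon, Region.other)
    # Intronic: the intron index follows from the flanking exon edge.
    if offset > 0:
        exon = _exon_of(base, tmap)
        intron = exon if exon and base == tmap.cds_exon_bounds[exon - 1][1] else None
    else:
        exon = _exon_of(base, tmap)
        intron = exon - 1 if exon and base == tmap.cds_exon_bounds[exon - 1][0] else None
    if intron == 1:
        lo, hi = tmap.e1prime_window
        if offset > 0 and lo <= offset <= hi:
            return Region.intron1_E1prime
        return Region.intron1
    if intron == 2:
        return Region.intron2
    return Region.other


def region_for_deletion(deleted_exons: frozenset[int], tmap: TranscriptMap) -> Region:
    if set(deleted_exons) == set(range(1, tmap.n_exons + 1)):
        return Region.whole_gene_deletion
    return Region.multi_exon_deletion


_P_SUB_RE = re.compile(
    r"^p\.(?P<ref>[A-Z][a-z]{2}|[A-Z*=?])(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|[A-Z*=?]|Ter|fs.*|del.*|dup.*)?$"
)


def _normalize_p(hgvs_p: str) -> str:
    s = re.sub(r"\s+", "", hgvs_p)
    s = s.replace("(", "").replace(")", "")
    if ":" in s:
        s = s.rsplit(":", 1)[1]
    return s


def classify_effect(
    hgvs_c: Optional[str] = None,
    hgvs_p: Optional[str] = None,
    *,
    is_copy_deletion: bool = False,
) -> Effect:
    """Structural effect class from the c. and (optionally) p. descriptions.

    null = nonsense, frameshift, canonical +/-1/+/-2 splice, start-loss;
    synonymous = protein '=' notation; missense = single-residue
    substitution; intronic = offset beyond the canonical splice positions;
    copy_deletion = copy-number loss.  Insensitive to whitespace and
    parenthesis formatting.  Raises :class:`AnnotationConflictError` when
    the two levels disagree (e.g., a deep-intronic c. with a protein
    substitution).
    """
    if is_copy_deletion:
        return Effect.copy_deletion
    if hgvs_c is None and hgvs_p is None:
        raise ValueError("at least one of hgvs_c / hgvs_p is required")

    p_class: Optional[Effect] = None
    if hgvs_p:
        p = _normalize_p(hgvs_p)
        if "=" in p:
            p_class = Effect.synonymous
        elif "fs" in p or "Ter" in p or "*" in p:
            p_class = Effect.null
        elif re.match(r"^p\.Met1(\?|[A-Z][a-z]{2})?$", p) or p == "p.M1?":
            p_class = Effect.null
        elif p.endswith("?"):
            p_class = None
        else:
            m = _P_SUB_RE.match(p)
            if m and m.group("alt") and not m.group("alt").startswith(("del", "dup")):
                p_class = Effect.missense
            else:
                p_class = Effect.other

    if hgvs_c is None:
        return p_class or Effect.other

    pos = parse_cdna(hgvs_c)
    if pos.is_intronic:
        c_class = Effect.null if abs(pos.start_offset) <= 2 else Effect.intronic
        if c_class is Effect.intronic and p_class in (Effect.missense, Effect.synonymous):
            raise AnnotationConflictError(
                f"annotation_conflict: intronic {hgvs_c!r} vs protein change {hgvs_p!r}"
            )
        return c_class

    if pos.kind == "sub":
        if p_class is not None:
            return p_class
        return Effect.other  # coding substitution, protein consequence unstated
    # coding del/dup/ins/delins: frame decides
    span = pos.end - pos.start + 1
    if pos.kind == "del":
        net = -span
    elif pos.kind == "dup":
        net = span
    elif pos.kind == "ins":
        net = len(pos.alt or "")
    else:  # delins
        net = len(pos.alt or "") - span
    if net % 3 != 0:
        return Effect.null
    return p_class or Effect.other
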