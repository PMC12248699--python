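"""Somatic VHL data rules: QC filters, copy calls, allelic status.

These operations reproduce the threshold rules applied to tumor-panel
output before it feeds the evidence framework:

* SNV/indel detection limits — 50x coverage, 10% VAF, >=5 unique reads,
  population allele frequency <= 0.1% with a COSMIC-recurrence rescue
  (reported at least twice).
* Copy calls from Log2 ratios — >= 0.43 amplification, <= -0.32 loss,
  both thresholds closed; in between is copy-neutral.
* The presumed-somatic heuristic — a VAF outside the expected heterozygous
  band in a patient without clinical suspicion of VHL syndrome.
* Allelic status — zero, one, or two-plus inactivating events on the
  somatic alleles, distinguishing a candidate second hit (monoallelic)
  from biallelic inactivation / LOH.  Copy-neutral LOH and promoter
  methylation are invisible to this data model, so "biallelic" is claimed
  on genetic evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import isfinite
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .evidence_model import AlterationType, SomaticAlteration, VHL_COMPONENT_TUMORS
from . import gene_annotation
from .gene_annotation import Effect, Region

__all__ = [
    "SomaticQCConfig",
    "CopyCallConfig",
    "CopyCall",
    "SomaticStatus",
    "Mechanism",
    "AllelicStatus",
    "PresumedSomaticResult",
    "TumorProfile",
    "LandscapeSummary",
    "qc_filter",
    "call_copy",
    "presumed_somatic",
    "is_inactivating",
    "allelic_status",
    "landscape_summary",
    "write_landscape_tsv",
]


@dataclass(frozen=True)
class SomaticQCConfig:
    min_coverage: int = 50
    min_vaf_percent: float = 10.0
    min_unique_reads: int = 5
    max_population_af_percent: float = 0.1
    cosmic_rescue_min_count: int = 2

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CopyCallConfig:
    amp_log2_min: float = 0.43
    loss_log2_max: float = -0.32

    def __post_init__(self) -> None:
        if not (self.loss_log2_max < 0 < self.amp_log2_min):
            raise ValueError("require loss_log2_max < 0 < amp_log2_min")


class CopyCall(str, Enum):
    amplification = "amplification"
    loss = "loss"
    neutral = "neutral"


class SomaticStatus(str, Enum):
    no_inactivation = "no_inactivation"
    monoallelic_second_hit_candidate = "monoallelic_second_hit_candidate"
    biallelic_loh = "biallelic_loh"
    uninformative = "uninformative"


class Mechanism(str, Enum):
    snv_plus_deletion = "snv_plus_deletion"
    two_snvs = "two_snvs"
    two_copy_deletion = "two_copy_deletion"
    other = "other"


@dataclass(frozen=True)
class AllelicStatus:
    status: SomaticStatus
    mechanism: Optional[Mechanism] = None

    def __post_init__(self) -> None:
        if (self.mechanism is not None) != (self.status is SomaticStatus.biallelic_loh):
            raise ValueError("mechanism present iff status is biallelic_loh")


class QCResult(NamedTuple):
    retained: list[SomaticAlteration]
    rejections: list[tuple[SomaticAlteration, list[str]]]


def qc_filter(
    alterations: Sequence[SomaticAlteration],
    cfg: SomaticQCConfig = SomaticQCConfig(),
    *,
    strict: bool = False,
) -> QCResult:
    """Apply the detection-limit filters to SNV/indel records.

    A record is rejected when any *available* metric fails; missing metrics
    pass by default because retrospective records lack some fields
    (``strict=True`` rejects on missing metrics instead).  A population-AF
    failure is overridden when the variant recurs in COSMIC at least
    ``cosmic_rescue_min_count`` times.  Copy-number and SV records carry no
    read-level metrics and pass through.
    """
    retained: list[SomaticAlteration] = []
    rejections: list[tuple[SomaticAlteration, list[str]]] = []
    for alt in alterations:
        if alt.alteration_type not in (AlterationType.snv, AlterationType.indel):
            retained.append(alt)
            continue
        reasons: list[str] = []

        def _fail(metric: Optional[float], ok: bool, reason: str) -> None:
            if metric is None:
                if strict:
                    reasons.append(f"missing_{reason}")
            elif not ok:
                reasons.append(reason)

        _fail(alt.coverage, (alt.coverage or 0) >= cfg.min_coverage, "coverage")
        _fail(alt.vaf_percent, (alt.vaf_percent or 0) >= cfg.min_vaf_percent, "vaf")
        _fail(
            alt.unique_reads,
            (alt.unique_reads or 0) >= cfg.min_unique_reads,
            "unique_reads",
        )
        if alt.population_af_percent is not None:
            if alt.population_af_percent > cfg.max_population_af_percent:
                if (alt.cosmic_count or 0) >= cfg.cosmic_rescue_min_count:
                    pass  # rescued by COSMIC recurrence
                else:
                    reasons.append("population_af")
        elif strict:
            reasons.append("missing_population_af")

        if reasons:
            rejections.append((alt, reasons))
        else:
            retained.append(alt)
    return QCResult(retained, rejections)


def call_copy(log2_ratio: float, cfg: CopyCallConfig = CopyCallConfig()) -> CopyCall:
    """Copy call from a Log2 ratio; both thresholds are closed."""
    if not isfinite(log2_ratio):
        raise ValueError(f"bad_ratio: {log2_ratio!r}")
    if log2_ratio >= cfg.amp_log2_min:
        return CopyCall.amplification
    if log2_ratio <= cfg.loss_log2_max:
        return CopyCall.loss
    return CopyCall.neutral


class PresumedSomaticResult(NamedTuple):
    is_presumed_somatic: bool
    rule: str


def presumed_somatic(
    vaf_percent: float,
    het_band: tuple[float, float] = (40.0, 60.0),
    *,
    clinical_suspicion: bool = False,
) -> PresumedSomaticResult:
    """Heuristic for tumor-only variants: presumed somatic when the VAF
    falls outside the expected heterozygous band and there is no clinical
    suspicion of VHL syndrome.  The returned rule names what fired."""
    if not 0 <= vaf_percent <= 100:
        raise ValueError("vaf_percent must be in [0, 100]")
    lo, hi = het_band
    if clinical_suspicion:
        return PresumedSomaticResult(False, "clinical_suspicion_present")
    if vaf_percent < lo:
        return PresumedSomaticResult(True, f"vaf_below_het_band(<{lo:g})")
    if vaf_percent > hi:
        return PresumedSomaticResult(True, f"vaf_above_het_band(>{hi:g})")
    return PresumedSomaticResult(False, "vaf_within_het_band")


def is_inactivating(
    alt: SomaticAlteration, copy_cfg: CopyCallConfig = CopyCallConfig()
) -> Optional[bool]:
    """Whether one retained alteration inactivates a VHL allele.

    Null and missense SNVs/indels and copy losses count; amplifications and
    neutral segments never do (VHL disease is loss of function).  Returns
    ``None`` for SV records and other unclassifiable events.
    """
    t = alt.alteration_type
    if t in (AlterationType.one_copy_deletion, AlterationType.two_copy_deletion):
        return True
    if t is AlterationType.amplification:
        return False
    if t is AlterationType.sv:
        return None
    if alt.log2_ratio is not None and t not in (AlterationType.snv, AlterationType.indel):
        return call_copy(alt.log2_ratio, copy_cfg) is CopyCall.loss
    try:
        effect = gene_annotation.classify_effect(alt.hgvs_c)
    except gene_annotation.BadHgvsError:
        return None
    if effect in (Effect.null, Effect.missense):
        return True
    if effect is Effect.other and alt.alteration_type is AlterationType.snv:
        # Coding substitution without a stated protein consequence: treated
        # as a candidate inactivating event (panel-reported somatic SNVs).
        return True
    if effect is Effect.other and alt.alteration_type is AlterationType.indel:
        return True
    return False  # synonymous / deep intronic


def allelic_status(
    alterations: Sequence[SomaticAlteration],
    copy_cfg: CopyCallConfig = CopyCallConfig(),
) -> AllelicStatus:
    """Allelic status of one tumor from its retained VHL alterations.

    Zero inactivating events -> no inactivation; exactly one -> candidate
    second hit (monoallelic); two distinct events, or a homozygous deletion
    alone -> biallelic inactivation (LOH) with its mechanism.  SV-only or
    unclassifiable profiles are uninformative.
    """
    inactivating: list[SomaticAlteration] = []
    saw_unclassifiable = False
    for alt in alterations:
        flag = is_inactivating(alt, copy_cfg)
        if flag is None:
            saw_unclassifiable = True
        elif flag:
            inactivating.append(alt)

    if any(a.alteration_type is AlterationType.two_copy_deletion for a in inactivating):
        return AllelicStatus(SomaticStatus.biallelic_loh, Mechanism.two_copy_deletion)
    if len(inactivating) >= 2:
        kinds = [a.alteration_type for a in inactivating]
        n_small = sum(k in (AlterationType.snv, AlterationType.indel) for k in kinds)
        n_loss = sum(k is AlterationType.one_copy_deletion for k in kinds)
        if n_small >= 1 and n_loss >= 1:
            mech = Mechanism.snv_plus_deletion
        elif n_small >= 2:
            mech = Mechanism.two_snvs
        else:
            mech = Mechanism.other
        return AllelicStatus(SomaticStatus.biallelic_loh, mech)
    if len(inactivating) == 1:
        return AllelicStatus(SomaticStatus.monoallelic_second_hit_candidate)
    if saw_unclassifiable:
        return AllelicStatus(SomaticStatus.uninformative)
    return AllelicStatus(SomaticStatus.no_inactivation)


# ---------------------------------------------------------------------------
# cohort-level landscape summary


@dataclass(frozen=True)
class TumorProfile:
    """One profiled tumor: its type and the somatic VHL alterations found."""

    tumor_type: str
    alterations: tuple[SomaticAlteration, ...] = ()
    sdh_deficient: bool = False


class LandscapeSummary(NamedTuple):
    table: pd.DataFrame
    n_excluded_sdh_deficient: int


_LANDSCAPE_COLUMNS = ["tumor_type", "status", "mechanism", "effect", "region", "count"]


def landscape_summary(
    tumors: Iterable[TumorProfile],
    qc_cfg: SomaticQCConfig = SomaticQCConfig(),
    copy_cfg: CopyCallConfig = CopyCallConfig(),
    tmap: Optional[gene_annotation.TranscriptMap] = None,
) -> LandscapeSummary:
    """Tidy count table of allelic status, SNV effect class, and region by
    tumor type.  SDH-deficient paragangliomas are excluded from the
    VHL-related tumor list and reported separately; total tumors in equals
    the sum of counts plus the excluded count."""
    if tmap is None:
        tmap = gene_annotation.load_transcript_map()
    rows: list[dict[str, object]] = []
    n_excluded = 0
    for tumor in tumors:
        if tumor.sdh_deficient and tumor.tumor_type == "paraganglioma":
            n_excluded += 1
            continue
        retained = qc_filter(tumor.alterations, qc_cfg).retained
        status = allelic_status(retained, copy_cfg)
        effect = region = ""
        snvs = [
            a
            for a in retained
            if a.alteration_type in (AlterationType.snv, AlterationType.indel)
        ]
        if snvs:
            try:
                effect = gene_annotation.classify_effect(snvs[0].hgvs_c).value
                region = gene_annotation.map_region(
                    gene_annotation.parse_cdna(snvs[0].hgvs_c), tmap
                ).value
            except gene_annotation.BadHgvsError:
                effect = region = "unparseable"
        rows.append(
            {
                "tumor_type": tumor.tumor_type,
                "status": status.status.value,
                "mechanism": status.mechanism.value if status.mechanism else "",
                "effect": effect,
                "region": region,
            }
        )
    if not rows:
        table = pd.DataFrame(columns=_LANDSCAPE_COLUMNS)
    else:
        table = (
            pd.DataFrame(rows)
            .groupby(["tumor_type", "status", "mechanism", "effect", "region"])
            .size()
            .reset_index(name="count")
            .sort_values(_LANDSCAPE_COLUMNS[:-1], kind="stable")
            .reset_index(drop=True)
        )
    return LandscapeSummary(table, n_excluded)


def write_landscape_tsv(summary: LandscapeSummary, path: Union[str, Path]) -> None:
    summary.table.to_csv(path, sep="\t", index=False)
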