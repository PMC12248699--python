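"""Somatic QC filters, copy calls, presumed-somatic rule, allelic status."""

from itertools import combinations_with_replacement

import pytest
from hypothesis import given, settings, strategies as st

from int2grate_vhl import somatic_analysis as sa
from int2grate_vhl.evidence_model import SomaticAlteration


def snv(**kw):
    base = dict(hgvs_c="c.263G>A", alteration_type="snv")
    base.update(kw)
    return SomaticAlteration(**base)


# ---------------------------------------------------------------------------
# qc_filter


@pytest.mark.parametrize(
    "kw, retained, reason",
    [
        (dict(coverage=49, vaf_percent=20, unique_reads=10, population_af_percent=0), False, "coverage"),
        (dict(coverage=50, vaf_percent=9.9, unique_reads=10), False, "vaf"),
        (dict(coverage=200, vaf_percent=30, unique_reads=4), False, "unique_reads"),
        (dict(coverage=200, vaf_percent=30, unique_reads=20, population_af_percent=0.2), False, "population_af"),
        # COSMIC recurrence (>=2) rescues a population-AF failure
        (dict(coverage=200, vaf_percent=30, unique_reads=20, population_af_percent=0.2, cosmic_count=3), True, None),
        (dict(coverage=50, vaf_percent=10, unique_reads=5, population_af_percent=0.1), True, None),
        (dict(), True, None),  # missing metrics pass (retrospective records)
    ],
)
def test_qc_filter_detection_limits(kw, retained, reason):
    result = sa.qc_filter([snv(**kw)])
    if retained:
        assert result.retained and not result.rejections
    else:
        (_, reasons), = result.rejections
        assert reason in reasons


def test_qc_filter_empty_and_strict():
    assert sa.qc_filter([]) == ([], [])
    result = sa.qc_filter([snv()], strict=True)
    assert not result.retained
    (_, reasons), = result.rejections
    assert "missing_coverage" in reasons


def test_qc_filter_copy_records_pass_through():
    alt = SomaticAlteration(alteration_type="one_copy_deletion", log2_ratio=-0.9)
    assert sa.qc_filter([alt]).retained == [alt]


@given(
    coverage=st.integers(0, 300),
    vaf=st.floats(0, 100),
    reads=st.integers(0, 50),
    bump=st.integers(1, 50),
)
@settings(max_examples=100, derandomize=True)
def test_qc_filter_monotone_in_thresholds(coverage, vaf, reads, bump):
    """Tightening any threshold never retains a previously rejected record."""
    alt = snv(coverage=coverage or None, vaf_percent=vaf, unique_reads=reads)
    loose = sa.SomaticQCConfig()
    tight = sa.SomaticQCConfig(
        min_coverage=loose.min_coverage + bump,
        min_vaf_percent=loose.min_vaf_percent + bump,
        min_unique_reads=loose.min_unique_reads + bump,
    )
    if not sa.qc_filter([alt], loose).retained:
        assert not sa.qc_filter([alt], tight).retained


# ---------------------------------------------------------------------------
# call_copy


@pytest.mark.parametrize(
    "log2, call",
    [
        (0.43, sa.CopyCall.amplification),   # threshold closed
        (0.44, sa.CopyCall.amplification),
        (0.42, sa.CopyCall.neutral),
        (0.0, sa.CopyCall.neutral),
        (-0.31, sa.CopyCall.neutral),
        (-0.32, sa.CopyCall.loss),           # threshold closed
        (-1.5, sa.CopyCall.loss),
    ],
)
def test_call_copy_thresholds(log2, call):
    assert sa.call_copy(log2) is call


def test_call_copy_partitions_the_line():
    calls = {sa.call_copy(x / 100) for x in range(-200, 201)}
    assert calls == set(sa.CopyCall)


def test_call_copy_rejects_non_finite():
    with pytest.raises(ValueError, match="bad_ratio"):
        sa.call_copy(float("nan"))


# ---------------------------------------------------------------------------
# presumed_somatic


@pytest.mark.parametrize(
    "vaf, suspicion, expected",
    [
        (27, False, True),   # below the heterozygous band
        (68, False, True),   # above the heterozygous band
        (50, False, False),  # center of band
        (40, False, False),  # band is closed
        (60, False, False),
        (68, True, False),   # rule applies only without clinical suspicion
    ],
)
def test_presumed_somatic(vaf, suspicion, expected):
    result = sa.presumed_somatic(vaf, clinical_suspicion=suspicion)
    assert result.is_presumed_somatic is expected
    assert result.rule


# ---------------------------------------------------------------------------
# allelic_status against a brute-force oracle

_KINDS = {
    "missense_snv": snv(hgvs_c="c.292T>C"),
    "null_snv": snv(hgvs_c="c.263_264del"),
    "one_copy_deletion": SomaticAlteration(alteration_type="one_copy_deletion", log2_ratio=-0.8),
    "two_copy_deletion": SomaticAlteration(alteration_type="two_copy_deletion", log2_ratio=-2.5),
    "amplification": SomaticAlteration(alteration_type="amplification", log2_ratio=0.6),
    "sv": SomaticAlteration(alteration_type="sv"),
}


def _oracle(kinds):
    """First-principles status: count inactivating events directly."""
    inactivating = [
        k for k in kinds
        if k in ("missense_snv", "null_snv", "one_copy_deletion", "two_copy_deletion")
    ]
    if "two_copy_deletion" in inactivating:
        return ("biallelic_loh", "two_copy_deletion")
    if len(inactivating) >= 2:
        has_snv = any(k.endswith("snv") for k in inactivating)
        has_loss = "one_copy_deletion" in inactivating
        if has_snv and has_loss:
            return ("biallelic_loh", "snv_plus_deletion")
        if sum(k.endswith("snv") for k in inactivating) >= 2:
            return ("biallelic_loh", "two_snvs")
        return ("biallelic_loh", "other")
    if len(inactivating) == 1:
        return ("monoallelic_second_hit_candidate", None)
    if "sv" in kinds:
        return ("uninformative", None)
    return ("no_inactivation", None)


def test_allelic_status_matches_oracle_on_all_small_multisets():
    """Exhaustive agreement over every alteration multiset of size <= 3."""
    names = sorted(_KINDS)
    checked = 0
    for size in range(0, 4):
        for combo in combinations_with_replacement(names, size):
            status = sa.allelic_status([_KINDS[k] for k in combo])
            expected_status, expected_mech = _oracle(combo)
            assert status.status.value == expected_status, combo
            assert (status.mechanism.value if status.mechanism else None) == expected_mech, combo
            checked += 1
    assert checked == 1 + 6 + 21 + 56


def test_allelic_status_mechanism_only_for_biallelic():
    with pytest.raises(ValueError):
        sa.AllelicStatus(sa.SomaticStatus.no_inactivation, sa.Mechanism.two_snvs)


def test_amplification_never_inactivating():
    assert sa.is_inactivating(_KINDS["amplification"]) is False


# ---------------------------------------------------------------------------
# landscape summary


def _profile(tt, alts=(), sdh=False):
    return sa.TumorProfile(tumor_type=tt, alterations=tuple(alts), sdh_deficient=sdh)


def test_landscape_summary_counts_and_loh_proportion():
    biallelic = [_KINDS["missense_snv"], _KINDS["one_copy_deletion"]]
    single = [_KINDS["missense_snv"]]
    tumors = [
        _profile("rcc", biallelic), _profile("rcc", biallelic),
        _profile("rcc", single), _profile("rcc", single),
    ]
    summary = sa.landscape_summary(tumors)
    counts = summary.table.groupby("status")["count"].sum()
    assert counts["biallelic_loh"] == 2
    assert counts["monoallelic_second_hit_candidate"] == 2
    loh = counts["biallelic_loh"] / counts.sum()
    assert loh == 0.5


def test_landscape_summary_excludes_sdh_deficient_paraganglioma():
    tumors = [
        _profile("paraganglioma", [_KINDS["missense_snv"]], sdh=True),
        _profile("rcc", [_KINDS["missense_snv"]]),
    ]
    summary = sa.landscape_summary(tumors)
    assert summary.n_excluded_sdh_deficient == 1
    # conservation: rows in = cells + excluded
    assert summary.table["count"].sum() + summary.n_excluded_sdh_deficient == 2


def test_landscape_summary_empty():
    summary = sa.landscape_summary([])
    assert summary.table.empty
    assert summary.n_excluded_sdh_deficient == 0
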