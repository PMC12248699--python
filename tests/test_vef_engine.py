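"""Evidence vectors and scenario-table classification."""

import pytest

from int2grate_vhl import evidence_model as em
from int2grate_vhl import vef_engine as ve
from int2grate_vhl.somatic_analysis import SomaticStatus


def make_case(**kw):
    base = dict(
        subject_id="case",
        germline=dict(hgvs_c="c.292T>C", reported_classification="VUS", zygosity="heterozygous"),
        clinical=dict(evaluated_in_genetics=True, age_years=50, family_history_vhl="negative"),
    )
    for key, val in kw.items():
        if key in ("clinical", "germline") and isinstance(val, dict) and base.get(key):
            merged = dict(base[key])
            merged.update(val)
            base[key] = merged
        else:
            base[key] = val
    return em.CaseRecord.model_validate(base)


def make_vector(**kw):
    base = dict(
        eligible=True,
        gate_reason=None,
        n_vhl_tumors=0,
        n_rcc=0,
        has_vhl_feature=False,
        has_non_vhl_tumor=False,
        family_history=em.FamilyHistory.negative,
        somatic_available=False,
        somatic_status=SomaticStatus.uninformative,
        age_band=ve.AgeBand.adult,
        germline_class=em.VariantClassification.VUS,
    )
    base.update(kw)
    return ve.EvidenceVector(**base)


# ---------------------------------------------------------------------------
# gate


def test_gate_heterozygous_without_differential_is_eligible():
    assert ve.gate(make_case()).eligible


@pytest.mark.parametrize("zyg", ["homozygous", "compound_heterozygous", "hemizygous"])
def test_gate_rejects_non_heterozygous(zyg):
    g = ve.gate(make_case(germline=dict(zygosity=zyg)))
    assert (g.eligible, g.reason) == (False, "non_heterozygous")


def test_gate_rejects_differential_pathogenic_but_not_vus():
    case = make_case(differential_findings=[dict(gene="SDHB", classification="P")])
    assert ve.gate(case).reason == "differential_positive"
    case = make_case(differential_findings=[dict(gene="SDHB", classification="VUS")])
    assert ve.gate(case).eligible


def test_gate_requires_germline_variant_and_genetics_evaluation():
    assert ve.gate(make_case(germline=None)).reason == "no_germline_variant"
    case = make_case(clinical=dict(evaluated_in_genetics=False))
    assert ve.gate(case).reason == "not_evaluated_in_genetics"


# ---------------------------------------------------------------------------
# derive_vector


def test_vector_patient_21_profile():
    case = make_case(
        germline=dict(hgvs_c="c.208G>A", reported_classification="P"),
        clinical=dict(age_years=16, family_history_vhl="positive", family_degree="first"),
    )
    v = ve.derive_vector(case)
    assert (v.n_vhl_tumors, v.has_vhl_feature) == (0, False)
    assert v.family_history is em.FamilyHistory.positive
    assert v.age_band is ve.AgeBand.young


def test_vector_counts_per_laterality():
    case = make_case(
        clinical=dict(
            personal_tumors=[
                dict(tumor_type="cns_hemangioblastoma"),
                dict(tumor_type="rcc", laterality_count=2),
            ]
        )
    )
    v = ve.derive_vector(case)
    assert (v.n_vhl_tumors, v.n_rcc) == (3, 2)


def test_vector_excludes_sdh_deficient_paraganglioma():
    case = make_case(
        clinical=dict(
            personal_tumors=[dict(tumor_type="paraganglioma", sdh_deficient=True)]
        )
    )
    v = ve.derive_vector(case)
    assert v.n_vhl_tumors == 0


def test_vector_distant_family_history_does_not_count():
    case = make_case(
        clinical=dict(family_history_vhl="positive", family_degree="other")
    )
    assert ve.derive_vector(case).family_history is em.FamilyHistory.negative


def test_vector_somatic_status_from_qc_retained_alterations():
    case = make_case(
        somatic_tested=True,
        somatic=[
            dict(hgvs_c="c.263G>A", alteration_type="snv", vaf_percent=40,
                 coverage=200, unique_reads=50, tumor_source="rcc"),
        ],
        clinical=dict(personal_tumors=[dict(tumor_type="rcc")]),
    )
    v = ve.derive_vector(case)
    assert v.somatic_available
    assert v.somatic_status is SomaticStatus.monoallelic_second_hit_candidate


def test_vector_invariants_enforced():
    with pytest.raises(ValueError):
        make_vector(n_vhl_tumors=1, n_rcc=2)
    with pytest.raises(ValueError):
        make_vector(somatic_available=False, somatic_status=SomaticStatus.biallelic_loh)


# ---------------------------------------------------------------------------
# classify: worked examples and anchored scenarios


@pytest.mark.parametrize(
    "kw, code, category",
    [
        # no personal phenotype, positive first-degree family history
        (dict(family_history=em.FamilyHistory.positive), "II-VI", ve.Category.Neutral),
        # one non-RCC tumor, negative family history, no somatic data, adult
        (dict(n_vhl_tumors=1), "IV-II", ve.Category.NOS),
        # no tumors of any kind, adult
        (dict(), "III-III", ve.Category.Negative),
        # only non-VHL tumors, adult
        (dict(has_non_vhl_tumor=True), "III-II", ve.Category.Negative),
        # two non-RCC component tumors
        (dict(n_vhl_tumors=2), "I-I", ve.Category.Positive),
        # isolated tumor with biallelic somatic inactivation = sporadic
        (dict(n_vhl_tumors=1, somatic_available=True,
              somatic_status=SomaticStatus.biallelic_loh), "III-I", ve.Category.Negative),
        # bilateral RCC only, adult
        (dict(n_vhl_tumors=2, n_rcc=2), "II-IV", ve.Category.Neutral),
        # bilateral RCC only, young
        (dict(n_vhl_tumors=2, n_rcc=2, age_band=ve.AgeBand.young), "II-VII", ve.Category.Neutral),
        # multiple tumors incl. one RCC with a somatic second-hit candidate
        (dict(n_vhl_tumors=2, n_rcc=1, somatic_available=True,
              somatic_status=SomaticStatus.monoallelic_second_hit_candidate),
         "I-II", ve.Category.Positive),
        # family history unavailable with a single tumor
        (dict(n_vhl_tumors=1, family_history=em.FamilyHistory.unknown), "IV-III", ve.Category.NOS),
    ],
)
def test_classify_scenarios(table, kw, code, category):
    c = ve.classify(make_vector(**kw), table)
    assert (c.code, c.category) == (code, category)


def test_classify_ineligible_routes_to_nos(table):
    v = make_vector(eligible=False, gate_reason="non_heterozygous")
    assert ve.classify(v, table).code == "IV-I"
    v = make_vector(eligible=False, gate_reason="differential_positive")
    assert ve.classify(v, table).code == "IV-III"


def test_classification_is_deterministic_and_carries_pattern(table):
    v = make_vector(n_vhl_tumors=1)
    a, b = ve.classify(v, table), ve.classify(v, table)
    assert a == b
    assert "t_band=1" in a.evidence_pattern


# ---------------------------------------------------------------------------
# table-level properties


def test_default_table_has_17_codes_with_consistent_categories(table):
    assert table.codes == set(ve.ALL_CODES)
    for rule in table.rules:
        assert ve.CODE_FAMILY[rule.code.split("-")[0]] is rule.category


def test_table_rules_pairwise_disjoint_by_exhaustive_enumeration(table):
    """No two rules may match the same discretized vector."""
    n = 0
    for vec in ve.enumerate_vector_space():
        hits = [r.id for r in table.rules if r.matches(vec)]
        assert len(hits) <= 1, (vec, hits)
        n += 1
    assert n > 1000  # the space really was enumerated


def test_table_total_with_fallback(table):
    """Every vector matches a rule or falls back to the NOS code."""
    for vec in ve.enumerate_vector_space():
        hits = [r for r in table.rules if r.matches(vec)]
        if not hits:
            assert ve.CODE_FAMILY[table.fallback_code.split("-")[0]] is ve.Category.NOS


def test_code_prefix_always_matches_emitted_category(table):
    for vec in ve.enumerate_vector_space():
        hits = [r for r in table.rules if r.matches(vec)]
        code = hits[0].code if hits else table.fallback_code
        category = hits[0].category if hits else ve.Category.NOS
        assert ve.CODE_FAMILY[code.split("-")[0]] is category


def test_somatic_gated_codes_unreachable_without_somatic_data(table):
    """The six somatic-requiring codes never fire when no somatic data exist."""
    reached = set()
    for vec in ve.enumerate_vector_space():
        if vec["somatic_available"]:
            continue
        hits = [r for r in table.rules if r.matches(vec)]
        if hits:
            reached.add(hits[0].code)
    assert not (reached & ve.SOMATIC_GATED_CODES)


def test_no_positive_without_tumor_feature_or_family_history(table):
    """Conservativeness: T=0 without features and without positive family
    history can never be Positive."""
    for vec in ve.enumerate_vector_space():
        if (
            vec["t_band"] == 0
            and not vec["has_vhl_feature"]
            and vec["family_history"] != "positive"
        ):
            hits = [r for r in table.rules if r.matches(vec)]
            if hits:
                assert hits[0].category is not ve.Category.Positive


def test_invalid_table_rejected(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text(
        "metadata: {version: 'x'}\n"
        "fallback_code: IV-I\n"
        "rules:\n"
        "  - id: r1\n"
        "    code: I-I\n"
        "    category: Negative\n"  # wrong family
        "    priority: 1\n"
        "    when: {eligible: {eq: true}}\n"
        "    comment: c\n"
    )
    with pytest.raises(ve.TableValidationError, match="table_invalid"):
        ve.load_scenario_table(bad)
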