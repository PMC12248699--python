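# int2grate-vhl

Integrated evidence coding for germline *VHL* variant actionability.

Von Hippel–Lindau (VHL) syndrome is an autosomal dominant cancer syndrome
caused by heterozygous germline loss-of-function variants in the *VHL*
tumor suppressor. Interpreting a germline *VHL* variant is hard because
its component tumors — clear cell renal cell carcinoma (ccRCC), CNS and
retinal hemangioblastoma, pheochromocytoma, pancreatic neuroendocrine
tumor, endolymphatic sac tumor, paraganglioma — are frequently sporadic,
may be caused by differential syndromes (*SDHx*, *FH*, *FLCN*, *RET*,
*NF1*, …), and certain *VHL* alleles cause only the recessive
erythrocytosis ECYT2. This package is for clinical genetics and molecular
pathology groups who need a reproducible, rule-based way to integrate all
four evidence axes per patient and to share the result without patient
identifiers.

## The method

Each case is reduced to a discrete **evidence vector**

- **T** — count of VHL component tumors (per laterality: bilateral RCC
  counts 2; SDH-deficient paraganglioma excluded),
- **R** — RCC count within T,
- VHL-related features (multiple kidney/pancreatic cysts, epididymal or
  broad-ligament cysts) and non-VHL tumors as flags,
- **F** — family history of a VHL diagnosis in a first- or second-degree
  relative (positive / negative / unknown),
- **S** — somatic *VHL* allelic status of the tumor profile
  (no inactivation / monoallelic second-hit candidate / biallelic
  inactivation–LOH / uninformative), derived after detection-limit QC
  (50× coverage, 10% VAF, ≥5 unique reads, population AF ≤0.1% with a
  COSMIC ≥2 rescue) and Log2 copy calls (≥0.43 amplification, ≤−0.32
  loss, thresholds closed),
- an age band (young &lt; 30 years / adult / unknown).

An eligibility gate admits only heterozygous germline *VHL* variants in
patients evaluated in a genetics clinic with no pathogenic differential-
gene finding. The vector is then classified through a **declarative
scenario table** (YAML, shipped as data) into one of **17 codes** in four
actionability categories: `I-*` Positive (all evidence aligns with VHL
syndrome), `II-*` Neutral (strong but insufficient), `III-*` Negative
(evidence does not support VHL syndrome), `IV-*` NOS (a key piece of
evidence is absent). The loader proves the table total and pairwise
disjoint over the fully enumerated discretized vector space before any
classification, so every assignment is deterministic.

On top of the classifier sit a batch **encoder**, a **pattern
quantifier** (variant recurrence = distinct subjects; unique evidence
patterns with multiplicities), a **portal exporter** producing
de-identified per-variant records, *VHL*-specific HGVS/region annotation
(exons 1–3, intron 1 incl. the cryptic exon E1′, large deletions), and a
**synthetic cohort generator** whose truth labels are exact by
construction.

## Worked example

```python
from int2grate_vhl import encoder, pattern_quantifier as pq, synthetic_cohort as sc

df, report = encoder.encode_table(sc.fixture("patients_21_23"))
print(df[["subject_id", "int2grate_code", "int2grate_category"]].to_string(index=False))

portal_df, _ = encoder.encode_table(sc.fixture("portal_c340+578"))
summary = pq.unique_patterns(portal_df, "VHL:c.340+578C>T")
print(summary.recurrence, [(p.code, p.count) for p in summary.patterns])
```

prints

```
subject_id int2grate_code int2grate_category
patient-21          II-VI            Neutral
patient-22          IV-II                NOS
patient-23          IV-II                NOS
7 [('III-III', 4), ('III-II', 3)]
```

The 16-year-old with no personal phenotype but a first-degree relative
diagnosed with VHL is coded `II-VI` — the absent phenotype may simply be
age-related penetrance. The two adults each presenting a single component
tumor with negative family history and no somatic profile are `IV-II`:
without somatic data the tumor could equally be sporadic. The recurrent
deep-intronic (E1′) variant was seen in 7 subjects with two distinct
evidence patterns: 4 with no tumors at all (`III-III`) and 3 with only
non-VHL tumors (`III-II`) — both Negative.

The same pipeline is available from the shell:

```bash
int2grate simulate --n 100 --seed 7 --output cases.tsv --truth truth.tsv
int2grate encode --input cases.tsv --output coded.tsv --report report.json
int2grate quantify --input coded.tsv --output patterns.json
int2grate portal-export --coded coded.tsv --patterns patterns.json --out portal.json
```

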