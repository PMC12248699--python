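# Methods

## Model

The framework treats variant assessment as deterministic classification of
a discrete evidence vector. For one case it derives:

| field | values | derivation |
|---|---|---|
| T | 0, 1, ≥2 | VHL component tumors, summed per laterality; SDH-deficient paraganglioma excluded (it points to an SDHx differential etiology, not VHL) |
| R | 0, 1, ≥2, and the all-RCC flag | RCC contribution to T |
| features | bool | any of the three VHL-related cyst features |
| non-VHL tumors | bool | any free-text non-component tumor |
| F | positive / negative / unknown | positive only for a first- or second-degree relative *diagnosed* with VHL; more distant relationships are treated as not meeting the criterion |
| S | no inactivation / monoallelic second-hit candidate / biallelic LOH / uninformative | allelic status of QC-retained somatic *VHL* alterations; fixed to uninformative when no somatic testing was done |
| age band | young / adult / unknown | young = age &lt; threshold (default 30 y) |

An eligibility gate precedes classification: heterozygous germline *VHL*
variant present, patient evaluated in a genetics clinic, no P/LP finding
in the 13-gene differential panel (*FH, FLCN, MET, BAP1, SDHA, SDHB,
SDHC, SDHD, SDHAF2, TMEM127, MAX, RET, NF1*). Homozygous, compound-
heterozygous and hemizygous germline genotypes are excluded because two
*VHL* alleles cannot be assessed separately against one phenotype;
zygosity `unknown` is admitted (retrospective records rarely state it and
cohorts of this kind are overwhelmingly heterozygous).

Assumptions worth making explicit: tumor records are taken at face value
(no pathology re-review); features and tumors are independent axes even
when anatomically related (renal cysts vs RCC); the reported germline
classification is an input, never re-derived; and S reflects genetic
evidence only.

## The scenario table

The 17 codes and their four families (I Positive, II Neutral, III
Negative, IV NOS) are fixed; the rule predicates ship as a versioned YAML
file, not code, and an alternative table can be swapped in without any
code change. The packaged default is a reconstruction that honors every
published constraint on the framework: the code families and their
semantics; the multi-tumor family spanning I-I, I-II, I-IV, II-I, II-IV,
II-VII; the six somatic-gated codes I-II, I-III, II-I, II-II, II-III,
III-I; the age-related codes II-V, II-VI, II-VII; and the worked examples
(II-VI for the family-history-only minor; IV-II for isolated tumors
without somatic data; III-II/III-III for non-VHL-tumor / tumor-free
adults). Rules not pinned by those constraints are our own design and the
file's provenance block says so.

The loader enforces, by exhaustive enumeration of the ~6,000-point
discretized vector space: pairwise disjointness of all rules, totality
(unmatched vectors fall back to the NOS code IV-I), and code-prefix /
category consistency. Because the table is disjoint, rule priority never
decides an outcome; it exists as a safety net only. Deliberate fallback
gaps (combinations the cataloged scenarios do not cover, e.g. T ≥ 2 with
a mixed RCC/non-RCC pattern and negative family history, an adult with
features only, or a single tumor with somatic testing done but
uninformative) are NOS by construction — "a key piece of evidence is
absent" is exactly what the fallback expresses.

Two textual tensions in the source material were resolved as follows: the
code→category mapping always follows the family prefix (so IV-II is NOS
even where prose loosely calls such variants "neutral"), and III-II is
"non-VHL tumors present" (its definition) rather than the one caption
that glosses it otherwise.

## Somatic rules

* QC (SNV/indel only): coverage ≥ 50×, VAF ≥ 10%, unique reads ≥ 5,
  population AF ≤ 0.1% with rescue when COSMIC count ≥ 2. Missing
  metrics pass by default — retrospective records are incomplete — and a
  strict mode rejects on missingness instead. The filter is monotone in
  every threshold.
* Copy calls: Log2 ≥ 0.43 → amplification, ≤ −0.32 → loss, both closed;
  otherwise neutral.
* Presumed-somatic heuristic (landscape analysis only, never the VEF): a
  tumor-only variant with VAF outside the heterozygous band and no
  clinical suspicion of VHL. The band default is [40%, 60%],
  configurable; only the medians of the out-of-band groups (27% / 68%)
  are published, not the band itself, so the default is our choice of a
  conventional heterozygous interval.
* Allelic status: inactivating events are null/missense SNVs, indels and
  copy losses; amplifications never inactivate (loss-of-function
  disease). 0 events → no inactivation; 1 → monoallelic second-hit
  candidate; ≥2, or a homozygous deletion alone → biallelic LOH with a
  mechanism (SNV+deletion, two SNVs, two-copy deletion, other). Profiles
  with only SV/unclassifiable records are uninformative. Copy-neutral LOH
  and promoter hypermethylation are invisible here by design.
* A coding SNV without a stated protein consequence is treated as a
  candidate inactivating event; panel-reported somatic SNVs in this gene
  are reported because of a presumed functional impact.

## Gene annotation

Exon bounds (cDNA): exon 1 c.1–340, exon 2 c.341–463, exon 3 c.464–642 —
the two junctions are fixed by the canonical splice acceptors c.341-1 and
c.464-1. The cryptic exon E1′ window defaults to intron-1 offsets
[+400, +800]; published E1′ variants (c.340+578, +691, +694_+711dup,
+705, +742) all fall inside, but the true boundaries are not
standardized, so the window is declared data and echoed in metadata.
Effect classes are structural only: a synonymous change stays synonymous
even for alleles with reported splice consequences (functional
reinterpretation is out of scope). A nonsense call from c. alone is not
possible without the coding sequence, so nonsense variants need the p.
annotation; frameshifts and canonical ±1/±2 splice positions are called
from c. directly.

## Synthetic cohorts

Generation is scenario-first: codes are apportioned from the requested
mix by largest remainder (realized counts match the mix exactly), a case
is constructed to satisfy that scenario's predicate, then decorated with
a variant drawn from a pool of recurrent published-class-appropriate
alleles (including E1′ and ECYT2 alleles), a sex (74% female), and an age
(young 10–29, adult 31–85). Defaults emulate a retrospective germline
clinic cohort: ~60% VUS, ~22% P/LP (40% of which are large deletions),
~11% B/LB, ~7% ECYT2-only; somatic profiling in ~8% of cases where the
scenario does not itself require it. Same spec + seed is byte-identical.

What the generator does **not** emulate: allele frequencies and linkage,
VAF/coverage noise, multi-tumor correlation structure, pedigrees beyond
the degree enum, or incomplete/contradictory real-world records beyond
what the invalid-row path exercises. Passing tests therefore demonstrate
the correctness of the rule machinery on well-formed evidence, not the
clinical performance of the framework on messy hospital data.

## Numerical and degenerate-input choices

All thresholds are closed exactly as stated; no floating tolerance is
applied anywhere (inputs are counts, enums and printed decimal
thresholds). Age `unknown` never matches an age-conditioned rule, so such
cases reach the NOS fallback rather than being coerced adult. Empty
cohorts produce empty outputs, not errors. Variant keys normalize
whitespace, an optional `VHL:` prefix and case; large deletions are keyed
by their deleted-exon set. Duplicate subject ids abort a batch read;
within one encoded table a subject contributes once to recurrence even if
duplicated.

## Problem sizes

The test suite enumerates the full discretized vector space (~6.3k
vectors), all somatic multisets of size ≤ 3, and synthetic cohorts of up
to 1,000 cases; the acceptance script uses a 1,000-case cohort. These
sizes make every check exhaustive or exact while keeping the whole suite
in the low seconds.

## Known limitations

The default scenario table is a faithful reconstruction, not the
authoritative appendix-level definition; swap the YAML to supersede it.
Cohort-level published percentages (e.g. the Negative fraction of a real
133-patient cohort, or the 36% LOH fraction among 75 ccRCC) depend on the
unreleased patient data and are not reproduced here. Epigenetic *VHL*
inactivation, copy-neutral LOH, mosaicism and complex rearrangements are
outside the data model.
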