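# Methods

## The screening procedure

`drugfunnel` implements a genome-based drug-repurposing prioritization
screen. The inputs are (a) a drug catalog in a DrugBank-style XML dialect
and (b) an exome-array variant annotation table (one row per SNP/SNV with
array probe id, dbSNP rsID, gene symbol, per-population minor allele
frequency, and genotyping missingness). The output is the "repurposable
drugged genome": the set of (target gene, pharmacological action) classes
that carry an approved, selective small molecule *and* at least one
variant of sufficient quality for phenome-wide association (PheWAS)
follow-up, plus a prioritized shortlist with marketing details.

### Pharmacodynamic attrition

Four record-wise filters run in a fixed order, so intermediate survivor
counts are comparable across runs:

1. **Type** — keep `small-molecule` drugs. Biologics are excluded on
   pragmatic grounds (cost and availability for trials).
2. **Approval status** — keep drugs whose status labels intersect a
   configurable allowlist (default `{approved}`) and contain no veto label
   (default `{withdrawn, illicit}`). Membership is exact: `vet-approved`
   does not satisfy the `approved` requirement. Veto dominates: a drug
   labeled both approved and withdrawn is excluded.
3. **Known-action count** — keep drugs with *exactly one* target of known
   mechanism of action. Extra targets of unknown action do not disqualify
   a drug; selectivity is asserted on known mechanisms only. The
   one-target-total rate (share of survivors whose total target count is
   also one) quantifies how much this distinction matters.
4. **Exclusions** — drop, with distinct reason codes and in this
   precedence order: (a) drugs whose known-action target organism is not
   human; (b) drugs on a name-based safety blocklist (DNA-damaging agents
   and other severe-toxicity drugs — a manually curated list supplied in
   configuration, since no structured toxicology field exists to mine);
   (c) drugs with a missing required field (name, action, gene symbol,
   status).

Survivors are **consolidated into target-action pairs** keyed on
(gene symbol uppercased and trimmed, action lowercased and trimmed).
Distinct action words (e.g. *inhibitor* vs. *antagonist*) are never
merged: there is no defensible synonym map, and merging would silently
change the pair count. Consolidation is a partition: every surviving drug
belongs to exactly one pair.

### Variant quality control

A variant is eligible iff its rsID is present, genotyping missingness
≤ `missingness_max` (default 0.05), and MAF in the configured analysis
population ≥ `maf_min` (default 0.001, the conventional floor below which
PheWAS power collapses). Removal conditions are strict inequalities, so
boundary values (missingness exactly 0.05, MAF exactly 0.001) are
retained. A variant failing several screens is counted once, under the
first failing screen in the order rsID → missingness → MAF; this makes
per-reason removal counts deterministic. MAF is stored per population in
a map so the analysis cohort is a configuration key, not a hard-coded
column. MAF is taken as given on the minor allele (bounded at load by
[0, 0.5]); genotype-level recomputation is out of scope.

### Integration

The join key is the normalized gene symbol. A pair is *covered* when at
least one eligible variant lies in its gene; two pairs on the same gene
receive identical variant lists. Uncovered pairs are kept in the mapping
(flagged by an empty list) so reports can enumerate them. "Unique
targets" means distinct gene symbols among covered pairs — gene symbol is
the join key, so it is the only internally consistent reading. The
coverage percent is rounded half-up to an integer (227/237 = 95.78…% →
96%); the exact fraction is reported alongside. The shortlist contains
one entry per covered pair, sorted by descending eligible-variant count
then gene then action, with each member drug's earliest marketing start
date and countries attached (earliest date = minimum over that drug's
dated products per country; unparseable or absent dates are treated as
absent with a warning).

## Synthetic study conditions

Real DrugBank exports are license-gated and biobank genotype data are
private, so the package ships a generator whose default composition is
calibrated to the published screen. The generator is *stratified*: each
stratum of records is constructed to pass every stage before its own and
fail exactly at its designated stage, so the pipeline's counts over the
default composition are ground truth by construction, not a statistical
outcome. Default calibration:

| stratum | count |
|---|---|
| total drugs | 10,505 |
| biologics (fail type) | 1,213 → 9,292 survive |
| not approved / vetoed (fail status) | 7,073 → 2,219 survive |
| known-action count ≠ 1 | 1,396 → 823 survive |
| excluded (150 nonhuman + 30 blocklist + 22 missing-field) | 202 → 621 survive |
| target-action pairs | 237 |
| variants total | 239,796 |
| ineligible (20,000 null-rsID + 60,851 high-missingness + 100,000 low-MAF) | 180,851 → 58,945 eligible |
| covered pairs / unique covered genes | 227 / 147 |

Only the aggregate exclusion count (202) and removal count (180,851) are
externally fixed; their splits above are this package's documented fixture
convention. Likewise the pair layout — 80 genes carrying two actions plus
67 genes carrying one (the 147 covered genes, 227 covered pairs) plus 10
uncovered pairs on 10 further genes — is the minimal structure consistent
with 237/227/147, and the allocation of the 621 drugs over the 237 pairs
(one each, surplus dealt round-robin) is a deterministic convention. 518
of the 621 final drugs carry a single total target, fixing the
one-target-total rate at 83.41%. The source material itself states both
239,796 and 237,796 for the variant total; the generator uses 239,796.

Generators are pure functions of (composition, seed): the seed randomizes
names, dates, MAF/missingness draws and record order, never stratum
counts, so every reported count is seed-invariant. MAF and missingness
draws keep a guard band around the QC thresholds (eligible missingness
≤ 0.049, ineligible ≥ 0.051; eligible MAF ≥ 0.0011, ineligible ≤ 0.0009)
so 6-decimal serialization can never move a record across a screen.

**What the synthetic data do not emulate:** realistic MAF spectra or
linkage structure, genotypes, phenotypes, real gene symbols or drug
names, and the long tail of catalog fields. Passing the calibrated
end-to-end checks therefore verifies the *logic* — filter predicates,
consolidation, QC screens, join and counting — against planted ground
truth; it says nothing about the behavior of the screen on a particular
real catalog release.

## Numerical and degenerate-input choices

- Percentages use decimal half-up rounding (two decimals for the
  one-target-total rate, integer for coverage), not banker's rounding.
- Dates are ISO-8601 only; anything else is absent-with-warning.
- `NULL`, empty, and whitespace-only cells normalize to absent at parse
  time in both readers, which makes the downstream missing-field and
  null-rsID rules testable.
- Empty inputs: an empty catalog yields an all-zero funnel and empty
  reports (exit 0); a rate or coverage over an empty set raises a
  dedicated error rather than returning NaN.
- Record-level failures (a drug missing name/type, a variant row with
  MAF > 0.5 or identical alleles) are collected as rejects with reasons
  and skipped; only document-level malformation aborts.
- The parser imposes no cap on targets per drug.

## Problem sizes

The default test suite runs the calibrated composition at full scale
(10,505 drugs; 239,796 variants) once in a shared fixture — about 10 s —
plus small randomized fixtures (tens to 1,000 records) for the oracle and
property tests. `scripts/acceptance.py` regenerates both fixtures and
runs the complete pipeline in under 10 s.

## Known limitations

- The safety blocklist is name-based and manual; there is no automated
  toxicology scoring.
- Action vocabulary is taken as-is; cross-catalog synonym drift would
  split pairs.
- PheWAS association testing itself, comparisons against external
  druggable-genome catalogs, and clinical-trial pipeline tracking are out
  of scope: the pipeline stops at PheWAS-ready shortlists.
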