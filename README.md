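# drugfunnel

Genome-based drug-repurposing prioritization: which existing, approved
drugs are worth re-testing against new indications, given the genomic
data a biobank can actually interrogate?

`drugfunnel` is for informaticians and repurposing programs who want to
go from a full drug catalog (~10,000 agents) and an exome-array variant
annotation (~240,000 SNPs/SNVs) to a short, ranked list of
phenome-wide-association-ready drug classes. It implements a staged
attrition screen:

1. **Pharmacodynamic attrition** of a DrugBank-style XML catalog:
   keep small molecules → keep approved drugs (veto labels *withdrawn*,
   *illicit* dominate) → keep drugs with exactly one target of known
   mechanism of action → exclude nonhuman-target drugs, a manual safety
   blocklist, and records with missing fields.
2. **Consolidation** of survivors into *target-action pairs*
   (gene symbol, action): same-class drugs (e.g. ACE inhibitors) collapse
   into one unit, moving the analysis from drugs to drug classes.
3. **Variant quality control**: a SNP/SNV is eligible iff its rsID is
   present, genotyping missingness ≤ 0.05, and minor allele frequency in
   the analysis population ≥ 0.001 (boundary values retained).
4. **Gene-level integration**: a pair is *covered* when ≥ 1 eligible
   variant lies in its target gene. Covered pairs form the "repurposable
   drugged genome"; the shortlist ranks them by variant support and
   attaches each drug's earliest marketing date per country.

Real drug-catalog exports are license-gated and biobank genotypes are
private, so the package ships a deterministic synthetic-data generator
(`drugfunnel.synthetic_data`) whose default composition is calibrated so
a correct pipeline reproduces the published screen's funnel exactly.

## Worked example

Generate the calibrated fixtures and run the full pipeline:

```sh
drugfunnel simulate --seed 1 --out demo
drugfunnel run demo/catalog.xml demo/variants.tsv \
    --config demo/config.yaml --out demo/reports
```

(the config supplies the safety blocklist; `tests/test_cli.py` shows how
to write one). The run logs each stage to stderr and prints:

```
INFO drugfunnel stage=type n_in=10505 n_out=9292
INFO drugfunnel stage=status n_in=9292 n_out=2219
INFO drugfunnel stage=known-action-count n_in=2219 n_out=823
INFO drugfunnel stage=exclusions n_in=823 n_out=621
INFO drugfunnel stage=consolidate n_in=621 n_out=237
INFO drugfunnel stage=qc n_in=239796 n_out=58945
INFO drugfunnel stage=integrate n_in=237 n_out=227
pairs=237 covered=227 unique_targets=147 coverage=96%
```

Reading the funnel: 10,505 cataloged drugs reduce to 9,292 small
molecules, 2,219 approved agents, 823 single-known-action drugs, and 621
drugs after exclusions, which consolidate into 237 target-action pairs.
On the genomic side 239,796 variants reduce to 58,945 QC-eligible
SNPs/SNVs; 227 of the 237 pairs (96%, rounded half-up from 227/237) have
at least one eligible variant in their target gene, on 147 distinct
genes. Those 227 pairs are the PheWAS-ready shortlist.

`demo/reports/` then contains `funnel.tsv`, `funnel_exclusions.tsv`,
`qc_report.tsv`, `eligible_variants.tsv`, `coverage.json`, and
`shortlist.tsv`. The shortlist is sorted by variant support:

```
gene      action           drugs                              n_variants  earliest_marketing_date  countries
SYNG0096  inhibitor        Candidate-00499|Candidate-00500    47          1964-09-24               Canada|United States
SYNG0103  partial agonist  Candidate-00513|Candidate-00514    40          1954-08-19               Canada|United States
```

and `coverage.json` records the headline statistics, including the
one-target-total rate — 83.41% (518 of the 621 surviving drugs list only
a single total target):

```json
{
  "n_pairs": 237,
  "n_pairs_covered": 227,
  "n_unique_targets_covered": 147,
  "coverage_percent": 96,
  "coverage_fraction": [227, 237],
  "one_target_total_rate": 83.41
}
```

The same pipeline runs on any catalog/annotation pair in the documented
dialects (see module docstrings in `drugfunnel.drugbank_io` and
`drugfunnel.genomic_qc`); per-stage subcommands (`parse`, `funnel`,
`qc`, `integrate`) exercise each step in isolation, and everything is
also available as a library (`drugfunnel.run_pipeline`).

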