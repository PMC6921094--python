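"""Exome-array variant annotation loading and eligibility screening.

Variants come from an exome genotyping array annotation table joined to
biobank genotype summaries: one row per SNP/SNV with its array probe id
(exmID), dbSNP rsID, gene symbol, per-population minor allele frequency
(MAF), genotyping missingness, and mutation annotation.

A variant is *eligible* for downstream phenome-wide association work when

* its rsID is present (variants that cannot be cross-referenced against
  dbSNP are dropped),
* genotyping missingness is not above 0.05 (stochastic-missingness
  assumption; higher missingness risks confounding), and
* MAF in the analysis population is not below 0.001 (rarer variants lack
  power for PheWAS).

Both thresholds are strict removal conditions: boundary values (missingness
exactly 0.05, MAF exactly 0.001) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .pd_attrition import normalize_gene

VALID_BASES = frozenset("ACGT")

# removal reason codes, in report precedence order
REASON_NULL_RSID = "null-rsid"
REASON_HIGH_MISSINGNESS = "high-missingness"
REASON_LOW_MAF = "low-maf"
REASON_MISSING_POPULATION = "missing-population"

#: prefix for per-population MAF columns in the annotation TSV
MAF_COLUMN_PREFIX = "MAF_"

REQUIRED_COLUMNS = ("exmID", "rsID", "Gene", "Missingness", "Mutation", "AlleleA", "AlleleB")


class VariantTableFormatError(ValueError):
    """The annotation TSV is missing a required column."""


@dataclass
class VariantRecord:
    """One exome-array SNP/SNV with its QC-relevant annotations."""

    exm_id: str
    rsid: Optional[str]
    gene_symbol: str
    maf_by_population: dict[str, float]
    missingness: float
    mutation_annotation: str = ""
    allele_major: str = "A"
    allele_minor: str = "G"

    def __post_init__(self) -> None:
        for pop, maf in self.maf_by_population.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"MAF[{pop}]={maf} outside [0, 0.5]")
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError(f"missingness {self.missingness} outside [0, 1]")
        if self.allele_major == self.allele_minor:
            raise ValueError("major and minor alleles must differ")
        if self.allele_major not in VALID_BASES or self.allele_minor not in VALID_BASES:
            raise ValueError("alleles must be single bases in {A, C, G, T}")


@dataclass
class QCConfig:
    """Eligibility thresholds and the analysis population key."""

    population: str = "white"
    maf_min: float = 0.001
    missingness_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if not 0.0 < self.missingness_max < 1.0:
            raise ValueError("missingness_max must be in (0, 1)")


@dataclass
class QCReport:
    """Removal counts per reason; eligible + removals account for the input."""

    n_input: int
    n_eligible: int
    removed_by_reason: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_eligible + sum(self.removed_by_reason.values()) != self.n_input:
            raise ValueError("QC accounting mismatch: eligible + removals != input")

    def to_rows(self) -> list[dict]:
        return [
            {"reason": reason, "n_removed": n}
            for reason, n in self.removed_by_reason.items()
        ]


@dataclass
class RejectedVariant:
    """A table row that violated a type invariant at load time."""

    row_index: int
    exm_id: str
    reason: str


def load_variant_table(
    path: Union[str, Path],
    rejects: Optional[list[RejectedVariant]] = None,
) -> list[VariantRecord]:
    """Load the variant annotation TSV into records.

    Literal ``NULL`` (or empty) rsID cells become absent rsids. Rows that
    violate a type invariant (MAF outside [0, 0.5], bad alleles, ...) are
    collected into ``rejects`` when a list is supplied, and skipped.

    Raises
    ------
    VariantTableFormatError
        If a required column, or every per-population MAF column, is absent.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise VariantTableFormatError(f"missing required column(s): {missing}")
    maf_cols = [c for c in frame.columns if c.startswith(MAF_COLUMN_PREFIX)]
    if not maf_cols:
        raise VariantTableFormatError(
            f"no per-population MAF column ({MAF_COLUMN_PREFIX}<pop>) found"
        )
    populations = [c[len(MAF_COLUMN_PREFIX):] for c in maf_cols]

    records: list[VariantRecord] = []
    columns = ["exmID", "rsID", "Gene", "Missingness", "Mutation", "AlleleA", "AlleleB"]
    for i, (exm, rsid, gene, missing_frac, mutation, major, minor, *mafs) in enumerate(
        frame[columns + maf_cols].itertuples(index=False, name=None)
    ):
        rsid = rsid.strip()
        try:
            records.append(
                VariantRecord(
                    exm_id=exm,
                    rsid=None if not rsid or rsid.upper() == "NULL" else rsid,
                    gene_symbol=normalize_gene(gene),
                    maf_by_population={
                        pop: float(maf) for pop, maf in zip(populations, mafs)
                    },
                    missingness=float(missing_frac),
                    mutation_annotation=mutation,
                    allele_major=major.strip().upper(),
                    allele_minor=minor.strip().upper(),
                )
            )
        except ValueError as exc:
            if rejects is not None:
                rejects.append(RejectedVariant(row_index=i, exm_id=exm, reason=str(exc)))
    return records


def qc_filter(
    variants: Sequence[VariantRecord], config: Optional[QCConfig] = None
) -> tuple[list[VariantRecord], QCReport]:
    """Apply the eligibility screens; return eligible variants and a report.

    A variant is removed iff its rsid is absent, OR missingness exceeds
    ``missingness_max``, OR MAF in the configured population is below
    ``maf_min`` (strict inequalities: boundary values are retained). A
    variant failing several screens is counted once, under the first
    failing screen in the order rsid -> missingness -> MAF. A record
    lacking the configured population key is removed with its own reason.
    """
    config = config or QCConfig()
    eligible: list[VariantRecord] = []
    removed = {
        REASON_NULL_RSID: 0,
        REASON_HIGH_MISSINGNESS: 0,
        REASON_LOW_MAF: 0,
        REASON_MISSING_POPULATION: 0,
    }
    for v in variants:
        if v.rsid is None:
            removed[REASON_NULL_RSID] += 1
        elif v.missingness > config.missingness_max:
            removed[REASON_HIGH_MISSINGNESS] += 1
        elif config.population not in v.maf_by_population:
            removed[REASON_MISSING_POPULATION] += 1
        elif v.maf_by_population[config.population] < config.maf_min:
            removed[REASON_LOW_MAF] += 1
        else:
            eligible.append(v)
    return eligible, QCReport(
        n_input=len(variants),
        n_eligible=len(eligible),
        removed_by_reason=removed,
    )


def write_eligible_table(
    variants: Iterable[VariantRecord], destination: Union[str, Path]
) -> None:
    """Write eligible variants back out in the annotation TSV dialect."""
    rows = []
    for v in variants:
        row = {
            "exmID": v.exm_id,
            "rsID": v.rsid if v.rsid is not None else "NULL",
            "Gene": v.gene_symbol,
            "Missingness": v.missingness,
            "Mutation": v.mutation_annotation,
            "AlleleA": v.allele_major,
            "AlleleB": v.allele_minor,
        }
        for pop, maf in v.maf_by_population.items():
            row[f"{MAF_COLUMN_PREFIX}{pop}"] = maf
        rows.append(row)
    pd.DataFrame(rows).to_csv(destination, sep="\t", index=False)
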