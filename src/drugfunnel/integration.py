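"""Gene-level integration of target-action pairs with eligible variants.

The join key is the normalized gene symbol: a target-action pair is
*covered* when at least one QC-eligible variant lies in its target gene.
Covered pairs define the "repurposable drugged genome"; the coverage
summary reports how much of the pair pool the genomic data can interrogate,
and the shortlist ranks covered pairs by variant support with marketing
details attached for pragmatic (intellectual-property) triage.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import decimal

import pandas as pd

from .genomic_qc import VariantRecord
from .pd_attrition import TargetActionPair

PairKey = tuple[str, str]


class UndefinedCoverageError(ZeroDivisionError):
    """Coverage was requested over an empty pair mapping."""


@dataclass
class CoverageSummary:
    """How many pairs (and distinct target genes) have variant support."""

    n_pairs: int
    n_pairs_covered: int
    n_unique_targets_covered: int
    coverage_percent: int
    coverage_fraction: Fraction

    def __post_init__(self) -> None:
        if self.n_pairs_covered > self.n_pairs:
            raise ValueError("covered pairs exceed total pairs")
        if self.n_unique_targets_covered > self.n_pairs_covered:
            raise ValueError("unique covered targets exceed covered pairs")


@dataclass
class ShortlistEntry:
    """One covered pair, its drugs, variant support, and marketing details."""

    gene_symbol: str
    action: str
    drug_names: tuple[str, ...]
    n_eligible_variants: int
    earliest_marketing_date: dict[str, Optional[datetime.date]]
    countries: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.n_eligible_variants < 1:
            raise ValueError("shortlist entries require >=1 eligible variant")


def map_pairs_to_variants(
    pairs: Sequence[TargetActionPair], eligible_variants: Sequence[VariantRecord]
) -> dict[PairKey, list[VariantRecord]]:
    """Map every pair to the eligible variants in its target gene.

    Pairs with no matching variant map to empty lists — they are kept and
    flagged uncovered rather than dropped, so reports can list them.
    Two pairs on the same gene (different actions) receive identical
    variant lists: the join is gene-level.
    """
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in eligible_variants:
        by_gene.setdefault(v.gene_symbol, []).append(v)
    return {p.key: list(by_gene.get(p.gene_symbol, [])) for p in pairs}


def coverage_summary(mapping: dict[PairKey, list[VariantRecord]]) -> CoverageSummary:
    """Summarize pair coverage; percent is rounded half-up to an integer."""
    if not mapping:
        raise UndefinedCoverageError("coverage undefined for an empty pair mapping")
    n_pairs = len(mapping)
    covered = [key for key, variants in mapping.items() if variants]
    fraction = Fraction(len(covered), n_pairs)
    percent = int(
        (decimal.Decimal(100 * len(covered)) / decimal.Decimal(n_pairs)).quantize(
            decimal.Decimal("1"), rounding=decimal.ROUND_HALF_UP
        )
    )
    return CoverageSummary(
        n_pairs=n_pairs,
        n_pairs_covered=len(covered),
        n_unique_targets_covered=len({gene for gene, _action in covered}),
        coverage_percent=percent,
        coverage_fraction=fraction,
    )


def build_shortlist(
    mapping: dict[PairKey, list[VariantRecord]],
    marketing_table: pd.DataFrame,
    pairs: Sequence[TargetActionPair],
) -> list[ShortlistEntry]:
    """One entry per covered pair, ranked by variant support.

    Sorted by descending eligible-variant count, then gene symbol, then
    action. Marketing fields are joined by drug name (case-insensitive);
    drugs without marketing information get absent fields.
    """
    earliest: dict[str, Optional[datetime.date]] = {}
    countries: dict[str, list[str]] = {}
    for row in marketing_table.itertuples(index=False):
        key = str(row.name).strip().lower()
        date = row.earliest_marketing_date
        if pd.notna(date) and date is not None:
            prev = earliest.get(key)
            if prev is None or date < prev:
                earliest[key] = date
        else:
            earliest.setdefault(key, None)
        if pd.notna(row.country) and row.country is not None:
            countries.setdefault(key, []).append(str(row.country))

    entries: list[ShortlistEntry] = []
    for pair in pairs:
        variants = mapping.get(pair.key, [])
        if not variants:
            continue
        entries.append(
            ShortlistEntry(
                gene_symbol=pair.gene_symbol,
                action=pair.action,
                drug_names=pair.member_drug_names,
                n_eligible_variants=len(variants),
                earliest_marketing_date={
                    name: earliest.get(name.strip().lower())
                    for name in pair.member_drug_names
                },
                countries={
                    name: tuple(sorted(set(countries.get(name.strip().lower(), ()))))
                    for name in pair.member_drug_names
                },
            )
        )
    entries.sort(key=lambda e: (-e.n_eligible_variants, e.gene_symbol, e.action))
    return entries


def write_shortlist_table(
    entries: Sequence[ShortlistEntry], destination
) -> None:
    """Shortlist TSV: gene, action, drugs, n_variants, marketing columns."""
    rows = []
    for e in entries:
        dates = [
            d.isoformat()
            for d in e.earliest_marketing_date.values()
            if d is not None
        ]
        all_countries = sorted({c for cs in e.countries.values() for c in cs})
        rows.append(
            {
                "gene": e.gene_symbol,
                "action": e.action,
                "drugs": "|".join(e.drug_names),
                "n_variants": e.n_eligible_variants,
                "earliest_marketing_date": min(dates) if dates else "",
                "countries": "|".join(all_countries),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene",
            "action",
            "drugs",
            "n_variants",
            "earliest_marketing_date",
            "countries",
        ],
    ).to_csv(destination, sep="\t", index=False)
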