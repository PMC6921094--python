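"""Deterministic generators for drug catalogs and variant tables.

Real drug encyclopedias are license-gated and biobank genotype data are
private, so this module generates stand-in inputs whose *composition* is
fully specified: each stratum of records is constructed to survive every
attrition stage before its own and to fail exactly at its designated
stage, so the funnel counts a pipeline run produces are known by
construction. The default calibration reproduces the published screen
end-to-end:

* drug catalog: 10,505 drugs -> 9,292 small molecules -> 2,219 approved
  -> 823 single-known-action -> 621 post-exclusion drugs -> 237
  target-action pairs (518 of the 621 have one total target);
* variant table: 239,796 SNPs/SNVs -> 58,945 eligible after QC;
* integration: 227 of 237 pairs covered, on 147 distinct target genes.

Generators are pure functions of (composition, seed): the seed randomizes
surface detail (names, dates, MAF draws, record order) but never the
stratum counts, so every funnel number is seed-invariant.

All gene symbols and drug names are synthetic vocabulary; they are not
real genes or agents.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from lxml import etree

from .pd_attrition import AttritionConfig

__all__ = [
    "CompositionError",
    "CatalogComposition",
    "VariantComposition",
    "generate_drug_catalog",
    "generate_variant_table",
    "attrition_config_for",
]


class CompositionError(ValueError):
    """A composition's stratum counts are internally inconsistent."""


ACTIONS = (
    "inhibitor",
    "antagonist",
    "agonist",
    "activator",
    "modulator",
    "blocker",
    "potentiator",
    "partial agonist",
)

NONHUMAN_ORGANISMS = (
    "Staphylococcus aureus",
    "Escherichia coli",
    "Hepatitis C virus",
    "Candida albicans",
    "Plasmodium falciparum",
    "Ascaris lumbricoides",
)

NON_APPROVED_LABEL_SETS = (
    ("investigational",),
    ("experimental",),
    ("nutraceutical",),
    ("vet-approved",),
    ("approved", "withdrawn"),
    ("approved", "illicit"),
)

MUTATION_CLASSES = (
    "missense",
    "synonymous",
    "nonsense",
    "splice-site",
    "intronic",
    "3'-UTR",
)

#: synthetic filler genes that carry variants but are not drug targets
N_FILLER_GENES = 2000


def _covered_gene(i: int) -> str:
    return f"SYNG{i:04d}"


def _uncovered_gene(i: int) -> str:
    return f"SYNU{i:04d}"


def _filler_gene(i: int) -> str:
    return f"FILG{i:04d}"


@dataclass
class CatalogComposition:
    """Per-stratum layout of a synthetic drug catalog.

    Stratum counts telescope through the funnel stages; the final stratum
    is laid out over a fixed pair structure: ``n_two_action_genes`` target
    genes carry two distinct actions each and ``n_one_action_genes`` carry
    one (together the genomically covered pairs), plus ``n_uncovered_pairs``
    pairs on distinct genes that the paired variant table leaves without
    eligible variants.
    """

    n_biotech: int = 1213
    n_not_approved: int = 7073
    n_wrong_known_action_count: int = 1396
    n_excluded_nonhuman: int = 150
    n_excluded_blocklist: int = 30
    n_excluded_missing_field: int = 22
    n_final: int = 621
    n_final_single_total_target: int = 518
    n_two_action_genes: int = 80
    n_one_action_genes: int = 67
    n_uncovered_pairs: int = 10

    def __post_init__(self) -> None:
        counts = (
            self.n_biotech,
            self.n_not_approved,
            self.n_wrong_known_action_count,
            self.n_excluded_nonhuman,
            self.n_excluded_blocklist,
            self.n_excluded_missing_field,
            self.n_final,
        )
        if any(c < 0 for c in counts):
            raise CompositionError("stratum counts must be nonnegative")
        if self.n_final_single_total_target > self.n_final:
            raise CompositionError(
                "single-total-target count exceeds the final stratum"
            )
        if self.n_final and self.n_pairs == 0:
            raise CompositionError("final drugs present but no pairs configured")
        if self.n_pairs > self.n_final:
            raise CompositionError(
                f"{self.n_pairs} pairs need at least {self.n_pairs} drugs; "
                f"only {self.n_final} configured"
            )

    @property
    def n_total(self) -> int:
        return (
            self.n_biotech
            + self.n_not_approved
            + self.n_wrong_known_action_count
            + self.n_excluded
            + self.n_final
        )

    @property
    def n_excluded(self) -> int:
        return (
            self.n_excluded_nonhuman
            + self.n_excluded_blocklist
            + self.n_excluded_missing_field
        )

    # expected funnel survivor counts, by construction
    @property
    def n_after_type(self) -> int:
        return self.n_total - self.n_biotech

    @property
    def n_after_status(self) -> int:
        return self.n_after_type - self.n_not_approved

    @property
    def n_after_known_action(self) -> int:
        return self.n_after_status - self.n_wrong_known_action_count

    @property
    def n_covered_pairs(self) -> int:
        return 2 * self.n_two_action_genes + self.n_one_action_genes

    @property
    def n_pairs(self) -> int:
        return self.n_covered_pairs + self.n_uncovered_pairs

    @property
    def covered_genes(self) -> tuple[str, ...]:
        return tuple(
            _covered_gene(i)
            for i in range(self.n_two_action_genes + self.n_one_action_genes)
        )

    @property
    def uncovered_genes(self) -> tuple[str, ...]:
        return tuple(_uncovered_gene(i) for i in range(self.n_uncovered_pairs))

    @property
    def blocklist_names(self) -> tuple[str, ...]:
        return tuple(
            f"Blocklisted-agent-{i:03d}" for i in range(self.n_excluded_blocklist)
        )

    def pair_layout(self) -> list[tuple[str, str]]:
        """The (gene, action) pair keys, covered genes first."""
        pairs: list[tuple[str, str]] = []
        for i in range(self.n_two_action_genes):
            gene = _covered_gene(i)
            pairs.append((gene, ACTIONS[i % len(ACTIONS)]))
            pairs.append((gene, ACTIONS[(i + 1) % len(ACTIONS)]))
        for i in range(self.n_one_action_genes):
            gene = _covered_gene(self.n_two_action_genes + i)
            pairs.append((gene, ACTIONS[i % len(ACTIONS)]))
        for i in range(self.n_uncovered_pairs):
            pairs.append((_uncovered_gene(i), ACTIONS[i % len(ACTIONS)]))
        return pairs


def attrition_config_for(composition: CatalogComposition) -> AttritionConfig:
    """The attrition configuration matching a catalog composition.

    The safety blocklist is a manual, name-based list in real screens; the
    synthetic catalog plants its own blocklisted names, which this config
    carries.
    """
    return AttritionConfig(
        excluded_drug_names=frozenset(composition.blocklist_names)
    )


def _random_date(rng: random.Random) -> datetime.date:
    start = datetime.date(1950, 1, 1).toordinal()
    end = datetime.date(2018, 12, 31).toordinal()
    return datetime.date.fromordinal(rng.randint(start, end))


def _target_element(
    gene: Optional[str],
    action: Optional[str],
    organism: Optional[str],
    known_action: bool,
    name: Optional[str] = None,
) -> etree._Element:
    el = etree.Element("target")
    etree.SubElement(el, "name").text = name or (
        f"{gene or 'unnamed'} protein" if gene else "unnamed protein"
    )
    etree.SubElement(el, "known-action").text = "yes" if known_action else "unknown"
    if action is not None:
        actions = etree.SubElement(el, "actions")
        etree.SubElement(actions, "action").text = action
    if organism is not None:
        etree.SubElement(el, "organism").text = organism
    if gene is not None:
        poly = etree.SubElement(el, "polypeptide")
        etree.SubElement(poly, "gene-name").text = gene
    return el


def _drug_element(
    drug_id: str,
    name: str,
    drug_type: str,
    groups: tuple[str, ...],
    targets: list[etree._Element],
    products: list[tuple[str, Optional[datetime.date]]],
) -> etree._Element:
    el = etree.Element("drug", type=drug_type)
    etree.SubElement(el, "drugbank-id").text = drug_id
    etree.SubElement(el, "name").text = name
    groups_el = etree.SubElement(el, "groups")
    for g in groups:
        etree.SubElement(groups_el, "group").text = g
    if products:
        products_el = etree.SubElement(el, "products")
        for country, date in products:
            p = etree.SubElement(products_el, "product")
            etree.SubElement(p, "country").text = country
            if date is not None:
                etree.SubElement(p, "started-marketing-on").text = date.isoformat()
    if targets:
        targets_el = etree.SubElement(el, "targets")
        for t in targets:
            targets_el.append(t)
    return el


def _final_stratum_specs(
    composition: CatalogComposition, rng: random.Random
) -> list[dict]:
    """Lay the final-retained drugs over the configured pair structure.

    Each pair receives at least one drug; the surplus is dealt round-robin.
    The configured number of drugs keeps a single total target; the rest
    gain extra unknown-action targets (which the known-action-count stage
    ignores).
    """
    pairs = composition.pair_layout()
    n_extra = composition.n_final - len(pairs)
    per_pair = [1] * len(pairs)
    for i in range(n_extra):
        per_pair[i % len(pairs)] += 1

    specs: list[dict] = []
    k = 0
    for (gene, action), count in zip(pairs, per_pair):
        for _ in range(count):
            specs.append(
                {
                    "name": f"Candidate-{k:05d}",
                    "gene": gene,
                    "action": action,
                }
            )
            k += 1
    # drugs beyond the single-total-target quota get extra unknown targets
    n_multi = composition.n_final - composition.n_final_single_total_target
    multi_idx = rng.sample(range(len(specs)), n_multi)
    for i in multi_idx:
        specs[i]["extra_unknown_targets"] = rng.randint(1, 3)
    return specs


def generate_drug_catalog(
    composition: Optional[CatalogComposition] = None,
    seed: int = 0,
    path: Optional[Union[str, Path]] = None,
) -> bytes:
    """Generate a drug-catalog XML document from a composition.

    Deterministic for fixed (composition, seed); repeated calls produce
    byte-identical documents. When ``path`` is given the document is also
    written there.
    """
    composition = composition or CatalogComposition()
    rng = random.Random(seed)

    records: list[dict] = []

    for i in range(composition.n_biotech):
        records.append(
            {
                "name": f"Biologic-{i:05d}",
                "type": "biotech",
                "groups": ("approved",),
                "targets": [(_filler_gene(i % N_FILLER_GENES), "inhibitor", "Humans", True)],
            }
        )
    for i in range(composition.n_not_approved):
        labels = NON_APPROVED_LABEL_SETS[i % len(NON_APPROVED_LABEL_SETS)]
        records.append(
            {
                "name": f"Unapproved-{i:05d}",
                "type": "small molecule",
                "groups": labels,
                "targets": [(_filler_gene(i % N_FILLER_GENES), "inhibitor", "Humans", True)],
            }
        )
    for i in range(composition.n_wrong_known_action_count):
        variant = i % 3
        if variant == 0:  # no targets at all
            targets = []
        elif variant == 1:  # targets, none with known action
            targets = [(_filler_gene(i % N_FILLER_GENES), None, "Humans", False)]
        else:  # two known-action targets
            targets = [
                (_filler_gene(i % N_FILLER_GENES), "inhibitor", "Humans", True),
                (_filler_gene((i + 1) % N_FILLER_GENES), "antagonist", "Humans", True),
            ]
        records.append(
            {
                "name": f"Nonselective-{i:05d}",
                "type": "small molecule",
                "groups": ("approved",),
                "targets": targets,
            }
        )
    for i in range(composition.n_excluded_nonhuman):
        records.append(
            {
                "name": f"Antiinfective-{i:05d}",
                "type": "small molecule",
                "groups": ("approved",),
                "targets": [
                    (
                        _filler_gene(i % N_FILLER_GENES),
                        "inhibitor",
                        NONHUMAN_ORGANISMS[i % len(NONHUMAN_ORGANISMS)],
                        True,
                    )
                ],
            }
        )
    for name in composition.blocklist_names:
        records.append(
            {
                "name": name,
                "type": "small molecule",
                "groups": ("approved",),
                "targets": [(_filler_gene(rng.randrange(N_FILLER_GENES)), "inhibitor", "Humans", True)],
            }
        )
    for i in range(composition.n_excluded_missing_field):
        records.append(
            {
                "name": f"Incomplete-{i:05d}",
                "type": "small molecule",
                "groups": ("approved",),
                # known-action target with the gene annotation absent
                "targets": [(None, "inhibitor", "Humans", True)],
            }
        )
    for spec in _final_stratum_specs(composition, rng):
        targets = [(spec["gene"], spec["action"], "Humans", True)]
        for j in range(spec.get("extra_unknown_targets", 0)):
            targets.append((_filler_gene(rng.randrange(N_FILLER_GENES)), None, "Humans", False))
        n_products = rng.randint(1, 2)
        countries = rng.sample(("United States", "Canada"), n_products)
        records.append(
            {
                "name": spec["name"],
                "type": "small molecule",
                "groups": ("approved",),
                "targets": targets,
                "products": [(c, _random_date(rng)) for c in countries],
            }
        )

    rng.shuffle(records)

    root = etree.Element("drugbank")
    for i, rec in enumerate(records):
        target_els = [
            _target_element(gene, action, organism, known)
            for gene, action, organism, known in rec["targets"]
        ]
        root.append(
            _drug_element(
                drug_id=f"SYN{i:05d}",
                name=rec["name"],
                drug_type=rec["type"],
                groups=rec["groups"],
                targets=target_els,
                products=rec.get("products", []),
            )
        )
    payload = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if path is not None:
        Path(path).write_bytes(payload)
    return payload


@dataclass
class VariantComposition:
    """Per-stratum layout of a synthetic exome-array variant table.

    ``covered_genes`` each receive at least one eligible variant;
    ``uncovered_genes`` receive only ineligible variants. The three
    ineligible strata fail exactly one screen each (absent rsID,
    missingness above threshold, MAF below threshold).
    """

    n_eligible: int = 58945
    n_null_rsid: int = 20000
    n_high_missingness: int = 60851
    n_low_maf: int = 100000
    covered_genes: tuple[str, ...] = field(
        default_factory=lambda: CatalogComposition().covered_genes
    )
    uncovered_genes: tuple[str, ...] = field(
        default_factory=lambda: CatalogComposition().uncovered_genes
    )
    population: str = "white"

    def __post_init__(self) -> None:
        counts = (self.n_eligible, self.n_null_rsid, self.n_high_missingness, self.n_low_maf)
        if any(c < 0 for c in counts):
            raise CompositionError("stratum counts must be nonnegative")
        if set(self.covered_genes) & set(self.uncovered_genes):
            raise CompositionError("covered and uncovered gene sets overlap")
        if self.n_eligible < len(self.covered_genes):
            raise CompositionError(
                "not enough eligible variants to cover every covered gene"
            )
        # ineligible rows planted on uncovered genes
        n_planted = 10 * len(self.uncovered_genes)
        if self.n_high_missingness + self.n_low_maf < n_planted:
            raise CompositionError(
                "not enough ineligible variants to populate uncovered genes"
            )

    @property
    def n_total(self) -> int:
        return self.n_eligible + self.n_null_rsid + self.n_high_missingness + self.n_low_maf

    @classmethod
    def for_catalog(cls, catalog: CatalogComposition, **kwargs) -> "VariantComposition":
        return cls(
            covered_genes=catalog.covered_genes,
            uncovered_genes=catalog.uncovered_genes,
            **kwargs,
        )


def _spread_genes(
    rng: np.random.Generator, pool: list[str], n: int
) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=object)
    return np.array(pool, dtype=object)[rng.integers(0, len(pool), n)]


def generate_variant_table(
    composition: Optional[VariantComposition] = None,
    seed: int = 0,
    path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Generate a variant annotation table from a composition.

    Columns follow the annotation dialect (exmID, rsID, Gene, MAF_<pop>,
    Missingness, Mutation, AlleleA, AlleleB). Deterministic for fixed
    (composition, seed). When ``path`` is given, also written as TSV.

    MAF and missingness draws keep a guard band around the QC thresholds
    (eligible missingness <= 0.049, ineligible >= 0.051; eligible MAF
    >= 0.0011, ineligible <= 0.0009) so 6-decimal serialization can never
    move a variant across a screen.
    """
    composition = composition or VariantComposition()
    rng = np.random.default_rng(seed)

    covered = list(composition.covered_genes)
    uncovered = list(composition.uncovered_genes)
    filler = [_filler_gene(i) for i in range(N_FILLER_GENES)]

    genes_parts: list[np.ndarray] = []
    maf_parts: list[np.ndarray] = []
    miss_parts: list[np.ndarray] = []
    rsid_parts: list[np.ndarray] = []
    rs_counter = 1_000_000

    def _rsids(n: int) -> np.ndarray:
        nonlocal rs_counter
        out = np.array([f"rs{rs_counter + j}" for j in range(n)], dtype=object)
        rs_counter += n
        return out

    # eligible stratum: every covered gene first, surplus over covered+filler
    n_el = composition.n_eligible
    surplus = n_el - len(covered)
    genes_parts.append(
        np.concatenate(
            [
                np.array(covered, dtype=object),
                _spread_genes(rng, covered + filler, surplus),
            ]
        )
        if covered
        else _spread_genes(rng, filler, n_el)
    )
    maf_parts.append(np.round(rng.uniform(0.0011, 0.5, n_el), 6))
    miss_parts.append(np.round(rng.uniform(0.0, 0.049, n_el), 6))
    rsid_parts.append(_rsids(n_el))

    # null-rsid stratum: otherwise eligible-looking
    n_nr = composition.n_null_rsid
    genes_parts.append(_spread_genes(rng, filler, n_nr))
    maf_parts.append(np.round(rng.uniform(0.0011, 0.5, n_nr), 6))
    miss_parts.append(np.round(rng.uniform(0.0, 0.049, n_nr), 6))
    rsid_parts.append(np.full(n_nr, "NULL", dtype=object))

    # high-missingness stratum; uncovered genes planted here (5 rows each)
    n_hm = composition.n_high_missingness
    planted_hm = np.repeat(np.array(uncovered, dtype=object), 5) if uncovered else np.empty(0, dtype=object)
    planted_hm = planted_hm[:n_hm]
    genes_parts.append(
        np.concatenate([planted_hm, _spread_genes(rng, filler, n_hm - len(planted_hm))])
    )
    maf_parts.append(np.round(rng.uniform(0.0011, 0.5, n_hm), 6))
    miss_parts.append(np.round(rng.uniform(0.051, 0.5, n_hm), 6))
    rsid_parts.append(_rsids(n_hm))

    # low-MAF stratum; remaining uncovered-gene rows planted here
    n_lm = composition.n_low_maf
    planted_lm = np.repeat(np.array(uncovered, dtype=object), 5) if uncovered else np.empty(0, dtype=object)
    planted_lm = planted_lm[: max(0, min(len(planted_lm), n_lm))]
    genes_parts.append(
        np.concatenate([planted_lm, _spread_genes(rng, filler, n_lm - len(planted_lm))])
    )
    maf_parts.append(np.round(rng.uniform(0.00001, 0.0009, n_lm), 6))
    miss_parts.append(np.round(rng.uniform(0.0, 0.049, n_lm), 6))
    rsid_parts.append(_rsids(n_lm))

    genes = np.concatenate(genes_parts)
    mafs = np.concatenate(maf_parts)
    miss = np.concatenate(miss_parts)
    rsids = np.concatenate(rsid_parts)

    n = composition.n_total
    maj_idx = rng.integers(0, 4, n)
    min_idx = (maj_idx + rng.integers(1, 4, n)) % 4
    bases = np.array(list("ACGT"), dtype=object)
    mutations = np.array(MUTATION_CLASSES, dtype=object)[
        rng.integers(0, len(MUTATION_CLASSES), n)
    ]

    perm = rng.permutation(n)
    frame = pd.DataFrame(
        {
            "exmID": [f"exm{i:06d}" for i in range(n)],
            "rsID": rsids[perm],
            "Gene": genes[perm],
            f"MAF_{composition.population}": mafs[perm],
            "Missingness": miss[perm],
            "Mutation": mutations[perm],
            "AlleleA": bases[maj_idx[perm]],
            "AlleleB": bases[min_idx[perm]],
        }
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
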