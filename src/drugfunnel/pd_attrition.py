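"""Staged pharmacodynamic attrition and target-action-pair consolidation.

The screen narrows a full drug catalog to repurposing candidates in four
stages, in fixed order:

1. **type** — keep small molecules (biologics are costly to source for
   trials and are excluded);
2. **status** — keep drugs carrying an approval label, unless a veto label
   (withdrawn, illicit) is also present;
3. **known-action count** — keep drugs with exactly one target of known
   mechanism of action (additional targets of *unknown* action do not
   disqualify a drug);
4. **exclusions** — drop drugs whose known-action target is nonhuman, drugs
   on a configured safety blocklist (e.g. DNA-damaging agents), and drugs
   with missing required fields.

Survivors are then consolidated into *target-action pairs*: drugs sharing
the same (target gene, pharmacological action) are grouped, shifting the
analysis from individual agents to drug classes. The per-stage record of
inputs, survivors, and exclusion reasons is the attrition funnel.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .drugbank_io import SMALL_MOLECULE, DrugCard

# exclusion reason codes
REASON_BIOTECH = "biotech"
REASON_STATUS = "status-not-approved"
REASON_KNOWN_ACTION_COUNT = "known-action-count"
REASON_NONHUMAN = "nonhuman-target"
REASON_BLOCKLIST = "blocklist"
REASON_MISSING_FIELD = "missing-field"

STAGE_TYPE = "type"
STAGE_STATUS = "status"
STAGE_KNOWN_ACTION = "known-action-count"
STAGE_EXCLUSIONS = "exclusions"


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested over an empty drug set."""


class ConsolidationContractError(ValueError):
    """A card reached consolidation without a usable (gene, action)."""


@dataclass
class AttritionConfig:
    """Configuration for the staged screen.

    All label sets are stored lowercase. ``excluded_drug_names`` is the
    manually curated safety blocklist (the screen has no automated
    toxicology scoring); empty by default.
    """

    status_allowlist: frozenset[str] = frozenset({"approved"})
    status_veto: frozenset[str] = frozenset({"withdrawn", "illicit"})
    human_organism_labels: frozenset[str] = frozenset({"humans", "human"})
    excluded_drug_names: frozenset[str] = frozenset()
    required_fields: frozenset[str] = frozenset({"name", "action", "gene_symbol", "status"})

    def __post_init__(self) -> None:
        if not self.status_allowlist:
            raise ValueError("status_allowlist must be nonempty")
        self.status_allowlist = frozenset(s.lower() for s in self.status_allowlist)
        self.status_veto = frozenset(s.lower() for s in self.status_veto)
        self.human_organism_labels = frozenset(
            s.lower() for s in self.human_organism_labels
        )
        self.excluded_drug_names = frozenset(
            s.strip().lower() for s in self.excluded_drug_names
        )


@dataclass
class StageRecord:
    """One funnel stage: counts in/out plus per-drug exclusion reasons."""

    stage_name: str
    n_in: int
    n_out: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_out + len(self.exclusions) != self.n_in:
            raise ValueError(
                f"stage {self.stage_name}: n_out ({self.n_out}) + exclusions "
                f"({len(self.exclusions)}) != n_in ({self.n_in})"
            )


@dataclass
class FunnelReport:
    """Ordered stage records; consecutive stages must telescope."""

    stages: list[StageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.n_in != prev.n_out:
                raise ValueError(
                    f"stage {cur.stage_name}: n_in ({cur.n_in}) != previous "
                    f"n_out ({prev.n_out})"
                )

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.stage_name == name:
                return s
        raise KeyError(name)

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s.stage_name, "n_in": s.n_in, "n_out": s.n_out}
            for s in self.stages
        ]

    def exclusion_rows(self) -> list[dict]:
        return [
            {"drug_id": drug_id, "stage": s.stage_name, "reason": reason}
            for s in self.stages
            for drug_id, reason in s.exclusions
        ]


def normalize_gene(symbol: str) -> str:
    """HGNC-style gene symbol normalization: uppercase, trimmed."""
    return symbol.strip().upper()


def normalize_action(action: str) -> str:
    """Action normalization: lowercase, trimmed. Synonyms are NOT merged."""
    return action.strip().lower()


@dataclass
class TargetActionPair:
    """A (gene symbol, action) class with its member drugs."""

    gene_symbol: str
    action: str
    member_drug_ids: frozenset[str]
    target_names: frozenset[str] = frozenset()
    member_drug_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.member_drug_ids:
            raise ValueError("member_drug_ids must be nonempty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_symbol, self.action)


def filter_small_molecules(
    cards: Sequence[DrugCard],
) -> tuple[list[DrugCard], StageRecord]:
    """Stage 1: retain small molecules, exclude biologics."""
    retained = [c for c in cards if c.drug_type == SMALL_MOLECULE]
    exclusions = [
        (c.drug_id, REASON_BIOTECH) for c in cards if c.drug_type != SMALL_MOLECULE
    ]
    return retained, StageRecord(STAGE_TYPE, len(cards), len(retained), exclusions)


def filter_approved(
    cards: Sequence[DrugCard], config: AttritionConfig
) -> tuple[list[DrugCard], StageRecord]:
    """Stage 2: retain drugs with an approval label and no veto label."""
    retained, exclusions = [], []
    for c in cards:
        ok = bool(c.status_labels & config.status_allowlist) and not (
            c.status_labels & config.status_veto
        )
        if ok:
            retained.append(c)
        else:
            exclusions.append((c.drug_id, REASON_STATUS))
    return retained, StageRecord(STAGE_STATUS, len(cards), len(retained), exclusions)


def filter_single_known_action(
    cards: Sequence[DrugCard],
) -> tuple[list[DrugCard], StageRecord]:
    """Stage 3: retain drugs with exactly one known-action target.

    Drugs with additional targets of unknown action are retained; the
    selectivity requirement is on the *known mechanism* count only.
    """
    retained, exclusions = [], []
    for c in cards:
        if c.number_of_known_action_targets == 1:
            retained.append(c)
        else:
            exclusions.append((c.drug_id, REASON_KNOWN_ACTION_COUNT))
    return retained, StageRecord(
        STAGE_KNOWN_ACTION, len(cards), len(retained), exclusions
    )


def _missing_required(card: DrugCard, config: AttritionConfig) -> bool:
    target = card.known_action_target
    checks = {
        "name": bool(card.name),
        "status": bool(card.status_labels),
        "action": bool(target and target.action),
        "gene_symbol": bool(target and target.gene_symbol),
    }
    return any(not checks.get(f, True) for f in config.required_fields)


def apply_exclusions(
    cards: Sequence[DrugCard], config: AttritionConfig
) -> tuple[list[DrugCard], StageRecord]:
    """Stage 4: nonhuman targets, safety blocklist, missing required fields.

    Each card must already carry exactly one known-action target. A card
    matching several rules is excluded once, under the first matching
    reason in the order: nonhuman-target, blocklist, missing-field.
    """
    retained, exclusions = [], []
    for c in cards:
        target = c.known_action_target
        organism = (target.organism or "").strip().lower() if target else ""
        if organism not in config.human_organism_labels:
            exclusions.append((c.drug_id, REASON_NONHUMAN))
        elif c.name.strip().lower() in config.excluded_drug_names:
            exclusions.append((c.drug_id, REASON_BLOCKLIST))
        elif _missing_required(c, config):
            exclusions.append((c.drug_id, REASON_MISSING_FIELD))
        else:
            retained.append(c)
    return retained, StageRecord(
        STAGE_EXCLUSIONS, len(cards), len(retained), exclusions
    )


def consolidate_pairs(cards: Sequence[DrugCard]) -> list[TargetActionPair]:
    """Group drugs into target-action pairs keyed on (gene, action).

    The grouping is a partition: every input drug appears in exactly one
    pair. Output is sorted by gene symbol then action.
    """
    groups: dict[tuple[str, str], dict] = {}
    for c in cards:
        target = c.known_action_target
        if target is None or not target.gene_symbol or not target.action:
            raise ConsolidationContractError(
                f"drug {c.drug_id!r} lacks a consolidatable (gene, action); "
                "it should have been excluded upstream"
            )
        key = (normalize_gene(target.gene_symbol), normalize_action(target.action))
        g = groups.setdefault(
            key, {"ids": set(), "target_names": set(), "names": []}
        )
        g["ids"].add(c.drug_id)
        g["target_names"].add(target.target_name)
        g["names"].append(c.name)
    return [
        TargetActionPair(
            gene_symbol=gene,
            action=action,
            member_drug_ids=frozenset(g["ids"]),
            target_names=frozenset(g["target_names"]),
            member_drug_names=tuple(sorted(g["names"])),
        )
        for (gene, action), g in sorted(groups.items())
    ]


def one_target_total_rate(cards: Sequence[DrugCard]) -> float:
    """Percent of drugs whose *total* target count is exactly one.

    Computed over the post-exclusion drug set and rounded half-up to two
    decimals; distinguishes truly single-target agents from drugs that are
    selective only in their known mechanisms.
    """
    if not cards:
        raise UndefinedRateError("one-target-total rate undefined on empty input")
    n_single = sum(1 for c in cards if c.number_of_targets == 1)
    rate = (
        decimal.Decimal(100 * n_single) / decimal.Decimal(len(cards))
    ).quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP)
    return float(rate)


def apply_stages(
    cards: Sequence[DrugCard], config: Optional[AttritionConfig] = None
) -> tuple[list[DrugCard], list[StageRecord]]:
    """Run the four filter stages in order; return survivors and records."""
    config = config or AttritionConfig()
    stages: list[StageRecord] = []
    current = list(cards)
    for fn in (
        filter_small_molecules,
        lambda cc: filter_approved(cc, config),
        filter_single_known_action,
        lambda cc: apply_exclusions(cc, config),
    ):
        current, record = fn(current)
        stages.append(record)
    return current, stages


def run_funnel(
    cards: Sequence[DrugCard], config: Optional[AttritionConfig] = None
) -> tuple[list[TargetActionPair], FunnelReport]:
    """Full attrition: four stages then consolidation into pairs."""
    survivors, stages = apply_stages(cards, config)
    pairs = consolidate_pairs(survivors) if survivors else []
    return pairs, FunnelReport(stages=stages)
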