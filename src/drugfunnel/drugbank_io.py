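"""Reading and writing DrugBank-style drug catalogs.

A drug catalog is an XML document with one ``<drug>`` element per agent,
carrying the fields a repurposing screen needs: name, type (small molecule
vs. biotech), regulatory status labels, marketed products with start dates,
and the drug's targets with their pharmacological actions and gene symbols.
This module parses that dialect into :class:`DrugCard` records, extracts
marketing details (earliest marketing date per country), and writes tabular
exports.

The parser is tolerant by design: unknown elements are ignored so that
richer real-world exports remain parseable, and record-level problems
(a ``<drug>`` missing its name or type) are collected as rejects rather
than aborting the whole parse.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

SMALL_MOLECULE = "small-molecule"
BIOTECH = "biotech"

#: delimiter used to serialize list-valued fields in tabular exports
LIST_DELIMITER = "|"


class CatalogParseError(ValueError):
    """Raised when the catalog XML is malformed beyond record level."""


@dataclass
class RejectedRecord:
    """A record that failed parsing, with its position and the reason."""

    index: int
    reason: str


def _clean(text: Optional[str]) -> Optional[str]:
    """Normalize raw XML text: trim, and map empty / literal NULL to absent."""
    if text is None:
        return None
    text = text.strip()
    if not text or text.upper() == "NULL":
        return None
    return text


@dataclass
class ProductRecord:
    """One marketed product: the country and when marketing started."""

    country: str
    marketing_start_date: Optional[datetime.date] = None


@dataclass
class TargetRecord:
    """One drug target, with its pharmacological action when known.

    ``known_action`` is true only when the catalog asserts the drug's
    pharmacological action at this target (``<known-action>yes``); in that
    case ``action`` must be present.
    """

    target_name: str
    action: Optional[str] = None
    known_action: bool = False
    gene_symbol: Optional[str] = None
    organism: Optional[str] = None
    enzymes: list[str] = field(default_factory=list)
    transporters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.known_action and not self.action:
            raise ValueError(
                f"target {self.target_name!r}: known_action requires a non-empty action"
            )
        if len(self.enzymes) != len(set(self.enzymes)):
            raise ValueError("duplicate enzyme entries")
        if len(self.transporters) != len(set(self.transporters)):
            raise ValueError("duplicate transporter entries")


@dataclass
class DrugCard:
    """One drug's parsed record.

    The two target counts are derived from ``targets`` at construction and
    always satisfy ``number_of_known_action_targets <= number_of_targets``.
    """

    drug_id: str
    name: str
    drug_type: str
    status_labels: frozenset[str] = frozenset()
    countries_approved: frozenset[str] = frozenset()
    products: list[ProductRecord] = field(default_factory=list)
    targets: list[TargetRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.drug_type not in (SMALL_MOLECULE, BIOTECH):
            raise ValueError(f"invalid drug_type {self.drug_type!r}")
        self.status_labels = frozenset(s.lower() for s in self.status_labels)
        self.countries_approved = frozenset(self.countries_approved)

    @property
    def number_of_targets(self) -> int:
        return len(self.targets)

    @property
    def number_of_known_action_targets(self) -> int:
        return sum(1 for t in self.targets if t.known_action)

    @property
    def known_action_target(self) -> Optional[TargetRecord]:
        """The unique known-action target, when exactly one exists."""
        known = [t for t in self.targets if t.known_action]
        return known[0] if len(known) == 1 else None


def _parse_date(text: Optional[str]) -> Optional[datetime.date]:
    text = _clean(text)
    if text is None:
        return None
    try:
        return datetime.date.fromisoformat(text)
    except ValueError:
        logger.warning("unparseable marketing date %r treated as absent", text)
        return None


def _parse_target(el: etree._Element) -> TargetRecord:
    name = _clean(el.findtext("name"))
    known_raw = (_clean(el.findtext("known-action")) or "unknown").lower()
    actions = [
        a for a in (_clean(x.text) for x in el.findall("actions/action")) if a
    ]
    gene = _clean(el.findtext("polypeptide/gene-name"))
    organism = _clean(el.findtext("organism"))
    enzymes = [e for e in (_clean(x.text) for x in el.findall("enzymes/enzyme")) if e]
    transporters = [
        t for t in (_clean(x.text) for x in el.findall("transporters/transporter")) if t
    ]
    return TargetRecord(
        target_name=name or "",
        action=actions[0] if actions else None,
        known_action=known_raw == "yes" and bool(actions),
        gene_symbol=gene,
        organism=organism,
        enzymes=list(dict.fromkeys(enzymes)),
        transporters=list(dict.fromkeys(transporters)),
    )


def _parse_drug(el: etree._Element, index: int) -> DrugCard:
    name = _clean(el.findtext("name"))
    if name is None:
        raise ValueError("missing <name>")
    raw_type = _clean(el.get("type"))
    if raw_type is None:
        raise ValueError("missing type attribute")
    norm_type = raw_type.lower().replace(" ", "-")
    if norm_type not in (SMALL_MOLECULE, BIOTECH):
        raise ValueError(f"unrecognized drug type {raw_type!r}")

    drug_id = _clean(el.findtext("drugbank-id")) or f"drug-{index:05d}"

    labels: set[str] = set()
    for g in el.findall("groups/group"):
        text = _clean(g.text)
        if text:
            # status may be multi-valued within one element ("approved, investigational")
            labels.update(part.strip().lower() for part in text.split(",") if part.strip())

    products: list[ProductRecord] = []
    countries: set[str] = set()
    for p in el.findall("products/product"):
        country = _clean(p.findtext("country"))
        if country is None:
            continue
        countries.add(country)
        products.append(
            ProductRecord(
                country=country,
                marketing_start_date=_parse_date(p.findtext("started-marketing-on")),
            )
        )

    targets = [_parse_target(t) for t in el.findall("targets/target")]

    return DrugCard(
        drug_id=drug_id,
        name=name,
        drug_type=norm_type,
        status_labels=frozenset(labels),
        countries_approved=frozenset(countries),
        products=products,
        targets=targets,
    )


def parse_drugbank_xml(
    source: Union[str, Path, IO[bytes]],
    rejects: Optional[list[RejectedRecord]] = None,
) -> list[DrugCard]:
    """Parse a drug catalog XML document into :class:`DrugCard` records.

    Parameters
    ----------
    source
        Path to the XML file, or a binary file-like object.
    rejects
        Optional list; ``<drug>`` elements that fail record-level parsing
        (missing name or type) are appended here as :class:`RejectedRecord`
        and parsing continues. Without a list, rejects are only logged.

    Returns
    -------
    One card per well-formed ``<drug>`` element, in document order. Target
    counts are derived from the child elements, never trusted from
    attributes. Missing optional elements become absent (``None``) fields.

    Raises
    ------
    CatalogParseError
        If the document itself is not well-formed XML.
    """
    if isinstance(source, (str, Path)):
        source = str(source)
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise CatalogParseError(f"malformed catalog XML: {exc}") from exc

    cards: list[DrugCard] = []
    for i, el in enumerate(tree.getroot().iterfind("drug")):
        try:
            cards.append(_parse_drug(el, i))
        except ValueError as exc:
            logger.warning("rejecting drug record %d: %s", i, exc)
            if rejects is not None:
                rejects.append(RejectedRecord(index=i, reason=str(exc)))
    return cards


def extract_marketing_details(
    cards: Iterable[DrugCard], names: Iterable[str]
) -> pd.DataFrame:
    """Earliest marketing start date and country for each requested drug.

    Name matching is case-insensitive after whitespace trimming. The result
    has one row per (matched drug, country with >=1 dated product); drugs
    with no products (or no dated products) and unmatched names yield a
    single row with absent country and date, with a logged warning for the
    unmatched case.

    Columns: ``name``, ``country``, ``earliest_marketing_date``.
    """
    names = list(names)
    if not names:
        raise ValueError("names must be nonempty")
    by_name = {c.name.strip().lower(): c for c in cards}

    rows: list[dict] = []
    for requested in names:
        card = by_name.get(requested.strip().lower())
        if card is None:
            logger.warning("marketing extraction: no catalog match for %r", requested)
            rows.append(
                {"name": requested, "country": None, "earliest_marketing_date": None}
            )
            continue
        dated: dict[str, datetime.date] = {}
        for product in card.products:
            if product.marketing_start_date is None:
                continue
            prev = dated.get(product.country)
            if prev is None or product.marketing_start_date < prev:
                dated[product.country] = product.marketing_start_date
        if not dated:
            rows.append(
                {"name": card.name, "country": None, "earliest_marketing_date": None}
            )
        else:
            for country in sorted(dated):
                rows.append(
                    {
                        "name": card.name,
                        "country": country,
                        "earliest_marketing_date": dated[country],
                    }
                )
    return pd.DataFrame(rows, columns=["name", "country", "earliest_marketing_date"])


#: column order for tabular exports, following the catalog field order
CARD_TABLE_COLUMNS = [
    "drug_id",
    "name",
    "type",
    "status",
    "countries_approved",
    "number_of_targets",
    "number_of_targets_with_known_action",
    "target_names",
    "actions",
    "gene_names",
    "organisms",
    "enzymes",
    "transporters",
]


def write_cards_table(cards: Iterable[DrugCard], destination: Union[str, Path]) -> None:
    """Write cards as a UTF-8 TSV with a header row.

    List-valued fields are joined with :data:`LIST_DELIMITER`; absent values
    are written as empty cells. Scalar fields round-trip losslessly.
    """
    rows = []
    for c in cards:
        rows.append(
            {
                "drug_id": c.drug_id,
                "name": c.name,
                "type": c.drug_type,
                "status": LIST_DELIMITER.join(sorted(c.status_labels)),
                "countries_approved": LIST_DELIMITER.join(sorted(c.countries_approved)),
                "number_of_targets": c.number_of_targets,
                "number_of_targets_with_known_action": c.number_of_known_action_targets,
                "target_names": LIST_DELIMITER.join(t.target_name for t in c.targets),
                "actions": LIST_DELIMITER.join(t.action or "" for t in c.targets),
                "gene_names": LIST_DELIMITER.join(t.gene_symbol or "" for t in c.targets),
                "organisms": LIST_DELIMITER.join(t.organism or "" for t in c.targets),
                "enzymes": LIST_DELIMITER.join(
                    e for t in c.targets for e in t.enzymes
                ),
                "transporters": LIST_DELIMITER.join(
                    tr for t in c.targets for tr in t.transporters
                ),
            }
        )
    frame = pd.DataFrame(rows, columns=CARD_TABLE_COLUMNS)
    frame.to_csv(destination, sep="\t", index=False, encoding="utf-8")
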