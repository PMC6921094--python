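import random

import pytest

from drugfunnel import (
    CatalogComposition,
    VariantComposition,
    attrition_config_for,
    generate_drug_catalog,
    generate_variant_table,
)
from drugfunnel.cli import run_pipeline
from drugfunnel.drugbank_io import DrugCard, ProductRecord, TargetRecord


def make_card(
    drug_id="D1",
    name="drugone",
    drug_type="small-molecule",
    status=("approved",),
    targets=(),
    products=(),
):
    return DrugCard(
        drug_id=drug_id,
        name=name,
        drug_type=drug_type,
        status_labels=frozenset(status),
        products=list(products),
        targets=list(targets),
    )


def make_target(gene="ABC1", action="inhibitor", known=True, organism="Humans", name=None):
    return TargetRecord(
        target_name=name or f"{gene} protein",
        action=action,
        known_action=known,
        gene_symbol=gene,
        organism=organism,
    )


def random_cards(rng: random.Random, n: int) -> list[DrugCard]:
    """Cards with randomized type/status/target structure for oracle tests."""
    cards = []
    for i in range(n):
        n_targets = rng.randint(0, 3)
        targets = []
        for j in range(n_targets):
            known = rng.random() < 0.5
            targets.append(
                TargetRecord(
                    target_name=f"T{i}-{j}",
                    action=rng.choice(["inhibitor", "agonist", None])
                    if not known
                    else rng.choice(["inhibitor", "agonist"]),
                    known_action=known,
                    gene_symbol=rng.choice([f"G{rng.randint(1, 6)}", None]),
                    organism=rng.choice(["Humans", "Escherichia coli", None]),
                )
            )
        cards.append(
            DrugCard(
                drug_id=f"R{i:03d}",
                name=f"random-{i}",
                drug_type=rng.choice(["small-molecule", "biotech"]),
                status_labels=frozenset(
                    rng.sample(
                        ["approved", "investigational", "withdrawn", "illicit"],
                        rng.randint(1, 2),
                    )
                ),
                targets=targets,
            )
        )
    return cards


@pytest.fixture
def tiny_catalog_composition():
    return CatalogComposition(
        n_biotech=3,
        n_not_approved=4,
        n_wrong_known_action_count=3,
        n_excluded_nonhuman=2,
        n_excluded_blocklist=1,
        n_excluded_missing_field=1,
        n_final=12,
        n_final_single_total_target=9,
        n_two_action_genes=2,
        n_one_action_genes=3,
        n_uncovered_pairs=2,
    )


@pytest.fixture
def tiny_variant_composition(tiny_catalog_composition):
    return VariantComposition.for_catalog(
        tiny_catalog_composition,
        n_eligible=30,
        n_null_rsid=5,
        n_high_missingness=25,
        n_low_maf=25,
    )


@pytest.fixture(scope="session")
def calibrated_run(tmp_path_factory):
    """Full pipeline run on the default calibrated fixtures (shared)."""
    d = tmp_path_factory.mktemp("calibrated")
    catalog_comp = CatalogComposition()
    variant_comp = VariantComposition.for_catalog(catalog_comp)
    generate_drug_catalog(catalog_comp, seed=7, path=d / "catalog.xml")
    generate_variant_table(variant_comp, seed=7, path=d / "variants.tsv")
    result = run_pipeline(
        d / "catalog.xml",
        d / "variants.tsv",
        out_dir=d / "out",
        attrition=attrition_config_for(catalog_comp),
    )
    return result
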