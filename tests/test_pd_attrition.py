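import random

import pytest

from drugfunnel.pd_attrition import (
    AttritionConfig,
    ConsolidationContractError,
    FunnelReport,
    StageRecord,
    UndefinedRateError,
    apply_exclusions,
    apply_stages,
    consolidate_pairs,
    filter_approved,
    filter_single_known_action,
    filter_small_molecules,
    one_target_total_rate,
    run_funnel,
)
from tests.conftest import make_card, make_target, random_cards


class TestTypeFilter:
    def test_all_biotech_excluded(self):
        cards = [make_card(drug_id=f"B{i}", drug_type="biotech") for i in range(5)]
        retained, record = filter_small_molecules(cards)
        assert retained == []
        assert record.n_in == 5 and record.n_out == 0
        assert len(record.exclusions) == 5

    def test_empty_input(self):
        retained, record = filter_small_molecules([])
        assert retained == [] and record.n_in == record.n_out == 0

    def test_order_preserved_and_input_untouched(self):
        cards = [
            make_card(drug_id="a"),
            make_card(drug_id="b", drug_type="biotech"),
            make_card(drug_id="c"),
        ]
        retained, _ = filter_small_molecules(cards)
        assert [c.drug_id for c in retained] == ["a", "c"]
        assert len(cards) == 3


class TestStatusFilter:
    config = AttritionConfig()

    def test_veto_dominates(self):
        card = make_card(status=("approved", "withdrawn"))
        retained, _ = filter_approved([card], self.config)
        assert retained == []

    def test_investigational_only_excluded(self):
        card = make_card(status=("investigational",))
        retained, _ = filter_approved([card], self.config)
        assert retained == []

    def test_vet_approved_not_in_allowlist(self):
        card = make_card(status=("vet-approved",))
        retained, _ = filter_approved([card], self.config)
        assert retained == []

    def test_approved_retained(self):
        card = make_card(status=("approved", "investigational"))
        retained, _ = filter_approved([card], self.config)
        assert retained == [card]

    def test_empty_allowlist_invalid(self):
        with pytest.raises(ValueError):
            AttritionConfig(status_allowlist=frozenset())


class TestKnownActionFilter:
    def test_one_known_plus_unknown_targets_retained(self):
        card = make_card(
            targets=[
                make_target(known=True),
                make_target(gene="X2", known=False, action=None),
                make_target(gene="X3", known=False, action=None),
            ]
        )
        retained, _ = filter_single_known_action([card])
        assert retained == [card]

    def test_two_known_action_targets_excluded(self):
        card = make_card(
            targets=[make_target(known=True), make_target(gene="Z", known=True)]
        )
        retained, record = filter_single_known_action([card])
        assert retained == [] and record.exclusions[0][1] == "known-action-count"


class TestExclusions:
    def test_nonhuman_target_excluded(self):
        card = make_card(targets=[make_target(organism="Staphylococcus aureus")])
        retained, record = apply_exclusions([card], AttritionConfig())
        assert retained == []
        assert record.exclusions[0][1] == "nonhuman-target"

    def test_blocklisted_name_excluded(self):
        config = AttritionConfig(excluded_drug_names=frozenset({"Badactor"}))
        card = make_card(name="badactor", targets=[make_target()])
        retained, record = apply_exclusions([card], config)
        assert record.exclusions[0][1] == "blocklist"

    def test_absent_gene_symbol_excluded_as_missing_field(self):
        card = make_card(targets=[make_target(gene=None)])
        retained, record = apply_exclusions([card], AttritionConfig())
        assert record.exclusions[0][1] == "missing-field"

    def test_clean_card_retained(self):
        card = make_card(targets=[make_target()])
        retained, _ = apply_exclusions([card], AttritionConfig())
        assert retained == [card]

    def test_first_matching_reason_wins(self):
        # nonhuman AND missing gene: reported under nonhuman-target
        card = make_card(targets=[make_target(gene=None, organism="Hepatitis C virus")])
        _, record = apply_exclusions([card], AttritionConfig())
        assert record.exclusions[0][1] == "nonhuman-target"


class TestConsolidation:
    def test_same_gene_action_drugs_grouped(self):
        cards = [
            make_card(drug_id="d1", name="ace-one", targets=[make_target(gene="ACE")]),
            make_card(drug_id="d2", name="ace-two", targets=[make_target(gene="ace ")]),
        ]
        pairs = consolidate_pairs(cards)
        assert len(pairs) == 1
        assert pairs[0].gene_symbol == "ACE"
        assert pairs[0].member_drug_ids == {"d1", "d2"}

    def test_partition_property(self):
        rng = random.Random(3)
        cards = [
            make_card(
                drug_id=f"p{i}",
                name=f"pn{i}",
                targets=[
                    make_target(
                        gene=f"G{rng.randint(1, 4)}",
                        action=rng.choice(["inhibitor", "agonist"]),
                    )
                ],
            )
            for i in range(25)
        ]
        pairs = consolidate_pairs(cards)
        all_ids = [i for p in pairs for i in p.member_drug_ids]
        assert sorted(all_ids) == sorted(c.drug_id for c in cards)  # partition
        assert sum(len(p.member_drug_ids) for p in pairs) == len(cards)

    def test_sorted_by_gene_then_action(self):
        cards = [
            make_card(drug_id="1", targets=[make_target(gene="B", action="agonist")]),
            make_card(drug_id="2", targets=[make_target(gene="A", action="inhibitor")]),
            make_card(drug_id="3", targets=[make_target(gene="A", action="agonist")]),
        ]
        keys = [p.key for p in consolidate_pairs(cards)]
        assert keys == sorted(keys)

    def test_missing_gene_is_contract_violation(self):
        with pytest.raises(ConsolidationContractError):
            consolidate_pairs([make_card(targets=[make_target(gene=None)])])

    def test_action_synonyms_not_merged(self):
        cards = [
            make_card(drug_id="1", targets=[make_target(action="inhibitor")]),
            make_card(drug_id="2", targets=[make_target(action="antagonist")]),
        ]
        assert len(consolidate_pairs(cards)) == 2


class TestOneTargetTotalRate:
    def test_worked_example_fraction(self):
        cards = [
            make_card(drug_id=f"s{i}", targets=[make_target()]) for i in range(518)
        ] + [
            make_card(
                drug_id=f"m{i}",
                targets=[make_target(), make_target(gene="E", known=False, action=None)],
            )
            for i in range(103)
        ]
        assert one_target_total_rate(cards) == 83.41

    def test_all_single_target(self):
        cards = [make_card(drug_id=f"x{i}", targets=[make_target()]) for i in range(7)]
        assert one_target_total_rate(cards) == 100.00

    def test_matches_brute_force_recount(self):
        rng = random.Random(11)
        cards = []
        for i in range(40):
            n = rng.randint(1, 4)
            targets = [make_target()] + [
                make_target(gene=f"E{j}", known=False, action=None)
                for j in range(n - 1)
            ]
            cards.append(make_card(drug_id=f"b{i}", targets=targets))
        expected = round(
            100 * sum(1 for c in cards if len(c.targets) == 1) / len(cards), 2
        )
        assert one_target_total_rate(cards) == pytest.approx(expected, abs=0.005)

    def test_empty_input_undefined(self):
        with pytest.raises(UndefinedRateError):
            one_target_total_rate([])


class TestFunnel:
    def test_empty_catalog_all_zero(self):
        pairs, report = run_funnel([])
        assert pairs == []
        assert all(s.n_in == s.n_out == 0 for s in report.stages)

    def test_stage_accounting_invariants(self):
        rng = random.Random(5)
        cards = random_cards(rng, 30)
        _, report = run_funnel(cards)
        for s in report.stages:
            assert s.n_out + len(s.exclusions) == s.n_in
        for prev, cur in zip(report.stages, report.stages[1:]):
            assert cur.n_in == prev.n_out

    def test_funnel_equals_sequential_predicate_oracle(self):
        rng = random.Random(8)
        cards = random_cards(rng, 20)
        config = AttritionConfig()

        # independent per-record predicate oracle
        def p_type(c):
            return c.drug_type == "small-molecule"

        def p_status(c):
            return bool(c.status_labels & {"approved"}) and not (
                c.status_labels & {"withdrawn", "illicit"}
            )

        def p_known(c):
            return sum(1 for t in c.targets if t.known_action) == 1

        def p_excl(c):
            t = next(t for t in c.targets if t.known_action)
            return (
                (t.organism or "").lower() in {"humans", "human"}
                and c.name.lower() not in config.excluded_drug_names
                and bool(t.gene_symbol)
                and bool(t.action)
                and bool(c.name)
                and bool(c.status_labels)
            )

        expected = list(cards)
        expected_counts = []
        for pred in (p_type, p_status, p_known, p_excl):
            expected = [c for c in expected if pred(c)]
            expected_counts.append(len(expected))

        retained, stages = apply_stages(cards, config)
        assert [s.n_out for s in stages] == expected_counts
        assert [c.drug_id for c in retained] == [c.drug_id for c in expected]

    def test_type_and_status_filters_commute(self):
        rng = random.Random(13)
        cards = random_cards(rng, 40)
        config = AttritionConfig()
        a, _ = filter_small_molecules(cards)
        a, _ = filter_approved(a, config)
        b, _ = filter_approved(cards, config)
        b, _ = filter_small_molecules(b)
        assert [c.drug_id for c in a] == [c.drug_id for c in b]

    def test_stage_record_accounting_enforced(self):
        with pytest.raises(ValueError):
            StageRecord("bad", n_in=3, n_out=1, exclusions=[("x", "r")])

    def test_funnel_report_telescoping_enforced(self):
        s1 = StageRecord("a", 3, 2, [("x", "r")])
        s2 = StageRecord("b", 3, 3, [])  # n_in != previous n_out
        with pytest.raises(ValueError):
            FunnelReport(stages=[s1, s2])
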