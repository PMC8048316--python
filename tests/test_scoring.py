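"""Drug-category scoring formula, trigger evaluation and report assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxcns.genotypes import SampleGenotypes
from pgxcns.panel import AssociationRule, Trigger
from pgxcns.scoring import (
    TriggeredAssociation,
    build_report,
    score_drug,
    triggered_associations,
)


def _rule(drug, gene, category, level, el_score, rid):
    return AssociationRule(
        rule_id=rid,
        drug=drug,
        gene=gene,
        trigger=Trigger(kind="genotype", rsid="rs17782313", dosages=(1,)),
        evidence_level=level,
        el_score=el_score,
        category=category,
        advisory="Efficacy",
        fda_annotation="NoRecommendation",
    )


def _trig(rule):
    return TriggeredAssociation(rule=rule, evidence_value="x", gene=rule.gene)


def _ref_sample(panel, sid="ref", **overrides):
    calls = {rs: 0 for rs in panel.rsids}
    calls.update(overrides)
    return SampleGenotypes(sample_id=sid, calls=calls)


def test_empty_trigger_set_scores_low(panel):
    score = score_drug("quetiapine", [], panel)
    assert score.assigned_category == "L"
    assert all(s.total == 0 for s in score.per_category.values())
    assert not score.tie_broken


def test_hand_evaluated_argmax(panel):
    # H: EL 1A (5) + group A gene (3) = 8; M: EL 3 (1) + group C gene (1) = 2
    triggered = [
        _trig(_rule("quetiapine", "CYP2D6", "H", "1A", 5, "h1")),
        _trig(_rule("quetiapine", "GRIK1", "M", "3", 1, "m1")),
    ]
    score = score_drug("quetiapine", triggered, panel)
    assert score.per_category["H"].total == 8
    assert score.per_category["M"].total == 2
    assert score.assigned_category == "H"
    assert not score.tie_broken


def test_exact_tie_breaks_toward_higher_category(panel):
    # both categories total EL 2 + PG 1 = 3
    triggered = [
        _trig(_rule("quetiapine", "MC4R", "H", "2B", 2, "h1")),
        _trig(_rule("quetiapine", "GRIK1", "M", "2B", 2, "m1")),
    ]
    score = score_drug("quetiapine", triggered, panel)
    assert score.per_category["H"].total == score.per_category["M"].total == 3
    assert score.assigned_category == "H"
    assert score.tie_broken


def test_pg_counts_each_gene_once(panel):
    # two same-gene rules in one category: PG added once (set semantics)
    triggered = [
        _trig(_rule("quetiapine", "MC4R", "M", "3", 1, "a")),
        _trig(_rule("quetiapine", "MC4R", "M", "3", 1, "b")),
    ]
    score = score_drug("quetiapine", triggered, panel)
    assert score.per_category["M"].el_sum == 2
    assert score.per_category["M"].pg_sum == 1


def test_zero_weight_rule_is_neutral(panel):
    base = [
        _trig(_rule("quetiapine", "CYP2D6", "M", "2A", 3, "m1")),
        _trig(_rule("quetiapine", "GRIK1", "H", "3", 1, "h1")),
    ]
    before = score_drug("quetiapine", base, panel)
    for cat in ("L", "M", "H"):
        extra = base + [_trig(_rule("quetiapine", "CYP2C9", cat, "3", 0, f"z{cat}"))]
        after = score_drug("quetiapine", extra, panel)
        assert after.assigned_category == before.assigned_category


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    rules=st.lists(
        st.tuples(
            st.sampled_from(["CYP2D6", "MC4R", "FKBP5", "GRIK1", "CYP2C9"]),
            st.sampled_from(["L", "M", "H"]),
            st.integers(min_value=1, max_value=5),
        ),
        min_size=0,
        max_size=8,
    )
)
def test_argmax_matches_hand_formula_on_random_rule_sets(panel, rules):
    level_for = {5: "1A", 4: "1B", 3: "2A", 2: "2B", 1: "3"}
    triggered = [
        _trig(_rule("quetiapine", g, c, level_for[el], el, f"r{i}"))
        for i, (g, c, el) in enumerate(rules)
    ]
    score = score_drug("quetiapine", triggered, panel)
    # independent hand evaluation of the scoring formula
    totals = {}
    for cat in ("L", "M", "H"):
        cat_rules = [(g, el) for (g, c, el) in rules if c == cat]
        el_sum = sum(el for _, el in cat_rules)
        pg_sum = sum(panel.gene(g).pg_score for g in {g for g, _ in cat_rules})
        totals[cat] = el_sum + pg_sum
    if not rules:
        assert score.assigned_category == "L"
    else:
        best = max(totals.values())
        expect = [c for c in ("H", "M", "L") if totals[c] == best][0]
        assert score.assigned_category == expect
        assert score.tie_broken == (sum(t == best for t in totals.values()) > 1)
    for cat in ("L", "M", "H"):
        assert score.per_category[cat].total == totals.get(cat, 0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(boost=st.integers(min_value=1, max_value=10), el=st.integers(min_value=1, max_value=5))
def test_increasing_a_triggered_h_rule_never_demotes(panel, boost, el):
    others = [
        _trig(_rule("quetiapine", "CYP2D6", "M", "2A", 3, "m1")),
        _trig(_rule("quetiapine", "FKBP5", "L", "2B", 2, "l1")),
    ]
    h_rule = _rule("quetiapine", "MC4R", "H", "3", el, "h1")
    before = score_drug("quetiapine", others + [_trig(h_rule)], panel)
    boosted = _rule("quetiapine", "MC4R", "H", "3", el + boost, "h1")
    after = score_drug("quetiapine", others + [_trig(boosted)], panel)
    if before.assigned_category == "H":
        assert after.assigned_category == "H"


# ---------------------------------------------------------------------------
# trigger evaluation against the demo panel


def test_mc4r_carrier_triggers_quetiapine_weight_gain_rule(panel):
    sample = _ref_sample(panel, rs17782313=1)
    triggered, _ = triggered_associations(sample, panel)
    hits = [
        t
        for t in triggered
        if t.rule.drug == "quetiapine" and t.rule.trigger.rsid == "rs17782313"
    ]
    assert hits and hits[0].rule.advisory == "ADE (weight gain)"


def test_all_reference_sample_triggers_only_low_category_rules(panel):
    triggered, skipped = triggered_associations(_ref_sample(panel), panel)
    assert triggered
    assert not skipped
    assert {t.rule.category for t in triggered} == {"L"}


def test_case_c_fkbp5_lower_response_rule(panel, cases):
    triggered, _ = triggered_associations(cases.sample("case_c"), panel)
    fkbp5 = [t for t in triggered if t.rule.gene == "FKBP5"]
    assert {t.rule.drug for t in fkbp5} == {
        "fluoxetine",
        "paroxetine",
        "sertraline",
        "venlafaxine",
    }
    # wild-type GG homozygote: minimum-interaction (L) rules fire
    assert all(t.rule.trigger.dosages == (0,) for t in fkbp5)


def test_rule_triggers_at_most_once_per_sample_per_drug(panel, cases):
    for sample in cases:
        triggered, _ = triggered_associations(sample, panel)
        ids = [(t.rule.drug, t.rule.rule_id) for t in triggered]
        assert len(ids) == len(set(ids))


# ---------------------------------------------------------------------------
# report assembly


def test_case_a_report_flags_cyp2c19_poor_for_ssris(panel, cases):
    report = build_report(cases.sample("case_a"), panel)
    by_drug = {r.drug: r for r in report.drug_results}
    for drug in ("citalopram", "escitalopram", "sertraline", "amitriptyline"):
        r = by_drug[drug]
        assert r.assigned_category == "H"
        assert any(
            t.rule.gene == "CYP2C19" and t.rule.trigger.phenotype == "poor"
            for t in r.triggered
        )
        assert r.advice_keys  # M/H drugs carry advices


def test_all_reference_report_is_low_only_with_no_advices(panel):
    report = build_report(_ref_sample(panel), panel)
    assert len(report.drug_results) == 28
    assert {r.assigned_category for r in report.drug_results} == {"L"}
    assert all(not r.advice_keys for r in report.drug_results)


def test_every_drug_appears_exactly_once(panel, cases):
    for sample in cases:
        report = build_report(sample, panel)
        names = [r.drug for r in report.drug_results]
        assert sorted(names) == sorted(d.name for d in panel.drugs)


def test_report_serialization_is_deterministic(panel, cases):
    s = cases.sample("case_b")
    assert build_report(s, panel).to_json() == build_report(s, panel).to_json()
    assert build_report(s, panel).to_markdown(panel) == build_report(s, panel).to_markdown(panel)


def test_missing_call_makes_dependent_drug_indeterminate(panel):
    sample = _ref_sample(panel, rs2832407=None)
    report = build_report(sample, panel)
    by_drug = {r.drug: r for r in report.drug_results}
    assert by_drug["topiramate"].assigned_category == "indeterminate"
    assert by_drug["topiramate"].caveats
    assert by_drug["citalopram"].assigned_category == "L"


def test_unresolved_diplotype_makes_cyp_drugs_indeterminate(panel):
    sample = _ref_sample(panel, rs4244285=None)
    report = build_report(sample, panel)
    by_drug = {r.drug: r for r in report.drug_results}
    assert by_drug["citalopram"].assigned_category == "indeterminate"
    assert report.diplotypes["CYP2C19"].ambiguous
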