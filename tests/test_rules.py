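"""Rule algebra: enumeration, counting, condensation, matching, text form."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssir.library import LibrarySpec, SiteSpec, enumerate_full_library
from ssir.rules import (
    Rule,
    RuleSet,
    RuleTerm,
    TermKind,
    condense,
    condensed_size,
    count_rules,
    enumerate_rules,
    matches,
    parse_rule,
    rules_matching_code,
)


def random_spec(ms):
    return LibrarySpec(
        tuple(
            SiteSpec(f"s{i}", tuple(chr(65 + j) for j in range(m)))
            for i, m in enumerate(ms)
        )
    )


spec_sizes = st.lists(st.integers(min_value=1, max_value=6), min_size=2, max_size=5)


def test_toy_total_rule_count(toy_spec):
    assert count_rules(toy_spec, (1, 2, 3)) == 59
    assert sum(1 for _ in enumerate_rules(toy_spec, (1, 2, 3))) == 59


@pytest.mark.parametrize(
    "orders,negations,expected",
    [
        ((1,), False, 39),
        ((2,), False, 531),
        ((3,), False, 3029),
        ((4,), False, 6120),
        ((1,), True, 78),
        ((2,), True, 2124),
        ((3,), True, 24232),
        ((4,), True, 97920),
    ],
)
def test_four_site_library_rule_counts(fpr, orders, negations, expected):
    assert count_rules(fpr.spec, orders, negations) == expected


def test_enumerate_matches_count_on_four_site_library(fpr):
    # no binary sites, so raw and deduplicated counting coincide
    n = sum(1 for _ in enumerate_rules(fpr.spec, (2,), negations=True))
    assert n == 2124 == count_rules(fpr.spec, (2,), True, raw=False)


def test_binary_site_negations_suppressed(toy_spec):
    # site 1 is binary: forbidding one residue just requires the other
    rules = list(enumerate_rules(toy_spec, (1,), negations=True))
    site1 = [r for r in rules if r.terms[0].kind != TermKind.WILDCARD]
    assert all(t.kind == TermKind.REQUIRE for r in site1 for t in [r.terms[0]])
    assert len(rules) == count_rules(toy_spec, (1,), True, raw=False) == 16
    assert count_rules(toy_spec, (1,), True, raw=True) == 18
    raw = list(enumerate_rules(toy_spec, (1,), True, binary_negations=True))
    assert len(raw) == 18


def test_enumeration_deterministic_order(toy_spec):
    first = [str(r) for r in itertools.islice(enumerate_rules(toy_spec, (1,)), 3)]
    assert first == ["A . .", "B . .", ". A ."]


def test_empty_orders_rejected(toy_spec):
    with pytest.raises(ValueError):
        list(enumerate_rules(toy_spec, ()))
    with pytest.raises(ValueError):
        count_rules(toy_spec, (5,))


def test_singleton_sites_never_constrained():
    spec = random_spec([1, 3, 4])
    rules = list(enumerate_rules(spec, (1, 2), negations=True))
    assert all(r.terms[0].kind == TermKind.WILDCARD for r in rules)


@pytest.mark.parametrize(
    "text,expected",
    [(". A .", 8), (". |A .", 16), ("|A |B .", 8), ("A A A", 1)],
)
def test_condensed_sizes_on_toy(toy_spec, text, expected):
    assert condensed_size(parse_rule(text, toy_spec), toy_spec) == expected


def test_matches_semantics(toy_spec):
    xax = parse_rule(". A .", toy_spec)
    assert matches(xax, ("B", "A", "D"))
    assert not matches(xax, ("A", "B", "A"))
    neg = parse_rule("|A |B .", toy_spec)
    assert matches(neg, ("B", "C", "A"))
    assert not matches(neg, ("A", "C", "A"))
    # the condensed set of . A . is exactly the listed 8 analogues
    hits = {"".join(c) for c in enumerate_full_library(toy_spec) if matches(xax, c)}
    assert hits == {"AAA", "AAB", "AAC", "AAD", "BAA", "BAB", "BAC", "BAD"}


def test_condense_counts(toy_lib):
    rule = parse_rule(". A .", toy_lib.spec)
    c, d = condense(rule, toy_lib)
    assert 0 <= d <= c <= toy_lib.a
    brute_c = sum(matches(rule, code) for code in toy_lib.codes)
    brute_d = sum(
        matches(rule, code) and bool(f)
        for code, f in zip(toy_lib.codes, toy_lib.interest)
    )
    assert (c, d) == (brute_c, brute_d)


def test_order1_require_rules_partition_library(toy_lib):
    # per site, the require rules split the known sublibrary: sum of c = a
    spec = toy_lib.spec
    for site in range(spec.n):
        total = 0
        for res in spec.sites[site].residues:
            terms = [RuleTerm(TermKind.WILDCARD)] * spec.n
            terms[site] = RuleTerm(TermKind.REQUIRE, res)
            total += condense(Rule(tuple(terms)), toy_lib)[0]
        assert total == toy_lib.a


@settings(derandomize=True, max_examples=25)
@given(spec_sizes, st.booleans())
def test_count_equals_enumeration_on_random_specs(ms, negations):
    spec = random_spec(ms)
    orders = tuple(range(1, spec.n + 1))
    n_enum = sum(1 for _ in enumerate_rules(spec, orders, negations))
    assert n_enum == count_rules(spec, orders, negations, raw=False)


@settings(derandomize=True, max_examples=25)
@given(spec_sizes)
def test_fixed_sites_require_rules_partition_full_library(ms):
    spec = random_spec(ms)
    pool = spec.constrained_sites
    if not pool:
        return
    combo = pool[: min(2, len(pool))]
    total = 0
    for picked in itertools.product(*(spec.sites[i].residues for i in combo)):
        terms = [RuleTerm(TermKind.WILDCARD)] * spec.n
        for i, res in zip(combo, picked):
            terms[i] = RuleTerm(TermKind.REQUIRE, res)
        total += condensed_size(Rule(tuple(terms)), spec)
    assert total == spec.M


def test_condensed_size_equals_full_library_matches(toy_spec):
    full = list(enumerate_full_library(toy_spec))
    for rule in enumerate_rules(toy_spec, (1, 2, 3), negations=True):
        brute = sum(matches(rule, code) for code in full)
        assert brute == condensed_size(rule, toy_spec)


def test_rule_text_roundtrip(fpr):
    for text in [". G . |C", "|B G . .", ". |G |I .", "C . . |G"]:
        rule = parse_rule(text, fpr.spec)
        assert str(rule) == text
        assert parse_rule(str(rule), fpr.spec) == rule


def test_rule_validation_errors(toy_spec):
    with pytest.raises(KeyError):
        parse_rule(". Z .", toy_spec)
    with pytest.raises(ValueError):
        parse_rule(". . .", toy_spec)
    with pytest.raises(ValueError):
        parse_rule(". A", toy_spec)


def test_rules_matching_code_closed_form(fpr):
    # sum over site triples of prod m_i rules match any given code
    code = fpr.spec.parse_code("CBDD")
    n = sum(1 for _ in rules_matching_code(fpr.spec, code, (3,), negations=True))
    assert n == 3029


def test_rules_matching_code_trivial(toy_spec):
    got = [str(r) for r in rules_matching_code(toy_spec, ("A", "A", "A"), (1,))]
    assert got == ["A . .", ". A .", ". . A"]


@settings(derandomize=True, max_examples=15)
@given(spec_sizes, st.booleans(), st.integers(0, 10**6))
def test_rules_matching_code_equals_filtered_enumeration(ms, negations, pick):
    spec = random_spec(ms)
    full = list(enumerate_full_library(spec))
    code = full[pick % len(full)]
    orders = tuple(range(1, spec.n + 1))
    got = list(rules_matching_code(spec, code, orders, negations))
    expected = [r for r in enumerate_rules(spec, orders, negations) if matches(r, code)]
    assert got == expected


def test_ruleset_match_matrix_agrees_with_scalar_matches(toy_lib):
    rules = list(enumerate_rules(toy_lib.spec, (1, 2), negations=True))
    rs = RuleSet(rules, toy_lib.spec)
    mat = rs.match_matrix(toy_lib.encoded())
    brute = np.array(
        [[matches(r, code) for code in toy_lib.codes] for r in rules]
    )
    assert np.array_equal(mat, brute)
    assert np.array_equal(
        rs.condensed_sizes(),
        [condensed_size(r, toy_lib.spec) for r in rules],
    )
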