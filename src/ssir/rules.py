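"""Substitution rules: enumeration, counting, matching and condensation.

A rule of order ``k`` constrains ``k`` substitution sites, each with a single
positive term (require residue ``R``) or a negation term (forbid residue
``R``, written ``|R``), wildcards elsewhere.  A rule defines a sublibrary:
the analogues it *condenses*.  The text dialect joins per-site tokens with
spaces, ``.`` standing for the wildcard, e.g. ``. G . |C`` (require ``G`` at
site 2, forbid ``C`` at site 4).

Only juxtaposed single-residue terms are supported -- at most one term per
site, no unions -- which is the algebra the voting model is built on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Iterator, Sequence

import numpy as np

from .library import AnalogueCode, LabeledLibrary, LibrarySpec

__all__ = [
    "TermKind",
    "RuleTerm",
    "Rule",
    "parse_rule",
    "enumerate_rules",
    "count_rules",
    "condensed_size",
    "matches",
    "condense",
    "rules_matching_code",
    "RuleSet",
]


class TermKind(IntEnum):
    WILDCARD = 0
    REQUIRE = 1
    FORBID = 2


@dataclass(frozen=True)
class RuleTerm:
    """Per-site constraint: wildcard, require-residue or forbid-residue."""

    kind: TermKind
    residue: str | None = None

    def __post_init__(self) -> None:
        if self.kind is TermKind.WILDCARD:
            if self.residue is not None:
                raise ValueError("wildcard term carries no residue")
        elif self.residue is None:
            raise ValueError("require/forbid term needs a residue")

    def __str__(self) -> str:
        if self.kind is TermKind.WILDCARD:
            return "."
        prefix = "|" if self.kind is TermKind.FORBID else ""
        return f"{prefix}{self.residue}"


WILDCARD = RuleTerm(TermKind.WILDCARD)


@dataclass(frozen=True)
class Rule:
    """A conjunction of per-site terms, one per substitution site."""

    terms: tuple[RuleTerm, ...]

    @property
    def order(self) -> int:
        """Number of constrained (non-wildcard) sites."""
        return sum(t.kind is not TermKind.WILDCARD for t in self.terms)

    def __str__(self) -> str:
        return " ".join(str(t) for t in self.terms)

    def validate(self, spec: LibrarySpec) -> "Rule":
        if len(self.terms) != spec.n:
            raise ValueError(
                f"rule has {len(self.terms)} terms, library has {spec.n} sites"
            )
        if self.order < 1:
            raise ValueError("rule must constrain at least one site")
        for term, site in zip(self.terms, spec.sites):
            if term.kind is not TermKind.WILDCARD and term.residue not in site.residues:
                raise KeyError(
                    f"residue {term.residue!r} not in site {site.name!r} alphabet"
                )
        return self


def parse_rule(text: str, spec: LibrarySpec | None = None) -> Rule:
    """Parse the space-joined rule dialect (``. G . |C``)."""
    terms = []
    for tok in text.split():
        if tok == ".":
            terms.append(WILDCARD)
        elif tok.startswith("|"):
            terms.append(RuleTerm(TermKind.FORBID, tok[1:]))
        else:
            terms.append(RuleTerm(TermKind.REQUIRE, tok))
    rule = Rule(tuple(terms))
    return rule.validate(spec) if spec is not None else rule


def _site_terms(
    site_index: int, spec: LibrarySpec, negations: bool, binary_negations: bool
) -> list[RuleTerm]:
    """Admissible terms of one site, require before forbid, alphabet order."""
    site = spec.sites[site_index]
    out = [RuleTerm(TermKind.REQUIRE, r) for r in site.residues]
    if negations and (site.m > 2 or binary_negations):
        # forbidding one of two residues is just requiring the other, so
        # binary-site negations are redundant and suppressed by default
        out += [RuleTerm(TermKind.FORBID, r) for r in site.residues]
    return out


def _normalize_orders(orders: int | Iterable[int], spec: LibrarySpec) -> tuple[int, ...]:
    if isinstance(orders, int):
        orders = (orders,)
    orders = tuple(sorted(set(int(k) for k in orders)))
    if not orders:
        raise ValueError("orders set is empty")
    if any(k < 1 or k > spec.n for k in orders):
        raise ValueError(f"orders {orders} outside [1, n={spec.n}]")
    return orders


def enumerate_rules(
    spec: LibrarySpec,
    orders: int | Iterable[int],
    negations: bool = False,
    binary_negations: bool = False,
) -> Iterator[Rule]:
    """Yield every admissible rule of the requested orders exactly once.

    The order is deterministic: site combinations lexicographically, then the
    Cartesian product of per-site term lists (require terms in alphabet order
    before forbid terms).  Sites with a single residue are never constrained.
    """
    orders = _normalize_orders(orders, spec)
    pool = spec.constrained_sites
    for k in orders:
        for combo in itertools.combinations(pool, k):
            choices = [
                _site_terms(i, spec, negations, binary_negations) for i in combo
            ]
            for picked in itertools.product(*choices):
                terms = [WILDCARD] * spec.n
                for i, term in zip(combo, picked):
                    terms[i] = term
                yield Rule(tuple(terms))


def count_rules(
    spec: LibrarySpec,
    orders: int | Iterable[int],
    negations: bool = False,
    raw: bool = True,
) -> int:
    """Closed-form rule count over the requested orders.

    With ``raw=True`` (default) each constrained site contributes ``2*m_i``
    term choices when negations are on, reproducing the plain nested-product
    totals even where binary-site negations duplicate an existing rule.
    ``raw=False`` counts what :func:`enumerate_rules` emits by default
    (binary-site forbid terms suppressed).
    """
    orders = _normalize_orders(orders, spec)
    pool = spec.constrained_sites
    total = 0
    for k in orders:
        for combo in itertools.combinations(pool, k):
            prod = 1
            for i in combo:
                m = spec.sites[i].m
                if not negations:
                    prod *= m
                elif raw or m > 2:
                    prod *= 2 * m
                else:
                    prod *= m
            total += prod
    return total


def condensed_size(rule: Rule, spec: LibrarySpec) -> int:
    """Number of full-library analogues the rule condenses.

    Product over sites of ``m_i`` (wildcard), 1 (require) or ``m_i - 1``
    (forbid).
    """
    rule.validate(spec)
    size = 1
    for term, site in zip(rule.terms, spec.sites):
        if term.kind is TermKind.WILDCARD:
            size *= site.m
        elif term.kind is TermKind.FORBID:
            size *= site.m - 1
    return size


def matches(rule: Rule, code: AnalogueCode) -> bool:
    """True iff the code satisfies every term of the rule."""
    for term, tok in zip(rule.terms, code):
        if term.kind is TermKind.REQUIRE and tok != term.residue:
            return False
        if term.kind is TermKind.FORBID and tok == term.residue:
            return False
    return True


def condense(rule: Rule, lib: LabeledLibrary) -> tuple[int, int]:
    """Condensation counts ``(c, d)`` of a rule over the known sublibrary:
    ``c`` known analogues matched, ``d`` of them of interest."""
    hit = np.fromiter((matches(rule, code) for code in lib.codes), dtype=bool, count=lib.a)
    return int(hit.sum()), int((hit & lib.interest).sum())


def rules_matching_code(
    spec: LibrarySpec,
    code: AnalogueCode,
    orders: int | Iterable[int],
    negations: bool = False,
    binary_negations: bool = False,
) -> Iterator[Rule]:
    """Yield exactly the rules of :func:`enumerate_rules` matching *code*.

    Generated directly (a site contributes its require term and, when
    negations are on, the forbid terms of every other residue), preserving
    the global enumeration order within the matching subset.
    """
    code = spec.validate_code(code)
    orders = _normalize_orders(orders, spec)
    pool = spec.constrained_sites
    for k in orders:
        for combo in itertools.combinations(pool, k):
            choices = [
                [
                    t
                    for t in _site_terms(i, spec, negations, binary_negations)
                    if (t.kind is TermKind.REQUIRE) == (t.residue == code[i])
                ]
                for i in combo
            ]
            for picked in itertools.product(*choices):
                terms = [WILDCARD] * spec.n
                for i, term in zip(combo, picked):
                    terms[i] = term
                yield Rule(tuple(terms))


class RuleSet:
    """A list of rules compiled to arrays for vectorized matching.

    Attributes
    ----------
    kinds : ``(n_rules, n_sites)`` int8 array of :class:`TermKind` values.
    residx : parallel array of residue indices (-1 at wildcards).
    """

    def __init__(self, rules: Sequence[Rule], spec: LibrarySpec):
        self.spec = spec
        self.rules = list(rules)
        n = spec.n
        lut = [{r: j for j, r in enumerate(s.residues)} for s in spec.sites]
        self.kinds = np.zeros((len(self.rules), n), dtype=np.int8)
        self.residx = np.full((len(self.rules), n), -1, dtype=np.int16)
        for row, rule in enumerate(self.rules):
            for i, term in enumerate(rule.terms):
                self.kinds[row, i] = int(term.kind)
                if term.kind is not TermKind.WILDCARD:
                    self.residx[row, i] = lut[i][term.residue]

    def __len__(self) -> int:
        return len(self.rules)

    @classmethod
    def enumerate(
        cls,
        spec: LibrarySpec,
        orders: int | Iterable[int],
        negations: bool = False,
        binary_negations: bool = False,
    ) -> "RuleSet":
        return cls(
            list(enumerate_rules(spec, orders, negations, binary_negations)), spec
        )

    def condensed_sizes(self) -> np.ndarray:
        m = np.array(self.spec.m, dtype=np.int64)
        size = np.where(
            self.kinds == TermKind.WILDCARD,
            m[None, :],
            np.where(self.kinds == TermKind.FORBID, m[None, :] - 1, 1),
        )
        return size.prod(axis=1)

    def match_matrix(self, codes_idx: np.ndarray) -> np.ndarray:
        """Boolean ``(n_rules, n_codes)`` matrix of rule-code matches."""
        codes_idx = np.asarray(codes_idx, dtype=np.int16)
        out = np.ones((len(self.rules), codes_idx.shape[0]), dtype=bool)
        for i in range(self.spec.n):
            k = self.kinds[:, i][:, None]
            r = self.residx[:, i][:, None]
            t = codes_idx[None, :, i]
            out &= (k == TermKind.WILDCARD) | (
                (k == TermKind.REQUIRE) & (r == t)
            ) | ((k == TermKind.FORBID) & (r != t))
        return out
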