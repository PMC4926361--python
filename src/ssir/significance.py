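"""Hypergeometric rule significance and vote assignment.

A rule condensing ``c`` of the ``a`` known analogues, ``d`` of them among the
``b`` of interest, is scored by the hypergeometric point probability

    P(d, c; b, a) = C(b, d) C(a-b, c-d) / C(a, c)

and its tails: the upper tail ``p(d+, c; b, a)`` (collecting d or more
analogues of interest by chance) and the lower tail ``p(d-, c; b, a)``,
related by ``p(d-) = 1 - p(d+) + P(d) = p((b-d)+, a-c; b, a)``.  A rule whose
upper tail is at or below the cutoff ``p_c`` receives a +1 vote; failing
that, a lower tail at or below ``p_c`` earns a -1 vote; otherwise no vote.
A -1 vote is equivalent to a +1 vote for the rule's full set-complement.

Two arithmetic backends are provided.  ``"exact"`` evaluates tails as exact
rational numbers (integer binomials), so vote decisions at the ``p <= p_c``
boundary are unambiguous; it is the reference semantics and is cheap at
sublibrary sizes up to a few thousand thanks to per-``(a, b)`` vote tables.
``"float"`` delegates to :mod:`scipy.stats` (log-gamma evaluation) and
applies a small relative tolerance at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "SignificanceConfig",
    "hypergeom_pmf",
    "p_upper",
    "p_lower",
    "assign_vote",
    "vote_table",
]


@dataclass(frozen=True)
class SignificanceConfig:
    """Cutoff and arithmetic used to turn tail p-values into votes.

    Parameters
    ----------
    p_c : significance cutoff; comparisons are inclusive (``p <= p_c``).
    arithmetic : ``"exact"`` (rational reference) or ``"float"`` (log-gamma).
    boundary_tolerance : relative slack for ``p <= p_c`` under floats.
    """

    p_c: float = 0.005
    arithmetic: str = "exact"
    boundary_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.p_c < 1:
            raise ValueError(f"p_c must lie in (0, 1), got {self.p_c}")
        if self.arithmetic not in ("exact", "float"):
            raise ValueError(f"unknown arithmetic backend {self.arithmetic!r}")

    @property
    def p_c_exact(self) -> Fraction:
        # via the decimal string so 0.005 means 1/200, not its float neighbour
        return Fraction(str(self.p_c))


def _check_counts(d: int, c: int, b: int, a: int) -> None:
    if not all(isinstance(x, (int, np.integer)) for x in (d, c, b, a)):
        raise ValueError("counts must be integers")
    if not (0 <= d <= c <= a and 0 <= d <= b <= a):
        raise ValueError(f"invalid counts d={d}, c={c}, b={b}, a={a}")


def _pmf_exact(d: int, c: int, b: int, a: int) -> Fraction:
    if d < max(0, c + b - a) or d > min(b, c):
        return Fraction(0)
    return Fraction(math.comb(b, d) * math.comb(a - b, c - d), math.comb(a, c))


def _p_upper_exact(d: int, c: int, b: int, a: int) -> Fraction:
    return sum(
        (_pmf_exact(i, c, b, a) for i in range(d, min(b, c) + 1)),
        start=Fraction(0),
    ) if d > max(0, c + b - a) else Fraction(1)


def hypergeom_pmf(d: int, c: int, b: int, a: int, exact: bool = False):
    """Point probability ``P(d, c; b, a)``; a :class:`~fractions.Fraction`
    when ``exact``, a float otherwise."""
    _check_counts(d, c, b, a)
    if exact:
        return _pmf_exact(d, c, b, a)
    return float(hypergeom.pmf(d, a, b, c))


def p_upper(d: int, c: int, b: int, a: int, exact: bool = False):
    """Upper-tail significance ``p(d+, c; b, a)``: probability of condensing
    *d* or more analogues of interest by chance."""
    _check_counts(d, c, b, a)
    if exact:
        return _p_upper_exact(d, c, b, a)
    return float(hypergeom.sf(d - 1, a, b, c))


def p_lower(d: int, c: int, b: int, a: int, exact: bool = False):
    """Lower-tail significance ``p(d-, c; b, a)``: probability of condensing
    *d* or fewer analogues of interest by chance."""
    _check_counts(d, c, b, a)
    if exact:
        return Fraction(1) - _p_upper_exact(d, c, b, a) + _pmf_exact(d, c, b, a)
    return float(hypergeom.cdf(d, a, b, c))


def assign_vote(
    c: int, d: int, b: int, a: int, config: SignificanceConfig | None = None
) -> int:
    """Vote of a rule with condensation counts ``(c, d)``: +1, -1 or 0.

    The positive tail is tested first; comparisons are inclusive.
    """
    config = config or SignificanceConfig()
    _check_counts(d, c, b, a)
    if config.arithmetic == "exact":
        p_c = config.p_c_exact
        if _p_upper_exact(d, c, b, a) <= p_c:
            return 1
        if Fraction(1) - _p_upper_exact(d, c, b, a) + _pmf_exact(d, c, b, a) <= p_c:
            return -1
        return 0
    cut = config.p_c * (1 + config.boundary_tolerance)
    if float(hypergeom.sf(d - 1, a, b, c)) <= cut:
        return 1
    if float(hypergeom.cdf(d, a, b, c)) <= cut:
        return -1
    return 0


@lru_cache(maxsize=64)
def _vote_table_cached(
    a: int, b: int, p_c_str: str, arithmetic: str, boundary_tolerance: float
) -> np.ndarray:
    config = SignificanceConfig(float(p_c_str), arithmetic, boundary_tolerance)
    table = np.zeros((a + 1, b + 1), dtype=np.int8)
    if arithmetic == "exact":
        p_c = Fraction(p_c_str)
        for c in range(a + 1):
            lo, hi = max(0, c + b - a), min(b, c)
            pmf = [_pmf_exact(d, c, b, a) for d in range(lo, hi + 1)]
            sf = Fraction(1)  # p_upper at d = lo
            for j, d in enumerate(range(lo, hi + 1)):
                table[c, d] = (
                    1 if sf <= p_c
                    else (-1 if Fraction(1) - sf + pmf[j] <= p_c else 0)
                )
                sf -= pmf[j]
    else:
        for c in range(a + 1):
            for d in range(max(0, c + b - a), min(b, c) + 1):
                table[c, d] = assign_vote(c, d, b, a, config)
    table.setflags(write=False)
    return table


def vote_table(a: int, b: int, config: SignificanceConfig | None = None) -> np.ndarray:
    """Vote lookup table ``T[c, d]`` for a sublibrary of size *a* with *b*
    analogues of interest; entries outside the hypergeometric support are 0.

    Cached per ``(a, b, config)``: the cross-validation fast paths re-vote
    thousands of rules per cycle against the same table.
    """
    config = config or SignificanceConfig()
    return _vote_table_cached(
        a, b, str(config.p_c), config.arithmetic, config.boundary_tolerance
    )
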