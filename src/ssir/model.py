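"""The SSIR voting model: a scikit-learn style rule-voting ranker.

Fitting enumerates every admissible substitution rule of the requested
orders, computes each rule's condensation counts over the training
sublibrary, keeps the rules whose hypergeometric tail significance reaches
the cutoff ``p_c`` and attaches their +1/-1 votes.  Any analogue code --
training or unseen -- is then scored by the sum of votes of the significant
rules that condense it; the ranking by summed votes is the model output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom, rankdata
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve as _sk_roc_curve

from .library import AnalogueCode, LabeledLibrary, LibrarySpec, SiteSpec
from .rules import Rule, RuleSet, parse_rule
from .significance import SignificanceConfig, vote_table

__all__ = [
    "RuleStats",
    "SSIRVoting",
    "RankingResult",
    "fit_ssir",
    "rank",
    "auroc",
    "roc_curve",
]


@dataclass(frozen=True)
class RuleStats:
    """One selected rule with its condensation counts, tails and vote."""

    rule: Rule
    c: int
    d: int
    p_up: float
    p_down: float
    vote: int

    def to_dict(self) -> dict:
        return {
            "rule": str(self.rule),
            "c": self.c,
            "d": self.d,
            "p_up": self.p_up,
            "p_down": self.p_down,
            "vote": self.vote,
        }


class SSIRVoting(BaseEstimator):
    """Superposing-significant-interaction-rules voting ranker.

    Parameters
    ----------
    spec : LibrarySpec
        The combinatorial library the codes live in.
    orders : int or iterable of int, default (2,)
        Exact rule orders to enumerate (e.g. ``{2}`` or ``{1, 2}``).
    negations : bool, default True
        Allow forbid-residue terms alongside require-residue terms.
    p_c : float, default 0.005
        Inclusive significance cutoff for rule selection.
    arithmetic : {"exact", "float"}, default "exact"
        Backend for tail evaluation and boundary comparisons.

    Attributes
    ----------
    rules_ : list of Rule -- selected rules, canonical enumeration order.
    votes_ : int8 array, +1/-1 per selected rule.
    rule_stats_ : list of RuleStats for the selected rules.
    n_rules_ : number of selected rules.
    a_, b_ : training sublibrary size and number of analogues of interest.

    Examples
    --------
    >>> from ssir.datasets import load_fpr
    >>> fpr = load_fpr()
    >>> model = SSIRVoting(fpr.spec, orders={2}).fit(fpr.fpr1.codes,
    ...                                              fpr.fpr1.interest)
    >>> model.n_rules_
    117
    """

    def __init__(
        self,
        spec: LibrarySpec | None = None,
        orders: int | Iterable[int] = (2,),
        negations: bool = True,
        p_c: float = 0.005,
        arithmetic: str = "exact",
        boundary_tolerance: float = 1e-9,
    ):
        self.spec = spec
        self.orders = orders
        self.negations = negations
        self.p_c = p_c
        self.arithmetic = arithmetic
        self.boundary_tolerance = boundary_tolerance

    # -- helpers -----------------------------------------------------------

    def _config(self) -> SignificanceConfig:
        return SignificanceConfig(self.p_c, self.arithmetic, self.boundary_tolerance)

    def _orders_tuple(self) -> tuple[int, ...]:
        orders = (self.orders,) if isinstance(self.orders, int) else self.orders
        return tuple(sorted(set(int(k) for k in orders)))

    def _encode(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 2 and np.issubdtype(X.dtype, np.integer):
            return X.astype(np.int16)
        codes = [self.spec.parse_code(c) for c in X]
        return self.spec.encode(codes)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y) -> "SSIRVoting":
        """Select significant rules and votes from codes *X* and flags *y*.

        *X* is a sequence of analogue codes (strings or token tuples, or an
        already-encoded integer index array); *y* the interest flags.
        """
        if self.spec is None:
            raise ValueError("SSIRVoting needs a LibrarySpec")
        y = np.asarray(y, dtype=bool)
        codes_idx = self._encode(X)
        if codes_idx.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        a, b = int(y.shape[0]), int(y.sum())
        if b == 0 or b == a:
            raise ValueError("both classes must be present in y")
        config = self._config()
        ruleset = RuleSet.enumerate(self.spec, self._orders_tuple(), self.negations)
        match = ruleset.match_matrix(codes_idx)
        c = match.sum(axis=1)
        d = match[:, y].sum(axis=1)
        votes = vote_table(a, b, config)[c, d]
        keep = np.flatnonzero(votes)

        self.a_, self.b_ = a, b
        self.rules_ = [ruleset.rules[i] for i in keep]
        self.votes_ = votes[keep].astype(np.int8)
        self.c_, self.d_ = c[keep], d[keep]
        p_up = hypergeom.sf(self.d_ - 1, a, b, self.c_)
        p_down = hypergeom.cdf(self.d_, a, b, self.c_)
        self.rule_stats_ = [
            RuleStats(r, int(ci), int(di), float(pu), float(pd_), int(v))
            for r, ci, di, pu, pd_, v in zip(
                self.rules_, self.c_, self.d_, p_up, p_down, self.votes_
            )
        ]
        self.n_rules_ = len(self.rules_)
        self._ruleset = RuleSet(self.rules_, self.spec)
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Summed votes of the matching selected rules, per code."""
        if not hasattr(self, "rules_"):
            raise RuntimeError("SSIRVoting is not fitted")
        codes_idx = self._encode(X)
        if self.n_rules_ == 0:
            return np.zeros(codes_idx.shape[0], dtype=np.int64)
        scores = np.zeros(codes_idx.shape[0], dtype=np.int64)
        votes = self.votes_.astype(np.int64)
        for start in range(0, codes_idx.shape[0], 4096):
            chunk = codes_idx[start : start + 4096]
            scores[start : start + 4096] = votes @ self._ruleset.match_matrix(chunk)
        return scores

    def predict(self, X) -> np.ndarray:
        """Interest prediction: strictly positive summed votes."""
        return self.decision_function(X) > 0

    def score(self, X, y) -> float:
        """Tie-aware AU-ROC of the vote ranking against flags *y*."""
        return auroc(self.decision_function(X), np.asarray(y, dtype=bool))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        state = {
            "spec": {
                "sites": [
                    {"name": s.name, "residues": list(s.residues)}
                    for s in self.spec.sites
                ]
            },
            "config": {
                "orders": list(self._orders_tuple()),
                "negations": self.negations,
                "p_c": self.p_c,
                "arithmetic": self.arithmetic,
            },
            "training": {"a": self.a_, "b": self.b_},
            "rules": [s.to_dict() for s in self.rule_stats_],
        }
        return json.dumps(state, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SSIRVoting":
        state = json.loads(text)
        spec = LibrarySpec(
            tuple(
                SiteSpec(s["name"], tuple(s["residues"]))
                for s in state["spec"]["sites"]
            )
        )
        cfg = state["config"]
        model = cls(
            spec,
            orders=tuple(cfg["orders"]),
            negations=cfg["negations"],
            p_c=cfg["p_c"],
            arithmetic=cfg["arithmetic"],
        )
        model.a_ = state["training"]["a"]
        model.b_ = state["training"]["b"]
        model.rule_stats_ = [
            RuleStats(
                parse_rule(s["rule"], spec), s["c"], s["d"], s["p_up"], s["p_down"], s["vote"]
            )
            for s in state["rules"]
        ]
        model.rules_ = [s.rule for s in model.rule_stats_]
        model.votes_ = np.array([s.vote for s in model.rule_stats_], dtype=np.int8)
        model.c_ = np.array([s.c for s in model.rule_stats_])
        model.d_ = np.array([s.d for s in model.rule_stats_])
        model.n_rules_ = len(model.rules_)
        model._ruleset = RuleSet(model.rules_, spec)
        model.classes_ = np.array([False, True])
        return model


def fit_ssir(
    lib: LabeledLibrary,
    orders: int | Iterable[int] = (2,),
    negations: bool = True,
    p_c: float = 0.005,
    arithmetic: str = "exact",
) -> SSIRVoting:
    """Fit an :class:`SSIRVoting` model on a labeled library."""
    return SSIRVoting(lib.spec, orders, negations, p_c, arithmetic).fit(
        lib.codes, lib.interest
    )


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def auroc(scores: Sequence[float], flags: Sequence[bool]) -> float:
    """Tie-aware area under the ROC curve of *scores* against *flags*.

    Pair-counting form: (correctly ordered pairs + 0.5 * tied pairs) over
    all interest x non-interest pairs, computed through mid-ranks
    (the rank-sum statistic).
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    n_pos = int(flags.sum())
    n_neg = flags.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AU-ROC needs both classes present")
    ranks = rankdata(scores)  # mid-ranks on ties
    return float((ranks[flags].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, flags) -> tuple[np.ndarray, np.ndarray]:
    """ROC staircase (FPR, TPR) points, endpoints (0,0) and (1,1) included;
    tied scores produce diagonal segments."""
    flags = np.asarray(flags, dtype=bool)
    if flags.all() or not flags.any():
        raise ValueError("ROC curve needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(flags, np.asarray(scores, dtype=float))
    return fpr, tpr


@dataclass
class RankingResult:
    """Vote ranking of a set of codes, with metrics when flags are known."""

    codes: list[AnalogueCode]
    votes: np.ndarray
    order: np.ndarray  # positions sorted by descending votes
    flags: np.ndarray | None = None
    auroc: float | None = None
    roc: tuple[np.ndarray, np.ndarray] | None = None

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "code": ["".join(c) for c in self.codes],
                "votes": self.votes,
            }
        )
        if self.flags is not None:
            df["interest"] = self.flags.astype(int)
        df = df.iloc[self.order].reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df


def rank(
    model: SSIRVoting,
    codes: Sequence[AnalogueCode | str],
    flags: Sequence[bool] | None = None,
) -> RankingResult:
    """Score and sort codes by descending summed votes.

    Ties are broken by canonical (input) code order; when flags are given the
    tie-aware AU-ROC and ROC points are attached.
    """
    parsed = [model.spec.parse_code(c) for c in codes]
    votes = model.decision_function(parsed)
    order = np.argsort(-votes, kind="stable")
    result = RankingResult(parsed, votes, order)
    if flags is not None:
        result.flags = np.asarray(flags, dtype=bool)
        result.auroc = auroc(votes, result.flags)
        result.roc = roc_curve(votes, result.flags)
    return result
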