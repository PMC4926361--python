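"""Internal-test-set cross-validation and label-randomization tests.

Both cross-validation schemes follow the internal-test-sets discipline: each
cycle re-selects the significant rules from scratch as if the left-out
analogue(s) had never been measured.  Because a rule's significance depends
only on its condensation counts ``(c, d)`` and the sublibrary sizes
``(a', b')``, leaving compounds out reduces to decrementing ``c``/``d`` for
the rules that match them and re-reading the vote from a per-``(a', b')``
vote table -- the fast recount.  The fast paths are exactly equivalent to a
naive per-cycle refit (asserted in the test suite) but run in vectorized
time over all rules.

* L1O: every analogue is left out once; its prediction is the summed vote of
  the re-selected rules that condense it.
* Balanced leave-two-out (BL2O): every (interest, non-interest) pair is left
  out together -- ``n_act * n_nact`` cycles -- and the pair is marked a win
  when the left-out interest compound outscores its partner.  Per-compound
  vote sums are homogenized (interest sums divided by ``n_nact``,
  non-interest by ``n_act``) before the final AU-ROC.
* Randomization: the interest flags are permuted (``b`` preserved) and the
  whole modeling redone; permutations where no rule reaches significance
  yield no model at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .library import LabeledLibrary
from .model import SSIRVoting, auroc
from .rules import RuleSet
from .significance import SignificanceConfig, vote_table

__all__ = [
    "L1OResult",
    "BL2OResult",
    "RandomizationResult",
    "leave_one_out",
    "balanced_leave_two_out",
    "randomization_test",
]


@dataclass
class L1OResult:
    """Leave-one-out predictions and summary."""

    predictions: np.ndarray  # per-code predicted vote sum
    flags: np.ndarray
    auroc: float
    n_rules_seen: int  # distinct rules significant in any cycle

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "n_rules_seen": self.n_rules_seen,
            "predictions": self.predictions.tolist(),
        }


@dataclass
class BL2OResult:
    """Balanced leave-two-out pair outcomes and homogenized ranking."""

    n_act: int
    n_nact: int
    wins: int
    ties: int
    losses: int
    homogenized: np.ndarray  # per-code homogenized vote sums
    flags: np.ndarray
    auroc: float
    n_rules_seen: int

    @property
    def cycles(self) -> int:
        return self.n_act * self.n_nact

    def to_dict(self) -> dict:
        return {
            "cycles": self.cycles,
            "wins": self.wins,
            "ties": self.ties,
            "losses": self.losses,
            "auroc": self.auroc,
            "n_rules_seen": self.n_rules_seen,
            "homogenized": self.homogenized.tolist(),
        }


@dataclass
class RandomizationResult:
    """Label-scrambling test: models surviving under permuted flags."""

    n_perm: int
    seed: int
    points: list[tuple[int, float]]  # (n_rules, L1O auroc) per surviving perm
    reference: tuple[int, float]  # same pair for the true labels

    @property
    def n_reproduced(self) -> int:
        return len(self.points)

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_reproduced": self.n_reproduced,
            "reference": list(self.reference),
            "points": [list(p) for p in self.points],
        }


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

class _FastCounts:
    """Full-training match matrix and condensation counts for all rules."""

    def __init__(
        self,
        lib: LabeledLibrary,
        orders: int | Iterable[int],
        negations: bool,
        config: SignificanceConfig,
    ):
        if lib.b < 2 or lib.a - lib.b < 2:
            raise ValueError(
                "cross-validation needs at least two compounds per class"
            )
        self.lib = lib
        self.config = config
        self.ruleset = RuleSet.enumerate(lib.spec, orders, negations)
        self.match = self.ruleset.match_matrix(lib.encoded())  # (R, a)
        self.c = self.match.sum(axis=1).astype(np.int64)
        self.d_of = lambda y: self.match[:, y].sum(axis=1).astype(np.int64)

    def l1o(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-code L1O predictions and the union mask of rules ever voted."""
        a = y.shape[0]
        b = int(y.sum())
        d = self.d_of(y)
        tables = {
            True: vote_table(a - 1, b - 1, self.config),
            False: vote_table(a - 1, b, self.config),
        }
        preds = np.zeros(a, dtype=np.int64)
        seen = np.zeros(len(self.ruleset), dtype=bool)
        for i in range(a):
            mi = self.match[:, i]
            c1 = self.c - mi
            d1 = d - mi if y[i] else d
            votes = tables[bool(y[i])][c1, d1]
            preds[i] = int(votes[mi].sum())
            seen |= votes != 0
        return preds, seen

    def bl2o(self, y: np.ndarray) -> BL2OResult:
        a = y.shape[0]
        b = int(y.sum())
        d = self.d_of(y)
        act = np.flatnonzero(y)
        nact = np.flatnonzero(~y)
        table = vote_table(a - 2, b - 1, self.config)
        wins = ties = 0
        sums = np.zeros(a, dtype=np.int64)
        seen = np.zeros(len(self.ruleset), dtype=bool)
        m_nact = self.match[:, nact]  # (R, n_nact)
        for i in act:
            mi = self.match[:, i][:, None]
            c2 = self.c[:, None] - mi - m_nact
            d2 = (d - self.match[:, i])[:, None] * np.ones_like(m_nact, dtype=np.int64)
            votes = table[c2, d2]  # (R, n_nact) int8
            s_act = mi.T @ votes.astype(np.int64)  # (1, n_nact)
            s_act = s_act.ravel()
            s_nact = np.einsum("rj,rj->j", votes.astype(np.int64), m_nact)
            wins += int((s_act > s_nact).sum())
            ties += int((s_act == s_nact).sum())
            sums[i] += int(s_act.sum())
            sums[nact] += s_nact
            seen |= (votes != 0).any(axis=1)
        n_act, n_nact = act.size, nact.size
        homog = sums.astype(float)
        homog[act] /= n_nact
        homog[nact] /= n_act
        return BL2OResult(
            n_act=n_act,
            n_nact=n_nact,
            wins=wins,
            ties=ties,
            losses=n_act * n_nact - wins - ties,
            homogenized=homog,
            flags=y.copy(),
            auroc=auroc(homog, y),
            n_rules_seen=int(seen.sum()),
        )


def _naive_l1o(
    lib: LabeledLibrary, orders, negations, config: SignificanceConfig
) -> np.ndarray:
    """Reference L1O by full per-cycle refits (oracle for the fast path)."""
    preds = np.zeros(lib.a, dtype=np.int64)
    for i in range(lib.a):
        keep = [j for j in range(lib.a) if j != i]
        model = SSIRVoting(
            lib.spec, orders, negations, config.p_c, config.arithmetic
        ).fit([lib.codes[j] for j in keep], lib.interest[keep])
        preds[i] = int(model.decision_function([lib.codes[i]])[0])
    return preds


def _naive_bl2o(
    lib: LabeledLibrary, orders, negations, config: SignificanceConfig
) -> BL2OResult:
    """Reference BL2O by full per-cycle refits (oracle for the fast path)."""
    y = lib.interest
    act = np.flatnonzero(y)
    nact = np.flatnonzero(~y)
    wins = ties = 0
    sums = np.zeros(lib.a, dtype=np.int64)
    seen: set = set()
    for i in act:
        for j in nact:
            keep = [k for k in range(lib.a) if k not in (i, j)]
            model = SSIRVoting(
                lib.spec, orders, negations, config.p_c, config.arithmetic
            ).fit([lib.codes[k] for k in keep], lib.interest[keep])
            si, sj = model.decision_function([lib.codes[i], lib.codes[j]])
            wins += si > sj
            ties += si == sj
            sums[i] += si
            sums[j] += sj
            seen.update(model.rules_)
    homog = sums.astype(float)
    homog[act] /= nact.size
    homog[nact] /= act.size
    return BL2OResult(
        n_act=act.size,
        n_nact=nact.size,
        wins=int(wins),
        ties=int(ties),
        losses=act.size * nact.size - int(wins) - int(ties),
        homogenized=homog,
        flags=y.copy(),
        auroc=auroc(homog, y),
        n_rules_seen=len(seen),
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def leave_one_out(
    lib: LabeledLibrary,
    orders: int | Iterable[int] = (2,),
    negations: bool = True,
    config: SignificanceConfig | None = None,
    naive: bool = False,
) -> L1OResult:
    """Leave-one-out cross-validation with per-cycle rule re-selection.

    ``naive=True`` runs literal per-cycle refits instead of the fast recount
    (slow; intended for oracle checks on small libraries).
    """
    config = config or SignificanceConfig()
    if naive:
        preds = _naive_l1o(lib, orders, negations, config)
        fast = _FastCounts(lib, orders, negations, config)
        _, seen = fast.l1o(lib.interest)
        return L1OResult(preds, lib.interest.copy(), auroc(preds, lib.interest), int(seen.sum()))
    fast = _FastCounts(lib, orders, negations, config)
    preds, seen = fast.l1o(lib.interest)
    return L1OResult(
        predictions=preds,
        flags=lib.interest.copy(),
        auroc=auroc(preds, lib.interest),
        n_rules_seen=int(seen.sum()),
    )


def balanced_leave_two_out(
    lib: LabeledLibrary,
    orders: int | Iterable[int] = (2,),
    negations: bool = True,
    config: SignificanceConfig | None = None,
    naive: bool = False,
) -> BL2OResult:
    """Balanced leave-two-out over all interest x non-interest pairs."""
    config = config or SignificanceConfig()
    if naive:
        return _naive_bl2o(lib, orders, negations, config)
    return _FastCounts(lib, orders, negations, config).bl2o(lib.interest)


def randomization_test(
    lib: LabeledLibrary,
    orders: int | Iterable[int] = (2,),
    negations: bool = True,
    config: SignificanceConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Label-scrambling (y-randomization) test.

    Each permutation shuffles the interest flags across compounds (so ``b``
    is preserved), refits from scratch and, when at least one rule reaches
    significance, records (number of rules, L1O AU-ROC).  The reference
    point is the same pair under the true labels.
    """
    config = config or SignificanceConfig()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fast = _FastCounts(lib, orders, negations, config)
    a, b = lib.a, lib.b
    table = vote_table(a, b, config)
    rng = np.random.default_rng(seed)

    def survey(y: np.ndarray) -> tuple[int, float] | None:
        votes = table[fast.c, fast.d_of(y)]
        n_rules = int(np.count_nonzero(votes))
        if n_rules == 0:
            return None
        preds, _ = fast.l1o(y)
        return n_rules, auroc(preds, y)

    reference = survey(lib.interest)
    if reference is None:
        reference = (0, float("nan"))
    points = []
    for _ in range(n_perm):
        y_perm = rng.permutation(lib.interest)
        point = survey(y_perm)
        if point is not None:
            points.append(point)
    return RandomizationResult(
        n_perm=n_perm, seed=seed, points=points, reference=reference
    )
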