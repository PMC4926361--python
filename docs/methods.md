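# Methods

## Model

A combinatorial analogue series is an `n`-site scaffold; site `i` accepts
one of `m_i` symbolic residues, so `M = ∏ m_i` analogues are definable and
each is identified by its code (one token per site). Only sites with
`m_i > 1` carry information; singleton sites are kept in the codification
but never constrained.

A rule constrains `k` sites ("order k"), each with a single require-residue
or forbid-residue (negation) term, wildcards elsewhere; unions or
multi-residue site sets are out of scope. The number of positive-term rules
is `V = Σ_k Σ_{site k-subsets} ∏ m_i`; with negations each constrained site
contributes `2 m_i` term choices. A rule's *condensed size* over the full
library is the product over sites of `m_i` (wildcard), `1` (require) or
`m_i − 1` (forbid).

Given `a` known compounds, `b` of interest, and a rule condensing `c` of
them with `d` of interest, the rule's tails are hypergeometric:
`p(d+) = Σ_{i=d}^{min(b,c)} C(b,i) C(a−b,c−i) / C(a,c)` and
`p(d−) = 1 − p(d+) + P(d) = p((b−d)+, a−c; b, a)`. With an inclusive
cutoff `p_c` (default 0.005), `p(d+) ≤ p_c` earns a +1 vote, failing that
`p(d−) ≤ p_c` earns −1, otherwise no vote; the positive tail is tested
first (both tails cannot pass simultaneously at small `p_c`, but the order
is fixed for determinism). A −1 vote is equivalent to a +1 vote for the
rule's set complement. A compound's score is the summed vote of the
selected rules condensing it; a compound matched by no selected rule scores
0 and ranks between the positive- and negative-scoring ones. The assumption
behind superposition is that site effects on the property, though
non-linear, can be expanded in low-order interaction rules.

## Parameters

- `orders` (set of ints, default `{2}`): exact rule orders enumerated.
  Model sizes in the bundled application are *exact-order* fits: an
  "order 2" model contains order-2 rules only. Higher orders grow
  combinatorially (`2^k ∏ m_i` per site subset with negations).
- `negations` (default on): allow forbid terms. Forbid terms on binary
  sites are suppressed in enumeration (forbidding one of two residues is
  requiring the other); `count_rules(raw=True)` still counts them so the
  plain nested-product totals reproduce, and `binary_negations=True`
  re-enables them in enumeration (duplicate semantics tolerated).
- `p_c` (default 0.005): inclusive significance cutoff; dimensionless
  probability. Smaller values give sparser, more conservative models.
- `arithmetic`: `"exact"` (default) evaluates tails as exact rationals
  (integer binomials via `math.comb`), making boundary decisions
  `p ≤ p_c` unambiguous — `p_c` is parsed from its decimal string, so
  0.005 means exactly 1/200. `"float"` uses scipy's log-gamma evaluation
  with a relative boundary tolerance of 1e-9; the two backends agree
  exhaustively over all `(c, d)` at the bundled dataset's margins
  (a = 106, b = 32). Exact arithmetic is the reference semantics and is
  cheap because votes are read from a per-`(a, b)` lookup table over
  `(c, d)` (at most `(a+1) × (b+1)` cells, cached).

## Cross-validation

L1O and BL2O follow the internal-test-set discipline: every cycle
re-selects rules as if the left-out compound(s) had never been measured.
Since a rule's vote depends only on `(c, d, a', b')`, leaving compounds out
reduces to decrementing `c`/`d` for the rules matching them and re-reading
the vote table for `(a', b')` — L1O uses `(a−1, b−[flag])`, BL2O
`(a−2, b−1)`. The fast paths are asserted bit-identical to naive per-cycle
refits on toy-scale fixtures. BL2O loops over all `n_act × n_nact`
interest/non-interest pairs; a pair is a win when the left-out interest
compound strictly outscores its partner, a tie on equality (ties are
reported separately, not credited). Final BL2O ranking uses homogenized
votes — interest compounds' summed cycle scores divided by `n_nact`,
non-interest by `n_act` — and its AU-ROC is computed from that vector, not
from the pair outcomes: the two are distinct statistics (the win fraction
and the homogenized-vote AU-ROC differ legitimately, e.g. 2253/2368 ≈ 0.951
vs 0.947 for the FPR2 order-3 run).

The randomization test permutes the interest flags (preserving `b`, so rule
significances stay comparable) and refits from scratch; a permutation
"reproduces a model" when at least one rule reaches `p_c`. For those, the
number of rules and the L1O AU-ROC are recorded against the true-label
reference point. A single integer seed drives the permutation stream.

## Ranking metrics

AU-ROC is the tie-aware pair-counting statistic — (correct pairs + 0.5 ×
tied pairs) / (n_act · n_nact) — computed through mid-ranks; it equals the
trapezoidal area under the ROC staircase (property-tested, and
cross-checked against scikit-learn's independent implementation). ROC
points come from `sklearn.metrics.roc_curve`; tied scores produce diagonal
segments.

## Inverse SAR

All `M − a` non-training codes are enumerated in deterministic
lexicographic order and scored by fitted models. The neighbor filter keeps
candidates whose site-wise Hamming distance is ≤ `max_diff` (default 1) to
at least `min_neighbors` (default 3) training compounds, bounding
extrapolation in chemical space. Multi-property merging linearly rescales
each property's integer votes — positives divided by the maximum positive
vote onto (0, +1], negatives by the magnitude of the minimum onto [−1, 0),
zero staying exactly 0 — and sums them as the consensus score. Scaling
denominators are the extremes *within the candidate set being ranked*, so
full-set and filtered-set scalings differ legitimately; the
positive-in-all-properties membership is scale-invariant and is the robust
summary. Ties in consensus score keep canonical code order; published
top-lists are treated as set membership, not exact sequence, since tie
order within equal-vote blocks is undefined.

## Bundled data and the synthetic toy fixture

The bundled dataset (5 × 8 × 9 × 17 sites, M = 6120; a = 106, b = 32 per
receptor) is stored as printed, and the interest flags are stored directly
rather than re-derived from the pK values: the printed values are rounded
to three decimals and transformed (values above 10 000 nM floored at
pK = 4), so thresholding them in log units cannot reproduce the flag sets
exactly, while count-based dichotomization (32 lowest) does.

The toy library (2 × 3 × 4 sites, M = 24) has a published structure but no
published labeled sublibrary; `make_toy_labeled` draws a seeded synthetic
one (default a = 15, b = 5, matching the worked-example sizes) with
interest flags biased toward residue A at site 2 so that site rules are
genuinely informative. It exists to exercise oracle equivalences
(fast-recount vs naive refit, matrix vs scalar matching) at a size where
brute force is feasible; it does not emulate assay noise, activity cliffs,
correlated substitutions or unbalanced class ratios, so passing those
tests certifies algorithmic correctness, not real-data performance.

## Numerical and design choices

- Deterministic enumeration everywhere: site combinations lexicographic,
  residues in alphabet order, require before forbid; all listings inherit
  this order, so reruns are byte-identical given the same inputs and seed.
- Degenerate inputs: rules condensing zero known compounds get no vote
  (both tails are 1); empty models are legal, score everything 0 and are
  flagged with a warning; single-class label vectors are rejected;
  dichotomization boundary ties are split by stable input order with a
  warning, never silently exceeding the requested count.
- Rule p-values are used raw, as a selection device; no multiple-testing
  correction is applied. The randomization test is the guard against the
  selection bias this implies.
- Vote tables and match matrices are the only caches; both are exact.

## Problem sizes

The default suite and the acceptance script run the full bundled pipeline:
order-2 and order-3 fits (2 124 and 24 232 enumerated rules over 106
compounds), the 2 368-cycle BL2O at order 3, candidate scoring over 6 014
codes, and 300-permutation randomization checks — a few seconds each on
one CPU thanks to the vectorized match matrices and vote tables.

## Limitations

- Libraries with a single substitution site are out of scope by
  construction (no rule superposition is possible).
- The model cannot score residues absent from the training codification.
- Only juxtaposed single-residue terms are supported; richer Boolean rule
  algebra, continuous-property variants and heuristic high-order rule
  search are deliberately not implemented.
- Exhaustive enumeration above order ~4 on large alphabets hits
  combinatorial explosion; orders are exposed as a set so users choose the
  trade-off explicitly.
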