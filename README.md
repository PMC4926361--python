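# ssir — superposing significant interaction rules

`ssir` models and ranks **combinatorial analogue series**: families of
compounds sharing a scaffold with `n` substitution sites, site `i` accepting
one of `m_i` residues, so the full library holds `M = ∏ m_i` analogues.
Each compound is a purely symbolic code (one token per site, e.g. `CBDD`),
which makes the method applicable to any combinatorial dataset — even a
confidential one — with no structure preparation, alignment or descriptor
calculation.

It is aimed at medicinal and combinatorial chemists who have measured a
property on part of a library, want an interpretable structure–activity
model over the substitution sites, and want a ranked list of the
not-yet-synthesized analogues (inverse SAR).

## The method

A **rule of order k** constrains `k` sites, each with a positive term
(require residue `R`) or a negation term (forbid residue `R`, written `|R`),
wildcards (`.`) elsewhere; e.g. `. G . |C` requires `G` at site 2 and
forbids `C` at site 4. A rule *condenses* the sublibrary of analogues that
match it.

Given a known sublibrary of `a` compounds, `b` of them flagged *of
interest*, a rule condensing `c` known compounds, `d` of them of interest,
is scored by the hypergeometric point probability

    P(d, c; b, a) = C(b,d) C(a−b, c−d) / C(a,c)

and its tails `p(d+, c; b, a) = Σ_{i≥d} P(i, c; b, a)` and
`p(d−) = 1 − p(d+) + P(d)`. With an inclusive cutoff `p_c`, a rule gets a
**+1 vote** if `p(d+) ≤ p_c`, a **−1 vote** if `p(d−) ≤ p_c`, and is
discarded otherwise. The model is the set of selected rules with their
votes; any analogue code — measured or not — is scored by the **sum of
votes** of the rules that condense it, and compounds are ranked by that sum.
Ranking quality is measured by the tie-aware AU-ROC (0.5 credit per tied
pair). Validation uses internal-test-set leave-one-out (L1O) and balanced
leave-two-out (BL2O, looping over all interest × non-interest pairs)
cross-validation, both re-selecting rules from scratch each cycle via exact
fast recounts, plus label-scrambling randomization tests.

## Worked example

The bundled dataset is a four-site series (5 × 8 × 9 × 17 residues,
M = 6120) of 106 pyrrolidine bis-diketopiperazines with binding affinities
against the formylpeptide receptors FPR1 and FPR2; for each receptor the 32
lowest-Ki compounds are flagged of interest.

```python
from ssir import fit_ssir, balanced_leave_two_out, SignificanceConfig
from ssir.datasets import load_fpr

fpr = load_fpr()
model = fit_ssir(fpr.fpr1, orders={2}, negations=True, p_c=0.005)
print(model.n_rules_)                                  # 117
print(round(model.score(fpr.fpr1.codes, fpr.fpr1.interest), 3))  # 0.894
best = min(model.rule_stats_, key=lambda s: min(s.p_up, s.p_down))
print(best.rule, best.vote)                            # . G . |C 1

bl2o = balanced_leave_two_out(fpr.fpr2, orders={3}, negations=True,
                              config=SignificanceConfig(0.005))
print(bl2o.cycles, bl2o.wins, bl2o.ties, bl2o.losses)  # 2368 2253 0 115
```

117 order-2 rules reach `p ≤ 0.005` for FPR1 and their vote ranking
separates binders from non-binders with a training AU-ROC of 0.894; the
strongest rules all involve residue `G` at site 2. The BL2O run for FPR2
leaves out each of the 32 × 74 interest/non-interest pairs in turn and the
re-selected model orders 2253 of the 2368 pairs correctly.

The same pipeline is available from the shell:

```sh
ssir fit --spec sites.tsv --data compounds.tsv --flag-col fpr1_interest \
         --orders 2 --pc 0.005 --out runs/fpr1-o2
ssir validate ... ; ssir randomize ... ; ssir predict ...
```

Inverse SAR: `ssir.inverse` enumerates the 6014 untested analogues, filters
them to the 511 within one substitution of at least three training
compounds, scores them with fitted models and merges multi-property
rankings by summing votes rescaled onto [−1, +1].

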