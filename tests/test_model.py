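"""Model fitting, scoring, ranking and ROC metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from ssir.model import SSIRVoting, auroc, fit_ssir, rank, roc_curve
from ssir.rules import TermKind, matches


def test_fit_selects_only_significant_rules(toy_lib):
    model = fit_ssir(toy_lib, (1, 2), negations=True, p_c=0.05)
    assert model.n_rules_ > 0
    for s in model.rule_stats_:
        assert min(s.p_up, s.p_down) <= 0.05
        assert s.vote in (-1, 1)
        assert (s.vote == 1) == (s.p_up <= 0.05)


def test_score_is_sum_of_matching_rule_votes(toy_lib):
    model = fit_ssir(toy_lib, (1, 2), negations=True, p_c=0.05)
    for code in toy_lib.codes:
        brute = sum(
            int(v) for r, v in zip(model.rules_, model.votes_) if matches(r, code)
        )
        assert model.decision_function([code])[0] == brute


def test_empty_model_scores_zero(toy_lib):
    model = fit_ssir(toy_lib, (1,), negations=False, p_c=1e-9)
    assert model.n_rules_ == 0
    assert np.all(model.decision_function(toy_lib.codes) == 0)


def test_fit_invariant_to_row_order(toy_lib):
    model = fit_ssir(toy_lib, (1, 2), True, 0.05)
    perm = np.random.default_rng(0).permutation(toy_lib.a)
    shuffled = toy_lib.subset(perm)
    model2 = fit_ssir(shuffled, (1, 2), True, 0.05)
    assert model.rules_ == model2.rules_
    assert np.array_equal(model.votes_, model2.votes_)


def test_label_inversion_flips_votes(toy_lib):
    model = fit_ssir(toy_lib, (1, 2), True, 0.05)
    inverted = toy_lib.relabel(~toy_lib.interest)
    flipped = fit_ssir(inverted, (1, 2), True, 0.05)
    assert set(zip(model.rules_, model.votes_.tolist())) == set(
        zip(flipped.rules_, (-flipped.votes_).tolist())
    )


def test_fpr1_order2_model_is_dominated_by_G_at_site2(fpr):
    """The strongest order-2 rules for FPR1 require (or, with negative vote,
    forbid the absence of) residue G at substitution site 2."""
    model = fit_ssir(fpr.fpr1, (2,), True, 0.005)
    stats = sorted(model.rule_stats_, key=lambda s: min(s.p_up, s.p_down))
    top = stats[:25]
    site2 = [s for s in top if s.rule.terms[1].residue == "G"]
    assert len(site2) > 12
    for s in site2:
        if s.rule.terms[1].kind == TermKind.REQUIRE:
            assert s.vote == 1
        else:
            assert s.vote == -1
    # codes with G at site 2 outscore their G-negated counterparts
    scores = model.decision_function(fpr.fpr1.codes)
    g_mask = np.array([c[1] == "G" for c in fpr.fpr1.codes])
    assert scores[g_mask].mean() > scores[~g_mask].mean()


def test_most_significant_fpr1_rule_text(fpr):
    # the top of the order-2 list: require G at site 2, forbid C at site 4
    model = fit_ssir(fpr.fpr1, (2,), True, 0.005)
    best = min(model.rule_stats_, key=lambda s: min(s.p_up, s.p_down))
    assert str(best.rule) == ". G . |C"
    assert best.vote == 1


def test_sklearn_params_and_clone(fpr):
    model = SSIRVoting(fpr.spec, orders=(2,), p_c=0.005)
    cloned = clone(model)
    assert cloned.get_params()["p_c"] == 0.005
    cloned.set_params(orders=(1,), negations=False)
    fitted = cloned.fit(fpr.fpr1.codes, fpr.fpr1.interest)
    assert fitted.n_rules_ > 0


def test_model_json_roundtrip(toy_lib):
    model = fit_ssir(toy_lib, (1, 2), True, 0.05)
    back = SSIRVoting.from_json(model.to_json())
    assert back.rules_ == model.rules_
    assert np.array_equal(back.votes_, model.votes_)
    assert np.array_equal(
        back.decision_function(toy_lib.codes),
        model.decision_function(toy_lib.codes),
    )


def test_auroc_trivial_cases():
    assert auroc([2, 1], [True, False]) == 1.0
    assert auroc([1, 2], [True, False]) == 0.0
    assert auroc([1, 1], [True, False]) == 0.5
    assert auroc([3, 3, 3, 3], [True, False, True, False]) == 0.5
    with pytest.raises(ValueError):
        auroc([1, 2], [True, True])


def test_rank_orders_and_ties(toy_lib):
    model = fit_ssir(toy_lib, (1, 2), True, 0.05)
    result = rank(model, toy_lib.codes, toy_lib.interest)
    votes = result.votes[result.order]
    assert all(x >= y for x, y in zip(votes, votes[1:]))
    assert result.auroc == model.score(toy_lib.codes, toy_lib.interest)
    df = result.to_frame()
    assert list(df.columns[:3]) == ["rank", "code", "votes"]


score_vectors = st.lists(
    st.tuples(st.integers(-5, 5), st.booleans()), min_size=4, max_size=40
).filter(lambda sv: 0 < sum(f for _, f in sv) < len(sv))


@settings(derandomize=True, max_examples=200)
@given(score_vectors)
def test_pair_count_auroc_equals_trapezoidal_roc_area(sv):
    scores = [s for s, _ in sv]
    flags = [f for _, f in sv]
    fpr_pts, tpr_pts = roc_curve(scores, flags)
    area = np.trapezoid(tpr_pts, fpr_pts)
    assert auroc(scores, flags) == pytest.approx(area, abs=1e-12)
    # and both agree with the independent rank-statistic implementation
    assert auroc(scores, flags) == pytest.approx(roc_auc_score(flags, scores))


@settings(derandomize=True, max_examples=100)
@given(score_vectors)
def test_roc_curve_is_monotone_staircase(sv):
    scores = [s for s, _ in sv]
    flags = [f for _, f in sv]
    fpr_pts, tpr_pts = roc_curve(scores, flags)
    assert fpr_pts[0] == 0 and tpr_pts[0] == 0
    assert fpr_pts[-1] == 1 and tpr_pts[-1] == 1
    assert np.all(np.diff(fpr_pts) >= 0)
    assert np.all(np.diff(tpr_pts) >= 0)
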