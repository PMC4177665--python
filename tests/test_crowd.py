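"""Annotator screening, the latent-truth agreement model, and calibration."""

import numpy as np
import pytest
from scipy.stats import binomtest

from lexcap import (
    AgreementFit,
    calibrate_threshold,
    drop_annotators,
    filter_candidates,
    fit_agreement_model,
    screen_annotators,
    simulate_ratings,
)
from lexcap.crowd import posterior_bayes
from lexcap.simulate import RatingsMatrix


def _controls_matrix(accuracies, n_controls, seed=0):
    """One control block; annotator a answers correctly w.p. accuracies[a]."""
    rng = np.random.default_rng(seed)
    items = [f"ctrl{i}" for i in range(n_controls)]
    truth = rng.integers(0, 2, size=n_controls)
    mat = RatingsMatrix(items=items, annotators=[f"a{j}" for j in range(len(accuracies))])
    for i, it in enumerate(items):
        mat.labels[it] = "pos" if truth[i] else "neg"
        for j, acc in enumerate(accuracies):
            correct = rng.random() < acc
            vote = truth[i] if correct else 1 - truth[i]
            mat.votes[(it, f"a{j}")] = int(vote)
    return mat


def test_perfect_annotator_kept_chance_annotator_removed():
    mat = _controls_matrix([1.0, 0.5], n_controls=20, seed=1)
    res = screen_annotators(mat, alpha=0.05)
    assert "a0" in res.kept
    assert "a1" in res.removed


def test_exactly_chance_performance_removed():
    """10 of 20 controls correct is indistinguishable from coin flipping."""
    mat = RatingsMatrix(items=[f"c{i}" for i in range(20)], annotators=["a0"])
    for i in range(20):
        mat.labels[f"c{i}"] = "pos"
        mat.votes[(f"c{i}", "a0")] = 1 if i < 10 else 0
    res = screen_annotators(mat, alpha=0.05, correction="none")
    assert res.removed == ["a0"]


def test_screening_matches_exact_binomial_oracle():
    accs = [0.5, 0.6, 0.7, 0.8, 0.9, 0.95]
    mat = _controls_matrix(accs, n_controls=40, seed=2)
    res = screen_annotators(mat, alpha=0.05, correction="bonferroni")
    outcomes = {a: [] for a in mat.annotators}
    for (it, a), vote in mat.votes.items():
        truth = 1 if mat.labels[it] == "pos" else 0
        outcomes[a].append(int(vote == truth))
    for a, v in outcomes.items():
        p = binomtest(sum(v), len(v), 0.5, alternative="greater").pvalue
        decision_keep = min(p * len(accs), 1.0) <= 0.05
        assert (a in res.kept) == decision_keep


def test_annotator_without_controls_flagged_and_kept():
    mat = _controls_matrix([0.9], n_controls=15, seed=3)
    mat.annotators.append("a_nc")
    mat.items.append("cand0")
    mat.labels["cand0"] = "cand"
    mat.votes[("cand0", "a_nc")] = 1
    res = screen_annotators(mat)
    assert "a_nc" in res.flagged_no_controls
    assert "a_nc" in res.kept


def test_drop_annotators_removes_votes():
    mat = _controls_matrix([0.9, 0.5], n_controls=10, seed=4)
    out = drop_annotators(mat, ["a1"])
    assert out.annotators == ["a0"]
    assert all(a == "a0" for _, a in out.votes)


# ---------------------------------------------------------------------------
# agreement model
# ---------------------------------------------------------------------------


def test_em_recovers_annotator_rates():
    s_true, t_true = 0.67, 0.93
    ratings, _ = simulate_ratings(2000, 0.5, [(s_true, t_true)] * 20,
                                  assignment=3, seed=5)
    fit = fit_agreement_model(ratings, seed=0)
    assert abs(fit.sensitivity.mean() - s_true) < 0.05
    assert abs(fit.specificity.mean() - t_true) < 0.03
    d = np.diff(fit.loglik_trace)
    assert (d >= -1e-8 * (np.abs(fit.loglik_trace[:-1]) + 1)).all()


def test_em_deterministic_given_seed():
    ratings, _ = simulate_ratings(300, 0.5, [(0.7, 0.9)] * 6, assignment=3, seed=6)
    a = fit_agreement_model(ratings, init="random", seed=3)
    b = fit_agreement_model(ratings, init="random", seed=3)
    assert np.array_equal(a.posteriors, b.posteriors)
    assert np.array_equal(a.sensitivity, b.sensitivity)


def test_single_vote_posterior_matches_bayes_rule():
    s, t, prev = 0.8, 0.9, 0.3
    for vote in (0, 1):
        if vote:
            want = s * prev / (s * prev + (1 - t) * (1 - prev))
        else:
            want = (1 - s) * prev / ((1 - s) * prev + t * (1 - prev))
        assert posterior_bayes(s, t, prev, vote) == pytest.approx(want)


def test_unanimous_high_accuracy_yes_is_near_certain():
    """Controls pin the annotators' accuracy; a candidate with three
    unanimous yes votes from reliable annotators scores above 0.99."""
    rng = np.random.default_rng(7)
    mat = RatingsMatrix(items=[], annotators=["a0", "a1", "a2"])
    for i in range(120):
        it = f"ctrl{i}"
        truth = i % 2
        mat.items.append(it)
        mat.labels[it] = "pos" if truth else "neg"
        for a in mat.annotators:
            correct = rng.random() < 0.95
            mat.votes[(it, a)] = truth if correct else 1 - truth
    mat.items.append("cand")
    mat.labels["cand"] = "cand"
    for a in mat.annotators:
        mat.votes[("cand", a)] = 1
    fit = fit_agreement_model(mat, seed=0)
    assert fit.posterior_of("cand") > 0.99


def test_all_identical_votes_flagged_degenerate():
    mat = RatingsMatrix(items=["i0", "i1"], annotators=["a0", "a1"])
    for it in mat.items:
        mat.labels[it] = "cand"
        for a in mat.annotators:
            mat.votes[(it, a)] = 1
    fit = fit_agreement_model(mat, seed=0)
    assert fit.degenerate


def test_control_scores_are_unclamped_but_concordant():
    """Controls anchor the parameters during EM, yet their reported scores
    come from their votes, so the ROC over controls is non-trivial."""
    ratings, _ = simulate_ratings(400, 0.5, [(0.7, 0.9)] * 8, assignment=3, seed=8)
    fit = fit_agreement_model(ratings, seed=0)
    pos = [fit.posterior_of(it) for it, lab in ratings.labels.items() if lab == "pos"]
    neg = [fit.posterior_of(it) for it, lab in ratings.labels.items() if lab == "neg"]
    assert 0.0 < min(pos + neg) and max(pos + neg) < 1.0
    assert np.mean(pos) > 0.7 > 0.3 > np.mean(neg)


# ---------------------------------------------------------------------------
# calibration and filtering
# ---------------------------------------------------------------------------


def _fake_fit(scores: dict[str, float]) -> AgreementFit:
    items = list(scores)
    return AgreementFit(
        annotators=[], sensitivity=np.array([]), specificity=np.array([]),
        prevalence=0.5, items=items,
        posteriors=np.array([scores[i] for i in items]),
        loglik_trace=np.array([0.0]), converged=True, degenerate=False, seed=0)


def test_perfect_separation_gives_auc_one():
    scores = {f"p{i}": 0.9 + 0.001 * i for i in range(10)}
    scores |= {f"n{i}": 0.1 + 0.001 * i for i in range(10)}
    labels = {it: ("pos" if it.startswith("p") else "neg") for it in scores}
    cal = calibrate_threshold(_fake_fit(scores), labels, target_fdr=0.02)
    assert cal.auc == pytest.approx(1.0)
    assert cal.fpr_at_threshold <= 0.02
    assert cal.tpr_at_threshold == pytest.approx(1.0)


def test_uninformative_scores_give_half_auc():
    rng = np.random.default_rng(9)
    scores = {f"i{k}": float(rng.random()) for k in range(4000)}
    labels = {it: ("pos" if rng.random() < 0.5 else "neg") for it in scores}
    cal = calibrate_threshold(_fake_fit(scores), labels, target_fdr=0.05)
    assert cal.auc == pytest.approx(0.5, abs=0.03)


def test_calibration_requires_both_control_classes():
    scores = {"a": 0.9, "b": 0.8}
    with pytest.raises(ValueError):
        calibrate_threshold(_fake_fit(scores), {"a": "pos", "b": "pos"})


def test_threshold_respects_target_fdr():
    rng = np.random.default_rng(10)
    pos = {f"p{i}": float(np.clip(rng.normal(0.8, 0.15), 0, 1)) for i in range(300)}
    neg = {f"n{i}": float(np.clip(rng.normal(0.3, 0.2), 0, 1)) for i in range(300)}
    labels = {**{k: "pos" for k in pos}, **{k: "neg" for k in neg}}
    cal = calibrate_threshold(_fake_fit(pos | neg), labels, target_fdr=0.02)
    fp = np.mean([v > cal.threshold for v in neg.values()])
    assert fp <= 0.02


def test_filter_strictness_and_order_invariance():
    posts = {"b": 0.95, "a": 0.9, "c": 0.99, "d": 0.1}
    heads = {"a": "h1", "b": "h1", "c": "h2", "d": "h3"}
    accepted, n_heads = filter_candidates(posts, 0.9, heads)
    # strict inequality: 0.9 itself is excluded
    assert [it for it, _ in accepted] == ["b", "c"]
    assert n_heads == 2
    shuffled = dict(reversed(list(posts.items())))
    assert filter_candidates(shuffled, 0.9, heads) == (accepted, n_heads)
    assert filter_candidates(posts, 1.0)[0] == []
    assert len(filter_candidates(posts, -0.1)[0]) == len(posts)
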