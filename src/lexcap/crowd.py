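"""Crowd-sourced validation: screening, latent-truth agreement model,
posterior scoring, ROC/FDR calibration, and candidate filtering.

Binary yes/no judgments from many annotators of uneven quality are combined
with a two-class latent-truth model (per-annotator sensitivity and
specificity, global prevalence — the minimal Dawid–Skene variant) fit by
EM.  Items with known labels (positive and negative controls) have their
truths clamped during fitting and later anchor the ROC calibration of the
per-item posterior probability that a candidate pair is a true synonym.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest, ttest_1samp
from sklearn.metrics import roc_auc_score, roc_curve

from .simulate import RatingsMatrix

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Annotator screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningResult:
    kept: list[str]
    removed: list[str]
    flagged_no_controls: list[str]
    p_values: dict[str, float]          # raw one-sided p-values
    alpha: float
    correction: str


def _control_outcomes(ratings: RatingsMatrix) -> dict[str, list[int]]:
    """Per-annotator correctness indicators on control items."""
    out: dict[str, list[int]] = {a: [] for a in ratings.annotators}
    for (item, annot), vote in ratings.votes.items():
        label = ratings.labels.get(item, "cand")
        if label == "pos":
            out[annot].append(int(vote == 1))
        elif label == "neg":
            out[annot].append(int(vote == 0))
    return out


def screen_annotators(
    ratings: RatingsMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    method: str = "binomial",
) -> ScreeningResult:
    """Remove annotators whose control accuracy is not significantly above
    chance.

    The default test is an exact one-sided binomial test of the control
    correctness count against 0.5 (a one-sample t-test on the correctness
    indicators is available via ``method="ttest"``), Bonferroni-corrected
    across annotators.  Annotators with no control votes are flagged and
    kept.
    """
    outcomes = _control_outcomes(ratings)
    tested = {a: v for a, v in outcomes.items() if v}
    flagged = [a for a, v in outcomes.items() if not v]
    pvals: dict[str, float] = {}
    for a, v in tested.items():
        k, n = sum(v), len(v)
        if method == "binomial":
            pvals[a] = binomtest(k, n, 0.5, alternative="greater").pvalue
        elif method == "ttest":
            arr = np.asarray(v, dtype=float)
            if np.allclose(arr, arr[0]):
                pvals[a] = 0.0 if arr[0] > 0.5 else 1.0
            else:
                pvals[a] = ttest_1samp(arr, 0.5, alternative="greater").pvalue
        else:
            raise ValueError(f"unknown screening method {method!r}")
    if correction == "bonferroni":
        factor = max(len(pvals), 1)
    elif correction == "none":
        factor = 1
    else:
        raise ValueError(f"unknown correction {correction!r}")
    kept = [a for a in ratings.annotators
            if a in flagged or (a in pvals and min(pvals[a] * factor, 1.0) <= alpha)]
    removed = [a for a in ratings.annotators if a not in kept]
    return ScreeningResult(kept=kept, removed=removed, flagged_no_controls=flagged,
                           p_values=pvals, alpha=alpha, correction=correction)


def drop_annotators(ratings: RatingsMatrix, removed: list[str]) -> RatingsMatrix:
    """Ratings with all votes from the removed annotators excluded."""
    gone = set(removed)
    out = RatingsMatrix(
        items=list(ratings.items),
        annotators=[a for a in ratings.annotators if a not in gone],
        votes={k: v for k, v in ratings.votes.items() if k[1] not in gone},
        labels=dict(ratings.labels),
        headwords=dict(ratings.headwords),
    )
    voted = {k[0] for k in out.votes}
    out.items = [it for it in out.items if it in voted]
    return out


# ---------------------------------------------------------------------------
# Latent-truth agreement model (two-class Dawid–Skene)
# ---------------------------------------------------------------------------


@dataclass
class AgreementFit:
    annotators: list[str]
    sensitivity: np.ndarray      # (A,)
    specificity: np.ndarray      # (A,)
    prevalence: float
    items: list[str]
    posteriors: np.ndarray       # (I,) P(true | votes)
    loglik_trace: np.ndarray
    converged: bool
    degenerate: bool
    seed: int

    def posterior_of(self, item: str) -> float:
        return float(self.posteriors[self.items.index(item)])


def fit_agreement_model(
    ratings: RatingsMatrix,
    init: str = "majority",
    seed: int = 0,
    *,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> AgreementFit:
    """EM fit of the latent-truth model to (screened) ratings.

    Control items have their truths clamped to the labels while the
    parameters are estimated; only candidates carry latent truth.  The
    reported per-item posteriors are the *unclamped* model scores
    P(true | votes, fitted parameters) for every item — controls included —
    so that ROC calibration over controls is meaningful.  The observed-data
    log-likelihood is non-decreasing across EM iterations and the fit is
    deterministic given the seed (used only for the ``init="random"``
    strategy).
    """
    items = list(ratings.items)
    annots = list(ratings.annotators)
    item_ix = {it: i for i, it in enumerate(items)}
    annot_ix = {a: j for j, a in enumerate(annots)}
    I, A = len(items), len(annots)
    rows = np.array([item_ix[it] for (it, a) in ratings.votes], dtype=int)
    cols = np.array([annot_ix[a] for (it, a) in ratings.votes], dtype=int)
    vals = np.array([ratings.votes[k] for k in ratings.votes], dtype=float)
    if I == 0 or len(vals) == 0:
        raise ValueError("no ratings to fit")
    clamp = np.full(I, -1.0)  # -1 latent, else clamped truth
    for it, lab in ratings.labels.items():
        if it in item_ix and lab in ("pos", "neg"):
            clamp[item_ix[it]] = 1.0 if lab == "pos" else 0.0
    degenerate = bool(np.allclose(vals, vals[0]))

    rng = np.random.default_rng(seed)
    # initialization: posterior truth per item
    yes_frac = np.zeros(I)
    counts = np.zeros(I)
    np.add.at(yes_frac, rows, vals)
    np.add.at(counts, rows, 1.0)
    if init == "majority":
        mu = np.clip(yes_frac / np.maximum(counts, 1.0), 0.05, 0.95)
    elif init == "random":
        mu = rng.uniform(0.3, 0.7, size=I)
    else:
        raise ValueError(f"unknown init strategy {init!r}")
    mu = np.where(clamp >= 0, clamp, mu)

    sens = np.full(A, 0.7)
    spec = np.full(A, 0.7)
    prev = 0.5
    scores = mu.copy()
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # M-step from current truth posteriors
        w1 = mu[rows]
        w0 = 1.0 - w1
        yes1 = np.bincount(cols, weights=w1 * vals, minlength=A)
        tot1 = np.bincount(cols, weights=w1, minlength=A)
        no0 = np.bincount(cols, weights=w0 * (1.0 - vals), minlength=A)
        tot0 = np.bincount(cols, weights=w0, minlength=A)
        sens = np.clip((yes1 + _EPS) / (tot1 + 2 * _EPS), 1e-6, 1 - 1e-6)
        spec = np.clip((no0 + _EPS) / (tot0 + 2 * _EPS), 1e-6, 1 - 1e-6)
        free = clamp < 0
        if free.any():
            prev = float(np.clip(mu[free].mean(), 1e-6, 1 - 1e-6))
        # E-step: per-item log-odds of truth
        log_yes1, log_no1 = np.log(sens), np.log1p(-sens)
        log_yes0, log_no0 = np.log1p(-spec), np.log(spec)
        ll1 = np.zeros(I)
        ll0 = np.zeros(I)
        np.add.at(ll1, rows, np.where(vals > 0.5, log_yes1[cols], log_no1[cols]))
        np.add.at(ll0, rows, np.where(vals > 0.5, log_yes0[cols], log_no0[cols]))
        logit = np.log(prev) - np.log1p(-prev) + ll1 - ll0
        scores = 1.0 / (1.0 + np.exp(-logit))
        mu = np.where(clamp >= 0, clamp, scores)
        # observed-data log-likelihood (controls contribute their clamped class)
        p1 = np.where(clamp >= 0, clamp, prev)
        with np.errstate(divide="ignore", invalid="ignore"):
            item_ll = np.logaddexp(np.log(p1) + ll1, np.log(1.0 - p1) + ll0)
        # clamped items with p1 in {0,1}: logaddexp handles -inf cleanly
        item_ll = np.where(clamp == 1.0, ll1, item_ll)
        item_ll = np.where(clamp == 0.0, ll0, item_ll)
        ll = float(item_ll.sum())
        if trace and ll - trace[-1] <= tol * (abs(trace[-1]) + 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    return AgreementFit(
        annotators=annots, sensitivity=sens, specificity=spec, prevalence=prev,
        items=items, posteriors=scores, loglik_trace=np.asarray(trace),
        converged=converged, degenerate=degenerate, seed=seed)


def posterior_bayes(sens: float, spec: float, prevalence: float, vote: int) -> float:
    """Closed-form single-vote posterior, for cross-checking the EM fit."""
    if vote == 1:
        num = sens * prevalence
        den = num + (1.0 - spec) * (1.0 - prevalence)
    else:
        num = (1.0 - sens) * prevalence
        den = num + spec * (1.0 - prevalence)
    return num / den


# ---------------------------------------------------------------------------
# Calibration and filtering
# ---------------------------------------------------------------------------


@dataclass
class Calibration:
    threshold: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    tpr_at_threshold: float
    fpr_at_threshold: float


def calibrate_threshold(fit: AgreementFit, labels: dict[str, str],
                        target_fdr: float = 0.02) -> Calibration:
    """ROC over control items with the posterior as score; the threshold is
    the smallest posterior whose empirical false-positive rate on negative
    controls does not exceed the target."""
    scores, truths = [], []
    for it, lab in labels.items():
        if lab in ("pos", "neg") and it in fit.items:
            scores.append(fit.posterior_of(it))
            truths.append(1 if lab == "pos" else 0)
    if not truths or len(set(truths)) < 2:
        raise ValueError("need at least one positive and one negative control")
    scores_arr = np.asarray(scores)
    truth_arr = np.asarray(truths)
    fpr, tpr, _ = roc_curve(truth_arr, scores_arr)
    auc = float(roc_auc_score(truth_arr, scores_arr))
    neg = np.sort(scores_arr[truth_arr == 0])
    pos = scores_arr[truth_arr == 1]
    # candidate thresholds: observed scores (strict inequality semantics)
    candidates = np.unique(scores_arr)
    threshold = 1.0
    for t in candidates:
        fp = float((neg > t).mean())
        if fp <= target_fdr:
            threshold = float(t)
            break
    tpr_at = float((pos > threshold).mean())
    fpr_at = float((neg > threshold).mean())
    return Calibration(threshold=threshold, roc_fpr=fpr, roc_tpr=tpr, auc=auc,
                       tpr_at_threshold=tpr_at, fpr_at_threshold=fpr_at)


def filter_candidates(
    posteriors: dict[str, float],
    threshold: float,
    headwords: dict[str, str] | None = None,
) -> tuple[list[tuple[str, float]], int]:
    """Candidates with posterior strictly above the threshold, plus the count
    of distinct headwords among them.  Output order is by item id, so the
    result is invariant to input order."""
    accepted = sorted((it, p) for it, p in posteriors.items() if p > threshold)
    heads = {headwords[it] for it, _ in accepted if headwords and it in headwords} \
        if headwords else set()
    return accepted, len(heads)
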