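"""Synonym-knockdown recall curves and the redundancy-mixture estimator.

Randomly removing synonyms from a terminology and re-running normalization
reveals redundancy: if every recalled concept depended on a single synonym,
recall of the synonym-attributable concepts falls linearly with the
retention fraction f; concepts reachable through m interchangeable synonyms
survive with probability 1 - (1-f)^m, bending the curve upward.  Fitting
recall(f) = sum_m w_m (1 - (1-f)^m) over a simplex of multiplicity weights
w recovers the redundancy structure; the redundant synonym fraction is the
expected share of usable synonym mappings beyond the first,
sum_m w_m (m-1) / sum_m w_m m.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .io import Compendium, TermRecord

Normalizer = Callable[[str], str | None]
NormalizerFactory = Callable[[Compendium], Normalizer]


def _fold(text: str) -> str:
    return " ".join(unicodedata.normalize("NFC", text).casefold().split())


def exact_match_normalizer(terminology: Compendium) -> Normalizer:
    """Case-folded, whitespace-normalized exact lookup.

    Terms mapping to two or more concepts are ambiguous and resolve to None.
    """
    table: dict[str, str | None] = {}
    for cid, rec in terminology.iter_records():
        key = _fold(rec.term)
        if key in table and table[key] != cid:
            table[key] = None
        else:
            table[key] = cid

    def normalize(mention: str) -> str | None:
        return table.get(_fold(mention))

    return normalize


@dataclass
class RecallCurve:
    fractions: np.ndarray   # (F,) synonym retention fractions
    recall: np.ndarray      # (F, R) per-fraction, per-replicate recall
    n_attributable: int     # size of the synonym-attributable concept set
    seed: int

    @property
    def mean_recall(self) -> np.ndarray:
        return self.recall.mean(axis=1)


def _knockdown(terminology: Compendium, keep: set[tuple[str, str]]) -> Compendium:
    out = Compendium(terminology.resources, mode=terminology.mode)
    for cid, rec in terminology.iter_records():
        if rec.is_preferred or (cid, rec.term) in keep:
            out.add_record(cid, TermRecord(rec.term, rec.presence, rec.is_preferred))
    return out


def knockdown_recall(
    terminology: Compendium,
    corpus: Iterable[tuple[str, str]],
    normalizer: NormalizerFactory = exact_match_normalizer,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    replicates: int = 5,
    seed: int = 0,
) -> RecallCurve:
    """Recall of synonym-attributable concepts vs synonym retention.

    The corpus is first reduced to unique mention-concept pairs.  Preferred
    terms are never removed; each non-preferred synonym record is retained
    independently with probability f.  The denominator is the set of concepts
    recalled with the full terminology but not with all synonyms removed —
    the concepts whose recall is attributable to synonymy.
    """
    pairs = list(dict.fromkeys(corpus))
    if not pairs:
        raise ValueError("empty mention corpus")
    by_concept: dict[str, list[str]] = {}
    for mention, cid in pairs:
        by_concept.setdefault(cid, []).append(mention)

    def recalled(norm: Normalizer) -> set[str]:
        hits = set()
        for cid, mentions in by_concept.items():
            if any(norm(m) == cid for m in mentions):
                hits.add(cid)
        return hits

    synonyms = [(cid, rec.term) for cid, rec in terminology.iter_records()
                if not rec.is_preferred]
    full = recalled(normalizer(terminology))
    bare = recalled(normalizer(_knockdown(terminology, set())))
    attributable = full - bare
    if not attributable:
        raise ValueError("no concept's recall is attributable to synonymy")

    fractions_arr = np.asarray(sorted(fractions), dtype=float)
    rng = np.random.default_rng(seed)
    recall = np.zeros((len(fractions_arr), replicates))
    for r in range(replicates):
        for fi, f in enumerate(fractions_arr):
            mask = rng.random(len(synonyms)) < f
            keep = {syn for syn, m in zip(synonyms, mask) if m}
            hits = recalled(normalizer(_knockdown(terminology, keep)))
            recall[fi, r] = len(hits & attributable) / len(attributable)
    return RecallCurve(fractions=fractions_arr, recall=recall,
                       n_attributable=len(attributable), seed=seed)


@dataclass
class RedundancyEstimate:
    weights: np.ndarray                     # (M,) simplex over m = 1..M
    fraction_concepts_redundant: float      # sum_{m>=2} w_m
    redundant_synonym_fraction: float       # sum w_m (m-1) / sum w_m m
    ci_fraction_concepts_redundant: tuple[float, float]
    ci_redundant_synonym_fraction: tuple[float, float]
    degenerate: bool = False


def _fit_weights(fractions: np.ndarray, recall: np.ndarray, m_max: int) -> np.ndarray:
    """Simplex-constrained least squares for recall(f) = sum w_m (1-(1-f)^m)."""
    ms = np.arange(1, m_max + 1)
    design = 1.0 - (1.0 - fractions[:, None]) ** ms[None, :]   # (F, M)

    def loss(w: np.ndarray) -> float:
        return float(((design @ w - recall) ** 2).sum())

    w0 = np.full(m_max, 1.0 / m_max)
    res = minimize(loss, w0, method="SLSQP",
                   bounds=[(0.0, 1.0)] * m_max,
                   constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
                   options={"maxiter": 500, "ftol": 1e-12})
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def _redundant_fraction(w: np.ndarray) -> float:
    ms = np.arange(1, len(w) + 1)
    return float((w * (ms - 1)).sum() / (w * ms).sum())


def estimate_redundancy(
    curve: RecallCurve,
    m_max: int = 10,
    bootstrap: int = 1000,
    seed: int = 0,
) -> RedundancyEstimate:
    """Fit the multiplicity mixture to a knockdown curve.

    The 95% intervals come from bootstrapping over replicates.  An all-equal
    (degenerate) curve is flagged: the weights are undefined there.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    if len(curve.fractions) < 3:
        raise ValueError("need at least 3 distinct retention fractions")
    if np.allclose(curve.recall, curve.recall.flat[0]):
        return RedundancyEstimate(
            weights=np.full(m_max, np.nan),
            fraction_concepts_redundant=float("nan"),
            redundant_synonym_fraction=float("nan"),
            ci_fraction_concepts_redundant=(float("nan"), float("nan")),
            ci_redundant_synonym_fraction=(float("nan"), float("nan")),
            degenerate=True,
        )
    w = _fit_weights(curve.fractions, curve.mean_recall, m_max)
    rng = np.random.default_rng(seed)
    n_rep = curve.recall.shape[1]
    boot_frac, boot_red = [], []
    for _ in range(bootstrap):
        idx = rng.integers(0, n_rep, size=n_rep)
        wb = _fit_weights(curve.fractions, curve.recall[:, idx].mean(axis=1), m_max)
        boot_frac.append(float(wb[1:].sum()))
        boot_red.append(_redundant_fraction(wb))
    return RedundancyEstimate(
        weights=w,
        fraction_concepts_redundant=float(w[1:].sum()),
        redundant_synonym_fraction=_redundant_fraction(w),
        ci_fraction_concepts_redundant=(
            float(np.quantile(boot_frac, 0.025)), float(np.quantile(boot_frac, 0.975))),
        ci_redundant_synonym_fraction=(
            float(np.quantile(boot_red, 0.025)), float(np.quantile(boot_red, 0.975))),
    )
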