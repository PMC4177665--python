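"""Generative simulators with known ground truth.

Everything downstream (the capture model, the knockdown estimator, the
annotator-agreement model) is exercised against data drawn from its own
generative story, so recovery and coverage can be checked without any
external resource.  All simulators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Compendium, ResourceSet, TermRecord
from .model import ModelParams, hidden_concept_prob


@dataclass
class GroundTruth:
    """The latent state behind one simulated compendium."""

    params: ModelParams
    c_total: int
    seed: int
    concept_class: np.ndarray        # (C_total,) latent concept classes
    true_term_counts: np.ndarray     # (C_total,) N_i
    n_hidden_concepts: int = 0
    n_observed_concepts: int = 0
    n_hidden_terms: int = 0
    n_observed_terms: int = 0
    n_total_terms: int = 0

    def summary(self) -> dict:
        return {
            "c_total": self.c_total,
            "seed": self.seed,
            "n_hidden_concepts": self.n_hidden_concepts,
            "n_observed_concepts": self.n_observed_concepts,
            "n_hidden_terms": self.n_hidden_terms,
            "n_observed_terms": self.n_observed_terms,
            "n_total_terms": self.n_total_terms,
            "fraction_concepts_hidden": self.n_hidden_concepts / self.c_total,
            "fraction_terms_hidden": self.n_hidden_terms / max(self.n_total_terms, 1),
        }


def simulate_compendium(
    params: ModelParams,
    c_total: int,
    resources: ResourceSet,
    seed: int,
    *,
    mode: str = "undirected_concepts",
) -> tuple[Compendium, GroundTruth]:
    """Draw a compendium from the capture mixture's generative story.

    Per concept: class z ~ w; N ~ Geometric(theta_z) on N >= 1; each of the
    N relationships gets a term class c ~ pi_z and independent Bernoulli(q[d,c])
    detections.  Concepts with no detected relationship are excluded from the
    compendium but tallied in the ground truth.  In ``undirected_concepts``
    mode the first detected term of each observed concept is marked preferred.
    """
    if c_total < 1:
        raise ValueError("c_total must be >= 1")
    if params.n_resources != resources.d:
        raise ValueError("params and resources disagree on D")
    rng = np.random.default_rng(seed)
    Z = params.n_concept_classes
    z_i = rng.choice(Z, size=c_total, p=params.w)
    n_i = rng.geometric(1.0 - params.theta[z_i])  # support >= 1, mean 1/(1-theta)
    comp = Compendium(resources, mode=mode)  # type: ignore[arg-type]
    truth = GroundTruth(params=params, c_total=c_total, seed=seed,
                        concept_class=z_i, true_term_counts=n_i)
    truth.n_total_terms = int(n_i.sum())
    for i in range(c_total):
        z = z_i[i]
        n = n_i[i]
        classes = rng.choice(params.n_term_classes, size=n, p=params.pi[z])
        detected = rng.random((n, resources.d)) < params.q[:, classes].T
        observed = detected.any(axis=1)
        n_obs = int(observed.sum())
        truth.n_hidden_terms += int(n - n_obs)
        truth.n_observed_terms += n_obs
        if n_obs == 0:
            truth.n_hidden_concepts += 1
            continue
        truth.n_observed_concepts += 1
        cid = f"c{i}"
        first = True
        for j in np.flatnonzero(observed):
            rec = TermRecord(
                term=f"c{i}_t{j}",
                presence=tuple(int(b) for b in detected[j]),
                is_preferred=first and mode == "undirected_concepts",
            )
            comp.add_record(cid, rec)
            first = False
    comp.validate()
    return comp, truth


def expected_hidden_fraction(params: ModelParams) -> float:
    """Closed-form check value for the simulator's hidden-concept rate."""
    return hidden_concept_prob(params)[1]


@dataclass
class MentionCorpus:
    """Unique mention-concept pairs with known redundancy multiplicity."""

    mentions: list[tuple[str, str, int]]  # (mention string, concept_id, m)
    seed: int

    def __len__(self) -> int:
        return len(self.mentions)


def simulate_mention_corpus(
    compendium: Compendium,
    multiplicity_dist: dict[int, float],
    n_mentions: int,
    seed: int,
) -> MentionCorpus:
    """Build a mention corpus whose concept-recall redundancy is known.

    A concept assigned multiplicity m contributes m unique mention-concept
    pairs, each mention exactly matching a distinct non-preferred synonym, so
    under exact-match normalization the concept is recalled at synonym
    retention f with probability 1 - (1-f)^m.
    """
    if n_mentions == 0:
        return MentionCorpus(mentions=[], seed=seed)
    ms = sorted(multiplicity_dist)
    weights = np.array([multiplicity_dist[m] for m in ms], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("multiplicity weights must form a simplex")
    if min(ms) < 1:
        raise ValueError("multiplicities must be >= 1")
    rng = np.random.default_rng(seed)
    pools: dict[str, list[str]] = {}
    for cid, entry in compendium.entries.items():
        syns = [t.term for t in entry.terms if not t.is_preferred]
        if syns:
            pools[cid] = syns
    # quota per multiplicity so the realized concept-level mixture matches
    # the requested weights: n_concepts * sum_m w_m * m ~= n_mentions
    mean_m = float(weights @ np.asarray(ms))
    n_concepts = max(int(round(n_mentions / mean_m)), 1)
    quotas = {m: int(round(n_concepts * w)) for m, w in zip(ms, weights)}
    order = list(pools)
    rng.shuffle(order)
    used: set[str] = set()
    mentions: list[tuple[str, str, int]] = []
    for m in sorted(quotas, reverse=True):  # scarce (large-m) pools first
        needed = quotas[m]
        for cid in order:
            if needed == 0:
                break
            if cid in used or len(pools[cid]) < m:
                continue
            used.add(cid)
            chosen = rng.choice(len(pools[cid]), size=m, replace=False)
            for k in chosen:
                mentions.append((pools[cid][k], cid, m))
            needed -= 1
        if needed > 0:
            raise ValueError(
                f"compendium too small for the requested corpus: short "
                f"{needed} concepts of multiplicity {m}"
            )
    return MentionCorpus(mentions=mentions, seed=seed)


@dataclass
class RatingsMatrix:
    """Sparse item x annotator binary judgments with control labels."""

    items: list[str]
    annotators: list[str]
    votes: dict[tuple[str, str], int] = field(default_factory=dict)  # (item, annot) -> 0/1
    labels: dict[str, str] = field(default_factory=dict)  # item -> pos|neg|cand
    headwords: dict[str, str] = field(default_factory=dict)  # item -> headword

    def votes_for(self, item: str) -> dict[str, int]:
        return {a: v for (it, a), v in self.votes.items() if it == item}

    def validate(self) -> None:
        per_item: dict[str, int] = dict.fromkeys(self.items, 0)
        for (it, _a) in self.votes:
            per_item[it] += 1
        missing = [it for it, k in per_item.items() if k == 0]
        if missing:
            raise ValueError(f"items without any vote: {missing[:5]}")


def simulate_ratings(
    n_items: int,
    prevalence: float,
    annotators: list[tuple[float, float]],
    assignment: int,
    seed: int,
    *,
    control_fraction: float = 0.2,
) -> tuple[RatingsMatrix, np.ndarray]:
    """Simulate a crowd-validation experiment.

    Latent truths are Bernoulli(prevalence); annotator a votes yes with
    probability sensitivity_a on true items and 1 - specificity_a on false
    ones.  ``assignment`` is the number of distinct annotators voting on each
    item.  A fraction of items (half positive, half negative, drawn to match
    their truths) are flagged as controls.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be a probability")
    for s, t in annotators:
        if not (0.0 < s < 1.0 and 0.0 < t < 1.0):
            raise ValueError("annotator rates must lie in (0, 1)")
    if assignment > len(annotators):
        raise ValueError("more votes per item than annotators")
    rng = np.random.default_rng(seed)
    truth = (rng.random(n_items) < prevalence).astype(int)
    item_ids = [f"item{i}" for i in range(n_items)]
    annot_ids = [f"annot{a}" for a in range(len(annotators))]
    sens = np.array([s for s, _ in annotators])
    spec = np.array([t for _, t in annotators])
    mat = RatingsMatrix(items=item_ids, annotators=annot_ids)
    for i in range(n_items):
        chosen = rng.choice(len(annotators), size=assignment, replace=False)
        for a in chosen:
            p_yes = sens[a] if truth[i] else 1.0 - spec[a]
            mat.votes[(item_ids[i], annot_ids[a])] = int(rng.random() < p_yes)
    # controls: a seeded subset with truths revealed
    n_ctrl = int(round(control_fraction * n_items))
    ctrl = rng.choice(n_items, size=n_ctrl, replace=False)
    for i in range(n_items):
        mat.labels[item_ids[i]] = "cand"
    for i in ctrl:
        mat.labels[item_ids[i]] = "pos" if truth[i] else "neg"
    mat.validate()
    return mat, truth
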