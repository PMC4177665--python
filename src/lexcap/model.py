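"""Multi-list Poisson-capture mixture model for undocumented synonymy.

The generative story: a linguistic domain contains ``C_total`` concepts.
Concept i belongs to a latent class z (mixture weight ``w_z``) and carries
``N_i >= 1`` true concept-term relationships, geometrically distributed
with class parameter ``theta_z`` (P(N) = (1-theta) theta^(N-1), mean
1/(1-theta)).  Each relationship belongs to a latent term class c drawn
from the class-specific simplex ``pi_z`` and is annotated ("captured") by
resource d independently with probability ``q[d, c]``.  Annotation events
follow a Poisson process with rate lambda, but since only presence/absence
is observed, the rate and its prior are identifiable only through the
detection probability q = 1 - E[exp(-lambda)], which is what we
parameterize.  A relationship missed by every resource is undocumented; a
concept whose relationships are all missed is entirely absent from the
compendium, so observed concepts are a zero-truncated sample.

Inference is an expectation-maximization scheme on the zero-truncated
likelihood: each observed concept is treated as the first detected unit in
an i.i.d. stream of concepts, so the number of entirely-undetected concepts
accompanying it is geometric in the marginal hidden-concept probability and
can be imputed in closed form.  Parameter point estimates are MAP under
Beta/Dirichlet hyperpriors; the conjugate pseudo-count posteriors built
from the same expected sufficient statistics serve as an approximate
(variational-style) posterior from which Monte-Carlo credible intervals
are drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import nbinom

from .io import Compendium

_EPS = 1e-12
_U_MAX = 1.0 - 1e-12
_P_MIN = 1e-9  # probabilities are kept strictly inside (0, 1)


# ---------------------------------------------------------------------------
# Parameters and configuration
# ---------------------------------------------------------------------------


@dataclass
class Hyperparams:
    """Conjugate hyperprior settings (flat by default)."""

    beta_q: tuple[float, float] = (1.0, 1.0)
    beta_theta: tuple[float, float] = (1.0, 1.0)
    dirichlet_w: float = 1.0
    dirichlet_pi: float = 1.0


@dataclass
class ModelParams:
    """Mixture parameters.

    w : (Z,) concept-class weights (simplex).
    theta : (Z,) geometric parameters for the true relationship count.
    pi : (Z, C) per-concept-class term-class mixing (rows on the simplex).
    q : (D, C) detection probability of a class-c relationship by resource d.
    """

    w: np.ndarray
    theta: np.ndarray
    pi: np.ndarray
    q: np.ndarray
    hyperparams: Hyperparams = field(default_factory=Hyperparams)

    def __post_init__(self) -> None:
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.pi = np.atleast_2d(np.asarray(self.pi, dtype=float))
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        z, c, d = self.n_concept_classes, self.n_term_classes, self.n_resources
        if self.w.shape != (z,) or self.theta.shape != (z,) or self.pi.shape != (z, c):
            raise ValueError("inconsistent parameter dimensions")
        if not np.isclose(self.w.sum(), 1.0):
            raise ValueError("w must sum to 1")
        if not np.allclose(self.pi.sum(axis=1), 1.0):
            raise ValueError("pi rows must sum to 1")
        if np.any(self.theta <= 0.0) or np.any(self.theta >= 1.0):
            raise ValueError("theta must lie strictly inside (0, 1)")
        if np.any(self.q < 0.0) or np.any(self.q > 1.0):
            raise ValueError("q must lie in [0, 1]")

    @property
    def n_concept_classes(self) -> int:
        return self.pi.shape[0]

    @property
    def n_term_classes(self) -> int:
        return self.pi.shape[1]

    @property
    def n_resources(self) -> int:
        return self.q.shape[0]

    @property
    def miss(self) -> np.ndarray:
        """(C,) probability a class-c relationship escapes every resource."""
        with np.errstate(divide="ignore"):
            return np.exp(np.log1p(-self.q).sum(axis=0))

    @property
    def u(self) -> np.ndarray:
        """(Z,) all-resource miss probability of a class-z concept's term."""
        return np.minimum(self.pi @ self.miss, _U_MAX)

    @classmethod
    def single_class(cls, q: Sequence[float], theta: float, **kw) -> "ModelParams":
        q = np.asarray(q, dtype=float).reshape(-1, 1)
        return cls(w=np.array([1.0]), theta=np.array([theta]),
                   pi=np.array([[1.0]]), q=q, **kw)


@dataclass
class MixtureConfig:
    n_concept_classes: int = 10
    n_term_classes: int = 4
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    restarts: int = 5
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 500
    # If True the preferred term is conditioned upon rather than sampled:
    # the geometric prior then governs synonym counts (support N >= 0) and
    # no concept can be entirely hidden.
    condition_on_preferred: bool = False


# ---------------------------------------------------------------------------
# Closed-form building blocks
# ---------------------------------------------------------------------------


def detection_prob(lambda_rate: float | np.ndarray) -> float | np.ndarray:
    """Probability of at least one capture under a Poisson(lambda) process."""
    lam = np.asarray(lambda_rate, dtype=float)
    if np.any(lam < 0):
        raise ValueError("Poisson rate must be nonnegative")
    out = -np.expm1(-lam)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MissingTermsPosterior:
    """Posterior over the number of undocumented relationships of a concept.

    With n observed relationships, geometric parameter theta and all-resource
    miss probability u, the count of missing relationships j = N - n follows
    a negative-binomial-shaped posterior proportional to C(n+j, n) (theta*u)^j,
    i.e. NB(n+1, 1 - theta*u), with mean (n+1) theta u / (1 - theta u).
    """

    n_obs: int
    x: float  # theta * u

    @property
    def mean(self) -> float:
        return (self.n_obs + 1) * self.x / (1.0 - self.x)

    @property
    def variance(self) -> float:
        return (self.n_obs + 1) * self.x / (1.0 - self.x) ** 2

    def pmf(self, j: np.ndarray | int) -> np.ndarray | float:
        return nbinom.pmf(j, self.n_obs + 1, 1.0 - self.x)

    def quantile(self, p: float | np.ndarray) -> float | np.ndarray:
        return nbinom.ppf(p, self.n_obs + 1, 1.0 - self.x)


def posterior_missing_terms(n_obs: int, theta: float, miss_prob: float) -> MissingTermsPosterior:
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if not (0.0 <= theta < 1.0 and 0.0 <= miss_prob < 1.0):
        raise ValueError("theta and miss_prob must lie in [0, 1)")
    x = theta * miss_prob
    if x >= 1.0:
        raise ValueError("theta * miss_prob must be < 1")
    return MissingTermsPosterior(n_obs=n_obs, x=x)


def hidden_concept_prob(params: ModelParams) -> tuple[np.ndarray, float]:
    """Per-class and marginal probability a concept is entirely undocumented.

    Averaging the geometric generating function over N >= 1 gives
    P_hidden(z) = u_z (1 - theta_z) / (1 - theta_z u_z).
    """
    u = params.u
    per_class = u * (1.0 - params.theta) / (1.0 - params.theta * u)
    return per_class, float(params.w @ per_class)


@dataclass
class ConceptSufficientStats:
    """Observed capture histories of one concept: a list of presence patterns."""

    patterns: list[tuple[int, ...]]

    @property
    def n_obs(self) -> int:
        return len(self.patterns)


def _pattern_logprob(params: ModelParams, patterns: np.ndarray) -> np.ndarray:
    """(P, C) log-probability of each nonzero presence pattern per term class.

    Boundary detection probabilities (0 or 1) yield exact -inf entries for
    impossible patterns rather than NaNs from 0 * inf products.
    """
    with np.errstate(divide="ignore"):
        logq = np.log(params.q)          # (D, C)
        log1q = np.log1p(-params.q)
    picked = np.where(patterns[:, :, None] == 1, logq[None, :, :], log1q[None, :, :])
    return picked.sum(axis=1)


def concept_loglik(stats: ConceptSufficientStats, params: ModelParams) -> float:
    """Unconditional log-marginal likelihood of one concept's capture data.

    Marginalizes the concept class, each observed term's class, and the
    geometric tail of unobserved terms:  sum_N Geom(N) C(N, n) u^(N-n)
    collapses to (1-theta) theta^(n-1) (1 - theta u)^(-(n+1)).
    """
    n = stats.n_obs
    if n < 1:
        raise ValueError("a documented concept has at least one observed term")
    B = np.asarray(stats.patterns, dtype=float)
    if B.shape[1] != params.n_resources:
        raise ValueError("pattern length does not match the number of resources")
    patlp = _pattern_logprob(params, B)  # (n, C)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)        # (Z, C)
        logw = np.log(params.w)
    # per-term log prob under each concept class: (n, Z)
    per_term = logsumexp(patlp[:, None, :] + logpi[None, :, :], axis=2)
    u = params.u
    th = params.theta
    tail = np.log1p(-th) + (n - 1) * np.log(th) - (n + 1) * np.log1p(-th * u)
    return float(logsumexp(logw + tail + per_term.sum(axis=0)))


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


@dataclass
class _CaptureData:
    patterns: np.ndarray       # (P, D) distinct nonzero presence patterns
    pat_of_term: np.ndarray    # (T,) pattern index per observed term
    concept_of_term: np.ndarray  # (T,) concept index per observed term
    n_obs: np.ndarray          # (I,) observed terms per concept
    concept_ids: list[str]

    @property
    def n_concepts(self) -> int:
        return len(self.n_obs)

    @property
    def n_terms(self) -> int:
        return len(self.pat_of_term)


def _prepare(compendium: Compendium, *, drop_preferred: bool = False) -> _CaptureData:
    pat_index: dict[tuple[int, ...], int] = {}
    pats: list[tuple[int, ...]] = []
    pat_of_term: list[int] = []
    concept_of_term: list[int] = []
    n_obs: list[int] = []
    concept_ids: list[str] = []
    for cid, entry in compendium.entries.items():
        recs = [r for r in entry.terms if not (drop_preferred and r.is_preferred)]
        if not recs:
            continue
        i = len(concept_ids)
        concept_ids.append(cid)
        n_obs.append(len(recs))
        for rec in recs:
            p = pat_index.setdefault(rec.presence, len(pats))
            if p == len(pats):
                pats.append(rec.presence)
            pat_of_term.append(p)
            concept_of_term.append(i)
    return _CaptureData(
        patterns=np.asarray(pats, dtype=float),
        pat_of_term=np.asarray(pat_of_term, dtype=np.int64),
        concept_of_term=np.asarray(concept_of_term, dtype=np.int64),
        n_obs=np.asarray(n_obs, dtype=np.int64),
        concept_ids=concept_ids,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class PseudoPosterior:
    """Conjugate pseudo-count posteriors over the model parameters.

    Natural parameters are hyperprior plus expected sufficient statistics at
    convergence — the conjugate parameter factors of a mean-field scheme.
    """

    q_a: np.ndarray      # (D, C) Beta alpha for q
    q_b: np.ndarray      # (D, C) Beta beta for q
    theta_a: np.ndarray  # (Z,) Beta alpha for theta (successes ~ extra terms)
    theta_b: np.ndarray  # (Z,)
    w_alpha: np.ndarray  # (Z,) Dirichlet
    pi_alpha: np.ndarray  # (Z, C) Dirichlet per row


@dataclass
class FitResult:
    params: ModelParams
    config: MixtureConfig
    responsibilities: np.ndarray        # (I, Z) concept-class posteriors
    objective_trace: np.ndarray         # per-iteration penalized loglik (best restart)
    restart_objectives: np.ndarray      # final objective of each restart
    converged: bool
    seed: int
    posterior: PseudoPosterior
    data: _CaptureData

    @property
    def n_obs_concepts(self) -> int:
        return self.data.n_concepts

    def term_class_posterior(self) -> np.ndarray:
        """(T, C) marginal term-class posterior for every observed term."""
        patlp = _pattern_logprob(self.params, self.data.patterns)
        logpi = np.log(np.clip(self.params.pi, _EPS, None))
        g = np.exp(patlp[:, None, :] + logpi[None, :, :])   # (P, Z, C)
        g /= g.sum(axis=2, keepdims=True)
        r_term = self.responsibilities[self.data.concept_of_term]  # (T, Z)
        return np.einsum("tz,tzc->tc", r_term, g[self.data.pat_of_term])


def _log_prior(params: ModelParams, hp: Hyperparams) -> float:
    aq, bq = hp.beta_q
    at, bt = hp.beta_theta
    lp = np.sum((aq - 1) * np.log(params.q) + (bq - 1) * np.log1p(-params.q))
    lp += np.sum((at - 1) * np.log(params.theta) + (bt - 1) * np.log1p(-params.theta))
    lp += np.sum((hp.dirichlet_w - 1) * np.log(params.w))
    lp += np.sum((hp.dirichlet_pi - 1) * np.log(np.clip(params.pi, _EPS, None)))
    return float(lp)


def _e_quantities(params: ModelParams, data: _CaptureData, *, truncated: bool,
                  geom_offset: int):
    """Everything the E-step needs, computed at the current parameters."""
    patlp = _pattern_logprob(params, data.patterns)          # (P, C)
    with np.errstate(divide="ignore"):
        logpi = np.log(np.clip(params.pi, _EPS, None))       # (Z, C)
    term_lp = logsumexp(patlp[:, None, :] + logpi[None, :, :], axis=2)  # (P, Z)
    I, Z = data.n_concepts, params.n_concept_classes
    per_concept = np.zeros((I, Z))
    np.add.at(per_concept, data.concept_of_term, term_lp[data.pat_of_term])
    u = params.u
    th = params.theta
    x = th * u
    n = data.n_obs[:, None].astype(float)
    # geometric exponent: (n - 1) for support N>=1, n for the synonym-count
    # variant with support N>=0
    tail = np.log1p(-th) + (n - 1 + geom_offset) * np.log(th) \
        - (n + 1) * np.log1p(-x)
    logjoint = np.log(params.w) + tail + per_concept         # (I, Z)
    ll_marg = logsumexp(logjoint, axis=1)
    resp = np.exp(logjoint - ll_marg[:, None])
    if truncated:
        ph_z = u * (1.0 - th) / (1.0 - x)
        ph = float(params.w @ ph_z)
    else:
        ph_z = np.zeros(Z)
        ph = 0.0
    loglik = float(ll_marg.sum()) - I * math.log1p(-ph)
    return patlp, logpi, u, x, resp, loglik, ph_z, ph


def _m_step(params: ModelParams, data: _CaptureData, hp: Hyperparams, *,
            truncated: bool, geom_offset: int):
    """One EM sweep; returns (new params, objective at the *old* params,
    pseudo-count posteriors built from the old-parameter expectations)."""
    patlp, logpi, u, x, resp, loglik, ph_z, ph = _e_quantities(
        params, data, truncated=truncated, geom_offset=geom_offset)
    I = data.n_concepts
    Z, C = params.n_concept_classes, params.n_term_classes
    objective = loglik + _log_prior(params, hp)

    # expected hidden concepts per class (zero-truncation augmentation)
    if truncated and ph > 0.0:
        h_total = I * ph / (1.0 - ph)
        h_z = h_total * (params.w * ph_z) / ph
    else:
        h_z = np.zeros(Z)
    # expected missing relationships
    n = data.n_obs[:, None].astype(float)
    m_doc = (n + 1) * x / (1.0 - x)                      # (I, Z)
    en_hidden = 1.0 / (1.0 - x)                          # (Z,) mean N | hidden

    # --- sufficient statistics -------------------------------------------
    r_sum = resp.sum(axis=0) + h_z                        # concepts per class
    terms_obs_z = (resp * n).sum(axis=0)                  # observed terms
    miss_doc_z = (resp * m_doc).sum(axis=0)               # missing @ documented
    miss_hid_z = h_z * en_hidden                          # terms @ hidden
    total_terms_z = terms_obs_z + miss_doc_z + miss_hid_z

    # geometric theta: successes = terms beyond the support minimum
    min_terms = (1 - geom_offset) * r_sum
    at, bt = hp.beta_theta
    theta_a = total_terms_z - min_terms + at
    theta_b = r_sum + bt
    theta = np.clip((theta_a - 1) / np.maximum(theta_a + theta_b - 2, _EPS),
                    _P_MIN, 1 - _P_MIN)

    # concept-class weights
    aw = hp.dirichlet_w
    w_alpha = r_sum + aw
    w = np.maximum(w_alpha - 1, _EPS)
    w = w / w.sum()

    # term-class assignments of observed terms, aggregated by pattern
    P = data.patterns.shape[0]
    W = np.zeros((P, Z))
    np.add.at(W, data.pat_of_term, resp[data.concept_of_term])
    g = np.exp(patlp[:, None, :] + logpi[None, :, :])     # (P, Z, C)
    g /= np.maximum(g.sum(axis=2, keepdims=True), _EPS)
    g_obs_zc = np.einsum("pz,pzc->zc", W, g)              # (Z, C)
    # undetected relationships: class posterior ~ pi_zc * miss_c / u_z
    miss_c = params.miss
    undet_class = params.pi * miss_c[None, :] / u[:, None]
    g_miss_zc = (miss_doc_z + miss_hid_z)[:, None] * undet_class
    api = hp.dirichlet_pi
    pi_alpha = g_obs_zc + g_miss_zc + api
    pi = np.maximum(pi_alpha - 1, _EPS)
    pi = pi / pi.sum(axis=1, keepdims=True)

    # detection probabilities: per (d, c) successes over per-class trials
    U = np.einsum("pz,pzc->pc", W, g)                     # (P, C)
    succ = data.patterns.T @ U                            # (D, C)
    trials = U.sum(axis=0) + g_miss_zc.sum(axis=0)        # (C,)
    aq, bq = hp.beta_q
    q_a = succ + aq
    q_b = trials[None, :] - succ + bq
    q = np.clip((q_a - 1) / np.maximum(q_a + q_b - 2, _EPS), _P_MIN, 1 - _P_MIN)

    new = ModelParams(w=w, theta=theta, pi=pi, q=q, hyperparams=hp)
    post = PseudoPosterior(q_a=q_a, q_b=q_b,
                           theta_a=theta_a, theta_b=theta_b,
                           w_alpha=w_alpha, pi_alpha=pi_alpha)
    return new, objective, post, resp


def _init_params(rng: np.random.Generator, z: int, c: int, d: int,
                 hp: Hyperparams) -> ModelParams:
    w = rng.dirichlet(np.full(z, 5.0))
    pi = rng.dirichlet(np.full(c, 5.0), size=z)
    theta = rng.uniform(0.25, 0.75, size=z)
    q = rng.uniform(0.1, 0.8, size=(d, c))
    return ModelParams(w=w, theta=theta, pi=pi, q=q, hyperparams=hp)


def _sort_classes(params: ModelParams, post: PseudoPosterior, resp: np.ndarray):
    """Canonical label order: term classes by decreasing marginal detection,
    concept classes by decreasing expected relationship count."""
    c_order = np.argsort(-(1.0 - params.miss), kind="stable")
    z_order = np.argsort(-params.theta, kind="stable")
    params = ModelParams(
        w=params.w[z_order], theta=params.theta[z_order],
        pi=params.pi[np.ix_(z_order, c_order)], q=params.q[:, c_order],
        hyperparams=params.hyperparams)
    post = PseudoPosterior(
        q_a=post.q_a[:, c_order], q_b=post.q_b[:, c_order],
        theta_a=post.theta_a[z_order], theta_b=post.theta_b[z_order],
        w_alpha=post.w_alpha[z_order],
        pi_alpha=post.pi_alpha[np.ix_(z_order, c_order)])
    return params, post, resp[:, z_order]


def fit(compendium: Compendium, config: MixtureConfig | None = None) -> FitResult:
    """Fit the capture mixture by seeded, multi-restart EM.

    The traced objective (zero-truncated log-likelihood plus log-hyperprior)
    is non-decreasing within each restart; the best restart is returned.
    Non-convergence within ``max_iter`` sets ``converged=False`` rather than
    raising.
    """
    config = config or MixtureConfig()
    if compendium.resources.d < 2:
        raise ValueError("at least two resources are required for fitting")
    drop_pref = config.condition_on_preferred and compendium.mode == "undirected_concepts"
    data = _prepare(compendium, drop_preferred=drop_pref)
    if data.n_concepts == 0:
        raise ValueError("no documented concepts to fit")
    truncated = not config.condition_on_preferred
    geom_offset = 0 if truncated else 1
    hp = config.hyperparams
    z, c, d = config.n_concept_classes, config.n_term_classes, compendium.resources.d

    best = None
    restart_objs = []
    root = np.random.SeedSequence(config.seed)
    for child in root.spawn(max(config.restarts, 1)):
        rng = np.random.default_rng(child)
        params = _init_params(rng, z, c, d, hp)
        trace: list[float] = []
        converged = False
        post = resp = None
        for _ in range(config.max_iter):
            params_new, obj, post, resp = _m_step(
                params, data, hp, truncated=truncated, geom_offset=geom_offset)
            if trace and obj - trace[-1] <= config.tol * (abs(trace[-1]) + 1.0):
                trace.append(obj)
                converged = True
                params = params_new
                break
            trace.append(obj)
            params = params_new
        # one final E-pass so posterior/responsibilities match the last params
        _, final_obj, post, resp = _m_step(
            params, data, hp, truncated=truncated, geom_offset=geom_offset)
        restart_objs.append(final_obj)
        if best is None or final_obj > best[0]:
            best = (final_obj, params, post, resp, np.array(trace + [final_obj]),
                    converged)
    final_obj, params, post, resp, trace, converged = best
    params, post, resp = _sort_classes(params, post, resp)
    return FitResult(
        params=params, config=config, responsibilities=resp,
        objective_trace=trace, restart_objectives=np.asarray(restart_objs),
        converged=converged, seed=config.seed, posterior=post, data=data)


# ---------------------------------------------------------------------------
# Downstream estimates
# ---------------------------------------------------------------------------


@dataclass
class RichnessEstimate:
    n_obs_concepts: int
    n_obs_relationships: int
    n_latent_concepts: float
    n_missing_synonyms_documented_concepts: float
    n_missing_synonyms_latent_concepts: float
    n_total_concepts: float
    n_total_relationships: float
    fraction_concepts_missing: float
    fraction_synonyms_missing: float
    mean_synonyms_per_concept: float
    per_component: dict[str, list[float]]
    ci: dict[str, tuple[float, float]]
    ci_level: float = 0.99

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k not in ("per_component", "ci")}
        out["per_component"] = self.per_component
        out["ci"] = {k: list(v) for k, v in self.ci.items()}
        return out


def _posterior_draws(fit: FitResult, rng: np.random.Generator, n_draws: int,
                     biomedical: bool) -> dict[str, np.ndarray]:
    """Monte-Carlo draws of the headline estimands from the pseudo-count
    posterior (responsibilities held fixed at their fitted values)."""
    post = fit.posterior
    data = fit.data
    i_obs = data.n_concepts
    t_obs = data.n_terms
    Z = fit.params.n_concept_classes
    # parameter draws
    q = rng.beta(post.q_a, post.q_b, size=(n_draws, *post.q_a.shape))  # (S, D, C)
    theta = rng.beta(post.theta_a, post.theta_b, size=(n_draws, Z))
    w = rng.gamma(post.w_alpha, size=(n_draws, Z))
    w /= w.sum(axis=1, keepdims=True)
    pi = rng.gamma(post.pi_alpha, size=(n_draws, *post.pi_alpha.shape))
    pi /= pi.sum(axis=2, keepdims=True)
    miss_c = np.exp(np.log1p(-q).sum(axis=1))                     # (S, C)
    u = np.minimum(np.einsum("szc,sc->sz", pi, miss_c), _U_MAX)   # (S, Z)
    x = np.minimum(theta * u, _U_MAX)
    ph_z = u * (1.0 - theta) / (1.0 - x)
    ph = np.minimum(np.einsum("sz,sz->s", w, ph_z), _U_MAX)
    # latent concept count: NB posterior under a flat prior on C_total
    c_latent = rng.negative_binomial(i_obs + 1, np.maximum(1.0 - ph, _EPS)).astype(float)
    # missing relationships at documented concepts: responsibilities fixed
    a_z = fit.responsibilities.T @ (data.n_obs + 1.0)             # (Z,)
    miss_doc = np.einsum("z,sz->s", a_z, x / (1.0 - x))
    # hidden concepts: class share and conditional mean term count
    pz_h = w * ph_z
    pz_h /= np.maximum(pz_h.sum(axis=1, keepdims=True), _EPS)
    en_h = np.einsum("sz,sz->s", pz_h, 1.0 / (1.0 - x))
    miss_latent = c_latent * en_h
    c_total = i_obs + c_latent
    total_rel = t_obs + miss_doc + miss_latent
    if biomedical:
        doc_syn = t_obs - i_obs
        total_syn = total_rel - c_total
    else:
        doc_syn = t_obs
        total_syn = total_rel
    return {
        "c_latent": c_latent,
        "c_total": c_total,
        "miss_doc": miss_doc,
        "miss_latent": miss_latent,
        "total_rel": total_rel,
        "frac_concepts_missing": c_latent / c_total,
        "frac_syn_missing": (total_syn - doc_syn) / np.maximum(total_syn, _EPS),
        "mean_syn_per_concept": total_syn / c_total,
        "slope_rel_per_concept": total_rel / c_total,
    }


def _quantile_ci(arr: np.ndarray, level: float) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(arr, lo)), float(np.quantile(arr, 1.0 - lo)))


def estimate_richness(
    fit: FitResult,
    compendium: Compendium,
    *,
    n_draws: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.99,
) -> RichnessEstimate:
    """Undocumented-concept and undocumented-synonym totals with credible
    intervals.

    The latent concept count combines the fitted hidden-concept probability
    with a flat prior on the true concept total (posterior mean equals the
    binomial-thinning estimator C_obs * P_hidden / (1 - P_hidden)); missing
    relationships at documented concepts sum the per-concept negative-
    binomial posterior means under the fitted responsibilities; latent
    concepts carry 1 / (1 - theta_z u_z) relationships each on average.
    """
    params = fit.params
    data = fit.data
    biomedical = (compendium.mode == "undirected_concepts"
                  and not fit.config.condition_on_preferred)
    i_obs, t_obs = data.n_concepts, data.n_terms
    u, th = params.u, params.theta
    x = th * u
    ph_z, ph = hidden_concept_prob(params)
    c_latent = i_obs * ph / (1.0 - ph)
    resp = fit.responsibilities
    n1 = data.n_obs + 1.0
    m_doc_iz = resp * n1[:, None] * (x / (1.0 - x))[None, :]
    miss_doc = float(m_doc_iz.sum())
    pz_h = params.w * ph_z
    pz_h = pz_h / max(pz_h.sum(), _EPS)
    en_h = float(pz_h @ (1.0 / (1.0 - x)))
    miss_latent = c_latent * en_h
    c_total = i_obs + c_latent
    total_rel = t_obs + miss_doc + miss_latent
    if biomedical:
        doc_syn, total_syn = t_obs - i_obs, total_rel - c_total
    else:
        doc_syn, total_syn = t_obs, total_rel

    # per-component breakdown (documented vs undocumented, by concept class)
    comp = {
        "documented_concepts": list(resp.sum(axis=0)),
        "undocumented_concepts": list(c_latent * pz_h),
        "documented_relationships": list(resp.T @ data.n_obs.astype(float)),
        "missing_relationships_documented_concepts": list(m_doc_iz.sum(axis=0)),
        "missing_relationships_latent_concepts": list(c_latent * pz_h / (1.0 - x)),
    }

    rng = np.random.default_rng(fit.seed if seed is None else seed)
    draws = _posterior_draws(fit, rng, n_draws, biomedical)
    ci = {
        "n_latent_concepts": _quantile_ci(draws["c_latent"], ci_level),
        "n_missing_synonyms_documented_concepts": _quantile_ci(draws["miss_doc"], ci_level),
        "n_missing_synonyms_latent_concepts": _quantile_ci(draws["miss_latent"], ci_level),
        "n_total_relationships": _quantile_ci(draws["total_rel"], ci_level),
        "fraction_concepts_missing": _quantile_ci(draws["frac_concepts_missing"], ci_level),
        "fraction_synonyms_missing": _quantile_ci(draws["frac_syn_missing"], ci_level),
        "mean_synonyms_per_concept": _quantile_ci(draws["mean_syn_per_concept"], ci_level),
    }
    return RichnessEstimate(
        n_obs_concepts=i_obs,
        n_obs_relationships=t_obs,
        n_latent_concepts=c_latent,
        n_missing_synonyms_documented_concepts=miss_doc,
        n_missing_synonyms_latent_concepts=miss_latent,
        n_total_concepts=c_total,
        n_total_relationships=total_rel,
        fraction_concepts_missing=c_latent / c_total,
        fraction_synonyms_missing=(total_syn - doc_syn) / max(total_syn, _EPS),
        mean_synonyms_per_concept=total_syn / c_total,
        per_component=comp,
        ci=ci,
        ci_level=ci_level,
    )


def synonyms_per_headword_fit(fit: FitResult, compendium: Compendium):
    """Observed vs model-predicted distribution of documented terms per
    concept, with the R^2 on the count histogram."""
    import pandas as pd

    data = fit.data
    params = fit.params
    n_max = int(data.n_obs.max())
    counts = np.bincount(data.n_obs, minlength=n_max + 1)[1:]  # n = 1..n_max
    ns = np.arange(1, n_max + 1, dtype=float)
    u, th, w = params.u, params.theta, params.w
    x = th * u
    ph_z, _ = hidden_concept_prob(params)
    # P(n | documented, z), n >= 1
    log_pn_z = (np.log1p(-th)[None, :] + (ns[:, None] - 1) * np.log(th)[None, :]
                + ns[:, None] * np.log1p(-u)[None, :]
                - (ns[:, None] + 1) * np.log1p(-x)[None, :])
    pn = (np.exp(log_pn_z) @ w) / float(w @ (1.0 - ph_z))
    expected = data.n_concepts * pn
    ss_res = float(((counts - expected) ** 2).sum())
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    frame = pd.DataFrame({"n_terms": ns.astype(int), "observed": counts,
                          "expected": expected})
    return frame, r2


def discovery_curve(fit: FitResult, resource_subset: Sequence[int],
                    r_max: int) -> np.ndarray:
    """Expected fraction of currently undocumented relationships captured by
    r fresh, independent copies of the given resource subset, r = 0..r_max.

    Undocumented relationships are distributed over term classes according to
    the fitted posterior conditioned on current non-detection; each new copy
    of the subset misses a class-c relationship with probability
    prod_{d in subset} (1 - q[d, c]).
    """
    subset = list(resource_subset)
    if not subset:
        raise ValueError("resource subset must be non-empty")
    params = fit.params
    data = fit.data
    u, th = params.u, params.theta
    x = th * u
    ph_z, ph = hidden_concept_prob(params)
    resp = fit.responsibilities
    a_z = resp.T @ (data.n_obs + 1.0)
    miss_doc_z = a_z * x / (1.0 - x)
    c_latent = data.n_concepts * ph / (1.0 - ph) if ph > 0 else 0.0
    pz_h = params.w * ph_z
    pz_h = pz_h / max(pz_h.sum(), _EPS) if ph > 0 else pz_h
    miss_hid_z = c_latent * pz_h / (1.0 - x)
    undet_class = params.pi * params.miss[None, :] / u[:, None]   # (Z, C)
    omega = (miss_doc_z + miss_hid_z) @ undet_class               # (C,)
    omega = omega / max(omega.sum(), _EPS)
    m_c = np.exp(np.log1p(-params.q[subset, :]).sum(axis=0))      # (C,)
    r = np.arange(r_max + 1)
    return 1.0 - (omega[None, :] * m_c[None, :] ** r[:, None]).sum(axis=1)


def extrapolate_total_synonymy(
    fit: FitResult,
    n_headwords: float,
    *,
    n_draws: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.99,
) -> tuple[float, tuple[float, float]]:
    """Expected total relationships in a domain of ``n_headwords`` concepts.

    Linear in the concept count with slope equal to the posterior mean number
    of relationships per concept; the interval propagates the posterior
    uncertainty of the slope.
    """
    rng = np.random.default_rng(fit.seed if seed is None else seed)
    draws = _posterior_draws(fit, rng, n_draws, biomedical=False)
    slope_draws = draws["slope_rel_per_concept"]
    # point estimate from the fitted parameters, not the draw average:
    params = fit.params
    data = fit.data
    ph_z, ph = hidden_concept_prob(params)
    x = params.theta * params.u
    c_latent = data.n_concepts * ph / (1.0 - ph)
    resp = fit.responsibilities
    miss_doc = float((resp * (data.n_obs[:, None] + 1.0)
                      * (x / (1.0 - x))[None, :]).sum())
    pz_h = params.w * ph_z
    pz_h = pz_h / max(pz_h.sum(), _EPS)
    total_rel = data.n_terms + miss_doc + c_latent * float(pz_h @ (1.0 / (1.0 - x)))
    slope = total_rel / (data.n_concepts + c_latent)
    point = slope * float(n_headwords)
    ci = _quantile_ci(slope_draws * float(n_headwords), ci_level)
    return point, ci


def save_fit(fit: FitResult, path) -> None:
    """Serialize a fit to JSON (parameters, config, pseudo-count posterior,
    trace).  Responsibilities are recomputed on load from the compendium."""
    import json
    from pathlib import Path

    post = fit.posterior
    payload = {
        "params": {
            "w": fit.params.w.tolist(),
            "theta": fit.params.theta.tolist(),
            "pi": fit.params.pi.tolist(),
            "q": fit.params.q.tolist(),
        },
        "posterior": {
            "q_a": post.q_a.tolist(), "q_b": post.q_b.tolist(),
            "theta_a": post.theta_a.tolist(), "theta_b": post.theta_b.tolist(),
            "w_alpha": post.w_alpha.tolist(), "pi_alpha": post.pi_alpha.tolist(),
        },
        "config": {
            "n_concept_classes": fit.config.n_concept_classes,
            "n_term_classes": fit.config.n_term_classes,
            "restarts": fit.config.restarts,
            "seed": fit.config.seed,
            "tol": fit.config.tol,
            "max_iter": fit.config.max_iter,
            "condition_on_preferred": fit.config.condition_on_preferred,
            "hyperparams": {
                "beta_q": list(fit.config.hyperparams.beta_q),
                "beta_theta": list(fit.config.hyperparams.beta_theta),
                "dirichlet_w": fit.config.hyperparams.dirichlet_w,
                "dirichlet_pi": fit.config.hyperparams.dirichlet_pi,
            },
        },
        "objective_trace": fit.objective_trace.tolist(),
        "restart_objectives": fit.restart_objectives.tolist(),
        "converged": fit.converged,
        "seed": fit.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_fit(path, compendium: Compendium) -> FitResult:
    """Rebuild a FitResult saved by :func:`save_fit`; the concept-class
    responsibilities are recomputed from the compendium at the stored
    parameters."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    hpd = payload["config"]["hyperparams"]
    hp = Hyperparams(beta_q=tuple(hpd["beta_q"]), beta_theta=tuple(hpd["beta_theta"]),
                     dirichlet_w=hpd["dirichlet_w"], dirichlet_pi=hpd["dirichlet_pi"])
    cfgd = payload["config"]
    config = MixtureConfig(
        n_concept_classes=cfgd["n_concept_classes"],
        n_term_classes=cfgd["n_term_classes"], hyperparams=hp,
        restarts=cfgd["restarts"], seed=cfgd["seed"], tol=cfgd["tol"],
        max_iter=cfgd["max_iter"],
        condition_on_preferred=cfgd["condition_on_preferred"])
    p = payload["params"]
    params = ModelParams(w=np.array(p["w"]), theta=np.array(p["theta"]),
                         pi=np.array(p["pi"]), q=np.array(p["q"]), hyperparams=hp)
    pp = payload["posterior"]
    post = PseudoPosterior(
        q_a=np.array(pp["q_a"]), q_b=np.array(pp["q_b"]),
        theta_a=np.array(pp["theta_a"]), theta_b=np.array(pp["theta_b"]),
        w_alpha=np.array(pp["w_alpha"]), pi_alpha=np.array(pp["pi_alpha"]))
    drop_pref = config.condition_on_preferred and compendium.mode == "undirected_concepts"
    data = _prepare(compendium, drop_preferred=drop_pref)
    truncated = not config.condition_on_preferred
    *_, resp, _, _, _ = _e_quantities(
        params, data, truncated=truncated, geom_offset=0 if truncated else 1)
    return FitResult(
        params=params, config=config, responsibilities=resp,
        objective_trace=np.asarray(payload["objective_trace"]),
        restart_objectives=np.asarray(payload["restart_objectives"]),
        converged=payload["converged"], seed=payload["seed"],
        posterior=post, data=data)


def model_comparison(
    compendium: Compendium,
    candidates: Iterable[str] = ("mixture", "geometric", "log-gaussian"),
    *,
    config: MixtureConfig | None = None,
) -> dict[str, float]:
    """Penalized fit scores of candidate models for the documented
    synonyms-per-concept distribution (higher is better).

    Scores are maximized log-likelihood of the observed term counts minus a
    BIC-style penalty (k/2 * log I); only the ordering is meaningful.
    """
    from scipy.stats import norm

    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate models given")
    data = _prepare(compendium)
    n = data.n_obs.astype(float)
    i_obs = len(n)
    scores: dict[str, float] = {}
    for cand in candidates:
        if cand == "geometric":
            total = n.sum()
            theta = np.clip((total - i_obs) / max(total, 1.0), _P_MIN, 1 - _P_MIN)
            ll = float(i_obs * np.log1p(-theta) + (total - i_obs) * np.log(theta))
            scores[cand] = ll - 0.5 * 1 * math.log(i_obs)
        elif cand == "log-gaussian":
            logs = np.log(n)
            mu, sigma = float(logs.mean()), float(max(logs.std(), 1e-6))
            # discretized, zero-truncated lognormal
            grid = np.arange(1, int(n.max()) + 1, dtype=float)
            upper = norm.cdf((np.log(grid + 0.5) - mu) / sigma)
            lower = norm.cdf((np.log(np.maximum(grid - 0.5, 1e-9)) - mu) / sigma)
            pmf = np.maximum(upper - lower, 1e-300)
            pmf = pmf / pmf.sum()
            counts = np.bincount(n.astype(int), minlength=len(grid) + 1)[1:]
            ll = float(counts @ np.log(pmf))
            scores[cand] = ll - 0.5 * 2 * math.log(i_obs)
        elif cand == "mixture":
            cfg = config or MixtureConfig(n_concept_classes=3, n_term_classes=2,
                                          restarts=3)
            result = fit(compendium, cfg)
            frame, _ = synonyms_per_headword_fit(result, compendium)
            pn = frame["expected"].to_numpy() / i_obs
            pn = np.maximum(pn / pn.sum(), 1e-300)
            counts = frame["observed"].to_numpy()
            ll = float(counts @ np.log(pn))
            k = 3 * cfg.n_concept_classes - 1  # (w, theta, u) per class
            scores[cand] = ll - 0.5 * k * math.log(i_obs)
        else:
            raise ValueError(f"unknown candidate model {cand!r}")
    return scores
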