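# Methods

## The estimation problem

A synonym compendium is built by intersecting D independently constructed
resources (thesauri, terminologies).  Every concept-term relationship that
at least one resource documents is observed together with its *capture
history* — the bit-vector saying which resources documented it.  Two things
are never observed: relationships that every resource missed, and concepts
none of whose relationships were documented anywhere.  `lexcap` estimates
both, treating the compendium as a multi-list capture-recapture sample in
which concept-term relationships play the role of species.

## Generative model

For each of `C_total` concepts:

1. a concept class `z ~ Categorical(w)`, `z = 1..Z`;
2. a true relationship count `N ~ Geometric(theta_z)` on support `N >= 1`
   (`P(N) = (1 - theta_z) theta_z^(N-1)`, mean `1/(1 - theta_z)`) — a
   concept cannot exist without at least one term;
3. for each of the N relationships, a term class `c ~ Categorical(pi_z)`,
   `c = 1..C`;
4. independent detections: resource d documents a class-c relationship
   with probability `q[d, c]`.

Annotation is conceived as a Poisson capture process with rate lambda and
rate prior g(lambda); because only presence/absence is recorded, lambda and
g are identifiable only through `q = 1 - E[exp(-lambda)]`, so the model is
parameterized directly by q with Beta priors, and the per-relationship
sampling counts are marginalized exactly.  The concept- and term-class
structure is what absorbs annotation biases (frequency, granularity,
editorial policy): classes with different q and theta induce correlated
capture histories within and across resources without naming any specific
confounder.

Useful closed forms, writing `u_z = sum_c pi_zc prod_d (1 - q[d,c])` for
the probability that a class-z relationship escapes every resource and
`x = theta_z u_z`:

- marginal likelihood of a concept with n observed patterns `b_1..b_n`:
  `sum_z w_z (1-theta_z) theta_z^(n-1) (1-x)^-(n+1) prod_j p_z(b_j)`
  where `p_z(b) = sum_c pi_zc prod_d q[d,c]^b_d (1-q[d,c])^(1-b_d)`
  (the geometric tail over unobserved terms collapses analytically);
- posterior over the number of missing relationships `j = N - n`:
  negative binomial `NB(n+1, 1-x)`, mean `(n+1) x / (1-x)`;
- probability a class-z concept is entirely undocumented:
  `P_hidden(z) = u_z (1-theta_z) / (1-x)`.

These are verified in the test suite against brute-force enumeration over
all latent assignments and against direct series summation.

## Inference

Fitting maximizes the zero-truncated likelihood of the observed concepts
(observed concepts are, by construction, those with at least one detected
relationship).  The EM scheme treats each observed concept as the first
detected unit in an i.i.d. stream, so the number of entirely-hidden
concepts accompanying the sample is imputable in closed form
(`C_obs * P_hidden / (1 - P_hidden)` in expectation), and the E-step needs
only: concept-class responsibilities, per-pattern term-class posteriors,
expected missing-relationship counts (negative-binomial means), and the
hidden-concept imputation.  All M-step updates are conjugate-closed-form
MAP estimates under Beta/Dirichlet hyperpriors (flat, `Beta(1,1)` /
`Dirichlet(1)`, by default).  The traced objective — truncated
log-likelihood plus log-hyperprior — is non-decreasing by construction and
is asserted to be so in the tests.

Practical details:

- multi-restart (default 5) from seeded random initializations; the best
  final objective wins; deterministic given the seed;
- convergence when the relative objective change drops below `1e-8`
  (default), capped at `max_iter` (500); non-convergence sets a flag
  rather than raising;
- label switching is resolved by sorting term classes by marginal
  detection probability and concept classes by theta;
- all mixture sums are in log-space; `u_z` is clamped below `1 - 1e-12`
  and point estimates are kept strictly inside (0, 1);
- the mixture dimensions default to 10 concept classes x 4 term classes,
  the configuration used for the headline biomedical analyses; synthetic
  studies in this repository use matched (smaller) dimensions.

A configuration switch (`condition_on_preferred`) treats the preferred
term as conditioned upon rather than sampled; the geometric prior then
governs synonym counts on support `N >= 0` and no concept can be hidden.
The default treats every term, preferred included, as a capture — the
natural reading of the sampling story, and the only variant under which
hidden concepts are estimable.

## Estimates and uncertainty

The latent concept count uses a flat (improper) prior on `C_total`: the
posterior over `C_latent` is `NB(C_obs + 1, P_hidden)`, whose mean is the
binomial-thinning (Horvitz-Thompson) estimator.  Missing relationships at
documented concepts sum per-concept negative-binomial means under the
fitted responsibilities; hidden concepts carry `1/(1 - theta_z u_z)`
relationships each on average, weighted by the hidden-class distribution.
In biomedical (preferred-term) mode, synonym counts are relationship counts
minus one per concept; in directed headword mode every relationship is a
synonym pair.

Credible intervals are Monte Carlo (default 10,000 seeded draws) from the
conjugate pseudo-count posteriors accumulated at convergence — Beta factors
for q and theta, Dirichlet for w and pi, the negative-binomial for
`C_latent` — i.e. the parameter factors a mean-field scheme would carry,
with responsibilities held at their fitted values.

**Calibration caveat.**  Because the EM augmentation feeds *imputed*
missing-relationship and hidden-concept counts into those pseudo-count
posteriors as if they were observed, the intervals understate uncertainty
when the mixture is weakly identified.  Empirically (see the acceptance
script and test suite): in the single-class regime at 1,000-5,000 concepts
the nominal 99% interval for the latent concept count covered the
simulated truth in 50/50 replicates; for a 2x2-class mixture at 2,000
concepts coverage degrades to roughly two-thirds.  Headline estimates from
multi-class fits should therefore be read with point-estimate accuracy in
mind (which remains good and essentially unbiased in our simulations)
rather than literal interval coverage.

## Downstream analyses

- **Overlap tables** (`overlap_table`): for every k-subset of resources,
  the observed k-way intersection divided by the size of the smallest
  intersected resource ("percent maximum overlap"), at concept or
  concept-term-pair level.
- **Count-distribution fit** (`synonyms_per_headword_fit`): the model's
  predicted distribution of documented terms per concept,
  `P(n | documented)`, against the observed histogram, scored by R^2.
- **Model comparison** (`model_comparison`): the mixture against
  zero-truncated geometric and discretized log-Gaussian fits of the same
  histogram, scored by maximized log-likelihood minus a BIC-style penalty;
  only the ordering is meaningful.
- **Discovery curves** (`discovery_curve`): the expected fraction of
  currently undocumented relationships that r fresh, independent copies of
  a resource subset would capture, `1 - sum_c omega_c m_c^r`, where
  `omega_c` is the term-class distribution of undocumented relationships
  (conditioned on current non-detection) and `m_c` the subset's one-copy
  miss probability.
- **Extrapolation** (`extrapolate_total_synonymy`): linear in the concept
  count with slope the posterior mean relationships per concept.

## Synonym-knockdown redundancy

Non-preferred synonym records are retained independently with probability
f (preferred terms are never removed; default fractions 0.2-1.0 in steps
of 0.2, five replicates); a pluggable normalizer maps mentions to concepts
(the built-in one is case-folded, whitespace-normalized exact lookup that
returns nothing for ambiguous terms).  Recall is computed over the
*synonym-attributable* concept set: concepts recalled with full synonymy
but not with synonyms absent.  The recall curve is fit by
simplex-constrained least squares to `recall(f) = sum_m w_m (1-(1-f)^m)`;
`w_m` is the fraction of attributable concepts reachable through m
interchangeable synonyms, and the redundant synonym fraction is
`sum_m w_m (m-1) / sum_m w_m m` — the expected share of usable synonym
mappings beyond the first.  Bootstrap over replicates gives 95% intervals.
A flat curve is flagged degenerate (weights undefined).

## Crowd validation

Annotators are screened by an exact one-sided binomial test of their
control accuracy against chance (Bonferroni-corrected by default; a t-test
variant is available).  The agreement model is the minimal two-class
latent-truth (Dawid-Skene-style) model — per-annotator sensitivity and
specificity, global prevalence — fit by EM with control truths clamped.
Reported per-item posteriors are unclamped model scores, so the ROC over
controls is a genuine evaluation; the acceptance threshold is the smallest
posterior whose empirical false-positive rate on negative controls meets
the target (default 2%), and candidate filtering uses strict inequality
(posterior > threshold).

## What the simulators do and do not emulate

`simulate_compendium` draws exactly from the generative model above, so
recovery and coverage results certify internal consistency: correct
likelihood, correct estimator, calibrated single-class uncertainty.  They
do not certify that real terminologies satisfy the model's assumptions —
independent resources, class-structured rates, geometric tails.  Real
compendia violate independence to unknown degrees (shared editorial
ancestry between resources), which the class structure absorbs only
partially.  `simulate_mention_corpus` makes every mention an exact string
match of a distinct synonym; real normalization involves lexical variation
that the pluggable-normalizer interface admits but the built-in exact
matcher does not model.  `simulate_ratings` assumes annotator errors are
independent given the truth — the standard Dawid-Skene assumption, which
correlated annotator behavior would violate.

## Problem sizes

The shipped studies use 1,000-10,000 simulated concepts, 3-5 resources,
mixtures up to 2x2 classes, 10,000-mention corpora, and 2,000-item rating
matrices with 3 votes per item — sizes at which every recovery target in
the test suite is met with margin while the whole suite and the acceptance
script each run in about a minute on one core.  The model code is
vectorized over distinct capture patterns, so compendium-scale data
(hundreds of thousands of records, 10+ resources) fits in the same code
path.
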