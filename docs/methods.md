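# Methods

`teamdynam` implements a coordination dynamic network actor model (DyNAM)
for undirected face-to-face interaction events recorded by wearable
proximity badges, together with the preprocessing, imputation and
interpretation machinery that a complete analysis needs. This note
documents the model, the numerical choices, and what the synthetic-data
tests do and do not establish.

## From infrared detections to relational events

Proximity badges register up to ~50 infrared detections per minute while
two participants face each other at close range, so raw detection counts
track the badge scan rate, not distinct social exchanges. Detections of
the same dyad falling into the same tumbling 75-second window are
collapsed into one undirected relational event provided the window holds
at least two detections; a lone detection is discarded as an aleatory
passing-by. Two choices deserve comment:

* **Window anchoring.** Windows are tumbling (non-overlapping), anchored
  at the team-study origin. 86400 is an integer multiple of 75, so the
  anchoring is equivalently per civil day. Anchored windows make the rule
  deterministic and order-independent; a sliding-window variant would
  merge long interactions into one event and remove the repeated-event
  signal that the recency and inertia statistics are designed to pick up.
* **Event timestamp.** The first detection in the qualifying window — the
  observable onset of the interaction.

Consecutive qualifying windows are deliberately *not* merged: a
45-minute meeting yields a run of events for the same dyad, and the
strong recency effect typical of such data is exactly the tendency of the
next event to repeat the most recent dyad.

Badge on/off logs define per-actor presence as half-open `[on, off)`
intervals; a dangling `on` is closed at the end of its civil day. The
presence schedule is authoritative: qualifying windows at which either
actor's badge is off are dropped with a logged warning and count toward
the reported number of discarded detections.

## The coordination model

An undirected event between available actors i and j is modelled as a
two-sided choice. Each direction follows a multinomial logit over the
available partners,

    p(i -> j; y, beta) = exp(beta' s(i,j,y)) / sum_{k in A\{i}} exp(beta' s(i,k,y)),

and the probability that the *pair* {i, j} produces the next event is the
normalised product of the two directed probabilities,

    P_{i<->j}(y) = p(i->j) p(j->i) / sum_{k<l in A} p(k->l) p(l->k),

where y is the process state (the accumulated event history plus the
availability set A) and s(i,j,y) stacks the statistics. The event *rate*
is taken constant: the likelihood conditions on the event times and only
explains which dyad interacts next. Badge data do not distinguish an
interaction proposal from its acceptance, so the two-sided structure is
collapsed into this pairwise form.

### Statistics

Endogenous (functions of the history only; each is a named plug-in so
alternative parametrisations can be swapped in):

* `inertia` — raw count of the dyad's past events;
* `degree` — mean past-event degree of the two members, normalised by
  team size: (deg(i) + deg(j)) / (2 (n - 1));
* `recency` — reciprocal rank 1/(1 + r) of the dyad's last event among
  all dyads' last events; 0 for a dyad that never interacted.

These functional forms are standard relational-event conventions, not
facts fixed by any validation study; the raw-count inertia and
reciprocal-rank recency are the defaults and are what all reported
numbers use.

Exogenous (constant over the sequence, symmetric in i and j): gender
pairing indicators man-man and woman-woman against a mixed-gender
reference; seniority pairing junior-junior and senior-senior against a
mixed-seniority reference; woman-woman x senior-senior and woman-woman x
junior-junior interaction indicators (the gender-status-cue terms);
either-direction friendship and advice ties; co-location; same age band
and same tenure band.

Dichotomisation and banding: survey ratings (1-5) become ties iff the
rating exceeds 3, and the directed matrices are symmetrised to
either-direction indicators (the weakest assumption consistent with an
undirected effect). Age bands are young <= 30 < middle <= 45 < elderly —
the bands must be exhaustive for the same-band indicator to be
well-defined, so the upper band starts immediately above 45. Tenure
bands are newcomer <= 12 < consolidated <= 72 months < long-term.

## Hierarchical structure and priors

Every fixed effect is context-specific (university, research lab,
private company): beta_k^c. The inertia coefficient additionally varies
by team: alpha_g ~ N(gamma^c, sigma^2) with context-specific hypermeans
and a shared between-team SD. Priors are weakly informative:
Normal(0, 2^2) on fixed effects and hypermeans, Half-Normal(0, 1) on
sigma. These scales are package defaults, exposed in `EffectSpec`.
The random effect is parametrised **centred** (alpha_g free, Gaussian
prior tying it to gamma^c): with hundreds to thousands of events per team
the slopes are strongly identified and the non-centred form produces the
classic funnel in reverse — it was measurably worse in mixing when both
were implemented. Multiple random slopes are supported with independent
SDs; no between-slope correlation is modelled.

## Sampling

No probabilistic-programming backend is required: the log-posterior and
its gradient are evaluated analytically (the gradient of the pairwise
log-likelihood has closed form in the linear predictors), and a compact
Hamiltonian Monte Carlo sampler drives them:

1. L-BFGS finds the posterior mode. Log-scale parameters are boxed to
   [-4, 2.5] during this search only — with few groups the SD posterior
   has mass near zero and the optimiser would otherwise chase a
   degenerate corner that is useless as a preconditioning point.
2. A dense finite-difference Hessian of the analytic gradient at the
   mode, eigenvalue-floored (relative 1e-6 of the largest, absolute
   0.04 ~ the prior curvature), becomes the fixed HMC mass matrix.
3. Warmup adapts only the leapfrog step size (dual averaging, target
   acceptance 0.8); trajectory lengths are jittered uniformly on
   [1, max_leapfrog]. Iterations with Hamiltonian error beyond 1000 are
   counted divergent and rejected.

Rank-normalised split R-hat and bulk ESS (via arviz) are attached to
every fit; any parameter with R-hat > 1.05 flags the fit as
non-converged in its metadata and a warning is logged — results are
never silently dropped. Two independent cross-checks guard the
machinery: the jitted likelihood kernel is compared against a pure-numpy
implementation, and a small posterior is sampled with emcee's
affine-invariant ensemble and compared to the HMC marginals.

Production defaults mirror the analysis design: 2 chains x 500 retained
draws per imputed dataset, 100 imputations, pooled by concatenation.
Desk-scale runs (tests, the acceptance script) use M = 5 and
2 x 250 draws with warmup 120 and max_leapfrog 8 — with the Laplace
metric short trajectories already decorrelate well, and the pooled
posterior across imputations is what the summaries use.

## Multiple imputation

Missing survey covariates are imputed fully Bayesianly with the same HMC
machinery, assuming MAR conditional on team, gender and seniority:

* **Age and tenure** follow a joint lognormal: log age regresses on
  gender and seniority with team random intercepts; log tenure regresses
  on the same plus log age (this triangular form is exactly a bivariate
  normal with free residual covariance). Missing log-values are latent
  quantities sampled alongside the parameters, so each retained draw is
  a completed dataset and positivity is automatic.
* **Advice and friendship** (after dichotomisation) follow a
  hierarchical p2-type model: each unordered dyad's joint state
  (y_ij, y_ji) has log-scores 0, m_ij, m_ji, m_ij + m_ji + rho with
  m_ij = density + same-gender + same-seniority + sender/receiver gender
  and seniority effects + sender and receiver normal random effects
  shared across teams. Dyads with unobserved entries are marginalised in
  the likelihood; missing entries are then drawn from the conditional
  posterior predictive per retained draw. The sender-receiver covariance
  of the classical p2 model is omitted (independent random effects) — a
  deliberate simplification that keeps the gradient closed-form; a team
  with no observed ties is imputed from the cross-team hierarchy.

M completed datasets are M equally spaced post-warmup draws. Observed
cells are never altered, and pooling across imputations is plain
concatenation of posterior draws with imputation labels retained.

## Interpretation layer

Posterior summaries report the median, the 95% equal-tailed credible
interval, and the probability of direction pd — the share of draws on
the same side of the reference value (0 for coefficients, 1 for
probability ratios) as the median; a median exactly at the reference
gives pd = 0.5. Evidence grades: *strong* when the CI excludes the
reference (which implies pd >= 0.975), *moderate* for pd >= 0.95, *weak*
for pd >= 0.90, *insufficient* below. Cross-context heterogeneity is
summarised by per-draw coefficient differences Delta-beta.

Probability ratios compare two *prototypical dyads* — hypothetical dyads
with chosen attributes, endogenous statistics zeroed (prototypes carry
no history), in the same context. The baseline dyad has mixed gender,
mixed seniority and no ties. Per draw,

    PR = exp(2 (eta_num - eta_den)),

the factor 2 reflecting that an effect enters both directed choices of
the mutual-agreement mechanism. The PR uses only the numerator of the
multinomial logit, i.e. it is ceteris paribus with respect to the
opportunity structure; this caveat is carried in the result metadata.
PRs are computed per draw and then summarised; because exp(2x) is
strictly increasing, the posterior median PR equals the PR at the median
predictor difference, which is what makes published single-coefficient
PRs reproducible from published medians. Shared attributes of the two
dyads cancel exactly in the difference. For combined prototypes the sum
of coefficient medians is *not* the median of the sum, so published
combined PRs are only approximately recoverable from printed medians —
the acceptance layer therefore checks the twelve single-coefficient PRs.

## Synthetic-data generator

The generator emulates the study setting end to end: 3/5/3 teams in
university/lab/company contexts with 7-17 members each, 45% women, five
8-hour badge days, survey networks from a latent reciprocity model
(ratings in {4,5} for ties, {1,2,3} otherwise), co-location from a
two-room split, events drawn sequentially from the model's own pair
probabilities at uniformly drawn presence times, and raw detection
bursts re-expanded from events (exponential durations, mean 30 s,
confined to the event's 75-s window so aggregation is exactly invertible
for events in distinct windows; detections capped at 50 per dyad-minute).
Default generating coefficients: woman-woman -0.5, junior-junior -0.2,
all other effects zero, inertia hypermean 0 with between-team SD 0.15.
Missingness is MAR at rate 0.2, modulated by gender and seniority with
weights normalised so the overall rate is preserved. Ground truth is
serialised next to every simulation.

What passing recovery tests show: the estimation machinery — state
computation, likelihood, sampler, imputation, pooling — is consistent
with its own generative model at realistic sizes. What they do not show:
robustness to model misspecification (real badge data have detection
dropout, orientation artefacts, non-constant rates, and survey
covariates whose missingness may not be MAR).

## Problem sizes used by the shipped checks

The single-replicate recovery (test suite and acceptance script) uses 3
contexts x 2 teams x 8 actors, 1000 events per team, 20% MAR
missingness, M = 5 imputations, 2 chains x 250 draws; it completes in a
few minutes on one CPU and recovers all nonzero coefficient signs with
pd > 0.95 and full 95%-CI coverage of the generating values. The
20-replicate coverage study (`scripts/coverage_study.py`) is the
scheduled companion at the same per-replicate scale.

## Degenerate inputs and tie-breaks

Simultaneous events are ordered deterministically by (time, team, i, j);
sequence order, not the timestamp, is authoritative for the history.
Fewer than two available actors at an event time is an error, as is an
event involving an actor whose badge is off. Probabilities are computed
with max-shifted exponentials throughout; the pair normaliser and both
directed normalisers are exact logsumexps. pd at a sign tie is 0.5 by
definition; equal-tailed CIs are plain 2.5/97.5 percentiles of the
pooled draws.

## Known limitations

* The likelihood conditions on event times; duration and rate dynamics
  are out of scope.
* Directed DyNAM variants (separate rate + choice), windowed or
  time-decayed statistics, and between-random-slope correlations are not
  implemented (the plug-in registry and `EffectSpec` mark the extension
  points).
* The p2 imputation model omits sender-receiver covariance.
* Real-data posterior values cannot be reproduced without the original
  badge logs, which were never deposited; the published-median table
  bundled with the package supports the interpretation layer only.
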