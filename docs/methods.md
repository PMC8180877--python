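# Methods

## The measurement model

Ordinal responses are modelled with a cumulative link: a continuous latent
social-connection score η is cut into K ordered categories by thresholds
c₁ < … < c₍K₋₁₎, and P(Y = k) = F(c_k − η) − F(c₍k₋₁₎ − η) with F the
logistic CDF (c₀ = −∞, c_K = +∞).  Effects are therefore interpreted on
the latent logit scale.  Two constructs (connection to the artist and to
the audience) are measured by two instruments each: an explicit 1–5 rating
and the 1–7 IOS pictorial scale.  Design choices on points the study
description leaves open:

* **One latent score per construct.**  Both instruments of a construct
  share η; each instrument has its own threshold vector (a 5-point and a
  7-point scale cannot share cuts).  Instrument-specific coefficients are
  a plausible alternative; the shared-η choice is the more parsimonious
  reading of "two outcome measures of one latent variable" and is what the
  generator and likelihood both implement.
* **Thresholds are shared across constructs** (per instrument).  Construct
  differences in location are carried by the predictors and the
  participant effects.
* **Participant threshold shifts.**  Each participant has one scalar per
  construct, added uniformly to all thresholds of that construct's
  instruments: response styles slide along the latent scale while the
  threshold spacing is preserved.  The two shifts per participant are
  correlated bivariate-normal with scales σ_u and correlation ρ.
  Note one sign convention: the likelihood shifts *thresholds* by +u while
  the generator adds +u to the *latent score*.  The two differ only by the
  sign of u; because u is symmetric around zero the implied data law is
  identical, and no inference about β, σ_u, or ρ's magnitude depends on it.
* **No intercept.**  The linear predictor carries no intercept; location is
  absorbed by the thresholds (anchored by their prior), which is the usual
  identification for cumulative models.
* **Pooled scope.**  When all concerts are modelled jointly, a scalar
  per-concert shift w_c ~ N(0, σ_w) enters η, crossed with the participant
  effects (returnees keep their u across concerts).
* **Missing ordinals** contribute no likelihood term (marginalization),
  which is posterior-equivalent to imputing them during fitting; the
  posterior-predictive category distribution of each missing cell is
  available separately for reporting.

## Priors

β ~ N(0, 1) per coefficient.  Random-effect scales (σ_u, σ_w) ~
half-N(0, 1).  The artist/audience effect correlation has an LKJ(η = 4)
prior (mass pulled toward 0).  Each threshold vector has an induced
Dirichlet prior: the category probabilities implied at an anchor point
(default 0) get a Dirichlet(α) density, transported to ordered-threshold
space with the log-Jacobian Σ log f(c_k − anchor).  The default symmetric
α = 1 pools thresholds toward equal category probabilities with wide
flexibility; α and the anchor are exposed in `PriorConfig`.  With K = 2
the construction collapses to a logistic density on the single threshold,
and the K = 3 density integrates to 1 over the ordered-cut plane — both
are tested.

## Sampling

No gradient-based sampler is used; the posterior is explored by an
adaptive blocked random-walk Metropolis scheme designed around the
posterior's known pathologies:

* **Global block** — coefficients, thresholds (first cut + log-increments),
  log σ, atanh ρ, concert shifts — updated jointly, several sub-updates per
  sweep, with Robbins–Monro step-size adaptation toward 25% acceptance and
  a running empirical proposal covariance (warmup only).
* **Participant block** — all 2-D effects updated in parallel with
  independent per-participant accept/reject decisions (target 44%).
  Effects are *non-centered*: u = z·(diag(σ_u)·L_ρ)ᵀ with z ~ N(0, I), so
  scale updates move the effects with them and the hierarchical funnel is
  avoided.
* **Interweaved scale update** — after the participant block, (σ_u, ρ) are
  updated again *conditioned on u* (centered form), where their conditional
  involves only the MVN prior of the effects and is likelihood-free; z is
  then re-derived.  This centered/non-centered interweaving is what makes
  the scale and correlation parameters mix.
* **Translation move** — the likelihood is exactly invariant under
  (all cuts + δ, all u − δ); a dedicated move along this direction, accepted
  on the prior ratio alone, decorrelates threshold location from the
  effect mean.

Initialization: thresholds at equal-probability spacing, everything else
jittered around prior-typical values; a non-finite initial density raises
immediately with a diagnostic dump.  Chains are deterministic given
(seed, config); per-chain seeds spawn from the master seed.  Divergence
counts are recorded as 0 in the metadata — random-walk Metropolis has no
divergences; acceptance rates and final step sizes are stored instead.

Summaries use central credible intervals from empirical quantiles with
linear interpolation (the convention is frozen and tested: 1…1000 draws
give a 90% interval of (50.95, 950.05)).  The default interval is 90%,
flagged when it excludes zero.  Convergence is judged by split-R̂ < 1.01
and rank-normalized bulk ESS via arviz; a single chain is split into
halves with a warning.

## Grouped model comparison

The cross-validation unit is the participant.  The pointwise predictive
density of participant p under draw s integrates the unknown effect out
over its bivariate-normal law, by Gauss–Hermite quadrature (default 15²
nodes rotated through the draw's Cholesky factor).  PSIS smoothing of the
importance ratios uses the standard generalized-Pareto fit to the upper
tail (arviz `psislw`, tail fraction min(0.2·S, 3√S)/S per its
implementation); groups with Pareto k > 0.7 are flagged, and an exact
refit-based leave-one-group-out routine serves both as validation oracle
and as the (off-by-default, compute-heavy) fallback.  Comparison tables
rank models by elpd; difference SEs are *paired* (computed from pointwise
differences), so a model compared with itself gives exactly 0 / 0, and a
difference is flagged "meaningful" when it exceeds 3× its SE.

## Rank-based checks

Kendall correlations are τ-b (tie corrections in both variables — required
when correlating a binary condition with a 5-point rating), two-sided p
from the tie-adjusted normal approximation.  Kruskal–Wallis H is
tie-corrected with χ²₍g₋₁₎ p and ε² = H/(N−1) attached.  The Wilcoxon
rank-sum statistic W is fixed to the Mann–Whitney U of the first sample;
p is exact by enumeration when both samples are tie-free and n_a·n_b ≤ 400,
otherwise the tie-corrected normal approximation with continuity
correction (switchable, since the original analysis does not say).
Rank-biserial r = 1 − 2W/(n_a·n_b).  BH adjustment is the step-up
procedure (via statsmodels), applied within each family: the pairs of a
pairwise comparison, or the upper triangle of a correlation matrix.
Pairwise-complete observations are used in the correlation screen;
zero-variance variables are excluded with a warning.

## The synthetic-data generator

`simulate_study` emulates the deposited design: subgroup sizes 16/13
(voted / could not vote), 12/9/11 (YouTube / 360° / VR), 11/11
(Zoom / YouTube, the physically attending group being out of inferential
scope); ~25% of later-concert seats are taken by returnees who keep their
registration covariates and participant effects.  Registration covariates:
age ~ N(37, 12²) truncated to [18, 80]; gender woman/man/not-reported with
probabilities 0.55/0.41/0.04; empathic concern ~ N(3.5, 0.6) clipped to
[1, 5]; the six COVID-impact items share a participant trait with loading
0.69 against unit noise, which targets a composite reliability near the
study's reported level (measured by `cronbach_alpha` in the tests, not
asserted as a constant).  Psychometric items (MPS, IPQ, agency, emotional
change) discretize latent drivers through equal-probability thresholds;
experimental conditions shift the drivers (defaults: VR +2.0 on physical
presence and spatial presence, Zoom +1.5 on social presence), which is
what makes the manipulation-check batteries exercisable.  Outcomes are
drawn from the measurement model itself with β defaults that mirror the
study's headline pattern (COVID impact and physical presence → artist;
social presence, physical presence, −age → audience); covariates enter
centred so the fixed thresholds sit mid-scale.  Two IOS responses in
concert 1 are set missing, matching the deposited data's sporadic
missingness.

What the generator does *not* emulate: real covariate correlations beyond
the shared COVID trait, item-level idiosyncrasies (all items of a driver
are exchangeable), non-random attrition, or free-text/behavioural data.
Passing recovery and calibration tests therefore shows the estimator is
correct *under the model and design*, not that the model fits any
particular real dataset.

## Problem sizes and budgets

Chosen once, as the package's own verification scale: rank-statistic
oracle agreement over 1000 random instances (n ≤ 12, heavy ties);
recovery at n = 300 participants with planted β = (0, 1, 2) on both
constructs (2 chains, 1200 warmup + 800×3 thinned sweeps); interval
calibration over 50 replications at n = 120 with a 1-chain reduced budget
(30 replications in the acceptance script); grouped-LOO validation at 20
participants with one exact refit per participant.  Quadrature uses 11–15
nodes per dimension; the K = 3 normalization check integrates over
[−15, 15]² to 1e-3.

## Known limitations

* Random-walk mixing: worst-case split-R̂ around 1.1 at the default
  budgets for the hierarchical scale parameters; the diagnostics report is
  the guard, and budgets are exposed in `SamplerConfig`.
* The correlation ρ between artist and audience effects is weakly
  identified at study-scale n (each participant contributes two responses
  per construct); its posterior stays broad.
* Grouped pointwise densities loop over draws in Python; at thousands of
  draws × hundreds of groups this is the slowest path (vectorized within
  draw).
* No probit or category-specific (non-proportional) effects; no
  variational approximation; threshold locations are estimated but not
  part of the reporting surface.
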