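# Methods

## The measurement problem

In a visual-analog-scaling (VAS) speech task a listener hears a token from
a 9-step continuum between two minimal-pair words (e.g. *beach–peach*) and
marks a point on a continuous 0–100 line indicating how closely the token
matched either endpoint. Unlike two-alternative forced choice, the VAS
response separates two aspects of categorization that forced choice
confounds: the **slope** of the mean rating function (how categorical the
listener's long-term category structure is) and the **trial-to-trial
variability** of ratings around that function (how consistently the
listener maps the same input to the same response). Two listeners with
identical mean curves can differ radically in the second quantity — a
shallow mean slope can reflect genuinely gradient responding tightly
clustered around the mean, or noisy endpoint-jumping that only averages to
a shallow curve.

## Model

The mean rating at continuum step `x` is a piecewise-linear approximation
of the four-parameter logistic: two flat asymptotes `L` and `U` joined by
a diagonal with slope `s` crossing the midpoint at the crossover `c`:

    m(x) = clip( (L + U)/2 + s·(x − c),  L,  U )

Trial ratings are truncated-Normal on the rating scale:

    rating ~ TruncNormal( m(x), σ; [0, 100] )

Five quantities per subject × continuum are carried on a latent scale
where constraints hold by construction and random effects are additive
Normals:

    θ = (L, δ, c, η, ν),   U = L + exp(δ),   s = exp(η),   σ = max(exp(ν), 0.1)

The hierarchical model places Normal priors on the fixed effects and
independent subject random intercepts on all five latent parameters
(non-centered), with half-Normal priors on the intercept SDs. `ν` is the
listener's response-variability parameter: it appears as a fixed intercept
plus subject intercept exactly like the curve parameters, so trial noise
is estimated per subject jointly with the curve. One fit per continuum is
the default (indices per subject × continuum fall out directly); a pooled
variant fits all continua jointly with additional item (continuum)
intercepts on every parameter.

Priors (defaults, configurable): `L ~ N(5, 10)` truncated to [0, 100];
`δ ~ N(log 90, 0.5)`; `c ~ N(5, 2)` truncated to [1, 9];
`η ~ N(log 12, 1)`; `ν ~ N(log 10, 1)`; intercept SDs half-Normal with
scale 0.5 latent units (10 rating units for `L`). These are weakly
informative around the observable rating scale: a 0–100 scale, asymptotes
near its ends, a crossover near midcontinuum, slopes of roughly one
category width over a few steps.

The truncated-Normal likelihood matches the generator (a plain-Normal
variant is selectable for sensitivity analysis). Truncation rather than
censoring keeps generator and fitter identical and avoids point masses at
the bounds that the model does not describe. A floor `σ ≥ 0.1` rating
units regularizes subjects with zero within-step variance.

## Sampling

Fitting is by adaptive random-walk Metropolis-within-Gibbs, written for
this model:

* per-(subject, parameter) vectorized random-walk updates of the
  non-centered intercepts (the five latent dimensions have very different
  posterior widths, so scales adapt per coordinate);
* **slide moves** in `(L, U, c)` coordinates: the clipped mean makes three
  directions nearly likelihood-flat — sliding `L` with `U` fixed, sliding
  `U` with `L` fixed (each with the shear `c' = c + ε/(2s)` that leaves
  the diagonal line unchanged) and shifting the whole curve vertically
  (`c' = c + ε/s`). Each runs per subject and, for the one-sided slides,
  also cohort-wide with a common ε; the change of variables from
  `δ = log(U − L)` contributes `log((U−L)/(U'−L'))`;
* scalar random-walk updates of the fixed effects and intercept SDs in the
  non-centered direction (likelihood-informed);
* ancillarity–sufficiency interweaving: with the subject-level θ held
  fixed, the fixed effects are redrawn from their exact conjugate Normal
  conditionals (truncated for `L` and `c`) and each intercept SD from its
  exact conditional via inverse-CDF on a 512-point log-grid. These moves
  cost no likelihood evaluations and break the strong coupling between
  the population parameters and the standardized intercepts;
* proposal scales adapt during warmup only (Robbins–Monro,
  rate `t^−0.6`), targeting 0.44 acceptance;
* chains initialize from per-subject moment estimates (step-wise means
  and within-step SDs), jittered per chain, so warmup starts near the
  data-supported subject spread instead of deep in the hierarchy's
  funnel.

Defaults: 4 chains × 1000 warmup + 1000 draws, optional thinning,
seed-deterministic (chain seeds spawn from one `SeedSequence`).
Convergence is summarized per scalar parameter with split-R̂ and bulk ESS
(via arviz); the default pass criterion is max R̂ ≤ 1.01 and min ESS ≥ 400,
both configurable. The pipeline refuses to continue on a failing fit
unless explicitly told to (`allow_nonconverged`).

**Known limitation.** At the study design only step 1 sits on the lower
asymptote, and the truncated likelihood flattens its information, so the
between-subject SD of `L` is weakly identified; the posterior correctly
shrinks it hard (verified by initializing chains at the simulation truth),
but the resulting funnel leaves R̂ ≈ 1.05 for `τ_L`/`μ_L` at the default
chain lengths. The indices this package exists for (`η`, `ν`) mix well and
their posterior means are stable across chains; fits whose data pin all
five parameters (steep slopes, low noise) pass the strict criterion
outright. For publication-grade inference on the asymptote hierarchy,
lengthen/thin the chains.

## Synthetic cohorts

The generator emulates the study design: 78 listeners × 8 continua × 9
steps × 3 repetitions × 2 sessions (432 trials per listener), ratings in
[0, 100], endpoint assignment reversed in the second session (the stored
raw rating is `100 − aligned` there, with `endpoint_reversed = 1`).

Population defaults: asymptotes 5/95, crossover 5, slope `exp(η)` with
`η̄ = log 12` (rating units per step), trial SD `exp(ν)` with
`ν̄ = log 10`; between-subject SDs (latent) 3.0 / 0.10 / 0.4 / 0.35 / 0.5
for `(L, δ, c, η, ν)` and smaller between-continuum offsets shared across
subjects. Cross-continuum trait structure is equicorrelated: a subject's
`ν` across continua shares a latent consistency trait with correlation
0.7, their `η` a latent slope trait with correlation 0.35 — the
"consistency is trait-like, slope less so" configuration whose recovery
the acceptance checks measure.

Three archetypes:

* **graded** (the model's own data-generating process): truncated-Normal
  around the subject's piecewise mean;
* **endpoint_bimodal**: a two-component mixture hugging 0 and 100 with
  within-component SD `exp(ν)` and a step-dependent weight. The default
  weight is a logistic in step with its own steepness; a `matched` mode
  instead derives the weight from the subject's piecewise mean and the
  analytic truncated component means, so the step-wise expected rating
  *exactly* equals the graded subject's. The matched mode exists because
  the bounded scale shifts the truncated component means, and no logistic
  weight can then match means exactly; moment-matching is what the
  graded-vs-bimodal dissociation checks need. Means match at interior
  steps; at the extreme steps the graded archetype's own truncation shift
  (≈ 0.8σ at an asymptote equal to the bound) leaves a small gap;
* **flat**: truncated-Normal around midscale regardless of step —
  random/unreliable responders, present by default at 10/78 of the cohort
  so the exclusion filter has its intended prey.

Archetype counts use deterministic largest-remainder rounding.
Everything is reproducible bitwise from the config seed.

What the generator does **not** emulate: session/order effects, reaction
times, step-dependent (heteroscedastic-in-step) noise, exact-0/100
response point masses, lapses, or any audio. Passing tests therefore show
that the pipeline recovers the structure this generator encodes, not that
real listeners satisfy the model.

Questionnaires (AQ 50 items 1–4, PSWQ 16 items 1–5, UPPS-P 59 items 1–4)
are simulated item-wise from a discretized latent Gaussian (item loading
0.7, equal-probability thresholds). Requested score-level correlations —
the AQ–PSWQ correlation (default 0.55) and any score-trait association
(default 0: the null configuration) — are disattenuated internally by a
Monte-Carlo estimate of the total-score/latent correlation so that the
*observed* total-score correlations hit their targets. Default scoring
schemes: PSWQ with the standard reverse-keyed set {1, 3, 8, 10, 11}; AQ
with the conventional 26-item reverse set and five 10-item subscales;
UPPS-P as five structural blocks (12/11/10/12/14 items) with no reverse
keys — the UPPS-P map here is a synthetic-data default, not the published
instrument's key, and all schemes are config-driven for real data.

## Preprocessing rules

Ratings are aligned so every psychometric function rises
(`aligned = 100 − raw` when the endpoints were reversed; a raw 100 becomes
0). The data-quality filter excludes a listener iff their mean aligned
rating over step-1 trials exceeds 25 **and** their mean over step-9 trials
falls below 75 — failure at *both* unambiguous endpoints, i.e. inability
to discriminate even the clear tokens. Both thresholds, the AND/OR
combination, and an alternative trial-share reading (fractions of extreme
trials on the wrong side of midscale) are configurable, because the
verbal rule admits more than one formalization; the mean-based AND
reading is the default.

## Indices and trait analysis

Per subject × continuum the package takes posterior means of the
subject-level `η` (slope index) and `ν` (variability index) — fixed
effect plus subject intercept, on the latent log scale where the random
effects are Normal and Pearson correlation is natural (a natural-scale
option exponentiates first). Trait consistency of an index is its matrix
of pairwise Pearson correlations across continua (pairwise-complete,
Spearman selectable), summarized by the raw arithmetic mean and the
Fisher-z back-transformed mean of the C(n,2) coefficients, with the
two-tailed critical value `r* = t*/√(t*² + n − 2)` reported for context.
No multiple-testing correction is applied to the matrix: the analysis
reads effect-size patterns, not individual significances.

Questionnaire totals are regressed on per-subject average indices by OLS
with outcome and predictors z-scored (sample SD, denominator N−1),
reporting the coefficient table, overall F with `(p, N−p−1)` degrees of
freedom, and adjusted R²; a collinearity pre-check reports the predictor
correlation matrix. Complete cases only throughout — no imputation
anywhere.

## Pipeline

`run_pipeline` sequences simulate/read → align → exclude → validate →
fit → indices → correlations → regressions, writing every artifact under
one run directory. A single seed derives per-stage seeds through
`SeedSequence` spawn keys; identical config + seed reproduces identical
index tables byte for byte. The MCMC stage is cached by a content hash of
its input table and fit configuration. The run report (pydantic model,
hence a published JSON schema) reconciles stage counts
(read = retained + excluded) and fails hard on mismatch.

## Problem sizes in the checks

The test suite and acceptance script run reduced-but-faithful sizes
chosen to exercise every claim at Monte-Carlo error well below the
asserted margins: recovery and dissociation cohorts of 40 subjects × 54
trials with 2 chains × 500 draws; the trait-consistency headline over 20
replicate cohorts of 40 subjects × 3 continua at 2 × 300 draws; the
full-design acceptance run at 78 subjects × 8 continua with 2 × 500
draws. Generator-level moment checks use 10⁴–10⁵ trials; the permutation
null uses 10⁵ permutations at n = 68.
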