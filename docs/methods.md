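# Methods

`lifespace` implements a day-level analysis pipeline linking momentary pain
reports to GPS-derived life-space mobility in home-anchored cohorts such as
older adults with knee osteoarthritis: a synthetic cohort generator, a
trajectory feature extractor, day-level pain aggregation, and a
within/between-person mixed-effects model. This note records the models,
the parameter choices and their rationale, the numerical decisions, and
what the test suite does and does not establish.

## Life-space features

One participant-day of GPS fixes (nominally every 15 minutes) is summarised
by ten features in four families.

**Excursion family.** Excursion size is the farthest great-circle distance
from home reached during the day (km); excursion span is the farthest
pairwise distance among away-from-home fixes (km, zero when fewer than two
fixes are away); total distance is the sum of consecutive fix-to-fix
distances (km). "Away from home" means strictly beyond the 100 m home
radius; "at home" means within it, inclusively. The triangle inequality of
the great-circle metric guarantees span ≤ 2 · size.

**Ellipsoid family.** The day's activity space is the minimum-area ellipse
(ellipsoid hull) containing *all* of the day's fixes, computed in a local
plane; reported as area (km²) and the minor and major axis diameters (km).
All fixes are used, not only stationary ones, matching the definitional
choice that the hull describes everywhere the person went.

**Clustering family.** Fixes are first classified stationary/moving by the
time-derivative speed at each fix (consecutive great-circle distance over
elapsed time); a fix is stationary below 1 km/h. The first fix of a day has
no backward difference and inherits the second fix's speed; a single-fix
day is stationary. Stationary fixes are grouped by adaptive k-means: k
starts at 1 and increases until every fix lies within 500 m of its assigned
centroid (an inclusion criterion, so the procedure always terminates — at
worst every distinct point is its own centroid). Reported features are the
number of clusters and the Shannon entropy H = −Σ pᵢ log pᵢ of the dwell
shares pᵢ (fraction of stationary fixes per cluster). The logarithm is
natural by default and configurable (`entropy_base`); dwell shares are
restricted to (0, 1], so empty clusters are dropped before the entropy is
taken and H = 0 exactly when one cluster holds everything.

**Trips and homestay.** Fixes are labelled home/away by the 100 m radius.
A trip is a maximal run of away fixes immediately preceded and followed by
a home fix within the same day; away runs truncated by the day boundary are
not counted. Homestay is the fraction of the day's fixes at home.

### Geometry

Distances use the haversine great-circle formula with Earth radius
6371.0088 km; at neighbourhood-to-city scale the difference from an
ellipsoidal geodesic is orders of magnitude below GPS noise. Planar work
(the ellipse, k-means) uses an azimuthal-equidistant projection about the
day's fix centroid: distances and bearings from the origin are preserved
exactly, and pairwise distances within 100 km of the origin distort by less
than 0.5% (tested). Points more than 500 km from the projection origin are
flagged with a warning.

### Minimum-area ellipse

The MVEE is computed by maximising log det of the weighted scatter of the
lifted points over the probability simplex (the dual of the minimum-volume
problem). Numerical pipeline: reduce to convex-hull vertices (the hull
determines the ellipse), whiten by the covariance (the MVEE commutes with
affine maps, and ascent methods crawl on clouds that are kilometres long
and metres wide), run Khachiyan-style ascent with pairwise add/away steps,
and finish with Newton steps on the KKT system of the active support
(every support point has leverage d + 1; the Jacobian is the closed form
−(qᵢᵀX⁻¹qⱼ)²). Convergence is declared at a duality gap below 1e−7 with a
10 000-iteration cap; exceeding the cap raises an error rather than
returning a silently unconverged ellipse. The shape matrix is scaled
minimally at the end so that every input point is inside within 1e−6 km.
Degenerate inputs are explicit: one point gives a zero ellipse; collinear
points (second singular value below 1e−9 of the first) give a zero-width
ellipse along the principal direction, with zero area. Tests verify the
area against an independent SLSQP constrained-optimisation oracle (1%
tolerance, in practice agreement is ~1e−7) and check containment, the
diameter bound, rigid-motion invariance and the area identity
A = (π/4)·major·minor.

### Day handling and validity

Timestamps are stored timezone-aware; days are bucketed by the local civil
date carried in the offset. Duplicate timestamps within a participant are
rejected at ingestion. Days with fewer than `min_fixes_per_day` fixes
(default 10) are summarised but flagged invalid and excluded from modelling
by default. Home coordinates are an explicit input (studies typically know
them); when absent they are estimated as the centroid of the modal
night-time (midnight–6 AM) dwell cluster.

## Pain aggregation

Prompts carry an integer 0–10 box-scale rating or are missing; at most one
answered prompt per window (morning 8–12, afternoon 12–16, evening 16–20)
per day. The day mean is the average over answered prompts — real-valued,
never rounded — and is missing when no prompt was answered (a
`min_prompts` option can require more). Days are dichotomised at 2 (low
< 2 ≤ high) for descriptive display only.

## Within/between-person model

For each feature y and participant i, day d:

y_id = β₀ + β_w·(pain_id − pain̄_i) + β_b·(pain̄_i − pain_gm)
     + γ₁·age_i + γ₂·female_i + γ₃·lives_alone_i + u_i + e_id,

with u_i ~ N(0, τ²) a participant random intercept and e_id ~ N(0, σ²)
independent within participant (the independent covariance structure).
Person-mean centering makes β_w the within-person effect (is mobility lower
on a person's worse-than-usual pain days?) and β_b the between-person
effect (do people with higher average pain move less?). Choices:

* the grand mean is the unweighted mean of person means by default, so
  participants with more wear days do not dominate the between contrast;
  a pooled-mean option exists (`grand="pooled"`);
* estimation is REML (statsmodels `MixedLM`); if the default optimiser
  fails — common when τ² sits at the zero boundary, as for near-constant
  features like trip counts — a short sequence of optimisers is tried and
  boundary fits are flagged in the output rather than silenced;
* covariates that are constant in the analysis sample (e.g. nobody lives
  alone in a tiny cohort) are dropped with a note instead of producing a
  singular design;
* inference is by the normal reference: z = coef/SE, two-sided p, 95% CI
  = coef ± 1.96·SE;
* one model per feature, no multiplicity adjustment, and per-feature
  failures are isolated in the results table;
* no random slope: the target estimand is a single within coefficient per
  feature with independent residuals, for which a random intercept is the
  matching two-level structure.

## Synthetic cohort

The generator is the test substrate; it emulates the statistical structure
of a small smartwatch deployment, not behavioural realism. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_participants` | 19 | cohort size |
| `mean_days`, `sd_days` | 13.16, 2.94 | wear days ~ Normal, rounded, min 1 |
| `fix_interval` | 15 min | GPS sampling |
| `prompt_response_rate` | 0.82 | per-prompt answer probability |
| `pain_grand_mean` | 1.0 | grand mean of latent pain |
| `pain_between_sd` | 1.2 | SD of person means μ_i |
| `pain_within_sd` | 1.5 | SD of day deviations |
| `beta_within` | {excursion_size: −3.06} | km per within pain point |
| `beta_between` | {excursion_size: −3.79} | km per between pain point |
| `base_excursion_mean/sd/min` | 25, 5, 10 km | participant mobility intercept |
| `excursion_noise_sd` | 4 km | day-level noise |
| `gps_noise_sd` | 10 m | isotropic fix noise |
| `age_mean/sd` | 73.1, 4.8 | demographics |
| `prop_female`, `prop_live_alone` | 0.68, 0.21 | demographics |

Latent day pain is p_id = clamp(round(μ_i + ε_id), 0, 10). The pain
defaults were set analytically so that P(p_id ≥ 2) = Φ(−(1.5 − 1.0)/√(1.2²
+ 1.5²)) ≈ 0.40, i.e. about 40% of day means reach the high-pain band, and
simulated day means span roughly 0–8; the tests confirm both marginals.
Each day's travel consists of 0–3 out-and-back trips from home sampled at
the fix interval, with trip speeds 5–40 km/h, dwells of 0.5–2 h at each
endpoint (so clustering sees non-degenerate dwell groups), and overnight
(8 PM–8 AM) fixes at home plus GPS noise. The farthest point of the day's
main trip equals the intended excursion size

max(0, base_i + β_b·(μ_i − grand mean) + β_w·(p_id − μ_i) + noise),

recorded in the ground-truth table, so the within- and between-person
effects on excursion size are known exactly. The base-excursion
distribution (Normal(25, 5) truncated at 10 km) is deliberately generous:
the additive pain effect spans up to about ±12 km, and keeping the linear
predictor far from the max(0, ·) floor keeps the generative model in its
linear regime, which is what makes exact parameter recovery a meaningful
contract. Consequently the synthetic cohort is *more* mobile than a
typical osteoarthritis cohort and has no mass of fully homebound days;
passing recovery tests therefore demonstrate estimator correctness under
the stated generative model, not robustness to floor effects, skewed
mobility distributions, wear-time gaps, weekday structure or reactivity —
none of which the generator models.

Prompt ratings carry the latent day pain. A `prompt_jitter_prob` option
adds ±1-point response noise; it defaults to 0 because symmetric rating
noise is classical measurement error on the within-pain regressor and
attenuates the fitted within effect (regression dilution) — with ~2.5
answered prompts per day the attenuation of a −3.06 effect is roughly
0.4 km/point, many standard errors at simulation scale. With the default
the day-mean pain the model sees equals the latent pain that generated the
mobility, so the generator's effect parameter is exactly the estimand and
confidence-interval coverage can be evaluated against it. Only the
excursion-size entries of the β maps drive geometry; other features respond
through the induced geometry (a shorter farthest trip shortens spans,
distances and ellipse axes mechanically).

`drop_gps_days` removes all fixes of a randomly chosen fraction of
participants, emulating missing-at-random device failures.

All randomness flows from a single seed through independent spawned
streams (participants, day panel, trajectories, prompt times), so the full
cohort and the day-level fast path `generate_day_panel` draw identical
day-level truths, and identical configs give identical tables.

## Simulation scale of the statistical checks

Parameter recovery and calibration are evaluated at 100 participants × 30
days. One replicate runs the full trajectory pipeline (simulate ~290k
fixes, extract ~3000 feature days, aggregate, fit) and checks sign and
|β̂_w − β_w| ≤ 0.5. Replicated checks use the day-level panel directly:
mean absolute error over 50 seeds, CI coverage of the true β_w over 600
replicates (expected in 93–97%; the band is narrow, so the coverage
estimate needs a Monte-Carlo standard error well below one percentage
point), and null calibration (β = 0) over 200 replicates (rejection at
α = 0.05 expected in 3–8%). Using the day-level
panel for the replicated statistics is justified by a separately tested
geometry-consistency property: on every generated day the extractor's
excursion size matches the ground-truth intended excursion within
3·GPS-noise plus a small sampling margin (≤ 50 m), which is negligible
against kilometre-scale effects.

## Known limitations

* The generator's mobility process is a stand-in; its only contract is the
  statistical structure above.
* The entropy base used in any given study is conventionally ambiguous;
  natural log is the default and the base is a reported configuration
  option.
* Trip counting at day boundaries: a person away over midnight contributes
  no trip to either day.
* The mixed model assumes homoskedastic Gaussian residuals; heavy-tailed
  mobility days in real data would call for robust or transformed variants
  that are out of scope here.
* With a single random intercept, within-person residual correlation
  beyond the intercept (e.g. autocorrelation across consecutive days) is
  not modelled.
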