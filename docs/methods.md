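# Methods

This note documents the models, default parameters, numerical choices and
design decisions behind `equialloc`, and states what the synthetic-data
generators do and do not emulate.

## Synthetic transplant registry

Ground truth is a Weibull proportional-hazards model for death-censored
graft failure:

```
S(t | x, g) = exp( −(t/λ)^k · exp(βᵀ(x − x₀) + b_g) )
```

* **Covariates** (EPTS/KDPI-inspired reduced set): recipient age
  ~ N(52, 13²) clipped to [18, 80] years; diabetes ~ Bernoulli(0.35);
  dialysis years ~ Exp(mean 3); donor age ~ N(40, 15²) clipped to [12, 75];
  donor quality index ~ U(0, 1). Coefficients are centred (`x₀`) so the
  default cohort has near-zero mean log relative hazard.
* **True coefficients** (log-hazard per unit): age 0.02/yr, diabetes 0.30,
  dialysis 0.05/yr, donor age 0.015/yr, donor quality 0.80. These produce a
  realistic covariate-driven spread of five-year graft survival around a
  baseline of ~75% (shape k = 1.1, scale λ = 5667 days).
* **Subpopulations**: ethnicity (7 levels, reference minority share 15%),
  gender (2), ABO blood type (O/A/B/AB at 45/40/11/4%). By default the
  joint distribution is the product of marginals, so groups are
  exchangeable with respect to outcomes — the null against which injected
  biases are detected.
* **Censoring**: enrollment uniform over a 3-year accrual window with a
  hard administrative cutoff 5 follow-up years after accrual ends; a record
  is an event iff failure precedes its cutoff. No competing-risk death
  process is modelled (death with a functioning graft is, by definition of
  the outcome, censoring; the administrative mechanism stands in for all
  censoring causes).
* **Bias injection**: `bias_spec` maps a group level to an additive
  log-hazard offset carried by an *unmeasured* term `b_g` — deterministic
  given the group, never exported as a feature. Fitted models therefore
  inherit the distortion. The degenerate (noise-free) carrier is a
  deliberate simplification: it gives the sharpest, most reproducible
  directional effect.

What the generator does **not** emulate: real OPTN covariate marginals and
correlations, HLA matching, re-transplantation, living donors, organ
discard, geography, or listing behaviour. Passing tests demonstrate that
the *mechanics* (estimation, metrics, policies, bias propagation) behave as
documented, not that real registry effect sizes are reproduced.

## Survival predictors

* **Cox** — scikit-survival backend: partial likelihood with Breslow tie
  handling, Breslow baseline hazard. Predictions use
  `S(t|x) = S₀(t)^{exp(xᵀβ)}` on the training event-time grid.
* **Survival tree** — log-rank splitting, Kaplan–Meier leaf curves;
  defaults min leaf 50, unlimited depth; `max_depth=0` is the degenerate
  single-leaf tree (pooled Kaplan–Meier), used as an oracle in tests.
* **Random survival forest** — bootstrap ensemble of log-rank trees,
  `√p` features per split, 100 trees, min leaf 15; prediction is the
  ensemble-average survival curve. Seeded, hence deterministic per seed.
* **Imputation** — single imputation, median (numeric) / mode (other),
  learned on the training split only and reused on the test split.
* **Monte-Carlo CV** — ten repetitions of a seeded random 80/20 split by
  default; repetition seeds derive from the protocol seed via a seed
  sequence; splits with fewer than two events on either side are redrawn
  (logged, at most ten times).
* **RMST** — trapezoidal integration of the survival curve on
  `[0] ∪ {event times ≤ H} ∪ [H]`, carrying the last value forward. For
  Cox inside the allocation simulator, RMST(e) = ∫S₀(t)^e dt is
  precomputed exactly on a dense log-spaced grid of relative hazards
  e ∈ [10⁻⁶, 10⁶] (4097 points) and interpolated in log e; the observed
  interpolation error is ~10⁻³ days on multi-year horizons, far below any
  decision threshold. Tree/forest predictions go through per-leaf curve
  tables / the backend's curve aggregation.
* Group labels are *not* features by default. `group_dummy_features`
  deliberately adds group indicators for experiments on learned bias
  (points-style allocation scores historically included a race term, so
  this is a realistic modelling choice, not only a test device).

## Prediction-equity metrics

* **IPCW** — calibration metrics are inverse-probability-of-censoring
  weighted with a Kaplan–Meier censoring-survival estimate Ĝ: weight
  1/Ĝ(Tᵢ⁻) for records failing by t, 1/Ĝ(t) for records followed past t,
  0 for records censored before t. Normalization is by n, so weights have
  mean ≈ 1.
* **Mean signed error** — weighted mean of (𝟙[T>t] − p̂): negative ⇔
  survival overestimated.
* **Concordance** — Harrell's C; a pair is comparable when the
  shorter-observed record has an observed event; prediction ties count ½.
  The subpopulation C-index keeps only comparable pairs with ≥1 group
  member; with the whole population as the group it reduces to the overall
  C-index exactly (the pair sets coincide). Undefined metrics (no
  qualifying pairs) raise and are reported as missing cells.
* **Bias flags** — "significantly different from overall" is implemented
  as a paired test across repetitions: per-rep difference (group − overall)
  with SE = SD(diff)/√reps, compared against a Student-t critical value at
  a Bonferroni-adjusted level α/m, where α = 2(1−Φ(k)) (k = 2 by default)
  and m is the number of group cells in the table. The family-wise
  control is deliberate: with ~20–40 cells per table, an unadjusted
  per-cell 2·SE rule would flag noise in most exchangeable runs, making
  "no flags under exchangeability" — a property the test suite checks —
  unattainable by construction. Injected biases of practical size exceed
  the adjusted threshold by a wide margin. Flag direction follows whether
  the deviation is favorable (lower Brier, higher C) and, for the signed
  error, the sign of the deviation itself.

## Allocation simulator

* Candidate and organ streams are homogeneous Poisson processes (defaults:
  1,000 and 650 arrivals/year; the reduced scale used in the heavier tests
  is 500/325 per year over 12 years with a 3-year warm-up and 10
  replications, chosen so a full directional experiment stays desk-scale).
  Each candidate draws a latent waitlist-departure day from an exponential
  per-day hazard (default 1/1500), independent of policy, so policies are
  compared on identical populations; the default scarcity and departure
  hazard put overall transplant probability near 0.6.
* Event processing is chronological; an arriving organ is offered once to
  the policy's choice among ABO-compatible, active (listed, not departed,
  not transplanted) candidates and discarded if no one is compatible.
  Standard ABO matrix only; the finer points of the operational allocation
  system (A2 subtyping, O/B protections, geographic units, offer refusal)
  are out of scope.
* Policies: `max_survival` (argmax predicted RMST), `fifo` (argmax waiting
  days), `hybrid` (argmax w_surv·RMST + w_wait·wait, both in days, default
  10:1 — declaring a common unit is what makes the ratio meaningful).
  Exact score ties always go to the longest-waiting candidate, so constant
  predictions collapse every policy onto FIFO.
* Statistics (TP, WTUT, ESAT) are restricted to candidates *listed* after
  the warm-up period — simpler and unambiguous relative to event-time
  filtering. Missing cells (no post-warm-up candidates or transplants in a
  group) are logged and skipped. Replication summaries reuse the
  family-wise flag rule above.
* Conservation invariants (each organ at most once, no incompatible or
  post-departure transplant, transplants ≤ min(#organs, #candidates)) are
  asserted inside the event loop on every run.

## Family-planning allocation

* Response curve: `a·f^γ` client visits/year — the simplest two-parameter
  concave family whose exponent is identified by the published
  monthly→six-monthly reduction band via `1 − 6^(−γ)`; γ ∈ [0.731, 0.957]
  maps onto 73%–82%. Default γ = 0.85 (≈78.2% reduction, mid-band).
  Site batteries draw a ∈ [5, 50] clients/year-at-one-visit, γ in the
  calibrated band and priority shares in [0, 0.5] — a heterogeneity level
  at which the three allocators separate clearly while all remain
  desk-solvable.
* Effect unit is client visits (strongly and linearly related to the
  clinical outcomes of interest); a per-site CYP conversion factor can be
  layered on the same interface.
* Equity weighting is multiplicative on a site's priority fraction
  (young + low-access shares, clipped at 1 since the subpopulations may
  overlap), default weight 1.5.
* `allocate_equal`: largest single category affordable for every site.
* `allocate_greedy`: sites ranked by average clients per visit at the
  middle (reference) category; categories assigned contiguously along the
  ranking with the split chosen to maximize total client visits within the
  budget (a search over category boundaries, O(n^|categories|) with early
  pruning). This keeps the method a transparent sentence — "the top n₁
  sites monthly, the next n₂ quarterly, the rest six-monthly" — while an
  earlier candidate rule (walk the ranking giving each site the highest
  affordable frequency while reserving the minimum for the rest) proved
  measurably far from optimal (~5% mean gap) because it over-commits the
  budget to top sites; the boundary form achieves the near-optimality the
  method is known for (measured mean gaps 0.09% effectiveness / 0.72%
  weighted on the default battery). A trailing zero-frequency block occurs
  only when the budget cannot cover the minimum category for all sites.
* `allocate_exact`: dynamic program over (site index, used team-days),
  exact for the stated model; ties broken toward the lower frequency, then
  site order; guarded to ~2·10⁶ DP cells.
* `optimality_gap` is relative to the exact plan per objective. The exact
  plan maximizes the *weighted* objective, so the weighted gap is
  nonnegative by construction while the effectiveness gap may be slightly
  negative for a method that happens to score higher on unweighted
  effectiveness.

## Reproducibility

Every generator and experiment takes an explicit integer seed;
sub-component seeds derive via `numpy` seed sequences. CLI bundles include
a manifest with the resolved configuration and master seed. Deterministic
families (Cox, tree) produce byte-identical outputs for identical inputs;
the forest is deterministic given its seed.

## Known limitations

* The registry generator's marginals are stylized, not fitted to any real
  registry; absolute metric levels (e.g. Brier ≈ 0.2, C ≈ 0.6 ranges) are
  not calibration targets.
* The bias carrier is deterministic per group; graded or noisy unmeasured
  confounding would attenuate, not redirect, the documented effects.
* The simulator has no geographic structure, offer-refusal behaviour or
  re-listing, and organs are never banked.
* The greedy FP allocator's boundary search is exponential in the number
  of categories; it is intended for the handful of frequency categories
  used in outreach practice.
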