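# equialloc

Effectiveness, equity and explainability of health-service resource
allocation: a tested Python implementation of two case-study pipelines —
**donor-kidney allocation** (survival prediction feeding waitlist
allocation-policy simulation, with subpopulation prediction-equity metrics)
and **family-planning outreach** (visit-frequency allocation under a
team-day budget with effectiveness and equity-weighted objectives) — plus
the distribution-level equity mathematics (Lorenz curve, Gini coefficient,
Atkinson index / EDE, Rawlsian leximin) that scores both.

Real transplant registries are access-restricted, so a first-class
synthetic-data module generates every input the pipelines need from
explicit, seeded configurations with a known proportional-hazards ground
truth — including controllable group-linked *unmeasured* biases, so that
the propagation of learned biases from prediction into allocation can be
studied by construction.

## The models at the core

**Survival prediction.** Death-censored graft survival `T` follows, in the
synthetic ground truth, a Weibull proportional-hazards model

```
S(t | x) = exp( −(t/λ)^k · exp(βᵀ(x − x₀) + b_g) )
```

with recipient covariates (age, diabetes, dialysis years) and donor
covariates (age, quality index), and an optional unmeasured group offset
`b_g`. Three predictor families of decreasing explainability are fitted
under single imputation and Monte-Carlo cross-validation (ten repetitions,
80/20): a Cox proportional-hazards model (Breslow ties and baseline), a
survival decision tree (log-rank splits, Kaplan–Meier leaves) and a random
survival forest. Each exposes `predict_survival_prob(x, t)` and
`predict_rmst(x, H)` (restricted mean survival time, `∫₀ᴴ S(t)dt`).

**Prediction equity.** Per subpopulation (ethnicity × gender) across CV
repetitions: IPCW Brier score, IPCW mean signed error (negative ⇔ survival
overestimated), Harrell's C-index, and the **subpopulation C-index** —
Harrell's C restricted to comparable pairs with at least one member in the
subpopulation. Cells deviating significantly from the overall row are
flagged as positive/negative biases under a family-wise-controlled rule.

**Allocation simulation.** Poisson candidate/organ arrival streams with
scarcity; every arriving organ goes to one ABO-compatible candidate chosen
by a policy — maximize predicted survival, FIFO (longest waiting), or a
10:1 hybrid of the two (ties always to the longest waiting). Replicated
simulations report TP (transplant probability), WTUT (waiting time until
transplant) and ESAT (expected survival after transplant) per
subpopulation.

**Family planning.** A site's yearly client visits respond to its visit
frequency `f` as a concave power law `a·f^γ`, with `γ ∈ [0.731, 0.957]`
calibrated so that moving from monthly to six-monthly visits reduces client
visits by 73%–82% (closed form `1 − 6^(−γ)`). Three allocators of
decreasing explainability assign frequencies from {12, 4, 2} visits/year
under a 220 team-day budget: equal frequencies, greedy categorization by
average clients per visit, and an exact dynamic program maximizing the
equity-weighted objective (priority weight 1.5 for young and low-access
client shares).

## Worked example

```bash
equialloc allocate-fp --seed 1 --out out/fp_demo
```

generates 40 synthetic outreach sites, runs the three allocators and prints
`out/fp_demo/scores.json`:

```json
{
  "equal":  {"effectiveness": 3670.4, "weighted_effectiveness": 4607.9,
             "gap_effectiveness_pct": 42.31, "gap_weighted_pct": 43.05},
  "greedy": {"effectiveness": 6325.8, "weighted_effectiveness": 8037.2,
             "gap_effectiveness_pct": 0.57,  "gap_weighted_pct": 0.67},
  "exact":  {"effectiveness": 6362.2, "weighted_effectiveness": 8091.6,
             "gap_effectiveness_pct": 0.0,   "gap_weighted_pct": 0.0}
}
```

Read: allocating every site the same quarterly frequency leaves ~42% of
attainable client visits on the table, while the explainable greedy
categorization ("top-ranked sites monthly, next block quarterly, rest
six-monthly") is within 0.6–0.7% of the exact optimum on both the plain and
the equity-weighted objective — explainability costs almost nothing here.

The kidney pipeline is driven the same way (`equialloc predict-equity`,
`equialloc allocate-kidney`); e.g. the per-ethnicity transplant
probabilities of a survival-maximizing policy can be summarized by their
Gini coefficient:

```python
>>> from equialloc import equity
>>> equity.gini([0.63, 0.68, 0.62, 0.56, 0.66, 0.41, 0.72])
0.0807743658210948
```

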