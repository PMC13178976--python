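# teamdynam

Coordination dynamic network actor models (DyNAM) for face-to-face team
interaction recorded with wearable proximity badges.

Small R&D teams generate thousands of brief face-to-face contacts per
week. Infrared badge sensors capture them as raw detection bursts; the
scientific questions — does gender homophily shape who talks to whom?
does professional status? do gender-based status cues? — live at the
level of *relational events*: time-stamped undirected interactions whose
probability depends on both the event history and the dyad's attributes.
`teamdynam` implements the full chain for that analysis:

1. **Aggregation** — collapse infrared detections into undirected events
   (tumbling 75-s windows, at least 2 detections), respecting badge
   on/off presence.
2. **Covariates** — dyadic indicators for gender pairing, seniority
   pairing, their interactions, dichotomised (> 3) advice and friendship
   surveys, co-location, and same age/tenure bands.
3. **Multiple imputation** — hierarchical lognormal model for missing
   age/tenure, hierarchical p2 model for missing network ties; M
   completed datasets from posterior-predictive draws.
4. **Estimation** — a hierarchical coordination DyNAM. The probability
   that the pair {i, j} produces the next event is

       P_{i<->j}(y) = p(i->j) p(j->i) / sum_{k<l} p(k->l) p(l->k),
       p(i -> j; y, b) = exp(b's(i,j,y)) / sum_{k in A\{i}} exp(b's(i,k,y)),

   with endogenous statistics (inertia, degree, recency), context-specific
   fixed effects b_k^c and team-level random inertia slopes
   a_g ~ N(g^c, s^2). Posterior sampling is Hamiltonian Monte Carlo with
   analytic gradients and a Laplace-preconditioned metric; draws are
   pooled across imputations.
5. **Interpretation** — posterior medians, 95% equal-tailed intervals,
   probability of direction (pd), cross-context contrasts, and
   prototypical-dyad probability ratios PR = exp(2 Db) (the factor 2
   reflects the mutual-agreement mechanism).

A synthetic-data generator (`teamdynam.simulate`) produces rosters,
surveys, presence schedules, model-drawn event sequences and raw
detection streams with known ground truth, so the entire pipeline runs
and is tested without any external data. See `docs/methods.md` for the
model details and numerical choices.

## Worked example

Simulate a small two-team study (known truth: woman-woman effect -0.5,
junior-junior -0.2), aggregate, impute and fit:

```bash
teamdynam simulate --outdir study --seed 7 --events-per-team 300 \
    --teams-per-context "uni=1,lab=1" --missing-rate 0.2
teamdynam aggregate --studydir study
# -> 595 events; 0 detections dropped
teamdynam impute --studydir study --m 3 --seed 7 --draws 300 --warmup 200
teamdynam fit --studydir study --seed 7 --chains 2 --draws 150 --warmup 100
# -> fitted 3 imputations; pooled 900 draws; converged=False
teamdynam summarize --studydir study
```

(The conservative convergence flag trips when any parameter's split
R-hat exceeds 1.05 — common at these demo-scale draw counts; the
per-parameter diagnostics are written next to the draws.)

The summary table reports, per coefficient and context, the posterior
median, 95% interval, pd, and an evidence grade; at this desk scale the
generating negative gender-homophily effect is recovered in both teams:

```
            parameter        effect context    median    ci_2.5   ci_97.5     pd evidence_grade
beta[woman_woman,uni]   woman_woman     uni -1.379710 -2.531507 -0.591048  1.000         strong
beta[woman_woman,lab]   woman_woman     lab -0.628031 -1.080705 -0.300020  1.000         strong
```

A probability ratio translates the coefficient into relative interaction
probabilities of two prototypical dyads (here: woman-woman vs
mixed-gender, no ties, mixed seniority, research-lab context):

```bash
teamdynam pr --studydir study --context lab \
    --numerator "gender=woman_woman" --denominator "gender=mixed"
# -> PR=0.285 CI95=[0.115, 0.549] pd=1.000
```

i.e. in this simulated lab, a woman-woman dyad is roughly a third as
likely as a mixed-gender dyad to produce the next interaction, all else
equal. `teamdynam report` writes the full coefficient, contrast and PR
tables; `teamdynam pipeline --config run.yaml` chains every stage from
one config file.

The same operations are available as library functions
(`teamdynam.aggregate_detections`, `teamdynam.fit_model`,
`teamdynam.probability_ratio`, ...) for scripted analyses.

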