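# coged — cognitive effort discounting toolkit

People treat cognitive effort as costly, and how costly varies across
individuals and with age. The cognitive-effort-discounting paradigm makes
that cost measurable by revealed preference: a participant repeatedly
chooses between redoing an easy task (1-back) for a small, adjustable
reward and a harder task (an N-back at load N > 1) for a fixed larger
reward A. An adjusting-amount staircase titrates the easy offer to the
point of indifference; the **subjective value**

> SV(N) = indifference amount / A ∈ [0, 1]

is the fraction of reward value that survives the effort cost, and the
trapezoid **area under the SV-by-load curve** (normalized x-axis, so
AUC = 1 means no discounting) summarises each person's effort costliness
in a single, model-free number — exactly as AUC is used in delay
discounting, against which the paradigm is benchmarked.

`coged` is for researchers building or simulating such studies. It
provides:

* **`coged.nback`** — stimulus lists with exact target/lure constraints
  (targets match at lag N; lures repeat within lag N+2 but not N), an
  independent brute-force validator, and signal-detection scoring
  (clamped d′, correct-trial mean RT, threshold feedback).
* **`coged.titration`** — the halving adjusting-amount staircase (six
  choices; sixth adjustment $0.015625 at the $2.00 base) and the
  randomized non-nested trial scheduler.
* **`coged.valuation`** — SV, effort premiums, discounting AUC for load
  and calendar delays, the NASA-TLX workload composite, and paired
  amount-effect summaries.
* **`coged.agents`** — synthetic participants (linear effort costs with a
  magnitude-effect exponent, hyperbolic delay discounting, logistic choice
  noise, load-dependent performance) for closed-loop simulation and
  parameter recovery.
* **`coged.inference`** — a statsmodels-style `SubjectiveValueModel`
  whose `fit()` returns REML estimates of the random-intercept model
  SV ~ d′ + mRT + N_c (optionally with age terms and age-stratified
  residual variance), plus linear-contrast ANOVA, rank/t group
  comparisons, and the covariate regression battery.
* **`coged.session` / `coged` CLI** — experiment presets, random payment
  selection, and a seeded end-to-end pipeline with checksummed artifacts.

## Worked example

A deterministic agent with effort cost κ = 0.17 per load step values the
4-back at 1 − 0.17·3 = 0.49 of the base. Running it through the staircase:

```python
from coged import (AgentParams, make_agent, run_titration,
                   subjective_value, extra_payment, discount_auc, SVCurve)

params = AgentParams(kappa=0.17, gamma=0.0, tau=0.0)
points = {}
for level in (2, 3, 4):
    rec = run_titration(make_agent(params), level, base_amount=2.0)
    points[level] = subjective_value(rec.indifference_amount, 2.0)
    print(f"N={level}: indifference ${rec.indifference_amount:.6f}  SV={points[level]:.6f}")
print(f"premium at N=4: ${extra_payment(points[4], 2.0):.6f}")
print(f"effort AUC (levels 2-4): {discount_auc(SVCurve('demo', 2.0, points)).auc:.6f}")
```

prints

```
N=2: indifference $1.671875  SV=0.835938
N=3: indifference $1.328125  SV=0.664062
N=4: indifference $0.984375  SV=0.492188
premium at N=4: $1.015625
effort AUC (levels 2-4): 0.664062
```

Six halving adjustments resolve the indifference point to within one final
step ($0.015625) of the agent's true value — the 4-back estimate $0.984375
sits one grid point from the latent $0.98, implying this agent demands
about a $1.02 premium to perform the 4-back instead of the 1-back.

From the shell, the same machinery end to end:

```bash
coged stimuli --level 3 --seed 11            # one 64-item stimulus list
coged simulate --preset exp2 --n-per-group 25 --seed 7 --out runs/exp2
coged analyze --in runs/exp2 --model eq2     # age terms, heterogeneous variance
```

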