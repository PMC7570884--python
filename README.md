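# glybolus

A deep-reinforcement-learning meal-time insulin bolus advisor for type 1
diabetes (T1D), trained and evaluated entirely in silico on a surrogate
virtual patient. The package is aimed at researchers studying adaptive
insulin dosing algorithms: it provides the closed-loop simulation
environment, the clinical baseline, the learning agent, the two-step
training protocol with safety constraints, and the standard glycemic
outcome metrics, all behind a small statsmodels-style API and a CLI.

## The problem and the method

People with T1D dose fast-acting insulin at meals. Clinical practice uses a
standard bolus calculator (SBC) with fixed, per-patient settings:

```
bolus = CHO / ICR + (G − G_T) / ISF − IOB
```

where `CHO` is the announced carbohydrate content (g), `ICR` the
insulin-to-carbohydrate ratio (g/IU), `G` the current CGM glucose, `G_T`
the target (mg/dL), `ISF` the insulin sensitivity factor (mg/dL per IU) and
`IOB` the insulin still active from the previous bolus, decaying linearly
over `T_IOB` minutes. Fixed settings cannot track intra-day insulin
sensitivity rhythms or systematic carb misestimation.

The advisor keeps the calculator's structure but learns to rescale its
three terms. A deterministic-policy actor-critic agent (DDPG) observes, at
each meal, the state

```
s_t = { G_t ∈ R^L (CGM history), CHO_t, t_of_day, IOB_t }
```

and outputs a gain vector `μ(s_t) = [g_ICR, g_ISF, g_IOB] ∈ [0.2, 2]^3`, so
the delivered dose is

```
bolus_t = g_ICR·CHO/ICR + g_ISF·(G − G_T)/ISF − g_IOB·IOB
```

with `[1, 1, 1]` reproducing the SBC exactly. The reward for a meal is the
mean of a step function of each postprandial CGM reading over
`min(5 h, time to next meal)`: +0.5 in [70, 180] mg/dL, graded penalties
above, and harsher penalties below 70 (hypoglycemia is the clinically
dangerous side). The critic `Q(s, a | θ^Q)` is trained by importance-
weighted TD regression against slow target networks; the actor follows the
deterministic policy gradient `∇_a Q · ∇_θ μ`. Transitions are replayed
with proportional prioritization `Pr(i) ∝ (|δ_i| + ε)^α` on the TD error.

Training is two-step: a population policy is first learned on the average
virtual subject with Gaussian exploration noise N(0, 0.3); each subject's
personalized policy is then initialized from it and fine-tuned on
subject-specific data under a safety constraint (in hyperglycemia the dose
may not fall below the SBC dose, in hypoglycemia not above it).

Because licensed T1D simulators are proprietary, the environment is a
transparent minimal-model surrogate (glucose/remote-insulin dynamics,
two-compartment subcutaneous insulin and gut chains, sinusoidal ±30%
intra-day insulin-sensitivity variation, AR(1) CGM noise) with a
three-meal daily protocol (7 am 70 g, 2 pm 110 g, 9 pm 90 g; meal-time StD
30 min, size CV 10%, announced carbs 0.7–1.1 × true). Absolute outcomes are
therefore surrogate-specific; SBC-vs-agent contrasts are the meaningful
quantity. See `docs/methods.md` for the full model and its limitations.

## Worked example

```python
from glybolus import PatientParams, derive_therapy, evaluate

adult = PatientParams.nominal_adult()
therapy = derive_therapy(adult)          # ICR 8.8 g/IU, ISF 62.5 mg/dL/IU
log, report = evaluate("sbc", adult, therapy, days=14, seed=3)
print(report.tir, report.tbr, report.tar)
```

prints `71.5 3.6 24.9`: under the fixed calculator this subject spends
71.5% of CGM samples in [70, 180] mg/dL, 3.6% below 70 and 24.9% above 180
over two simulated weeks (mean glucose 140.0 mg/dL, LBGI 1.38, HBGI 5.83).

The full cohort experiment — sample a cohort, train the population model,
personalize per subject, evaluate SBC and the agent on matched scenario
seeds, and tabulate the paired comparison:

```
glybolus run --scale reduced --out runs/reduced
glybolus report --results runs/reduced/results.csv --out runs/summary.csv
```

At the reduced scale (5 adult subjects × 3 seeds, 30 + 30 training days,
14 test days; ~30 s on one CPU) this prints

```
metric       SBC         DRL       p
tir      73.1±10.8   75.0±11.0  0.0383
tbr        7.0±6.5     7.9±6.3   0.603
tar       19.9±4.3    17.1±8.6  0.0554
```

the per-run mean ± StD of each metric and the paired t-test p-value: the
personalized agent raises time in range by ~2 percentage points at this
scale (median TIR 75.5% vs 73.4%, median TBR 6.9% vs 7.2%), mainly by
cutting hyperglycemia. `--scale full` runs the full protocol (10 adults +
10 adolescents, 180 training and 90 test days). The same pipeline is
available programmatically through `glybolus.BolusAdvisor` /
`BolusAdvisorResults` (see `docs/methods.md`).

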