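# Methods

This note documents the models, algorithms and design choices in glybolus:
what is simulated, how the advisor is trained, which conventions the
metrics follow, and what the package's tests do and do not establish.

## 1. Surrogate virtual patient

The environment is a deliberately transparent minimal-model surrogate, not
a licensed physiological simulator. Seven compartments evolve under
fixed-step RK4 (dt = 1 min):

* Plasma glucose `G` (mg/dL):
  `dG/dt = −p1 (G − Gb) − SI(t)·X·G + Ra(t)/(V_G·BW)`
* Remote insulin action `X` (1/min):
  `dX/dt = −p2 X + p3 (I − Ib)`
* Subcutaneous insulin chain `S1 → S2` (mU), time constant `tmax`, feeding
  plasma insulin `I` (mU/L): `dI/dt = S2/(tmax·V_I) − ke·I`
* Gut chain `Q1 → Q2` (mg), time constant `tmax,G`; appearance
  `Ra = f_bio·Q2/tmax,G`; meal carbs enter `Q1` at a constant rate over the
  15-min meal duration.

`SI(t) = SI_nom·(1 + a·sin(2π(t − φ)/1440))` is the intra-day
insulin-sensitivity rhythm (a = 0.30 adult, 0.35 adolescent; period 24 h;
per-subject random phase). Bolus doses are impulses into `S1` (1 IU =
1000 mU).

Nominal adult constants (config.py): Gb 130 mg/dL, p1 0.004 /min, p2
0.02 /min, p3 1.5e-5 /min per (mU/L), V_G 1.6 dL/kg, BW 70 kg, tmax 55 min,
ke 0.14 /min, V_I 12 L, tmax,G 40 min, f_bio 0.8, Ib 10 mU/L. They were
chosen once so that the fixed-parameter calculator baseline produces a
clinically plausible adult profile (time in range near 70%, a few percent
below range, mean glucose near 140 mg/dL) and then frozen; no constant was
revisited afterwards. The adolescent nominal is the adult with insulin
sensitivity × 0.6, body weight 50 kg and a larger sensitivity swing — a
surrogate-only contrast emulating the harder-to-control cohort.

**Basal insulin.** Subjects are modeled as receiving a constant basal
infusion equivalent. The rate is solved from the fasting steady state:
`u_b = Ib·ke·V_I` pins fasting plasma insulin at `Ib`, which zeroes remote
insulin action and leaves glucose at `Gb` exactly (the equilibrium is a
fixed point of the integrator, verified to 1e-6 over 24 h). Because `X = 0`
at rest, the sensitivity sinusoid does not disturb fasting glucose — a
known simplification of the surrogate.

**Cohorts.** `make_cohort` perturbs the nominal multiplicatively
(log-normal, geometric CV 15%) on rates, volumes, weight and `Ib`, mildly
on `Gb`, and draws a uniform sensitivity phase per subject. Element 0 is
always the unperturbed "average subject" used for population training.

**CGM sensor.** Additive AR(1) error: lag-1 autocorrelation 0.7,
stationary StD 5 mg/dL, readings clamped to [40, 400] mg/dL, sampled every
5 min. The sensor error model is a documented stand-in; no dropout,
calibration drift or compression artifacts are modeled.

**Scenario generator.** Three meals daily at 7 am (70 g), 2 pm (110 g),
9 pm (90 g); meal times get N(0, 30 min) jitter (re-drawn up to 10 times if
meals would overlap or leave their day), sizes are N(nominal, 10% CV)
truncated positive, and the announced carbs — the only value the calculator
and the agent see — are the true carbs times U(0.7, 1.1), drawn per meal.
Everything is deterministic given the scenario seed.

## 2. Therapy baseline

`derive_therapy` computes each subject's fixed clinical settings from their
nominal physiology: one IU produces an integrated remote-insulin exposure
`(p3/p2)·1000/(V_I·ke)`, giving `ISF ≈ SI_nom·exposure·G_ref` (G_ref
140 mg/dL) and `ICR = ISF·V_G·BW/1000/f_bio`. Target glucose is 120 mg/dL,
`T_IOB` 240 min. These settings are internally consistent with the
surrogate's mean dose response but ignore the intra-day sensitivity rhythm
and announcement errors — precisely the gap an adaptive policy can close.
Insulin on board uses the single most recent bolus with linear decay; an
optional stacked variant (summing all active boluses) exists but is off by
default, since close-together meals are rare under the three-meal protocol.
Negative calculator doses clamp to zero.

## 3. Reward

Each postprandial CGM reading is scored by a step function (+0.5 in
[70, 180], −0.8 in (180, 300], −1.0 in (300, 350], −1.5 in [30, 70), −2.0
otherwise; band edges closed exactly as stated). The meal reward averages
these scores over samples strictly after the meal start up to and including
`min(meal + 5 h, next meal)`. Averaging over *samples* rather than dividing
by elapsed clock time keeps the reward invariant to the sampling unit; the
pre-meal reading is excluded to avoid double counting across consecutive
windows. The reward is bounded in [−2, 0.5] and attains 0.5 exactly when
the whole window stays in range.

## 4. Agent

Actor and critic are three-hidden-layer fully connected ReLU networks
(default width 64) in plain float64 numpy with hand-written backprop — at
this scale no autodiff framework is needed, and the analytic gradients are
verified against central finite differences in the test suite. Output
layers are initialized near zero (U(±3e-3)) so the initial policy sits at
the mid-range gain and the initial value surface is flat.

* State: the last L = 12 CGM samples (55 min of history), announced carbs,
  (sin, cos) of clock time, and IOB, standardized by fixed affine scales
  ((G−140)/60, CHO/100, IOB/10) so checkpoints are portable across
  subjects.
* Action head: `g = 1.1 + 0.9·tanh(z)` maps pre-activations onto
  [0.2, 2]; the mid-range point 1.1 keeps the no-op (calculator-like)
  policy reachable near zero pre-activation. Exploration noise is Gaussian
  in gain space, after the squash, then re-clipped to [0.2, 2]; emitted
  gains therefore never leave the range regardless of noise magnitude.
* Critic update: targets `y = r + γ·Q′(s′, μ′(s′))` from slow target
  copies; the loss is the importance-weighted mean squared TD error; one
  Adam step (lr 1e-3, decoupled weight decay 1e-2). γ = 0.9 discounts
  across successive meals; the task is continuing (no terminal states — a
  "day" is only a logging unit), and for the final meal of a run the
  bootstrap state is taken at the end of its 5-h window with zero announced
  carbs.
* Actor update: one Adam step (lr 1e-4) ascending the batch-mean critic
  value of the actor's own action (importance weights enter through the
  critic only). Target networks blend with τ = 0.01 every update.

The critic weight decay and the near-zero output initialization are the
two stabilizers that matter at small sample sizes: without them the actor
exploits critic extrapolation error outside the visited action region and
drifts toward systematic over-dosing. Both were selected by ablation on
population-phase training reward; see `config.AgentConfig` for every
default.

## 5. Prioritized replay

Proportional prioritization: `Pr(i) = (|δ_i| + ε)^α / Σ (|δ_n| + ε)^α`
with ε = 0.01 (zero-error transitions stay sampleable) and α = 0.6; α = 0
recovers uniform sampling. New transitions enter with the current maximum
priority so each experience is trained on at least once. Importance weights
`w_i = (N·Pr(i))^{−β}` are normalized by the maximum weight over the whole
memory (so the largest possible weight is 1; a sampled batch's maximum
reaches 1 exactly when the minimum-priority item is drawn). β anneals
linearly 0.4 → 1 over the expected number of updates (configurable off).
Storage is a FIFO ring with linear-scan sampling — meal transitions are
sparse (3/day), so the memory never grows past a few hundred entries in
practice and a tree index would be an optimization, not a contract.

## 6. Two-step training and safety constraint

Population phase: the agent interacts with the average subject under
exploration noise N(0, 0.3) and no constraints. Personalized phase: weights
start from the population checkpoint (transfer learning; optimizer state
restarts), exploration is reduced to N(0, 0.1) — kept nonzero so
fine-tuning still explores locally, configurable to 0 — and the safety
constraint is enforced on every executed dose.

The constraint is stated on the *effective dose ratio* against the
calculator: above 180 mg/dL the executed dose is `max(proposed, SBC)`,
below 70 mg/dL `min(proposed, SBC)`, otherwise unchanged. The published
rule speaks of "the action gain" in the singular while the action has three
components; the dose-ratio reading is the only unambiguous one. When the
constraint changes the dose, the transition stored for learning carries the
proposed gains rescaled by the executed/proposed dose ratio (clipped to
range) — the gain-to-dose map is not invertible, so this is the closest
representable executed action.

Each stored transition triggers 5 gradient updates (prioritized sample,
critic step, priority refresh, actor step, soft update). Sparse meal events
(3/day) make this replay ratio the main sample-efficiency lever; 1 update
per transition is the literal single-step variant and remains available.
Updates begin once the memory holds max(32, batch) transitions, capped at
half the scenario's meals so short diagnostic runs still train.

Training stops at the configured horizon or earlier when the moving
average of the critic loss changes by < 0.1% between consecutive 50-update
windows ("loss convergence"); divergence (non-finite loss) aborts with a
diagnostic. The canned experiment protocols in `glybolus.experiments`
disable the early stop: it exists to cap long-horizon population training,
and truncating runs whose duration is already fixed explicitly only
discards data.

Evaluation freezes the policy (no learning, no exploration, no constraint)
and reuses one scenario seed per subject across compared methods, so the
calculator and the agent consume bit-identical meal sequences and sensor
noise; with gains pinned at [1, 1, 1] the full closed loop reproduces the
calculator trace bit for bit (a test asserts this).

## 7. Outcome metrics

* TIR / TBR / TAR: percentage of CGM samples in the closed interval
  [70, 180] mg/dL, below 70, above 180; the three always sum to 100%.
* Mean and CV: whole-evaluation-period mean and 100·StD/mean (sample StD,
  ddof 1). Per-day averaging of CV is a defensible alternative; the
  whole-period convention is used and documented here.
* LBGI / HBGI: Kovatchev symmetrized risk, `f(G) = 1.509((ln G)^1.084 −
  5.381)`, per-sample risk `10 f²` assigned to the low (f < 0) or high
  (f > 0) index, averaged over all samples. A trace constant at the
  symmetrization zero (≈112.5 mg/dL) scores (0, 0).
* CVGA: per-day (midnight to midnight, simulator clock) glucose extrema
  classified on the standard 3×3 grid — minimum axis 110 → 50 mg/dL with
  boundaries at 90 and 70, maximum axis 110 → 400 with boundaries at 180
  and 300, values clamped to the axes; best corner A, worst corner E, and
  an A+B membership flag for the "optimal control" zones.
* Method comparison: two-sided paired t-test across matched
  (subject, seed) runs. When all paired differences are identical the
  statistic is undefined; the implementation returns 1.0 for all-zero
  differences and 0.0 for a constant nonzero shift rather than NaN.

## 8. Problem sizes and determinism

The default test suite trains only short diagnostic runs (3–10 simulated
days) plus one scaled-down directional experiment: 5 sampled adult
subjects × 3 seeds, 30 population + 30 personalization days, 14 evaluation
days on matched scenarios (~25 s single-threaded). At that scale the
SBC-vs-agent contrast is directional — median time in range must not fall
and median time below range must not rise — while the full protocol
(`--scale full`: 10 + 10 subjects, 180 training / 90 test days) is the
setting on which quantitative claims would be made. All randomness flows
from explicit integer seeds through numpy Generators; everything is plain
single-threaded float64, so fixed seeds reproduce traces, checkpoints and
reports bit for bit.

## 9. Limitations

The surrogate omits, among other things: meal-absorption shape variability
beyond size/timing jitter, exercise, stress, circadian basal requirements
(basal is a constant infusion), sensor dropout and calibration error, and
any pharmacokinetic nonlinearity of large boluses. Passing the directional
experiment shows the learning machinery extracts real structure from this
environment (chiefly the sensitivity rhythm and dose–response mismatch);
it does not certify performance on physiological simulators or patients.
Numbers produced on the surrogate are not comparable in absolute terms to
results from licensed T1D simulators.
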