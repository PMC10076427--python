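# Methods

This note records the models implemented in `asalab`, their assumptions, the
defaults and why they were chosen, and what the synthetic components can and
cannot say about real data.

## Ethanol pharmacokinetics

State: central concentration `C_c` (g/L; BrAC in mg/dL is `100·C_c`) and
peripheral concentration `C_p`, with total distribution volume `vd` (Watson
total body water) split as `V_c = (1−f_per)·vd` and `V_p = f_per·vd`:

    dC_c/dt = q/V_c − k_per·vd·(C_c − C_p)/V_c − vmax·C_c/((km + C_c)·V_c)
    dC_p/dt = k_per·vd·(C_c − C_p)/V_p

where `q` is the infused ethanol mass rate (pump rate × 6.0 % v/v × 0.7893
g/ml).  Integration is fixed-step RK4 at `dt = 0.05` min (0.1 min in cohort
runs); the eliminated mass is integrated with the same stage weights, so the
mass balance *infused = eliminated + body content* holds to floating-point
precision and is asserted by a property test.  RK4 makes the step-size
convergence criterion (halving `dt` moves end-of-session BrAC by far less
than 0.1 mg/dL) trivial to satisfy.

Defaults, per subject:

| parameter | default | rationale |
|---|---|---|
| `vd` | Watson TBW (L) | standard in i.v. clamp work; needs only screening fields |
| `vmax` | calibrated so equilibrated zero-infusion decline at 50 mg/dL is 15 mg/dL/h | typical human elimination after oral ingestion |
| `km` | 0.1 g/L | conventional Michaelis constant for ethanol |
| `f_per` | 0.75 | central pool ≈ 25 % of TBW: blood + rapidly perfused tissue |
| `k_per` | 0.015 min⁻¹ | peripheral equilibration half-time ≈ 35 min |

The last two values are the load-bearing design choice.  The paradigm
prescribes a between-reward BrAC decline of −0.8 mg/dL/min — about four
times faster than metabolic elimination — which is only physically possible
while infused ethanol is still redistributing into a large, slowly
equilibrating tissue pool.  A small central compartment with slow exchange
reproduces exactly that: every +13 mg/dL reward ramp deposits its mass in
the central pool and leaves behind a central→peripheral gradient that funds
roughly 15 further minutes of prescribed decline; repeated rewards keep the
gradient stocked through a session, and once it is exhausted the decline
relaxes to the metabolic rate ("as long as pharmacokinetically possible").
A large-central/fast-exchange parameterization cannot sustain the
prescribed decline for more than ~3 min and was therefore rejected.  All
values are config-overridable, so a published clamp parameterization can be
dropped in without touching any contract.

Between-subject PK variability in cohort runs: seeded lognormal multipliers
(SD 0.15) on `vmax` and `vd`.

## Clamp controller

Model-inversion feedforward plus proportional feedback.  Each control step
(`dt` = integrator step) the controller solves its internal model for the
mass rate that lands BrAC on the target at `t+dt`, adds `gain·(target −
model BrAC)·V_c/dt` with `gain = 0.5`, converts to a pump rate and saturates
at [0, 1998] ml/h.  Saturation is a working state, not an error; a target
decline the model cannot realize simply yields rate 0.

The target path is piecewise linear: +13 mg/dL over 3.0 min per alcohol
reward, −0.8 mg/dL/min otherwise, floored at 0.  At each reward the new ramp
is anchored at the controller's current model BrAC rather than the stale
target value, so tracking errors do not accumulate across rewards.  Saline
rewards run 5 ml/min for 3 min through the same line and leave the target
untouched.

Recalibration every 20 min from a breathalyzer reading: `vmax` is rescaled
by `clip(predicted/measured, 0.7, 1.3)` (a reading above the prediction
means elimination was over-estimated) **and** the reading is assimilated
into the model's central concentration.  The assimilation step is a design
choice of this package: a single multiplicative parameter update cannot
re-synchronize a drifted model state, and the point of the readings is
precisely to re-anchor the controller.  A paired simulation test shows
recalibration shrinks tracking error against a subject with perturbed
`vmax`.

The 180 mg/dL safety gate is inclusive (`BrAC + 13 ≤ 180`) and checked at
work-set start only; a set that drifts over the threshold mid-work still
delivers, which cannot overshoot because the gate plus the prescribed
decline guarantee a ≥13 mg/dL margin at delivery time.

## Work task and schedule

Work-set requirement: `n_k = round(n1·ratio^(k−1))` correct trials,
calibrated from the two printed anchor durations — first set ≈ 30 s, 15th
set ≈ 23 min at 7.3 s per trial — giving `n1 = 4`, `ratio ≈ 1.3170`,
`n_15 = 189`.  The exact progression table of the original instrument is not
public; the geometric fit stands in, and both `n1` and `ratio` are
config-overridable so the true table can replace it.  The futility index
(first `k` with `n_k·7.3 s·0.8 mg/dL/min ≥ 13 mg/dL`) is 14 under these
defaults.

The constant attention task is modeled as: trial duration ~ Gamma with mean
7.3 s (CV 0.2); reaction time ~ lognormal (median 0.28 s, σ = 0.30) slowed
proportionally to BrAC (0.4 % per mg/dL); success iff the reaction time
fits the adaptive window.  The window follows a weighted up-down staircase
(×1.06 on failure, ×0.98 on success) whose detailed-balance equilibrium
`p·ln(0.98) + (1−p)·ln(1.06) = 0` gives p ≈ 0.742, matching the ~75 %
success target regardless of impairment, fatigue, or individual speed.

Session timeline: priming from T = −25 min (prompted sets of 4 trials,
excluded from cWFA and from the voluntary progression), waiting until T = 0,
then 150 min of voluntary work.  The priming pause between prompted sets is
a parameter (default 0); the BrAC reached at priming end depends on human
prompt latencies that no printed value pins down, so no specific value is
asserted.  cWFA/cWFS count **correct trials from T = 0, including trials of
incomplete sets** — the original instrument's counting convention is not
published, so this convention is documented here and in the config rather
than asserted against printed magnitudes.

## Behavioral agent

Choice among {work alcohol, work water, rest} by softmax over utilities:

    u_alc  = work_propensity + pos_weight·a(L)·(stim + well)/200
             + neg_weight·desire/100 − fatigue_rate·t
    u_water = water_propensity − fatigue_rate·t
    u_rest  = 0

with `a(L) = max(0, 1 − δ·L)` the drug attenuation at blood level `L`
(ng/ml).  Temperature 0 reduces to argmax; an ineligible alcohol reward
masks that action; within a work-set the only choices are continuing or
pausing (the reward kind is fixed at set start, as in the paradigm).

Subjective scales (VAS 0–100) follow linear drives with exponential return
to baseline: stimulation and wellbeing rise with BrAC level and with
*rising* BrAC (both scaled by `a(L)`), desire rises while BrAC *falls*,
sedation and drunkenness track the level.  The drug enters only through the
positive-reinforcement pathway by default; a switch (`attenuate_negative`)
extends it to the desire weight for contingency experiments.  These
dynamics are a stand-in — the paradigm measures but does not model VAS
dynamics — so tests assert only signs and correlation directions, never
values.

Agent defaults were calibrated once so that a default cohort reproduces a
realistic operating point of the paradigm (session peak BrAC ≈ 105–115
mg/dL, mean ≈ 85–95 mg/dL, several hundred correct trials for alcohol, an
order of magnitude fewer for water, an ascending-then-plateau mean BrAC
trajectory): `work_propensity = 0`, `pos_weight = 0.8`, `neg_weight = 0.5`,
`water_propensity = 0.15`, `temperature = 0.6`, `fatigue_rate = 0.35`/h.

## Cohort and trial

Genotypes are Hardy–Weinberg draws at G-allele frequency 0.15; screening
admits 3 of every block of 6 by priority GG > AG > AA with consent-order
tie-breaks, which raises the expected carrier fraction well above the
Hardy–Weinberg 27.8 %.  Randomization is permuted blocks of 4 within sex ×
carrier-status strata (carrier status, not three-level genotype, defines the
stratum).  Persistent per-subject random effects (normal SD 0.35 on work
propensity; lognormal SDs 0.3/0.4/0.5 on pos-weight, neg-weight, desire
gain) are shared across both sessions, with session-level propensity noise
(SD 0.22); this variance ratio was set once to put the placebo-arm
test-retest correlation of cWFA near 0.7.  Treated-arm blood levels are
Normal(55.4, 27.6) ng/ml truncated at zero; `δ` defaults to 0.005 per ng/ml
(so the mean level attenuates the positive pathway by ~28 %).  Config
switches inject protocol deviations: dropouts (second session imputed by the
intention-to-treat rule) and zero-blood-level noncompliers (the per-protocol
exclusion path).

Statistics: pooled-variance Student t (the printed degrees of freedom
`n1+n2−2` force pooled over Welch); Cohen's `d = Δmean / pooled SD` with the
normal-approximation CI `d ± z·sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2)))`, which
reproduces printed intervals to ~0.004; p-values are reported but never used
as targets.  The intention-to-treat imputation sets a missing subject's
change score to the mean change of the remaining subjects in the same arm —
the natural reading of the rule; the sign convention is documented because
the verbal phrasing ("subtracting the mean change") is ambiguous when the
mean change is negative.  Effect sizes are reported as placebo-minus-treated
so that a drug that reduces work yields a positive `d`.

## Numerical and testing notes

* Sessions are event-driven in continuous time; replays with the same seed
  are bit-identical, which the suite asserts.
* Problem sizes in the population-level tests — 200 subjects per arm for the
  directional drug-effect and correlation signatures, 60 per arm for the
  matched-seed monotonicity grid — were chosen as the smallest cohorts at
  which the directional properties are stable across seeds.
* The null case (δ = 0) is asserted statistically: the 99 % CI of the
  between-arm `d` must contain zero.  A point bound on a single simulated
  `d` would fail by sampling noise alone roughly a third of the time at
  these sizes.
* A classical one-compartment invariant (BrAC nondecreasing while infusion
  exceeds elimination) holds only with exchange disabled; with two
  compartments, outward distribution can lower central BrAC even under net
  mass gain, so the general invariant is asserted on total body content.

## What the generator does and does not emulate

The synthetic cohort reproduces the *structure* of the paradigm — exposure
dynamics, work schedule, contingency shift, genotype enrichment, stratified
randomization, test-retest stability, and a blood-level-scaled drug effect —
under parameters chosen to sit at a realistic operating point.  It does not
emulate human reaction-time psychophysics beyond a latency distribution,
learning or carry-over across sessions, craving instruments, real-life
drinking, or any neurobiological mechanism.  Passing population-level tests
therefore demonstrates internal consistency of the paradigm's logic and
analysis chain, not quantitative predictions about human samples; all
human-sample quantities are covered by sign/range properties only.
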