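# asalab

A desk-scale virtual laboratory for **intravenous alcohol self-administration
(ASA) paradigms** of the clamp-controlled, progressive-ratio type, written for
researchers who design or analyze human laboratory screens of alcoholism
medications and want to explore "drug effect" hypotheses in silico before (or
alongside) a human study.

The package simulates the entire experimental chain of one such paradigm and
reproduces its trial-level endpoint analysis:

* **Pharmacokinetics** — a two-compartment ethanol disposition model per
  subject: a small central (arterial/breath-equivalent) pool exchanging with a
  large, slowly equilibrating peripheral pool, Michaelis–Menten elimination,
  and a distribution volume from the Watson total-body-water equations.
* **Clamp controller** — inverts its internal model every step to find the
  pump rate (0–1998 ml/h of a 6.0 % v/v ethanol infusate) that makes BrAC
  follow the prescribed path: each earned alcohol reward raises BrAC by
  **+13 mg/dL in 3.0 min**, and between rewards BrAC falls linearly at
  **−0.8 mg/dL per minute** for as long as the pharmacokinetics permit.
  Breathalyzer readings every 20 min recalibrate the model; work for an
  alcohol reward may only start if the ensuing +13 mg/dL cannot push BrAC
  above the **180 mg/dL** safety limit.
* **Session engine** — priming (2 prompted saline and 4 prompted alcohol
  work-sets), waiting until T = 0, then 150 min of voluntary work for rewards
  under a geometric progressive-ratio schedule (requirement
  `round(4·1.317^(k−1))` correct trials of a ~7.3-s constant attention task,
  with an adaptive staircase holding the success rate near 75 %).  The
  schedule passes its *futility point* at work-set 14, where the BrAC lost
  while working exceeds what the next reward returns.
* **Behavioral agent** — a softmax decision model (work for alcohol / work
  for water / rest) driven by positive reinforcement (stimulation and
  wellbeing rising with BrAC) and negative reinforcement (desire rising while
  BrAC falls), with per-subject random effects and a drug parameter that
  attenuates the positive-reinforcement pathway in proportion to drug blood
  level.
* **Trial analysis and cohort experiment** — cumulative work for alcohol
  (cWFA) and saline (cWFS) with ascending [0, 75) / plateau [75, 150] phase
  splits, pooled-variance t-tests, Cohen's *d* with a normal-approximation CI,
  Pearson/Spearman correlations, subjective-slope analysis, the
  intention-to-treat imputation rule, genotype-enriched screening (3 of every
  6 by GG > AG > AA priority), and sex×genotype-stratified permuted-block
  randomization of a synthetic cohort through the full two-session trial.

## Worked example

Re-analyze a pair of printed group summaries (change in cWFA from the
pre-treatment to the on-treatment session, placebo vs. active arm):

```bash
$ printf 'group,n,mean,sd\nplacebo,24,-39,166.7\nnaltrexone,22,-76,174.5\n' > summaries.csv
$ asalab analyze --summaries summaries.csv
{
  ...
  "t": 0.7353579724763872,
  "df": 44,
  "p": 0.466023346811934,
  "cohens_d": 0.21705048460314455,
  "d_ci_95": [-0.36315608579695013, 0.7972570550032393]
}
```

Both arms reduced their work in the second session; the between-group
difference (37 work units more reduction under active drug) is a small,
non-significant effect of *d* ≈ 0.22 whose confidence interval spans zero —
the pooled t on 44 degrees of freedom is 0.74.

Simulate a complete randomized two-session trial of 46 synthetic subjects:

```bash
$ asalab trial --seed 4 --out trial_out
primary endpoint: change in cWFA -58 (treated) vs -40 (placebo); t(44) = 0.54, p = 0.592, d = 0.159
```

`trial_out/` then holds the per-subject endpoint table (`endpoints.csv`) and
all group statistics (`statistics.json`).  A single subject's session is
available via `asalab simulate --seed 2 --out run_out`, which prints, e.g.

```
cWFA=184 cWFS=16 peak BrAC=102.9 mg/dL
```

meaning this subject performed 184 correct trials for alcohol and 16 for
water and peaked at 103 mg/dL breath alcohol.  Everything is importable as a
library too — see `asalab.run_session`, `asalab.simulate_trial`, and the
module docstrings.

## Scope

The package models the operant laboratory session and its endpoint
statistics.  It does not model oral ingestion, fMRI sessions, genotyping
chemistry, drug assay chemistry, real-life drinking outcomes, or safety
follow-up; those appear only as opaque covariates or metadata where the
trial design needs them.  See `docs/methods.md` for the model equations,
parameter defaults, calibration choices, and known limitations.
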