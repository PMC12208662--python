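# beliefupdate

Analysis toolkit for **good-news / bad-news belief-updating tasks**: the
paradigm in which participants estimate their risk of experiencing adverse
life events (E1), see the event's base rate in the population (BR), and
re-estimate (E2). The asymmetry with which people integrate
belief-disconfirming information — updating more after learning they
over-estimated a risk (good news) than after learning they under-estimated it
(bad news) — is the behavioural signature of the optimism bias, and it is
known to bend under adverse real-life contexts such as a pandemic.

The package is aimed at computational-psychiatry researchers who want to run
this style of analysis end to end, or to probe its statistical behaviour
(identifiability, selection accuracy, power) on fully synthetic data — no
participant data are required anywhere.

## What it implements

**Task measures.** Estimation error `EE = E1 − BR` (or `eBR − BR` in the
alternative mode), valence (good news `EE > 0`, bad news `EE < 0`, `EE = 0`
excluded), update `UPD = E1 − E2` (good) / `E2 − E1` (bad), update bias
`UDB = mean UPD_good − mean UPD_bad`, personal relevance `PR ∈ [0, 1]`, and
distance `eBR − E1`, with the standard exclusion rules (no response, `EE = 0`).

**Twelve candidate update models.** Eight reinforcement-learning-like models

```
UPD = LR · EE,   LR_good = S + A,   LR_bad = S − A
```

optionally down-weighting the error by personal relevance via `(1 − PR)`, and
four Bayesian models in which the update is proportional to the gap between
E1 and the posterior estimate from Bayes' rule,

```
E2b = odds/(1+odds),   odds = [BR/(1−BR)] · [E1/(1−E1)] / [eBR/(1−eBR)]
```

(probability scale), with the same scaling/asymmetry decomposition. Variants
differ in which of `{S, A}` are free (fixed values `S = 1`, `A = 0`).

**Model inversion and selection.** Per-subject MAP estimation under Gaussian
priors (scaling prior mean 1, asymmetry prior mean 0) with a profiled Gaussian
observation noise, Laplace approximation to the log model evidence, and
random-effects Bayesian model selection producing estimated model frequencies
(Ef), exceedance probabilities, the Bayes omnibus risk (BOR) and protected
exceedance probabilities (pxp).

**Validation and group inference.** Parameter recovery (simulate → refit →
Pearson correlation), a 12×12 model-recovery confusion matrix, linear
mixed-effects models of updates and learning rates (valence-by-context
interaction), pooled-variance t-tests with Cohen's d, and a simulation-based
power analysis.

**Synthetic cohorts.** A seeded generator producing complete studies: a bank
of 40 adverse-event base rates (mean ≈ 40, range 10–70), four testing-context
groups (two outside, two during the pandemic; N = 30/34/31/28) with realistic
covariates, bounded integer ratings in [3, 77], and updates simulated from any
of the 12 models.

## Worked example

```python
import warnings
import numpy as np
import beliefupdate as bu
from beliefupdate.synthetic import pandemic_config

cfg = pandemic_config(seed=1)                      # 123 subjects, 4 groups
trials, _ = bu.generate_study(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    retained, _ = bu.apply_exclusions(bu.add_measures(trials))

evidence, params = bu.fit_cohort(retained, model_ids=[1, 10])
context = retained.groupby("subject_id")["context"].first()
for ctx, res in sorted(bu.compare_by_context(evidence, context, seed=1).items()):
    lab = "outside" if ctx == 0 else "during "
    print(f"{lab} pandemic: Ef={np.round(res.ef, 2)} pxp={np.round(res.pxp, 2)}")

summ = bu.subject_summaries(retained)
tt = bu.two_sample_t(summ[summ.context == 0].udb.dropna(),
                     summ[summ.context == 1].udb.dropna())
print(f"update bias outside vs during: t({tt.df:.0f})={tt.t:.2f}, "
      f"p={tt.p:.3f}, d={tt.cohens_d:.2f}")
```

prints

```
outside pandemic: Ef=[0.95 0.05] pxp=[1. 0.]
during  pandemic: Ef=[0.97 0.03] pxp=[1. 0.]
update bias outside vs during: t(121)=2.53, p=0.013, d=0.46
```

The cohort was generated from the asymmetric RL model (model 1) in both
contexts, and model selection correctly awards it essentially all of the
estimated frequency against the rational-Bayes alternative (model 10) in each
context. Because `pandemic_config` lowers the learning asymmetry of
during-pandemic subjects, the update bias (good-news minus bad-news updating)
is reliably smaller during the pandemic — a moderate effect, d ≈ 0.46.

## Command line

Every stage is also a seeded subcommand over a YAML configuration:

```bash
beliefupdate all --seed 1 --out results/demo     # simulate → … → stats
beliefupdate recover-models --seed 1 --out results/demo
beliefupdate power --seed 1 --out results/demo
```

Artifacts (`trials.csv`, `measures.csv`, `params.csv`, `evidence.csv`,
`bms.json`, `recovery.csv`, `stats.csv`, …) carry the seed and a configuration
hash in a header comment; a saved `config.yaml` reproduces a run byte for
byte.

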