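"""Parameter and model recovery.

Parameter recovery: draw per-subject generating parameters, simulate a
full study, refit the generating model, and correlate generating with
recovered values (Pearson).  Model recovery: simulate from each of the
12 candidate models in turn, refit all 12, run random-effects model
selection, and collect the estimated model frequencies into a 12 x 12
confusion matrix (columns = generating model, rows = fitted model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import models as bm
from .fitting import PriorSpec, fit_cohort
from .measures import add_measures, apply_exclusions
from .selection import rfx_bms
from .synthetic import CohortConfig, PARAM_MEAN_DEFAULT, PARAM_SD_DEFAULT, \
    generate_study

#: generating means reported for the Bayesian-family recovery scenario
BAYES_RECOVERY_MEAN = (0.42, 0.05)


@dataclass
class RecoveryReport:
    """Generating-versus-recovered parameter comparison for one model."""

    model: str
    pairs: pd.DataFrame  # subject_id, generating/recovered scaling & asymmetry
    pearson: dict        # parameter -> (r, p); NaN r flagged when degenerate
    settings: dict = field(default_factory=dict)


def _recovery_config(n_subjects, n_trials, model, pop_mean, pop_sd,
                     update_noise_sd, seed) -> CohortConfig:
    # a single-group cohort: context structure is irrelevant to recovery
    return CohortConfig(
        group_sizes={"oct2019": n_subjects},
        two_run_counts={"oct2019": 0},
        generating_model=bm.get_model(model).model_id,
        param_mean=tuple(pop_mean), param_sd=tuple(pop_sd),
        update_noise_sd=update_noise_sd,
        n_events=n_trials, seed=seed)


def parameter_recovery(model="rl_sa", pop_mean=PARAM_MEAN_DEFAULT,
                       pop_sd=PARAM_SD_DEFAULT, n_subjects: int = 123,
                       n_trials: int = 40, update_noise_sd: float = 8.0,
                       prior: PriorSpec | None = None, seed: int = 0
                       ) -> RecoveryReport:
    """Simulate -> refit -> correlate for one model's free parameters."""
    if n_subjects < 3:
        raise ValueError("parameter recovery needs at least 3 subjects")
    if n_trials < 2:
        raise ValueError("parameter recovery needs at least 2 trials")
    spec = bm.get_model(model)
    config = _recovery_config(n_subjects, n_trials, spec, pop_mean, pop_sd,
                              update_noise_sd, seed)
    trials, gen_params = generate_study(config)
    retained, _ = apply_exclusions(add_measures(trials))
    _, fitted = fit_cohort(retained, model_ids=[spec.model_id], prior=prior)
    pairs = gen_params.rename(columns={
        "scaling": "gen_scaling", "asymmetry": "gen_asymmetry"}).merge(
            fitted[["subject_id", "scaling", "asymmetry"]].rename(columns={
                "scaling": "rec_scaling", "asymmetry": "rec_asymmetry"}),
            on="subject_id")
    pearson = {}
    for par in spec.free_names:
        g = pairs[f"gen_{par}"].to_numpy()
        r = pairs[f"rec_{par}"].to_numpy()
        if np.std(g) == 0 or np.std(r) == 0:
            warnings.warn(
                f"{par}: degenerate (constant) values, correlation undefined",
                stacklevel=2)
            pearson[par] = (np.nan, np.nan)
        else:
            res = sps.pearsonr(g, r)
            pearson[par] = (float(res.statistic), float(res.pvalue))
    return RecoveryReport(
        model=spec.name, pairs=pairs, pearson=pearson,
        settings=dict(n_subjects=n_subjects, n_trials=n_trials,
                      pop_mean=tuple(pop_mean), pop_sd=tuple(pop_sd),
                      update_noise_sd=update_noise_sd, seed=seed))


def model_recovery(model_ids=None, param_table: pd.DataFrame | None = None,
                   n_subjects: int = 40, n_trials: int = 40,
                   update_noise_sd: float = 8.0, pop_sd=PARAM_SD_DEFAULT,
                   prior: PriorSpec | None = None, seed: int = 0,
                   mc_samples: int = 20_000) -> pd.DataFrame:
    """Confusion matrix of estimated model frequencies.

    For each generating model, a cohort is simulated (generating means
    taken from ``param_table`` -- per-model mean MAP scaling/asymmetry --
    or from the built-in defaults), all candidate models are refitted,
    and the estimated frequencies from random-effects BMS form one
    column.  Columns sum to 1.
    """
    specs = [bm.get_model(m) for m in (model_ids or range(1, 13))]
    columns = {}
    for i, gen in enumerate(specs):
        if param_table is not None:
            sub = param_table[param_table["model_id"] == gen.model_id]
            mean = (float(sub["scaling"].mean()), float(sub["asymmetry"].mean()))
        elif gen.family == "bayes":
            mean = BAYES_RECOVERY_MEAN
        else:
            mean = PARAM_MEAN_DEFAULT
        config = _recovery_config(n_subjects, n_trials, gen, mean, pop_sd,
                                  update_noise_sd, seed=seed + i)
        trials, _ = generate_study(config)
        retained, _ = apply_exclusions(add_measures(trials))
        evidence, _ = fit_cohort(
            retained, model_ids=[s.model_id for s in specs], prior=prior)
        res = rfx_bms(evidence, mc_samples=mc_samples, seed=seed + i)
        columns[gen.name] = res.ef
    out = pd.DataFrame(columns, index=[s.name for s in specs])
    out.index.name = "fitted"
    out.columns.name = "generating"
    return out
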