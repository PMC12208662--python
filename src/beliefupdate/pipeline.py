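"""End-to-end orchestration of the analysis stages.

Each stage reads the previous stage's CSV artifacts from the output
directory and writes its own, so stages can be run individually from
the command line or chained with :func:`run_pipeline`.  Every artifact
declares the seed and configuration hash in a header comment.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import models as bm
from .config import RunConfig, read_artifact, write_artifact, write_json
from .fitting import fit_cohort, learning_rates_from_params
from .measures import add_measures, apply_exclusions, subject_summaries
from .recovery import model_recovery, parameter_recovery
from .selection import compare_by_context, rfx_bms
from .stats import (fit_lme_learning_rate, fit_lme_parameters, fit_lme_update,
                    power_simulation, two_sample_t)
from .synthetic import generate_study


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are left in place."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _log(outdir: Path, message: str) -> None:
    with open(outdir / "run.log", "a") as fh:
        fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {message}\n")


def stage_simulate(cfg: RunConfig) -> pd.DataFrame:
    trials, gen_params = generate_study(cfg.cohort)
    h = cfg.hash()
    write_artifact(trials, Path(cfg.outdir) / "trials.csv", cfg.seed, h)
    write_artifact(gen_params, Path(cfg.outdir) / "generating_params.csv",
                   cfg.seed, h)
    return trials


def stage_measure(cfg: RunConfig, trials: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
    if trials is None:
        trials = read_artifact(Path(cfg.outdir) / "trials.csv")
    measured = add_measures(trials)
    apply_exclusions(measured)  # warns on empty subjects
    write_artifact(measured, Path(cfg.outdir) / "measures.csv",
                   cfg.seed, cfg.hash())
    return measured


def stage_fit(cfg: RunConfig, measured: pd.DataFrame | None = None):
    if measured is None:
        measured = read_artifact(Path(cfg.outdir) / "measures.csv")
    retained, _ = apply_exclusions(measured)
    evidence, params = fit_cohort(retained, model_ids=cfg.models,
                                  prior=cfg.prior, seed=cfg.seed)
    h = cfg.hash()
    write_artifact(params, Path(cfg.outdir) / "params.csv", cfg.seed, h)
    write_artifact(evidence.reset_index(), Path(cfg.outdir) / "evidence.csv",
                   cfg.seed, h)
    return evidence, params


def stage_compare(cfg: RunConfig, evidence: pd.DataFrame | None = None,
                  measured: pd.DataFrame | None = None) -> dict:
    if evidence is None:
        evidence = read_artifact(
            Path(cfg.outdir) / "evidence.csv").set_index("subject_id")
    if measured is None:
        measured = read_artifact(Path(cfg.outdir) / "measures.csv")
    context = measured.groupby("subject_id", sort=True)["context"].first()
    context = context.loc[evidence.index]
    overall = rfx_bms(evidence, alpha0=cfg.bms_alpha0,
                      mc_samples=cfg.bms_mc_samples, seed=cfg.seed)
    by_context = compare_by_context(evidence, context, alpha0=cfg.bms_alpha0,
                                    mc_samples=cfg.bms_mc_samples,
                                    seed=cfg.seed)
    report = {"overall": overall.to_dict(),
              "by_context": {str(k): v.to_dict() for k, v in by_context.items()}}
    write_json(report, Path(cfg.outdir) / "bms.json", cfg.seed, cfg.hash())
    return report


def stage_recover_params(cfg: RunConfig) -> pd.DataFrame:
    rep = parameter_recovery(
        model=cfg.cohort.generating_model,
        pop_mean=cfg.cohort.param_mean, pop_sd=cfg.cohort.param_sd,
        n_subjects=cfg.recovery_n_subjects, n_trials=cfg.recovery_n_trials,
        update_noise_sd=cfg.cohort.update_noise_sd, prior=cfg.prior,
        seed=cfg.seed)
    pairs = rep.pairs.copy()
    for par, (r, p) in rep.pearson.items():
        pairs[f"r_{par}"] = r
        pairs[f"p_{par}"] = p
    write_artifact(pairs, Path(cfg.outdir) / "recovery.csv", cfg.seed,
                   cfg.hash())
    return pairs


def stage_recover_models(cfg: RunConfig) -> pd.DataFrame:
    confusion = model_recovery(
        model_ids=cfg.models, n_subjects=cfg.model_recovery_n_subjects,
        n_trials=cfg.recovery_n_trials,
        update_noise_sd=cfg.cohort.update_noise_sd, prior=cfg.prior,
        seed=cfg.seed, mc_samples=min(cfg.bms_mc_samples, 20_000))
    write_artifact(confusion.reset_index(), Path(cfg.outdir) / "confusion.csv",
                   cfg.seed, cfg.hash())
    return confusion


def _covariate_table(measured: pd.DataFrame) -> pd.DataFrame:
    return (measured.groupby("subject_id", sort=True)
            [["group", "context", "design", "age", "gender", "education"]]
            .first().reset_index())


def stage_stats(cfg: RunConfig, measured: pd.DataFrame | None = None,
                params: pd.DataFrame | None = None) -> pd.DataFrame:
    if measured is None:
        measured = read_artifact(Path(cfg.outdir) / "measures.csv")
    if params is None:
        params = read_artifact(Path(cfg.outdir) / "params.csv")
    retained, _ = apply_exclusions(measured)
    blocks = []

    def _try(label, fn):
        # individual analyses may be unestimable on very small or
        # degenerate cohorts; skip them with a warning rather than
        # aborting the whole stage
        try:
            blocks.append(fn())
        except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
            warnings.warn(f"stats block {label!r} skipped: {exc}",
                          stacklevel=2)

    _try("lme_update", lambda: fit_lme_update(
        retained, re_structure=cfg.power_re_structure).table
        .assign(model="lme_update"))

    rl1 = learning_rates_from_params(params, "rl_sa")
    if len(rl1):
        cov = _covariate_table(measured)
        lr_table = rl1.merge(cov, on="subject_id")
        _try("lme_learning_rate", lambda: fit_lme_learning_rate(
            lr_table).table.assign(model="lme_learning_rate"))
        for which in ("scaling", "asymmetry"):
            _try(f"lme_{which}", lambda w=which: fit_lme_parameters(
                lr_table, w).table.assign(model=f"lme_{w}"))
        summaries = subject_summaries(retained).merge(
            lr_table, on="subject_id", suffixes=("", "_lr"))
        during = summaries[summaries["context"] == 1]
        outside = summaries[summaries["context"] == 0]
        if len(during) >= 2 and len(outside) >= 2:
            tt_rows = []
            for label in ("upd_good", "ee_pos_mag", "lr_good", "asymmetry"):
                x = outside[label].dropna()
                y = during[label].dropna()
                try:
                    tt = two_sample_t(x, y)
                except ValueError as exc:
                    warnings.warn(f"t-test {label!r} skipped: {exc}",
                                  stacklevel=2)
                    continue
                tt_rows.append({"model": f"ttest_{label}", "term": "outside-during",
                                "beta": tt.mean_x - tt.mean_y, "se": np.nan,
                                "t": tt.t, "df": tt.df, "p": tt.p,
                                "ci_low": np.nan, "ci_high": np.nan,
                                "cohens_d": tt.cohens_d})
            if tt_rows:
                blocks.append(pd.DataFrame(tt_rows))
    if not blocks:
        raise RuntimeError("no group-level analysis was estimable")
    stats_table = pd.concat(blocks, ignore_index=True)
    write_artifact(stats_table, Path(cfg.outdir) / "stats.csv", cfg.seed,
                   cfg.hash())
    return stats_table


def best_model_assignments(evidence: pd.DataFrame, params: pd.DataFrame,
                           context: pd.Series) -> pd.DataFrame:
    """Per-subject (model, parameters): each context's group-level winner."""
    by_context = compare_by_context(evidence, context, mc_samples=2000, seed=0)
    rows = []
    for sid in evidence.index:
        ctx = context.loc[sid]
        res = by_context[ctx]
        win_name = (res.model_names or list(evidence.columns))[int(np.argmax(res.ef))]
        win_id = bm.get_model(win_name).model_id
        fit = params[(params["subject_id"] == sid)
                     & (params["model_id"] == win_id)].iloc[0]
        rows.append({"subject_id": sid, "model_id": win_id,
                     "scaling": fit["scaling"], "asymmetry": fit["asymmetry"]})
    return pd.DataFrame(rows)


def stage_power(cfg: RunConfig, measured: pd.DataFrame | None = None,
                evidence: pd.DataFrame | None = None,
                params: pd.DataFrame | None = None) -> dict:
    if measured is None:
        measured = read_artifact(Path(cfg.outdir) / "measures.csv")
    if evidence is None:
        evidence = read_artifact(
            Path(cfg.outdir) / "evidence.csv").set_index("subject_id")
    if params is None:
        params = read_artifact(Path(cfg.outdir) / "params.csv")
    retained, _ = apply_exclusions(measured)
    context = measured.groupby("subject_id", sort=True)["context"].first()
    assignments = best_model_assignments(evidence, params, context)
    noise = float(np.sqrt(np.median(params["noise_var"])))
    report = power_simulation(retained, assignments, update_noise_sd=noise,
                              n_iterations=cfg.power_iterations,
                              alpha=cfg.power_alpha, seed=cfg.seed,
                              re_structure=cfg.power_re_structure)
    payload = {"power": report.power, "alpha": report.alpha,
               "n_iterations": report.n_iterations,
               "n_rejections": report.n_rejections,
               "n_failed": report.n_failed,
               "update_noise_sd": noise, "term": report.term}
    write_json(payload, Path(cfg.outdir) / "power.json", cfg.seed, cfg.hash())
    return payload


_CORE_STAGES = ("simulate", "measure", "fit", "compare", "recover-params",
                "stats")


def run_pipeline(cfg: RunConfig, stages=_CORE_STAGES) -> Path:
    """Run the configured stages in order and return the artifact directory.

    The default chain is generation -> measures -> fitting -> selection
    -> parameter recovery -> group statistics; model recovery and the
    power simulation are heavier and run on request (stage names
    ``recover-models`` and ``power``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    _log(outdir, f"beliefupdate {__version__} seed={cfg.seed} "
                 f"config={cfg.hash()} stages={','.join(stages)}")
    state: dict = {}
    runners = {
        "simulate": lambda: state.update(trials=stage_simulate(cfg)),
        "measure": lambda: state.update(
            measured=stage_measure(cfg, state.get("trials"))),
        "fit": lambda: state.update(
            zip(("evidence", "params"),
                stage_fit(cfg, state.get("measured")))),
        "compare": lambda: stage_compare(cfg, state.get("evidence"),
                                         state.get("measured")),
        "recover-params": lambda: stage_recover_params(cfg),
        "recover-models": lambda: stage_recover_models(cfg),
        "stats": lambda: stage_stats(cfg, state.get("measured"),
                                     state.get("params")),
        "power": lambda: stage_power(cfg, state.get("measured"),
                                     state.get("evidence"),
                                     state.get("params")),
    }
    for name in stages:
        if name not in runners:
            raise ValueError(f"unknown stage {name!r}")
        t0 = time.perf_counter()
        try:
            runners[name]()
        except Exception as exc:
            _log(outdir, f"stage {name} FAILED: {exc}")
            raise StageError(name, exc) from exc
        _log(outdir, f"stage {name} ok ({time.perf_counter() - t0:.1f}s)")
    return outdir
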