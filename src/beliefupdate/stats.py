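"""Group-level inference.

Linear mixed-effects models of trial-wise updates and of fitted
learning-rate parameters, two-sample t-tests with Cohen's d, and a
simulation-based power analysis for the valence-by-context interaction.

The update LME has fixed effects for estimation-error magnitude |EE|,
news valence (coded -1 bad / +1 good), pandemic context (0 outside /
1 during), task design (1 one-run / 2 two-run), age, gender (0 male /
1 female), education, and the valence-by-context interaction, with a
random intercept and independent random slopes for |EE| and valence by
subject.  Models are fitted by maximum likelihood; inference is Wald t
with residual-style degrees of freedom (n_obs - n_fixed_effects).  On
singular or non-convergent fits the random-effects structure is
simplified stepwise (full -> drop valence slope -> drop |EE| slope ->
intercept only), and the downgrade is recorded on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

_Z95 = 1.96  # the CI convention is beta +/- 1.96 SE

#: random-effects simplification ladder for the update LME
_RE_LADDER = ("full", "ee_slope", "intercept")


@dataclass
class LmeResult:
    """Fixed-effect table of one linear (mixed) model."""

    table: pd.DataFrame  # term, beta, se, t, df, p, ci_low, ci_high
    formula: str
    re_structure: str
    converged: bool
    n_obs: int
    downgraded_from: str | None = None

    def term(self, name: str) -> pd.Series:
        hits = self.table[self.table["term"] == name]
        if hits.empty:
            raise KeyError(
                f"term {name!r} not in model; terms: {list(self.table['term'])}")
        return hits.iloc[0]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    mean_x: float
    mean_y: float
    n_x: int
    n_y: int
    tails: int


@dataclass
class PowerReport:
    n_iterations: int
    n_rejections: int
    n_failed: int
    power: float
    alpha: float
    term: str
    settings: dict = field(default_factory=dict)


def two_sample_t(x, y, tails: int = 2) -> TTestResult:
    """Student's pooled-variance two-sample t-test with Cohen's d.

    One-tailed mode tests the alternative mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least 2 observations")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    res = sps.ttest_ind(x, y, equal_var=True,
                        alternative="greater" if tails == 1 else "two-sided")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    return TTestResult(float(res.statistic), float(df), float(res.pvalue),
                       float(d), float(x.mean()), float(y.mean()), nx, ny, tails)


def _wald_table(params: pd.Series, bse: pd.Series, n_obs: int) -> pd.DataFrame:
    k = len(params)
    df = max(n_obs - k, 1)
    t = params / bse
    p = 2 * sps.t.sf(np.abs(t), df)
    return pd.DataFrame({
        "term": params.index, "beta": params.to_numpy(),
        "se": bse.to_numpy(), "t": t.to_numpy(), "df": df, "p": p,
        "ci_low": params.to_numpy() - _Z95 * bse.to_numpy(),
        "ci_high": params.to_numpy() + _Z95 * bse.to_numpy(),
    }).reset_index(drop=True)


def lme_frame(retained: pd.DataFrame) -> pd.DataFrame:
    """Trial table -> LME analysis frame (retained trials only)."""
    need = retained.loc[retained["excluded"] == 0] \
        if "excluded" in retained.columns else retained
    out = pd.DataFrame({
        "subject_id": need["subject_id"],
        "group": need["group"],
        "upd": need["upd"],
        "ee_abs": need["ee"].abs(),
        "valence": need["valence_code"],
        "context": need["context"],
        "design": need["design"],
        "age": need["age"],
        "gender": need["gender"],
        "education": need["education"],
        "distance": need["distance"],
        "confidence": need["confidence"],
    })
    return out.dropna(subset=["upd"])


def _vc_for(structure: str) -> dict:
    if structure == "full":
        return {"ee_abs": "0 + ee_abs", "valence": "0 + valence"}
    if structure == "ee_slope":
        return {"ee_abs": "0 + ee_abs"}
    if structure == "intercept":
        return {}
    raise ValueError(f"unknown random-effects structure {structure!r}")


def _fit_mixed(formula: str, data: pd.DataFrame, structure: str):
    model = smf.mixedlm(formula, data, groups=data["subject_id"],
                        re_formula="1", vc_formula=_vc_for(structure) or None)
    res = fe = bse = None
    ok = False
    # lbfgs is fast but brittle on richer structures; powell is the robust
    # fallback before the random-effects structure itself is simplified
    for method in ("lbfgs", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, method=method, maxiter=500)
        fe = res.fe_params
        bse = res.bse.loc[fe.index]
        ok = bool(res.converged) and bool(np.all(np.isfinite(bse)))
        if ok:
            break
    return res, fe, bse, ok


def fit_lme_update(retained: pd.DataFrame, re_structure: str = "full",
                   context_coding: str = "binary",
                   include_distance: bool = False,
                   outcome: str = "upd") -> LmeResult:
    """Mixed model of trial-wise updates (or another trial outcome).

    ``context_coding='groups'`` replaces the 0/1 pandemic indicator with
    treatment-coded four-level group dummies (baseline oct2019) and the
    matching valence-by-group interactions.
    """
    data = lme_frame(retained) if "ee_abs" not in retained.columns else retained
    data = data.dropna(subset=[outcome])
    if data["subject_id"].nunique() < 2:
        raise ValueError("the mixed model needs at least 2 subjects")
    if context_coding == "binary":
        ctx = "context + valence:context"
    elif context_coding == "groups":
        ctx = ("C(group, Treatment('oct2019')) + "
               "valence:C(group, Treatment('oct2019'))")
    else:
        raise ValueError("context_coding must be 'binary' or 'groups'")
    rhs = f"ee_abs + valence + {ctx} + design + age + gender + education"
    if include_distance:
        rhs += " + distance"
    formula = f"{outcome} ~ {rhs}"

    start = _RE_LADDER.index(re_structure) if re_structure in _RE_LADDER else 0
    downgraded_from = None
    last_exc = None
    for structure in _RE_LADDER[start:]:
        try:
            res, fe, bse, ok = _fit_mixed(formula, data, structure)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            ok = False
        if ok:
            if structure != _RE_LADDER[start]:
                downgraded_from = _RE_LADDER[start]
                warnings.warn(
                    f"random-effects structure downgraded to {structure!r}",
                    stacklevel=2)
            return LmeResult(_wald_table(fe, bse, len(data)), formula,
                             structure, True, len(data), downgraded_from)
    # every rung failed: report the intercept-only fit as non-converged
    try:
        res, fe, bse, _ = _fit_mixed(formula, data, "intercept")
        return LmeResult(_wald_table(fe, bse, len(data)), formula,
                         "intercept", False, len(data), _RE_LADDER[start])
    except Exception as exc:  # pragma: no cover - pathological input
        raise RuntimeError("mixed model estimation failed") from exc


def fit_lme_learning_rate(lr_table: pd.DataFrame) -> LmeResult:
    """Mixed model of per-subject good/bad-news learning rates.

    ``lr_table`` needs ``subject_id, lr_good, lr_bad, context, design,
    age, gender, education``; it is reshaped to one row per subject and
    valence (+1 good, -1 bad), with a random intercept by subject.
    """
    if lr_table["subject_id"].nunique() < 2:
        raise ValueError("the learning-rate model needs at least 2 subjects")
    long = pd.concat([
        lr_table.assign(lr=lr_table["lr_good"], valence=1),
        lr_table.assign(lr=lr_table["lr_bad"], valence=-1),
    ], ignore_index=True)
    formula = ("lr ~ valence + context + design + age + gender + education"
               " + valence:context")
    model = smf.mixedlm(formula, long, groups=long["subject_id"],
                        re_formula="1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=200)
    fe = res.fe_params
    bse = res.bse.loc[fe.index]
    return LmeResult(_wald_table(fe, bse, len(long)), formula, "intercept",
                     bool(res.converged) and bool(np.all(np.isfinite(bse))),
                     len(long))


def fit_lme_parameters(param_table: pd.DataFrame, which: str) -> LmeResult:
    """Regression of a per-subject parameter on context and covariates.

    With one row per subject the by-subject random intercept is
    unidentifiable (it is absorbed by the residual), so the model is
    estimated as OLS with Wald t and residual degrees of freedom.
    """
    if which not in ("scaling", "asymmetry"):
        raise ValueError("which must be 'scaling' or 'asymmetry'")
    if which not in param_table.columns:
        raise ValueError(f"parameter table lacks a {which!r} column")
    formula = f"{which} ~ context + age + gender + education"
    res = smf.ols(formula, param_table).fit()
    return LmeResult(_wald_table(res.params, res.bse, int(res.nobs)),
                     formula, "none", True, int(res.nobs))


def power_simulation(retained: pd.DataFrame, assignments: pd.DataFrame,
                     update_noise_sd: float = 8.0, n_iterations: int = 1000,
                     alpha: float = 0.05, seed: int = 0,
                     re_structure: str = "full",
                     term: str = "valence:context") -> PowerReport:
    """Simulation-based power for the valence-by-context interaction.

    Holds every subject's first estimates, covariates and trial
    composition fixed, simulates fresh updates on each iteration from
    the per-subject model assignment (``assignments``: subject_id,
    model_id, scaling, asymmetry -- typically the best-fitting model per
    context with its MAP parameters), refits the update LME, and counts
    how often the interaction is significant at ``alpha``.  Iterations
    whose LME fails to converge are excluded from the denominator.
    """
    from . import models as bm
    from .synthetic import ESTIMATE_MIN, ESTIMATE_MAX

    data = lme_frame(retained)
    merged = retained.loc[retained["excluded"] == 0].merge(
        assignments, on="subject_id", suffixes=("", "_fit"))
    if len(merged) != len(data):
        raise ValueError("assignments must cover every subject")
    # the per-trial predicted update is fixed across iterations
    v = merged["valence_code"].to_numpy(int)
    e1 = merged["e1"].to_numpy(float)
    pred = np.empty(len(merged))
    for mid, sub in merged.groupby("model_id"):
        spec = bm.get_model(int(mid))
        idx = sub.index.to_numpy()
        pred[idx] = bm.predict_update(
            spec, sub["scaling"].to_numpy(), sub["asymmetry"].to_numpy(),
            ee=sub["ee"].to_numpy(float), valence=sub["valence_code"].to_numpy(int),
            pr=sub["pr"].to_numpy(float), br=sub["base_rate"], e1=sub["e1"],
            ebr=sub["ebr"])
    sim = data.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n_rej = n_fail = 0
    for _ in range(n_iterations):
        noise = rng.normal(0, update_noise_sd, len(merged))
        e2 = np.clip(e1 - v * pred + noise, ESTIMATE_MIN, ESTIMATE_MAX)
        sim["upd"] = v * (e1 - e2)
        try:
            res = fit_lme_update(sim, re_structure=re_structure)
        except (RuntimeError, ValueError):
            n_fail += 1
            continue
        if not res.converged:
            n_fail += 1
            continue
        if res.term(term)["p"] < alpha:
            n_rej += 1
    n_valid = n_iterations - n_fail
    power = n_rej / n_valid if n_valid else np.nan
    return PowerReport(n_iterations, n_rej, n_fail, float(power), alpha, term,
                       settings=dict(update_noise_sd=update_noise_sd,
                                     seed=seed, re_structure=re_structure))
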