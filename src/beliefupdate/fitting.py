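"""Per-subject model inversion.

Each candidate model predicts the trial-wise update from at most two
free parameters (scaling, asymmetry).  The observation model is additive
Gaussian noise on the update, with the noise variance profiled at its
conditional maximum-likelihood value.  Free parameters carry independent
Gaussian priors (mean 1 for scaling, 0 for asymmetry; unit variance by
default) and are estimated by MAP with deterministic multi-start
quasi-Newton optimization.  The log model evidence is approximated by
the Laplace method around the MAP (the "free energy" entered into
random-effects model selection); models with no free parameters use the
profiled log-likelihood directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from . import models as bm

NOISE_FLOOR = 1e-6  # keeps the profiled likelihood finite on perfect fits
N_STARTS = 8
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors over the free parameters."""

    mean_scaling: float = 1.0
    mean_asymmetry: float = 0.0
    variance_scaling: float = 1.0
    variance_asymmetry: float = 1.0

    def __post_init__(self):
        if self.variance_scaling <= 0 or self.variance_asymmetry <= 0:
            raise ValueError("prior variances must be positive")

    def means(self, model: bm.ModelSpec) -> np.ndarray:
        out = []
        if model.scaling_free:
            out.append(self.mean_scaling)
        if model.asymmetry_free:
            out.append(self.mean_asymmetry)
        return np.asarray(out)

    def variances(self, model: bm.ModelSpec) -> np.ndarray:
        out = []
        if model.scaling_free:
            out.append(self.variance_scaling)
        if model.asymmetry_free:
            out.append(self.variance_asymmetry)
        return np.asarray(out)


@dataclass
class FitResult:
    """MAP fit of one model to one subject."""

    subject_id: int
    model_id: int
    scaling: float
    asymmetry: float
    noise_variance: float
    free_energy: float
    converged: bool
    n_trials_used: int
    evidence_method: str = "laplace"  # or "prior_mc" on Hessian failure


class EmptySubjectError(ValueError):
    """Subject has no retained trials to fit."""


def _design(model: bm.ModelSpec, trials: pd.DataFrame):
    """Observed updates y and per-trial driver x with valence signs v."""
    v = trials["valence_code"].to_numpy(int)
    if np.any(v == 0):
        raise ValueError("excluded trials must be removed before fitting")
    y = trials["upd"].to_numpy(float)
    x = bm.update_driver(
        model, ee=trials["ee"].to_numpy(float), valence=v,
        pr=trials["pr"].to_numpy(float) if "pr" in trials else None,
        br=trials["base_rate"], e1=trials["e1"], ebr=trials["ebr"])
    return y, np.asarray(x, dtype=float), v


def _log_posterior(theta, model, prior, y, x, v):
    """Profiled log posterior and the profiled noise variance."""
    s, a = model.full_params(theta)
    resid = y - (s + a * v) * x
    n = y.size
    rss = float(resid @ resid)
    sigma2 = max(rss / n, NOISE_FLOOR)
    ll = -0.5 * n * (_LOG_2PI + np.log(sigma2)) - 0.5 * rss / sigma2
    lp = 0.0
    if model.n_free:
        mu = prior.means(model)
        var = prior.variances(model)
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        lp = float(np.sum(-0.5 * (_LOG_2PI + np.log(var))
                          - 0.5 * (th - mu) ** 2 / var))
    return ll + lp, sigma2


def laplace_free_energy(log_posterior_at_map: float, hessian_at_map,
                        n_free_params: int) -> float:
    """Laplace approximation to the log model evidence.

    F = log p(y|th) + log p(th) + (d/2) log 2pi - 0.5 log |-H|, where H
    is the Hessian of the log posterior at the MAP.  With no free
    parameters this reduces to the log-likelihood at the fixed values.

    Raises ``np.linalg.LinAlgError`` if the Hessian is not negative
    definite.
    """
    if n_free_params == 0:
        return float(log_posterior_at_map)
    H = np.atleast_2d(np.asarray(hessian_at_map, dtype=float))
    if H.shape != (n_free_params, n_free_params):
        raise ValueError("Hessian shape does not match the free-parameter count")
    eigvals = np.linalg.eigvalsh(-H)
    if np.any(eigvals <= 0):
        raise np.linalg.LinAlgError("Hessian is not negative definite at the MAP")
    _, logdet = np.linalg.slogdet(-H)
    return float(log_posterior_at_map + 0.5 * n_free_params * _LOG_2PI
                 - 0.5 * logdet)


def _fd_hessian(f, theta, rel_step=1e-4):
    """Central finite-difference Hessian of a scalar function."""
    theta = np.asarray(theta, dtype=float)
    d = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.empty((d, d))
    f0 = f(theta)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _prior_mc_evidence(model, prior, y, x, v, sigma2, n_samples=2000, seed=0):
    """Fallback evidence: Monte-Carlo average of the likelihood under the prior."""
    rng = np.random.default_rng(seed)
    mu = prior.means(model)
    sd = np.sqrt(prior.variances(model))
    thetas = rng.normal(mu, sd, size=(n_samples, model.n_free))
    n = y.size
    lls = np.empty(n_samples)
    for i, th in enumerate(thetas):
        s, a = model.full_params(th)
        resid = y - (s + a * v) * x
        lls[i] = (-0.5 * n * (_LOG_2PI + np.log(sigma2))
                  - 0.5 * float(resid @ resid) / sigma2)
    return float(logsumexp(lls) - np.log(n_samples))


def fit_subject(trials: pd.DataFrame, model, prior: PriorSpec | None = None,
                subject_id: int | None = None, seed: int = 0) -> FitResult:
    """MAP-fit one model to one subject's retained, measured trials.

    ``trials`` must carry the measure columns (``ee, valence_code, upd,
    pr``) with excluded trials already removed.  Eight deterministic
    multi-starts are jittered around the prior mean; the best local
    optimum is kept.
    """
    spec = bm.get_model(model)
    prior = prior or PriorSpec()
    if subject_id is None:
        subject_id = int(trials["subject_id"].iloc[0]) \
            if "subject_id" in trials and len(trials) else -1
    if len(trials) == 0:
        raise EmptySubjectError(f"subject {subject_id} has no retained trials")
    y, x, v = _design(spec, trials)
    n = y.size

    if spec.n_free == 0:
        lp, sigma2 = _log_posterior(np.empty(0), spec, prior, y, x, v)
        return FitResult(subject_id, spec.model_id, bm.FIXED_SCALING,
                         bm.FIXED_ASYMMETRY, sigma2, lp, True, n)

    def neg(theta):
        return -_log_posterior(theta, spec, prior, y, x, v)[0]

    rng = np.random.default_rng(seed)
    mu = prior.means(spec)
    starts = np.vstack([mu, mu + rng.normal(0, 0.5, (N_STARTS - 1, spec.n_free))])
    best = None
    any_converged = False
    for s0 in starts:
        res = optimize.minimize(neg, s0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = best.x
    lp_hat, sigma2 = _log_posterior(theta_hat, spec, prior, y, x, v)
    s_hat, a_hat = spec.full_params(theta_hat)

    def lp_fun(theta):
        return _log_posterior(theta, spec, prior, y, x, v)[0]

    method = "laplace"
    try:
        H = _fd_hessian(lp_fun, theta_hat)
        F = laplace_free_energy(lp_hat, H, spec.n_free)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"non-negative-definite Hessian for subject {subject_id}, model "
            f"{spec.name}; falling back to prior-predictive Monte Carlo",
            stacklevel=2)
        F = _prior_mc_evidence(spec, prior, y, x, v, sigma2, seed=seed)
        method = "prior_mc"
    return FitResult(subject_id, spec.model_id, s_hat, a_hat, sigma2, F,
                     bool(any_converged), n, method)


def fit_cohort(retained: pd.DataFrame, model_ids=None,
               prior: PriorSpec | None = None, seed: int = 0
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every (subject, model) pair on a retained measured trial table.

    Returns
    -------
    evidence : DataFrame, subjects x models, of Laplace free energies
        (index subject_id, one column per model name).
    params : long DataFrame of per-fit MAP estimates and diagnostics.
    """
    specs = [bm.get_model(m) for m in (model_ids or range(1, 13))]
    prior = prior or PriorSpec()
    rows, fits = [], []
    for sid, sub in retained.groupby("subject_id", sort=True):
        for spec in specs:
            fr = fit_subject(sub, spec, prior, subject_id=int(sid), seed=seed)
            fits.append(fr)
        rows.append(sid)
    params = pd.DataFrame([{
        "subject_id": f.subject_id, "model_id": f.model_id,
        "model": bm.get_model(f.model_id).name,
        "scaling": f.scaling, "asymmetry": f.asymmetry,
        "noise_var": f.noise_variance, "free_energy": f.free_energy,
        "converged": int(f.converged), "n_trials": f.n_trials_used,
        "evidence_method": f.evidence_method,
    } for f in fits])
    evidence = params.pivot(index="subject_id", columns="model",
                            values="free_energy")
    evidence = evidence[[s.name for s in specs]]
    evidence.columns.name = None
    return evidence, params


def learning_rates_from_params(params: pd.DataFrame, model="rl_sa") -> pd.DataFrame:
    """Per-subject good/bad-news learning rates (S+A, S-A) for one model."""
    spec = bm.get_model(model)
    sub = params[params["model_id"] == spec.model_id].copy()
    sub["lr_good"] = sub["scaling"] + sub["asymmetry"]
    sub["lr_bad"] = sub["scaling"] - sub["asymmetry"]
    return sub[["subject_id", "scaling", "asymmetry", "lr_good", "lr_bad"]]
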