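"""Candidate generative models of belief updating.

Twelve models of how people revise a self-risk estimate (E1) toward the
base rate (BR) of an adverse life event after seeing it, split into two
families:

* Reinforcement-learning-like models: the update is proportional to the
  estimation error EE = E1 - BR, with a valence-dependent learning rate
  composed of a scaling component S and an asymmetry component A
  (LR = S + A for good news, S - A for bad news).  Four of the eight RL
  variants additionally down-weight the error by the personal relevance
  of the event, via the factor (1 - PR).
* Bayesian models: the update is proportional to the gap between E1 and
  the posterior estimate E2b obtained from Bayes' rule, where the prior
  odds come from the base rate and the likelihood ratio from the self
  (E1) versus other (eBR) estimates.

Model variants differ in which of {scaling, asymmetry} are free; fixed
values are S = 1, A = 0, so the fully constrained variants predict an
update exactly equal to the estimation error (RL) or to the rational
Bayesian revision.

All predictions use the sign convention of the task measures: a positive
predicted update means movement toward the base rate, and the implied
posterior estimate is E2 = E1 - valence * UPD (valence +1 for good news,
-1 for bad news).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GOOD = 1
BAD = -1
EXCLUDED = 0

#: values used for parameters that a model variant holds fixed
FIXED_SCALING = 1.0
FIXED_ASYMMETRY = 0.0


@dataclass(frozen=True)
class ModelSpec:
    """One of the 12 candidate belief-updating models."""

    model_id: int
    name: str
    family: str  # "rl" or "bayes"
    scaling_free: bool
    asymmetry_free: bool
    pr_weighted: bool = False
    description: str = ""

    @property
    def n_free(self) -> int:
        return int(self.scaling_free) + int(self.asymmetry_free)

    @property
    def free_names(self) -> tuple[str, ...]:
        names = []
        if self.scaling_free:
            names.append("scaling")
        if self.asymmetry_free:
            names.append("asymmetry")
        return tuple(names)

    def full_params(self, free_values) -> tuple[float, float]:
        """Assemble (scaling, asymmetry) from a vector of free values."""
        free_values = np.atleast_1d(np.asarray(free_values, dtype=float))
        if free_values.size != self.n_free:
            raise ValueError(
                f"model {self.name} expects {self.n_free} free values, "
                f"got {free_values.size}"
            )
        it = iter(free_values)
        s = float(next(it)) if self.scaling_free else FIXED_SCALING
        a = float(next(it)) if self.asymmetry_free else FIXED_ASYMMETRY
        return s, a


_MODEL_TABLE = [
    # id, name, family, S free, A free, PR
    (1, "rl_sa", "rl", True, True, False,
     "updating asymmetrical and proportional to the estimation error"),
    (2, "rl_s", "rl", True, False, False,
     "updating non-asymmetrical and proportional to the estimation error"),
    (3, "rl_a", "rl", False, True, False,
     "asymmetrical updating equal to the estimation error"),
    (4, "rl_fixed", "rl", False, False, False,
     "updating equals the estimation error"),
    (5, "rl_sa_pr", "rl", True, True, True,
     "asymmetrical, proportional, moderated by personal relevance"),
    (6, "rl_s_pr", "rl", True, False, True,
     "non-asymmetrical, proportional, moderated by personal relevance"),
    (7, "rl_a_pr", "rl", False, True, True,
     "asymmetrical, equal to the error, moderated by personal relevance"),
    (8, "rl_fixed_pr", "rl", False, False, True,
     "equals the estimation error moderated by personal relevance"),
    (9, "bayes_sa", "bayes", True, True, False,
     "updating asymmetrical and proportional to Bayes' rule"),
    (10, "bayes_s", "bayes", True, False, False,
     "updating proportional to a rational Bayes rule"),
    (11, "bayes_a", "bayes", False, True, False,
     "updating equals an asymmetrical Bayes rule"),
    (12, "bayes_fixed", "bayes", False, False, False,
     "updating equals a rational Bayes rule"),
]

MODELS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(mid, name, fam, sf, af, pr, desc)
    for mid, name, fam, sf, af, pr, desc in _MODEL_TABLE
)

_BY_NAME = {m.name: m for m in MODELS}
_BY_ID = {m.model_id: m for m in MODELS}
# common aliases used in configs and on the command line
_ALIASES = {
    "bayes_rational": _BY_NAME["bayes_s"],
    "rl_optimistic": _BY_NAME["rl_sa"],
}


def enumerate_models() -> list[ModelSpec]:
    """Return the 12 model specifications in canonical order (RL 1-8, Bayes 1-4)."""
    return list(MODELS)


def get_model(key) -> ModelSpec:
    """Look a model up by integer id (1-12), canonical name, or alias."""
    if isinstance(key, ModelSpec):
        return key
    if isinstance(key, (int, np.integer)):
        try:
            return _BY_ID[int(key)]
        except KeyError:
            raise KeyError(f"no model with id {key}; valid ids are 1-12") from None
    if key in _BY_NAME:
        return _BY_NAME[key]
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(f"unknown model {key!r}")


def learning_rate(scaling, asymmetry, valence):
    """Valence-specific learning rate: S + A for good news, S - A for bad news.

    ``valence`` is +1 (good) or -1 (bad); arrays broadcast.
    """
    valence = np.asarray(valence)
    if np.any(valence == EXCLUDED):
        raise ValueError("learning rate is undefined for excluded (EE = 0) trials")
    return np.asarray(scaling) + np.asarray(asymmetry) * valence


def bayes_posterior(br, e1, ebr):
    """Posterior self-estimate from Bayes' rule, on the percent scale.

    Converts the three estimates to probabilities, forms the prior odds
    BR/(1-BR) and the likelihood ratio [E1/(1-E1)] / [eBR/(1-eBR)],
    multiplies them into posterior odds, and maps back to a percent via
    odds/(1+odds).

    Returns
    -------
    (prior_odds, lhr, e2b) : arrays (or scalars) of the prior odds, the
    likelihood ratio, and the posterior estimate E2b in percent.
    """
    br, e1, ebr = (np.asarray(x, dtype=float) for x in (br, e1, ebr))
    for name, x in (("BR", br), ("E1", e1), ("eBR", ebr)):
        if np.any((x <= 0) | (x >= 100)):
            raise ValueError(f"{name} must be strictly inside (0, 100) percent")
    p_br, p_e1, p_ebr = br / 100.0, e1 / 100.0, ebr / 100.0
    prior_odds = p_br / (1.0 - p_br)
    lhr = (p_e1 / (1.0 - p_e1)) / (p_ebr / (1.0 - p_ebr))
    post_odds = prior_odds * lhr
    e2b = 100.0 * post_odds / (1.0 + post_odds)
    if prior_odds.ndim == 0:
        return float(prior_odds), float(lhr), float(e2b)
    return prior_odds, lhr, e2b


def update_driver(model: ModelSpec, *, ee, valence, pr=None, br=None,
                  e1=None, ebr=None):
    """Per-trial driver x such that the predicted update is LR(valence) * x.

    RL family: x = |EE|, multiplied by (1 - PR) for PR-weighted variants.
    Bayesian family: x = valence * (E1 - E2b), i.e. E1 - E2b on good-news
    trials and E2b - E1 on bad-news trials.

    Excluded trials (valence 0) get a driver of 0.
    """
    valence = np.asarray(valence)
    if model.family == "rl":
        ee = np.asarray(ee, dtype=float)
        x = np.abs(ee)
        if model.pr_weighted:
            if pr is None:
                raise ValueError("PR-weighted model requires personal relevance values")
            x = x * (1.0 - np.asarray(pr, dtype=float))
    elif model.family == "bayes":
        if e1 is None or ebr is None or br is None:
            raise ValueError("Bayesian model requires BR, E1 and eBR")
        _, _, e2b = bayes_posterior(br, e1, ebr)
        x = valence * (np.asarray(e1, dtype=float) - np.asarray(e2b))
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown family {model.family!r}")
    return np.where(valence == EXCLUDED, 0.0, x)


def predict_update(model: ModelSpec, scaling, asymmetry, *, ee, valence,
                   pr=None, br=None, e1=None, ebr=None):
    """Model-predicted update magnitude (positive = toward the base rate)."""
    x = update_driver(model, ee=ee, valence=valence, pr=pr, br=br, e1=e1, ebr=ebr)
    lr = np.asarray(scaling) + np.asarray(asymmetry) * np.asarray(valence)
    return lr * x


def predict_e2(model: ModelSpec, scaling, asymmetry, *, ee, valence,
               pr=None, br=None, e1=None, ebr=None):
    """Implied posterior estimate E2 = E1 - valence * predicted update."""
    upd = predict_update(model, scaling, asymmetry, ee=ee, valence=valence,
                         pr=pr, br=br, e1=e1, ebr=ebr)
    return np.asarray(e1, dtype=float) - np.asarray(valence) * upd
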