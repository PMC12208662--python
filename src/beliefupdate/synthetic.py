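"""Synthetic belief-updating studies.

Generates complete cohorts with the statistical structure the analysis
assumes: a bank of adverse-event base rates, participants in four
testing-context groups with realistic covariates, optimistically offset
first estimates, and belief updates produced by any of the 12 candidate
models plus additive Gaussian noise.

Scale conventions: base rates are integers in [10, 70] (mean about 40);
self- and other-estimates are integer percent ratings clipped to the
response range [3, 77]; simulated second estimates E2 are real-valued
within the same range; confidence is rated on 0-100.

All randomness flows through numpy SeedSequence children derived from
the configured seed, one substream per subject, so the same
configuration reproduces a study byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models as bm
from .measures import add_measures

ESTIMATE_MIN = 3.0
ESTIMATE_MAX = 77.0

#: context label -> pandemic indicator (0 outside, 1 during)
CONTEXT_OF_GROUP = {"oct2019": 0, "mar2020": 1, "may2021": 1, "jun2022": 0}

#: chronological group order; cohort generation always follows it, so the
#: output is invariant to the key order of the configured group sizes
GROUP_ORDER = ("oct2019", "mar2020", "may2021", "jun2022")

TRIAL_COLUMNS = [
    "subject_id", "group", "context", "design", "age", "gender", "education",
    "event_id", "base_rate", "e1", "ebr", "confidence", "e2", "responded",
]


@dataclass(frozen=True)
class EventBank:
    """Bank of adverse life events, identified by integer id and base rate."""

    event_id: np.ndarray
    base_rate: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "event_id", np.asarray(self.event_id, dtype=int))
        object.__setattr__(self, "base_rate", np.asarray(self.base_rate, dtype=int))
        if self.event_id.size != self.base_rate.size or self.event_id.size < 1:
            raise ValueError("event bank needs at least one (id, base rate) pair")
        if np.any((self.base_rate < 10) | (self.base_rate > 70)):
            raise ValueError("base rates must lie within [10, 70] percent")

    @property
    def n_events(self) -> int:
        return int(self.event_id.size)


@dataclass(frozen=True)
class GroupCovariates:
    """Covariate distribution for one testing-context group."""

    age_mean: float
    age_sd: float
    p_female: float
    education_mean: float
    education_sd: float


def _tbl(mean_sem_n, edu_sem, p_f):
    age_mean, age_sem, n = mean_sem_n
    edu_mean, edu_s = edu_sem
    return GroupCovariates(age_mean, age_sem * math.sqrt(n), p_f,
                           edu_mean, edu_s * math.sqrt(n))


#: per-group covariate distributions; spreads reconstructed from the
#: group means +/- SEM via sd = SEM * sqrt(N)
DEFAULT_COVARIATES = {
    "oct2019": _tbl((34.0, 2.0, 30), (5.0, 0.4), 18 / 30),
    "mar2020": _tbl((42.0, 3.0, 34), (4.0, 0.3), 25 / 34),
    "may2021": _tbl((42.0, 3.0, 31), (5.0, 0.2), 20 / 31),
    "jun2022": _tbl((35.0, 3.0, 28), (4.0, 0.4), 14 / 28),
}

# population spread of generating parameters: reported SEM * sqrt(123)
PARAM_MEAN_DEFAULT = (0.39, 0.07)
PARAM_SD_DEFAULT = (0.02 * math.sqrt(123), 0.01 * math.sqrt(123))


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic study.

    ``context_param_shift`` optionally adds (d_scaling, d_asymmetry) to
    the generating parameter means of during-pandemic subjects, and
    ``context_offset_shift`` / ``context_noise_shift`` likewise perturb
    the optimism offset and estimate noise, to emulate the pandemic
    effects (weaker asymmetry, fewer but larger overestimations).
    """

    group_sizes: dict = field(default_factory=lambda: {
        "oct2019": 30, "mar2020": 34, "may2021": 31, "jun2022": 28})
    two_run_counts: dict = field(default_factory=lambda: {
        "oct2019": 30, "mar2020": 0, "may2021": 0, "jun2022": 15})
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    optimism_offset_mean: float = 5.0
    optimism_offset_sd: float = 2.0
    estimate_noise_sd: float = 20.0
    update_noise_sd: float = 8.0
    confidence_shift_during: float = 0.0
    nonresponse_rate: float = 0.011
    generating_model: int = 1
    param_mean: tuple = PARAM_MEAN_DEFAULT
    param_sd: tuple = PARAM_SD_DEFAULT
    context_param_shift: tuple = (0.0, 0.0)
    context_offset_shift: float = 0.0
    context_noise_shift: float = 0.0
    n_events: int = 40
    seed: int = 0

    def validate(self) -> None:
        for name, size in self.group_sizes.items():
            if size < 1:
                raise ValueError(f"group {name!r} must have at least one subject")
            if name not in CONTEXT_OF_GROUP:
                raise ValueError(f"unknown group label {name!r}")
            if not 0 <= self.two_run_counts.get(name, 0) <= size:
                raise ValueError(f"two-run count for {name!r} out of range")
        for name in ("optimism_offset_sd", "estimate_noise_sd",
                     "update_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.nonresponse_rate < 1:
            raise ValueError("nonresponse_rate must lie in [0, 1)")
        if any(s < 0 for s in self.param_sd):
            raise ValueError("parameter population sds must be non-negative")
        bm.get_model(self.generating_model)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes.values()))

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class SubjectRecord:
    """One participant: covariates plus their trial table."""

    subject_id: int
    group: str
    design: int
    age: float
    gender: int
    education: float
    trials: pd.DataFrame

    @property
    def context(self) -> int:
        return CONTEXT_OF_GROUP[self.group]


def pandemic_config(**overrides) -> CohortConfig:
    """Study configuration with the pandemic context effects switched on.

    During-pandemic subjects get a lower learning asymmetry (and slightly
    lower scaling), a larger underestimation offset with noisier first
    estimates (fewer but stronger overestimations), and higher confidence
    in the base rates.  Effect sizes are fixed design choices emulating
    the direction and rough magnitude of the reported pandemic effects.
    """
    defaults = dict(
        context_param_shift=(-0.05, -0.04),
        context_offset_shift=2.0,
        context_noise_shift=2.0,
        confidence_shift_during=14.0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def generate_event_bank(n_events: int = 40, seed=None) -> EventBank:
    """Draw adverse-event base rates: Normal(40, 15) rounded and clipped to [10, 70]."""
    if n_events < 1:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    raw = rng.normal(40.0, 15.0, size=n_events)
    rates = np.clip(np.rint(raw), 10, 70).astype(int)
    return EventBank(event_id=np.arange(1, n_events + 1), base_rate=rates)


def draw_parameters(model, n: int, mean, sd, rng) -> pd.DataFrame:
    """Per-subject generating (scaling, asymmetry); fixed components stay fixed."""
    spec = bm.get_model(model)
    s = (rng.normal(mean[0], sd[0], n) if spec.scaling_free
         else np.full(n, bm.FIXED_SCALING))
    a = (rng.normal(mean[1], sd[1], n) if spec.asymmetry_free
         else np.full(n, bm.FIXED_ASYMMETRY))
    return pd.DataFrame({"scaling": s, "asymmetry": a})


def _seed_children(seed, n):
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return ss.spawn(n)


def _subject_rngs(seed, n):
    return [np.random.default_rng(c) for c in _seed_children(seed, n)]


def generate_cohort(config: CohortConfig, events: EventBank) -> list[SubjectRecord]:
    """Generate participants with covariates and pre-update trial data.

    First estimates follow E1 = BR - offset + noise and eBR = BR + noise,
    both rounded and clipped to the response range; E2 is left NaN (fill
    with :func:`simulate_updates`).
    """
    config.validate()
    # child 0 is reserved for study-level draws (see generate_study)
    rngs = _subject_rngs(config.seed, config.n_subjects + 1)
    subjects: list[SubjectRecord] = []
    sid = 0
    groups = [g for g in GROUP_ORDER if g in config.group_sizes]
    for group in groups:
        size = config.group_sizes[group]
        cov = config.covariates[group]
        two_run = config.two_run_counts.get(group, 0)
        during = CONTEXT_OF_GROUP[group] == 1
        for j in range(size):
            sid += 1
            rng = rngs[sid]
            age = float(np.clip(np.rint(rng.normal(cov.age_mean, cov.age_sd)), 18, 90))
            gender = int(rng.random() < cov.p_female)
            education = float(np.clip(
                np.round(rng.normal(cov.education_mean, cov.education_sd), 1), 0, 15))
            offset_mean = config.optimism_offset_mean + (
                config.context_offset_shift if during else 0.0)
            noise_sd = config.estimate_noise_sd + (
                config.context_noise_shift if during else 0.0)
            offset = rng.normal(offset_mean, config.optimism_offset_sd)
            br = events.base_rate.astype(float)
            e1 = np.clip(np.rint(br - offset + rng.normal(0, noise_sd, events.n_events)),
                         ESTIMATE_MIN, ESTIMATE_MAX)
            ebr = np.clip(np.rint(br + rng.normal(0, noise_sd, events.n_events)),
                          ESTIMATE_MIN, ESTIMATE_MAX)
            confidence = rng.uniform(0, 100, events.n_events)
            if during:
                confidence = np.clip(
                    confidence + config.confidence_shift_during, 0, 100)
            responded = (rng.random(events.n_events) >=
                         config.nonresponse_rate).astype(int)
            trials = pd.DataFrame({
                "event_id": events.event_id,
                "base_rate": events.base_rate,
                "e1": e1, "ebr": ebr,
                "confidence": confidence,
                "e2": np.nan,
                "responded": responded,
            })
            subjects.append(SubjectRecord(
                subject_id=sid, group=group,
                design=2 if j < two_run else 1,
                age=age, gender=gender, education=education, trials=trials))
    return subjects


def simulate_updates(subjects: list[SubjectRecord], model, params: pd.DataFrame,
                     update_noise_sd: float, seed=None) -> list[SubjectRecord]:
    """Fill E2 by simulating each subject's updates from a candidate model.

    ``params`` must hold one (scaling, asymmetry) row per subject, in
    subject order.  E2 = E1 - valence * predicted update + noise, clipped
    to the response range; on excluded (EE = 0) trials the prediction is
    zero, so E2 = E1 + noise there.
    """
    spec = bm.get_model(model)
    if len(params) != len(subjects):
        raise ValueError(
            f"need one parameter row per subject: {len(params)} != {len(subjects)}")
    rngs = _subject_rngs(seed, len(subjects))
    out = []
    for rec, (_, prow), rng in zip(subjects, params.iterrows(), rngs):
        t = rec.trials
        ee = t["e1"].to_numpy(float) - t["base_rate"].to_numpy(float)
        valence = np.sign(ee).astype(int)
        pr = None
        if spec.pr_weighted:
            from .measures import personal_relevance
            pr = personal_relevance(t["e1"], t["ebr"])
        upd = bm.predict_update(
            spec, prow["scaling"], prow["asymmetry"], ee=ee, valence=valence,
            pr=pr, br=t["base_rate"], e1=t["e1"], ebr=t["ebr"])
        noise = (rng.normal(0, update_noise_sd, len(t))
                 if update_noise_sd > 0 else np.zeros(len(t)))
        e2 = np.clip(t["e1"].to_numpy(float) - valence * upd + noise,
                     ESTIMATE_MIN, ESTIMATE_MAX)
        trials = t.copy()
        trials["e2"] = e2
        out.append(replace_trials(rec, trials))
    return out


def replace_trials(rec: SubjectRecord, trials: pd.DataFrame) -> SubjectRecord:
    return SubjectRecord(rec.subject_id, rec.group, rec.design, rec.age,
                         rec.gender, rec.education, trials)


def cohort_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Concatenate a cohort into one long trial table (one row per trial)."""
    frames = []
    for rec in subjects:
        t = rec.trials.copy()
        t.insert(0, "subject_id", rec.subject_id)
        t.insert(1, "group", rec.group)
        t.insert(2, "context", rec.context)
        t.insert(3, "design", rec.design)
        t.insert(4, "age", rec.age)
        t.insert(5, "gender", rec.gender)
        t.insert(6, "education", rec.education)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    out = []
    for sid, sub in frame.groupby("subject_id", sort=True):
        first = sub.iloc[0]
        trials = sub[["event_id", "base_rate", "e1", "ebr", "confidence",
                      "e2", "responded"]].reset_index(drop=True)
        out.append(SubjectRecord(
            subject_id=int(sid), group=str(first["group"]),
            design=int(first["design"]), age=float(first["age"]),
            gender=int(first["gender"]), education=float(first["education"]),
            trials=trials))
    return out


def generate_study(config: CohortConfig, events: EventBank | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full study generation: cohort, parameters, simulated updates.

    Returns the long trial table and the per-subject generating-parameter
    table.  Parameter draws, cohort covariates and update noise use
    separate children of the configured seed.  During-pandemic subjects'
    generating parameter means are shifted by ``context_param_shift``.
    """
    config.validate()
    # study-level draws come from child 0 of the cohort seed tree, which
    # generate_cohort leaves untouched, so the two spawn paths never collide
    root = _seed_children(config.seed, config.n_subjects + 1)[0].spawn(3)
    if events is None:
        events = generate_event_bank(config.n_events, seed=root[0])
    subjects = generate_cohort(config, events)
    rng = np.random.default_rng(root[1])
    params = draw_parameters(config.generating_model, len(subjects),
                             config.param_mean, config.param_sd, rng)
    spec = bm.get_model(config.generating_model)
    shift_s, shift_a = config.context_param_shift
    during = np.array([rec.context == 1 for rec in subjects])
    if spec.scaling_free:
        params.loc[during, "scaling"] += shift_s
    if spec.asymmetry_free:
        params.loc[during, "asymmetry"] += shift_a
    params.insert(0, "subject_id", [rec.subject_id for rec in subjects])
    subjects = simulate_updates(subjects, spec, params,
                                config.update_noise_sd, seed=root[2])
    return cohort_to_frame(subjects), params


def measured_study(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: generate a study and return (retained measured trials, params)."""
    from .measures import apply_exclusions
    trials, params = generate_study(config)
    retained, _ = apply_exclusions(add_measures(trials))
    return retained, params
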