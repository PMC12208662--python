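"""Group-level inference: t-tests, mixed models, power simulation."""

import subprocess
import sys
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import beliefupdate as bu
from beliefupdate.stats import lme_frame


def test_t_test_hand_example():
    res = bu.two_sample_t([1, 2, 3], [4, 5, 6])
    assert res.t == pytest.approx(-3.674, abs=1e-3)
    assert res.df == 4
    assert res.cohens_d == pytest.approx(-3.0)


def test_t_test_identity_and_df_convention():
    x = np.arange(10.0)
    res = bu.two_sample_t(x, x)
    assert res.t == 0.0 and res.cohens_d == 0.0
    rng = np.random.default_rng(0)
    res = bu.two_sample_t(rng.normal(size=65), rng.normal(size=58))
    assert res.df == 121


def test_t_test_validation():
    with pytest.raises(ValueError):
        bu.two_sample_t([1.0], [2.0, 3.0])
    with pytest.raises(ValueError, match="pooled variance"):
        bu.two_sample_t([1.0, 1.0], [1.0, 1.0])


@settings(max_examples=60, deadline=None)
@given(x=arrays(float, st.integers(3, 20),
                elements=st.floats(-50, 50, allow_nan=False)),
       y=arrays(float, st.integers(3, 20),
                elements=st.floats(-50, 50, allow_nan=False)))
def test_t_test_matches_brute_force_formula(x, y):
    if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
        return
    res = bu.two_sample_t(x, y)
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                 / (nx + ny - 2))
    t = (np.mean(x) - np.mean(y)) / (sp * np.sqrt(1 / nx + 1 / ny))
    assert res.t == pytest.approx(t, abs=1e-10)
    assert res.cohens_d == pytest.approx((np.mean(x) - np.mean(y)) / sp,
                                         abs=1e-10)
    assert np.sign(res.cohens_d) == np.sign(np.mean(x) - np.mean(y))


def test_t_test_agrees_with_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    x, y = rng.normal(0.5, 1, 40), rng.normal(0, 1, 35)
    res = bu.two_sample_t(x, y)
    ref = pingouin.ttest(x, y, correction=False)
    assert res.t == pytest.approx(float(ref["T"].iloc[0]), abs=1e-9)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)
    assert res.cohens_d == pytest.approx(abs(float(ref["cohen_d"].iloc[0]))
                                         * np.sign(x.mean() - y.mean()),
                                         abs=1e-9)


def _constructed_updates(retained, beta_interaction, seed=0, sd_intercept=1.0,
                         noise=3.0):
    """Build updates from an explicit mixed model with known coefficients."""
    data = lme_frame(retained)
    rng = np.random.default_rng(seed)
    subj = data["subject_id"].unique()
    b0 = dict(zip(subj, rng.normal(0, sd_intercept, subj.size)))
    data = data.copy()
    data["upd"] = (2.0 + 0.3 * data["ee_abs"] + 1.0 * data["valence"]
                   + beta_interaction * data["valence"] * data["context"]
                   + data["subject_id"].map(b0)
                   + rng.normal(0, noise, len(data)))
    return data


def test_lme_recovers_constructed_interaction(measured_cohort_123):
    """The update LME recovers a known valence-by-context coefficient
    built into simulated updates (generator-truth recovery)."""
    _, _, _, retained, _ = measured_cohort_123
    data = _constructed_updates(retained, beta_interaction=-5.54, seed=3)
    res = bu.fit_lme_update(data, re_structure="intercept")
    term = res.term("valence:context")
    assert term["beta"] == pytest.approx(-5.54, abs=3 * term["se"])
    assert term["p"] < 0.001
    assert res.converged


def test_lme_null_covariates_stay_small(measured_cohort_123):
    _, _, _, retained, _ = measured_cohort_123
    data = _constructed_updates(retained, beta_interaction=0.0, seed=4)
    res = bu.fit_lme_update(data, re_structure="intercept")
    for name in ("design", "age", "gender", "education", "valence:context"):
        assert abs(res.term(name)["t"]) < 4.0
    # CI follows the stated beta +/- 1.96 SE convention
    t = res.table
    np.testing.assert_allclose(t["ci_low"], t["beta"] - 1.96 * t["se"],
                               atol=1e-6)


def test_lme_group_coding_variant(measured_cohort_123):
    _, _, _, retained, _ = measured_cohort_123
    data = _constructed_updates(retained, beta_interaction=0.0, seed=5)
    data["group"] = lme_frame(retained)["group"]
    res = bu.fit_lme_update(data, re_structure="intercept",
                            context_coding="groups")
    terms = set(res.table["term"])
    assert any("mar2020" in t and "valence" in t for t in terms)
    assert not any(t == "context" for t in terms)


def test_lme_duplicating_subjects_shrinks_standard_errors(small_retained):
    data = _constructed_updates(small_retained, beta_interaction=-3.0, seed=6)
    doubled = pd.concat([
        data, data.assign(subject_id=data["subject_id"] + 1000)],
        ignore_index=True)
    a = bu.fit_lme_update(data, re_structure="intercept")
    b = bu.fit_lme_update(doubled, re_structure="intercept")
    assert b.n_obs == 2 * a.n_obs
    assert b.term("valence:context")["se"] < a.term("valence:context")["se"]


def test_lme_requires_multiple_subjects(small_retained):
    one = small_retained[small_retained["subject_id"] ==
                         small_retained["subject_id"].iloc[0]]
    with pytest.raises(ValueError):
        bu.fit_lme_update(one)


def test_lme_against_lme4_oracle(small_retained):
    """Fixed effects agree with an independent lme4 ML fit."""
    if not _rscript_available():
        pytest.skip("Rscript with lme4 not available")
    data = _constructed_updates(small_retained, beta_interaction=-4.0, seed=7)
    import tempfile
    from pathlib import Path
    with tempfile.TemporaryDirectory() as td:
        csv = Path(td) / "d.csv"
        data.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(upd ~ ee_abs + valence + context + design + age + gender +
                  education + valence:context + (1|subject_id), data=d,
                  REML=FALSE)
        cat(paste(names(fixef(m)), fixef(m), sep="=", collapse="\\n"))
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = dict(line.split("=") for line in out.stdout.strip().splitlines())
    res = bu.fit_lme_update(data, re_structure="intercept")
    mapping = {"(Intercept)": "Intercept", "valence:context": "valence:context",
               "ee_abs": "ee_abs", "valence": "valence", "context": "context",
               "design": "design", "age": "age", "gender": "gender",
               "education": "education"}
    for rname, pname in mapping.items():
        assert res.term(pname)["beta"] == pytest.approx(float(ref[rname]),
                                                        abs=2e-3), pname


def _rscript_available():
    try:
        out = subprocess.run(
            ["Rscript", "-e", "suppressMessages(library(lme4)); cat('ok')"],
            capture_output=True, text=True, timeout=120)
        return out.returncode == 0 and "ok" in out.stdout
    except (OSError, subprocess.TimeoutExpired):
        return False


def test_learning_rate_lme_null_and_context_effect():
    rng = np.random.default_rng(2)
    n = 60
    base = pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "context": np.repeat([0, 1], n // 2),
        "design": rng.integers(1, 3, n), "age": rng.normal(38, 10, n).round(),
        "gender": rng.integers(0, 2, n),
        "education": rng.normal(4.5, 1.5, n).round(1),
        "scaling": rng.normal(0.4, 0.2, n),
    })
    # A = 0 for everyone: the valence term should vanish
    null = base.assign(asymmetry=0.0)
    null["lr_good"] = null["scaling"] + null["asymmetry"] + \
        rng.normal(0, 0.01, n)
    null["lr_bad"] = null["scaling"] - null["asymmetry"] + \
        rng.normal(0, 0.01, n)
    res = bu.fit_lme_learning_rate(null)
    assert abs(res.term("valence")["beta"]) < 0.01
    # context-dependent asymmetry: significant valence-by-context term
    shifted = base.assign(asymmetry=np.where(base["context"] == 1, 0.0, 0.3))
    shifted["lr_good"] = shifted["scaling"] + shifted["asymmetry"]
    shifted["lr_bad"] = shifted["scaling"] - shifted["asymmetry"]
    res = bu.fit_lme_learning_rate(shifted)
    assert res.term("valence:context")["p"] < 1e-6
    assert res.term("valence:context")["beta"] < 0
    with pytest.raises(ValueError):
        bu.fit_lme_learning_rate(null.iloc[:2].assign(subject_id=1))


def test_parameter_lme_recovers_context_shift():
    rng = np.random.default_rng(3)
    n = 120
    tbl = pd.DataFrame({
        "subject_id": np.arange(n), "context": np.repeat([0, 1], n // 2),
        "age": rng.normal(38, 10, n), "gender": rng.integers(0, 2, n),
        "education": rng.normal(4.5, 1.5, n),
    })
    tbl["asymmetry"] = 0.08 - 0.05 * tbl["context"] + rng.normal(0, 0.05, n)
    res = bu.fit_lme_parameters(tbl, "asymmetry")
    term = res.term("context")
    assert term["beta"] == pytest.approx(-0.05, abs=3 * term["se"])
    assert term["p"] < 0.01
    with pytest.raises(ValueError, match="lacks"):
        bu.fit_lme_parameters(tbl, "scaling")
    with pytest.raises(ValueError):
        bu.fit_lme_parameters(tbl, "noise")


def test_power_saturates_for_huge_effect():
    """A very large built-in valence-by-context effect is detected on
    every simulated iteration."""
    cfg = bu.CohortConfig(
        group_sizes={"oct2019": 10, "mar2020": 10},
        two_run_counts={"oct2019": 5, "mar2020": 0},
        param_sd=(0.05, 0.02), seed=8)
    trials, params = bu.generate_study(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained, _ = bu.apply_exclusions(bu.add_measures(trials))
    ctx = retained.groupby("subject_id")["context"].first()
    assign = params[["subject_id"]].copy()
    assign["model_id"] = 1
    assign["scaling"] = 0.5
    # opposite extreme asymmetries by context
    assign["asymmetry"] = np.where(ctx.loc[assign["subject_id"]] == 1,
                                   -0.45, 0.45)
    rep = bu.power_simulation(retained, assign, update_noise_sd=4.0,
                              n_iterations=12, seed=0,
                              re_structure="intercept")
    assert rep.power == 1.0
    assert rep.n_failed == 0
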