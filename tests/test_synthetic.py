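"""Synthetic study generation: distributions, bounds, determinism."""

import numpy as np
import pandas as pd
import pytest

import beliefupdate as bu
from beliefupdate.synthetic import (CONTEXT_OF_GROUP, ESTIMATE_MAX,
                                    ESTIMATE_MIN, draw_parameters,
                                    pandemic_config)


def test_event_bank_bounds_and_mean():
    bank = bu.generate_event_bank(40, seed=0)
    assert bank.n_events == 40
    assert bank.base_rate.min() >= 10 and bank.base_rate.max() <= 70
    assert 35 <= bank.base_rate.mean() <= 45


def test_event_bank_deterministic():
    a = bu.generate_event_bank(1, seed=5)
    b = bu.generate_event_bank(1, seed=5)
    assert a.base_rate[0] == b.base_rate[0]


def test_event_bank_truncation_mean_against_monte_carlo_oracle():
    """Large-sample mean matches a direct Monte-Carlo of the stated
    truncation (Normal(40, 15) rounded and clipped to [10, 70])."""
    rng = np.random.default_rng(123)
    oracle = np.clip(np.rint(rng.normal(40, 15, 200_000)), 10, 70).mean()
    bank = bu.generate_event_bank(10_000, seed=1)
    assert abs(bank.base_rate.mean() - oracle) < 1.0
    assert abs(bank.base_rate.mean() - 40) < 1.0


def test_event_bank_rejects_bad_n():
    with pytest.raises(ValueError):
        bu.generate_event_bank(0)


def test_default_cohort_has_paper_group_sizes():
    cfg = bu.CohortConfig()
    events = bu.generate_event_bank(40, seed=0)
    subjects = bu.generate_cohort(cfg, events)
    assert len(subjects) == 123
    frame = bu.cohort_to_frame(subjects)
    sizes = frame.groupby("group")["subject_id"].nunique().to_dict()
    assert sizes == {"oct2019": 30, "mar2020": 34, "may2021": 31,
                     "jun2022": 28}
    # context derives from the group label
    for g, ctx in CONTEXT_OF_GROUP.items():
        assert (frame.loc[frame["group"] == g, "context"] == ctx).all()
    # 40 trials per subject before exclusions
    assert (frame.groupby("subject_id").size() == 40).all()


def test_positive_offset_without_noise_gives_all_bad_news():
    cfg = bu.CohortConfig(group_sizes={"oct2019": 4},
                          two_run_counts={"oct2019": 0},
                          optimism_offset_mean=5.0, optimism_offset_sd=0.0,
                          estimate_noise_sd=0.0, seed=1)
    events = bu.generate_event_bank(40, seed=0)
    frame = bu.cohort_to_frame(bu.generate_cohort(cfg, events))
    assert (frame["e1"] < frame["base_rate"]).all()


def test_zero_offset_gives_balanced_valences():
    cfg = bu.CohortConfig(group_sizes={"oct2019": 40},
                          two_run_counts={"oct2019": 0},
                          optimism_offset_mean=0.0, optimism_offset_sd=0.0,
                          estimate_noise_sd=20.0, nonresponse_rate=0.0,
                          seed=3)
    events = bu.generate_event_bank(40, seed=0)
    frame = bu.cohort_to_frame(bu.generate_cohort(cfg, events))
    ee = frame["e1"] - frame["base_rate"]
    frac_good = (ee > 0).sum() / (ee != 0).sum()
    assert frac_good == pytest.approx(0.5, abs=0.03)


def test_estimates_and_confidence_within_scale(measured_cohort_123):
    _, trials, _, _, _ = measured_cohort_123
    for col in ("e1", "ebr", "e2"):
        assert trials[col].between(ESTIMATE_MIN, ESTIMATE_MAX).all()
    assert trials["confidence"].between(0, 100).all()


def test_same_seed_reproduces_study_exactly():
    cfg = bu.CohortConfig(group_sizes={"oct2019": 5, "mar2020": 5},
                          two_run_counts={"oct2019": 5, "mar2020": 0},
                          seed=9)
    t1, p1 = bu.generate_study(cfg)
    t2, p2 = bu.generate_study(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(p1, p2)


def test_simulated_updates_match_model_prediction_without_noise():
    cfg = bu.CohortConfig(group_sizes={"oct2019": 6},
                          two_run_counts={"oct2019": 0},
                          update_noise_sd=0.0, nonresponse_rate=0.0, seed=4)
    trials, params = bu.generate_study(cfg)
    measured = bu.add_measures(trials)
    retained, _ = bu.apply_exclusions(measured)
    spec = bu.get_model(cfg.generating_model)
    for (sid, sub), (_, prow) in zip(retained.groupby("subject_id"),
                                     params.iterrows()):
        unclipped = (sub["e2"] > ESTIMATE_MIN) & (sub["e2"] < ESTIMATE_MAX)
        sub = sub[unclipped]
        pred = bu.predict_update(spec, prow["scaling"], prow["asymmetry"],
                                 ee=sub["ee"].to_numpy(),
                                 valence=sub["valence_code"].to_numpy())
        np.testing.assert_allclose(sub["upd"].to_numpy(), pred, atol=1e-9)


@pytest.mark.parametrize("model_id, s, a, expect", [
    (1, 1.0, 0.0, "br"),   # full rational update lands on the base rate
    (1, 0.0, 0.0, "e1"),   # no learning leaves the first estimate
])
def test_update_simulation_limits(model_id, s, a, expect):
    events = bu.generate_event_bank(20, seed=2)
    cfg = bu.CohortConfig(group_sizes={"oct2019": 3},
                          two_run_counts={"oct2019": 0},
                          nonresponse_rate=0.0, seed=2)
    subjects = bu.generate_cohort(cfg, events)
    params = pd.DataFrame({"scaling": [s] * 3, "asymmetry": [a] * 3})
    subjects = bu.simulate_updates(subjects, model_id, params,
                                   update_noise_sd=0.0, seed=0)
    frame = bu.cohort_to_frame(subjects)
    frame = frame[frame["e1"] != frame["base_rate"]]
    target = frame["base_rate"] if expect == "br" else frame["e1"]
    np.testing.assert_allclose(frame["e2"], target, atol=1e-9)


def test_simulate_updates_requires_matching_params():
    events = bu.generate_event_bank(10, seed=0)
    cfg = bu.CohortConfig(group_sizes={"oct2019": 3},
                          two_run_counts={"oct2019": 0}, seed=0)
    subjects = bu.generate_cohort(cfg, events)
    with pytest.raises(ValueError, match="one parameter row per subject"):
        bu.simulate_updates(subjects, 1, pd.DataFrame({"scaling": [1.0],
                                                       "asymmetry": [0.0]}),
                            update_noise_sd=0.0)


def test_parameter_draws_centered_on_population_mean():
    rng = np.random.default_rng(0)
    n = 400
    draws = draw_parameters(1, n, (0.39, 0.07), (0.2, 0.1), rng)
    for col, mean, sd in (("scaling", 0.39, 0.2), ("asymmetry", 0.07, 0.1)):
        se = sd / np.sqrt(n)
        assert abs(draws[col].mean() - mean) < 3 * se
    # fixed components stay at their fixed values
    fixed = draw_parameters(4, 10, (0.39, 0.07), (0.2, 0.1), rng)
    assert (fixed["scaling"] == 1.0).all() and (fixed["asymmetry"] == 0.0).all()


def test_pandemic_config_shifts_during_subjects():
    cfg = pandemic_config(seed=1)
    trials, params = bu.generate_study(cfg)
    merged = params.merge(
        trials.groupby("subject_id")[["context", "confidence"]].first()
        .reset_index(), on="subject_id")
    a_out = merged.loc[merged["context"] == 0, "asymmetry"].mean()
    a_dur = merged.loc[merged["context"] == 1, "asymmetry"].mean()
    assert a_dur < a_out
    conf = trials.groupby("subject_id")["confidence"].mean().groupby(
        trials.groupby("subject_id")["context"].first()).mean()
    assert conf[1] > conf[0]


def test_config_validation():
    with pytest.raises(ValueError):
        bu.CohortConfig(group_sizes={"oct2019": 0}).validate()
    with pytest.raises(ValueError):
        bu.CohortConfig(estimate_noise_sd=-1).validate()
    with pytest.raises(ValueError):
        bu.CohortConfig(group_sizes={"atlantis": 5}).validate()


def test_frame_cohort_roundtrip(small_cohort):
    _, trials, _ = small_cohort
    back = bu.cohort_to_frame(bu.frame_to_cohort(trials))
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), trials.reset_index(drop=True),
        check_dtype=False)
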