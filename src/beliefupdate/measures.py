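"""Trial-level task measures and exclusion rules for the belief-updating task.

Each trial yields a first self-estimate (E1), an estimate for somebody
else (eBR), the true base rate (BR), a confidence rating, and a second
self-estimate (E2) given after seeing the base rate.  All quantities are
on the percent scale.  Derived measures:

estimation error  EE = E1 - BR (or eBR - BR in the alternative mode)
valence           good news if EE > 0 (risk overestimated), bad if EE < 0
update            UPD = E1 - E2 for good news, E2 - E1 for bad news
                  (positive = movement toward the base rate)
update bias       UDB = mean UPD(good) - mean UPD(bad)
personal relev.   PR in [0, 1], normalized |eBR - E1| discrepancy
distance          eBR - E1

Trials without a response and trials with EE = 0 are excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .models import BAD, EXCLUDED, GOOD

VALENCE_LABELS = {GOOD: "good", BAD: "bad", EXCLUDED: "excluded"}

#: columns added to a trial table by :func:`add_measures`
MEASURE_COLUMNS = ("ee", "valence", "upd", "pr", "distance", "excluded")


class UndefinedMeasureError(ValueError):
    """A measure was requested for a trial or subject where it is undefined."""


def estimation_error(e1, br, ebr=None, mode: str = "self"):
    """Signed estimation error: E1 - BR (self mode) or eBR - BR (other mode)."""
    if mode == "self":
        if e1 is None:
            raise ValueError("self mode requires E1")
        return np.asarray(e1, dtype=float) - np.asarray(br, dtype=float)
    if mode == "other":
        if ebr is None:
            raise ValueError("other mode requires eBR")
        return np.asarray(ebr, dtype=float) - np.asarray(br, dtype=float)
    raise ValueError(f"mode must be 'self' or 'other', got {mode!r}")


def classify_valence(ee):
    """+1 for good news (EE > 0), -1 for bad news (EE < 0), 0 for excluded."""
    ee = np.asarray(ee, dtype=float)
    if not np.all(np.isfinite(ee)):
        raise ValueError("estimation errors must be finite")
    return np.sign(ee).astype(int)


def update(e1, e2, valence):
    """Belief update, signed toward the base rate (Eq. UPD).

    Good news: E1 - E2; bad news: E2 - E1.  Raises for excluded trials.
    """
    valence = np.asarray(valence)
    if np.any(valence == EXCLUDED):
        raise UndefinedMeasureError("update is undefined for excluded trials")
    return valence * (np.asarray(e1, dtype=float) - np.asarray(e2, dtype=float))


def update_bias(mean_upd_good: float, mean_upd_bad: float) -> float:
    """Update bias UDB = mean good-news update - mean bad-news update."""
    if mean_upd_good is None or mean_upd_bad is None or \
            not (np.isfinite(mean_upd_good) and np.isfinite(mean_upd_bad)):
        raise UndefinedMeasureError(
            "update bias requires a mean update for both valences")
    return float(mean_upd_good) - float(mean_upd_bad)


def personal_relevance(e1, ebr):
    """Normalized self-versus-other discrepancy, in [0, 1].

    PR = (eBR - E1)/(eBR - 1) when eBR > E1, (E1 - eBR)/(99 - eBR) when
    eBR < E1, and 0 when they are equal; each branch divides the raw
    discrepancy by its maximum attainable magnitude on the 1-99 percent
    scale, and the result is clamped to [0, 1].
    """
    e1 = np.asarray(e1, dtype=float)
    ebr = np.asarray(ebr, dtype=float)
    if np.any((e1 < 1) | (e1 > 99)) or np.any((ebr < 1) | (ebr > 99)):
        raise ValueError("E1 and eBR must lie within [1, 99] percent")
    with np.errstate(divide="ignore", invalid="ignore"):
        above = (ebr - e1) / (ebr - 1.0)   # eBR > E1 (denominator > 0 there)
        below = (e1 - ebr) / (99.0 - ebr)  # eBR < E1 (denominator > 0 there)
    pr = np.where(ebr > e1, above, np.where(ebr < e1, below, 0.0))
    pr = np.clip(pr, 0.0, 1.0)
    return float(pr) if pr.ndim == 0 else pr


def distance(e1, ebr):
    """Distance = eBR - E1; positive reflects optimistic initial comparison."""
    return np.asarray(ebr, dtype=float) - np.asarray(e1, dtype=float)


def add_measures(trials: pd.DataFrame, ee_mode: str = "self") -> pd.DataFrame:
    """Return a copy of a trial table with all derived measure columns.

    Expects columns ``base_rate, e1, ebr, e2, responded``.  Adds ``ee``
    (per the active mode), ``valence`` (good/bad/excluded string label),
    ``upd`` (NaN on excluded trials), ``pr``, ``distance``, ``excluded``
    (1 if non-responded or EE = 0).
    """
    out = trials.copy()
    ee = estimation_error(out["e1"], out["base_rate"], out["ebr"], mode=ee_mode)
    val = classify_valence(ee)
    responded = out["responded"].to_numpy().astype(bool)
    excluded = (~responded) | (val == EXCLUDED)
    upd = np.where(val == EXCLUDED, np.nan,
                   val * (out["e1"].to_numpy(float) - out["e2"].to_numpy(float)))
    out["ee"] = ee
    out["valence"] = [VALENCE_LABELS[v] for v in val]
    out["valence_code"] = val
    out["upd"] = upd
    out["pr"] = personal_relevance(out["e1"], out["ebr"])
    out["distance"] = distance(out["e1"], out["ebr"])
    out["excluded"] = excluded.astype(int)
    return out


def apply_exclusions(measured: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-responded and EE = 0 trials from a measured trial table.

    Returns the retained rows and a per-subject table of exclusion
    counts (``n_trials, n_no_response, n_zero_ee, n_retained``).  Emits
    a warning for subjects that lose every trial.
    """
    if "excluded" not in measured.columns:
        raise ValueError("call add_measures before apply_exclusions")
    responded = measured["responded"].astype(bool)
    zero_ee = measured["ee"] == 0
    counts = (
        measured.assign(
            n_no_response=(~responded).astype(int),
            n_zero_ee=(responded & zero_ee).astype(int),
            n_retained=(measured["excluded"] == 0).astype(int),
        )
        .groupby("subject_id", sort=True)
        .agg(n_trials=("excluded", "size"),
             n_no_response=("n_no_response", "sum"),
             n_zero_ee=("n_zero_ee", "sum"),
             n_retained=("n_retained", "sum"))
        .reset_index()
    )
    empty = counts.loc[counts["n_retained"] == 0, "subject_id"].tolist()
    if empty:
        warnings.warn(f"subjects with no retained trials: {empty}", stacklevel=2)
    retained = measured.loc[measured["excluded"] == 0].copy()
    return retained, counts


def subject_summaries(retained: pd.DataFrame) -> pd.DataFrame:
    """Per-subject trial averages used for group comparisons.

    Computes, over retained trials of each subject: mean good- and
    bad-news updates and the update bias, mean positive and negative
    estimation-error magnitudes, good/bad trial counts, mean confidence
    and mean distance.  Subjects missing a valence get NaN for the
    corresponding means and for the update bias.
    """
    rows = []
    cov_cols = [c for c in ("group", "context", "design", "age", "gender",
                            "education") if c in retained.columns]
    for sid, sub in retained.groupby("subject_id", sort=True):
        good = sub[sub["valence"] == "good"]
        bad = sub[sub["valence"] == "bad"]
        row = {
            "subject_id": sid,
            "n_good": len(good),
            "n_bad": len(bad),
            "upd_good": good["upd"].mean() if len(good) else np.nan,
            "upd_bad": bad["upd"].mean() if len(bad) else np.nan,
            "ee_pos_mag": good["ee"].abs().mean() if len(good) else np.nan,
            "ee_neg_mag": bad["ee"].abs().mean() if len(bad) else np.nan,
            "confidence": sub["confidence"].mean(),
            "distance": sub["distance"].mean(),
        }
        row["udb"] = (row["upd_good"] - row["upd_bad"]
                      if len(good) and len(bad) else np.nan)
        for c in cov_cols:
            row[c] = sub[c].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    n_dropped = int(out["udb"].isna().sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} subject(s) lack trials of one valence; their update "
            "bias is undefined and they are dropped from bias summaries",
            stacklevel=2)
    return out
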