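"""Behavioral summaries, participant screening, and analysis factors.

Key semantics throughout: Key 1 = sure face, Key 2 = unsure face, Key 3 = no
idea, Key 4 = unsure house, Key 5 = sure house.  The derived Confidence
factor is *category-congruent*: high = Key 1 on a face or Key 5 on a house,
low = Key 2 / Key 4 congruently, guess = Key 3; incongruent keys carry no
confidence level and those trials drop out of the confidence analyses (they
stay in the table, flagged NA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import DURATION_LONG, DURATION_SHORT

KEYS = [1, 2, 3, 4, 5]


def _group_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Across-participant mean with a normal-approximation CI."""
    m = float(np.mean(values))
    if len(values) < 2:
        return m, np.nan, np.nan
    se = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    z = stats.norm.ppf(0.5 + level / 2)
    return m, m - z * se, m + z * se


def response_allocation(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion of each response key per (type, category, duration).

    Proportions are computed within participant (summing to 1 over keys per
    condition) and then summarized across participants with mean and 95% CI.
    Conditions with zero trials for some participant are flagged NaN for that
    participant and excluded from the group summary.
    """
    rows = []
    cond_cols = ["type", "category", "duration"]
    for cond, g in trials.groupby(cond_cols):
        per_part = (
            g.groupby("participant_id")["response_key"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=KEYS, fill_value=0.0)
        )
        for key in KEYS:
            m, lo, hi = _group_ci(per_part[key].to_numpy())
            rows.append((*cond, key, m, lo, hi, len(per_part)))
    out = pd.DataFrame(
        rows, columns=cond_cols + ["response_key", "proportion", "ci_low", "ci_high", "n_participants"]
    )
    return out


def face_given_response(trials: pd.DataFrame) -> pd.DataFrame:
    """P(stimulus is a face | response key, type, duration), with CIs.

    A key never used in a cell is reported as a missing (NaN) proportion,
    not zero.
    """
    rows = []
    for (typ, dur), g in trials.groupby(["type", "duration"]):
        for key in KEYS:
            gk = g[g["response_key"] == key]
            per_part = gk.groupby("participant_id")["category"].apply(
                lambda s: float((s == "face").mean())
            )
            if len(per_part) == 0:
                rows.append((typ, dur, key, np.nan, np.nan, np.nan, 0))
            else:
                m, lo, hi = _group_ci(per_part.to_numpy())
                rows.append((typ, dur, key, m, lo, hi, len(per_part)))
    return pd.DataFrame(
        rows,
        columns=["type", "duration", "response_key", "p_face", "ci_low", "ci_high", "n_participants"],
    )


def key1_accuracy(trials: pd.DataFrame) -> pd.Series:
    """Per-participant P(face | Key 1, intact, 33 ms) — the screening score.

    Participants who never pressed Key 1 on intact 33 ms trials get NaN.
    """
    sel = trials[
        (trials["type"] == "intact")
        & (trials["duration"] == DURATION_SHORT)
        & (trials["response_key"] == 1)
    ]
    acc = sel.groupby("participant_id")["category"].apply(
        lambda s: float((s == "face").mean())
    )
    all_p = pd.Index(np.sort(trials["participant_id"].unique()), name="participant_id")
    return acc.reindex(all_p)


def screen_participants(
    accuracy: pd.Series, threshold: float = 0.95
) -> tuple[list, pd.DataFrame]:
    """Retain participants with screening accuracy >= threshold (inclusive).

    Participants with undefined accuracy (never used Key 1 at 33 ms) are
    excluded with reason ``no-usage``.  Returns (retained ids, exclusion
    table with reasons).
    """
    retained, excluded = [], []
    for pid, acc in accuracy.items():
        if pd.isna(acc):
            excluded.append((pid, np.nan, "no-usage"))
        elif acc >= threshold:
            retained.append(pid)
        else:
            excluded.append((pid, acc, f"accuracy {acc:.3f} < {threshold}"))
    return retained, pd.DataFrame(
        excluded, columns=["participant_id", "accuracy", "reason"]
    )


_CONGRUENT_HIGH = {("face", 1), ("house", 5)}
_CONGRUENT_LOW = {("face", 2), ("house", 4)}


def derive_factors(trials: pd.DataFrame) -> pd.DataFrame:
    """Append Confidence, Duration-Confidence and Duration-Half factors.

    Duration Confidence (intact trials only) has four levels: 33_guess,
    33_low, 33_high and 216_high; intact trials outside those levels (e.g. a
    216 ms guess, or a category-incongruent key) are NA — excluded from that
    analysis but kept in the table.  Duration Half is defined only for
    high-confidence intact trials: 33_half1, 33_half2, 216_half2.
    """
    out = trials.copy()
    keys = out["response_key"].to_numpy()
    if not np.isin(keys, KEYS).all():
        raise ValueError("unknown response key value")
    cat = out["category"].to_numpy()

    conf = np.full(len(out), None, dtype=object)
    conf[keys == 3] = "guess"
    for c, k in _CONGRUENT_HIGH:
        conf[(cat == c) & (keys == k)] = "high"
    for c, k in _CONGRUENT_LOW:
        conf[(cat == c) & (keys == k)] = "low"
    out["confidence"] = conf

    intact = (out["type"] == "intact").to_numpy()
    dur = out["duration"].to_numpy()
    half = out["half"].to_numpy()

    dc = np.full(len(out), None, dtype=object)
    short = dur == DURATION_SHORT
    dc[intact & short & (conf == "guess")] = "33_guess"
    dc[intact & short & (conf == "low")] = "33_low"
    dc[intact & short & (conf == "high")] = "33_high"
    dc[intact & (dur == DURATION_LONG) & (conf == "high")] = "216_high"
    out["duration_confidence"] = dc

    dh = np.full(len(out), None, dtype=object)
    high = intact & (conf == "high")
    dh[high & short & (half == 1)] = "33_half1"
    dh[high & short & (half == 2)] = "33_half2"
    dh[high & (dur == DURATION_LONG) & (half == 2)] = "216_half2"
    out["duration_half"] = dh
    return out
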