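"""Trial-table behavioural metrics.

Implements the exclusion rules, choice repetition probability, absolute
history bias, accuracy/RT summaries and signal-detection metrics for
two-alternative forced-choice trial tables.  Repetition probability is the
side-bias-free mean of the two conditional repeat probabilities,

    P(repeat) = [ P(R_n = L | R_{n-1} = L) + P(R_n = R | R_{n-1} = R) ] / 2,

so an overall preference for one side does not masquerade as a sequential
effect.  All metrics are computed separately per participant and drug
condition by :func:`summarize`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "BehaviorSummary",
    "apply_exclusions",
    "repetition_probability",
    "absolute_bias",
    "sdt_metrics",
    "condition_on_feedback",
    "summarize",
    "group_summary",
]

_REQUIRED = [
    "participant_id", "session_id", "drug", "block", "trial_in_block",
    "stimulus_side", "strength", "choice", "rt", "prev_choice_available",
    "prev_choice",
]


@dataclass
class BehaviorSummary:
    participant_id: str
    drug: str
    strength: str | None
    p_repeat: float
    abs_bias: float
    accuracy: float
    mean_rt: float
    dprime: float
    criterion: float
    n_trials: int


def _check_schema(trials: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table lacks required columns: {missing}")


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop non-response trials and trials without an available previous choice.

    Excluded are (i) trials with no response within the deadline, (ii) the
    trial immediately after a non-response, (iii) the first trial of each
    block and (iv) the first trial after each mini-break.  Rules (ii)-(iv)
    are encoded in ``prev_choice_available`` (set by the generator or by an
    ingest annotator).  Returns the filtered table and an exclusion report.
    """
    _check_schema(trials)
    n = len(trials)
    responded = trials["choice"].notna() & trials["rt"].notna()
    available = trials["prev_choice_available"].astype(bool)
    keep = responded & available
    report = {
        "n_total": int(n),
        "n_no_response": int((~responded).sum()),
        "n_no_previous_choice": int((responded & ~available).sum()),
        "n_retained": int(keep.sum()),
        "fraction_excluded": float((n - keep.sum()) / n) if n else 0.0,
    }
    return trials[keep].copy(), report


def repetition_probability(trials: pd.DataFrame, on: str = "choice") -> float:
    """Side-bias-free repetition probability of choices (or stimulus sides).

    Averages P(left | previous left) and P(right | previous right).  Raises
    if either previous-side category is empty, because the average is then
    undefined rather than zero.
    """
    if on == "choice":
        cur = trials["choice"].to_numpy(dtype=float)
        prev = trials["prev_choice"].to_numpy(dtype=float)
    elif on == "stimulus":
        cur = trials["stimulus_side"].to_numpy(dtype=float)
        prev = (
            trials["prev_stimulus_side"].to_numpy(dtype=float)
            if "prev_stimulus_side" in trials.columns
            else _prev_stimulus(trials)
        )
    else:
        raise ValueError("on must be 'choice' or 'stimulus'")
    ok = np.isfinite(cur) & np.isfinite(prev) & (prev != 0)
    cur, prev = cur[ok], prev[ok]
    p = []
    for side in (-1.0, 1.0):
        sel = prev == side
        if not sel.any():
            raise ValueError(
                f"repetition probability undefined: no trials with previous side {int(side)}"
            )
        p.append(float(np.mean(cur[sel] == side)))
    return 0.5 * (p[0] + p[1])


def _prev_stimulus(trials: pd.DataFrame) -> np.ndarray:
    """Previous-trial stimulus side respecting block/session boundaries."""
    prev = np.full(len(trials), np.nan)
    sides = trials["stimulus_side"].to_numpy(dtype=float)
    grp = trials.groupby(["participant_id", "session_id", "block"], sort=False)
    pos = 0
    for _, idx in grp.indices.items():
        idx = np.sort(idx)
        prev[idx[1:]] = sides[idx[:-1]]
    return prev


def stimulus_repetition_probability(trials: pd.DataFrame) -> float:
    """Repetition probability of the stimulus sequence itself (design check)."""
    df = trials.copy().reset_index(drop=True)
    df["prev_stimulus_side"] = _prev_stimulus(df)
    keep = df["prev_choice_available"].astype(bool) & df["choice"].notna()
    return repetition_probability(df[keep], on="stimulus")


def absolute_bias(p_repeat: float) -> float:
    """Distance of the repetition probability from indifference, |P(repeat) - 0.5|."""
    if not 0.0 <= p_repeat <= 1.0:
        raise ValueError("p_repeat must lie in [0, 1]")
    return abs(p_repeat - 0.5)


def sdt_metrics(trials: pd.DataFrame) -> tuple[float, float]:
    """Signal-detection sensitivity and criterion.

    "Right"-signal trials are treated as signal: hit rate H = P(choice right |
    signal right), false-alarm rate F = P(choice right | signal left);
    d' = z(H) - z(F) and c = -(z(H) + z(F)) / 2.  Rates are clipped to
    [1/(2N), 1 - 1/(2N)] per class to keep the z-transform finite.
    """
    df = trials.dropna(subset=["choice"])
    rates = {}
    for side in (1, -1):
        sel = df["stimulus_side"] == side
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"no trials with stimulus side {side}")
        r = float((df.loc[sel, "choice"] == 1).mean())
        rates[side] = float(np.clip(r, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    zh, zf = norm.ppf(rates[1]), norm.ppf(rates[-1])
    return float(zh - zf), float(-(zh + zf) / 2.0)


def condition_on_feedback(trials: pd.DataFrame, prev_correct: bool) -> pd.DataFrame:
    """Trials whose previous available trial was correct (or incorrect)."""
    if "prev_correct" not in trials.columns:
        raise KeyError("trial table lacks a 'prev_correct' column")
    target = 1.0 if prev_correct else 0.0
    return trials[trials["prev_correct"] == target].copy()


def summarize(trials: pd.DataFrame, by_strength: bool = False) -> pd.DataFrame:
    """Tidy per-participant behaviour summary.

    One row per participant x drug (x strength when requested).  d' and
    criterion are computed per session and then averaged per drug, because
    sessions differ in stimulus-response mapping.  Repetition probability
    pools both strength levels unless ``by_strength``.
    """
    filtered, _ = apply_exclusions(trials)
    keys = ["participant_id", "drug"] + (["strength"] if by_strength else [])
    rows = []
    for key, sub in filtered.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        try:
            p_rep = repetition_probability(sub)
        except ValueError:
            p_rep = np.nan
        # per-session SDT, averaged
        dps, crs = [], []
        for _, ses in sub.groupby("session_id"):
            try:
                dp, cr = sdt_metrics(ses)
                dps.append(dp)
                crs.append(cr)
            except ValueError:
                pass
        rows.append(
            {
                "participant_id": key[0],
                "drug": key[1],
                "strength": key[2] if by_strength else None,
                "p_repeat": p_rep,
                "abs_bias": absolute_bias(p_rep) if np.isfinite(p_rep) else np.nan,
                "accuracy": float(sub["correct"].mean()),
                "mean_rt": float(sub["rt"].mean()),
                "dprime": float(np.mean(dps)) if dps else np.nan,
                "criterion": float(np.mean(crs)) if crs else np.nan,
                "n_trials": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def group_summary(summary: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Group mean and s.e.m. of one metric across participants per condition."""
    keys = [k for k in ("drug", "strength") if k in summary.columns and summary[k].notna().any()]
    out = (
        summary.groupby(keys, dropna=True)[metric]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return out
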