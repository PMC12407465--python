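"""Pupillometry and ECG preprocessing.

The pupil chain follows the standard four preprocessing steps: (i) linear
interpolation of missing data (blinks etc.) with a 150 ms pad on both sides,
(ii) zero-phase third-order Butterworth low-pass at 6 Hz, (iii) estimation of
blink- and saccade-locked artifact responses by FIR deconvolution and their
removal by multiple linear regression, and (iv) conversion to percent signal
change (PSC) around the session mean.  Downstream quantification: the
task-evoked pupil response (tpr) of a trial is the mean PSC 0-0.65 s after
the choice report minus the mean over the 0.25 s before trial onset;
block-wise pupil size is averaged on blink-interpolated raw units.  ECG
R-peaks are detected with an adaptive (running-percentile) threshold plus a
refractory period, and block-wise heart rate is peaks divided by time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.signal import butter, filtfilt, find_peaks

from histbias.synth import EcgTrace, PupilTrace

__all__ = [
    "CleanPupil",
    "IrfEstimate",
    "interpolate_missing",
    "lowpass",
    "estimate_event_irfs",
    "remove_event_responses",
    "to_psc",
    "preprocess",
    "task_evoked_response",
    "blockwise_pupil",
    "blockwise_heart_rate",
    "detect_rpeaks",
    "bin_trials_by_tpr",
]


@dataclass
class CleanPupil:
    """Fully preprocessed pupil series in percent signal change."""

    fs: float
    samples: np.ndarray
    provenance: list = field(default_factory=list)


@dataclass
class IrfEstimate:
    """Deconvolved event-locked impulse responses (one per event type)."""

    kernels: dict          # name -> sampled kernel
    fs: float
    window: float
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing steps
# ---------------------------------------------------------------------------

def interpolate_missing(trace: PupilTrace, pad: float = 0.150) -> PupilTrace:
    """Linearly interpolate missing samples, padded by ``pad`` seconds.

    Every run of NaNs is widened by the pad on both sides and replaced by
    the straight line (chord) between the surviving endpoints; edges are
    clamped to the nearest valid sample.
    """
    x = np.asarray(trace.samples, dtype=float).copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("trace is entirely missing")
    if not bad.any():
        return trace.copy_with(x)
    npad = int(round(pad * trace.fs))
    if npad > 0:
        # widen each missing run via binary dilation
        kernel = np.ones(2 * npad + 1, dtype=int)
        bad = np.convolve(bad.astype(int), kernel, mode="same") > 0
    idx = np.arange(len(x))
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return trace.copy_with(x)


def lowpass(trace: PupilTrace, order: int = 3, cutoff: float = 6.0) -> PupilTrace:
    """Zero-phase Butterworth low-pass (forward-backward, magnitude squared)."""
    if cutoff >= trace.fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({trace.fs / 2} Hz)")
    b, a = butter(order, cutoff, btype="low", fs=trace.fs)
    x = np.asarray(trace.samples, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("interpolate missing data before filtering")
    return trace.copy_with(filtfilt(b, a, x))


def _event_design(n: int, fs: float, events: dict, L: int) -> tuple:
    """Sparse FIR design matrix with L lags per event type."""
    cols = []
    names = []
    for name, times in events.items():
        t = np.asarray(times, dtype=float)
        t = t[np.isfinite(t)]
        rows_idx = []
        cols_idx = []
        for ti in t:
            i0 = int(round(ti * fs))
            lags = np.arange(L)
            valid = (i0 + lags >= 0) & (i0 + lags < n)
            rows_idx.append(i0 + lags[valid])
            cols_idx.append(lags[valid])
        if rows_idx:
            r = np.concatenate(rows_idx)
            c = np.concatenate(cols_idx)
        else:
            r = np.array([], dtype=int)
            c = np.array([], dtype=int)
        X = scipy.sparse.coo_matrix((np.ones(len(r)), (r, c)), shape=(n, L)).tocsr()
        cols.append(X)
        names.append(name)
    return scipy.sparse.hstack(cols).tocsr(), names


def estimate_event_irfs(
    trace: PupilTrace,
    events: dict | None = None,
    window: float = 6.0,
) -> IrfEstimate:
    """Jointly deconvolve event-locked impulse responses by least squares.

    ``events`` maps event-type name to anchor times (defaults: blink ends
    and saccade times from the trace annotations).  All event types are
    estimated in one FIR regression so overlapping responses are separated;
    a near-singular design falls back to a ridge-regularised solve and is
    flagged.
    """
    if events is None:
        events = {
            "blink": [e for _, e in trace.blink_intervals],
            "saccade": list(trace.saccade_times),
        }
    x = np.asarray(trace.samples, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("interpolate missing data before deconvolution")
    n = len(x)
    L = int(round(window * trace.fs))
    flags = []
    active = {k: v for k, v in events.items() if len(v) > 0}
    for k, v in events.items():
        if len(v) == 0:
            flags.append(f"no events of type '{k}': zero kernel returned")
        elif len(v) < 5:
            flags.append(f"only {len(v)} events of type '{k}'")
    kernels = {k: np.zeros(L) for k in events}
    if active:
        X, names = _event_design(n, trace.fs, active, L)
        X = scipy.sparse.hstack([scipy.sparse.csr_matrix(np.ones((n, 1))), X]).tocsr()
        XtX = (X.T @ X).toarray()
        Xty = X.T @ x
        try:
            beta = np.linalg.solve(XtX, Xty)
        except np.linalg.LinAlgError:
            beta = np.linalg.solve(XtX + 1e-6 * np.eye(XtX.shape[0]) * XtX.diagonal().mean(), Xty)
            flags.append("singular design: ridge-regularised solve used")
        beta = beta[1:]  # drop the intercept
        for j, name in enumerate(names):
            kernels[name] = beta[j * L: (j + 1) * L]
    return IrfEstimate(kernels=kernels, fs=trace.fs, window=window, flags=flags)


def remove_event_responses(
    trace: PupilTrace, irfs: IrfEstimate, events: dict | None = None
) -> PupilTrace:
    """Subtract fitted event-locked responses by multiple linear regression.

    Each kernel is convolved with its event train to form a regressor; the
    regressor amplitudes are refit jointly by OLS (with an intercept) and
    the fitted artifact components are subtracted from the trace.
    """
    if events is None:
        events = {
            "blink": [e for _, e in trace.blink_intervals],
            "saccade": list(trace.saccade_times),
        }
    x = np.asarray(trace.samples, dtype=float)
    n = len(x)
    regs = []
    for name, kernel in irfs.kernels.items():
        times = np.asarray(events.get(name, []), dtype=float)
        times = times[np.isfinite(times)]
        if times.size == 0 or not np.any(kernel):
            continue
        train = np.zeros(n)
        idx = np.round(times * trace.fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(train, idx, 1.0)
        reg = np.convolve(train, kernel)[:n]
        regs.append(reg)
    if not regs:
        return trace.copy_with(x)
    X = np.column_stack([np.ones(n)] + regs)
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    artifact = X[:, 1:] @ beta[1:]
    return trace.copy_with(x - artifact)


def to_psc(trace: PupilTrace) -> CleanPupil:
    """Percent signal change around the session mean: 100 (x - m) / m."""
    x = np.asarray(trace.samples, dtype=float)
    m = np.nanmean(x)
    if not m > 0:
        raise ValueError("session mean must be positive for PSC conversion")
    return CleanPupil(fs=trace.fs, samples=100.0 * (x - m) / m, provenance=["psc"])


def preprocess(trace: PupilTrace, window: float = 6.0) -> tuple[CleanPupil, IrfEstimate]:
    """Full chain: interpolate -> low-pass -> deconvolve/remove -> PSC."""
    interp = interpolate_missing(trace)
    filt = lowpass(interp)
    irfs = estimate_event_irfs(filt, window=window)
    cleaned = remove_event_responses(filt, irfs)
    psc = to_psc(cleaned)
    psc.provenance = ["interpolate", "lowpass", "deconvolve_remove", "psc"]
    return psc, irfs


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def task_evoked_response(
    clean: CleanPupil,
    choice_times: np.ndarray,
    trial_onsets: np.ndarray,
    response_window: tuple = (0.0, 0.65),
    baseline_window: float = 0.25,
) -> np.ndarray:
    """Per-trial task-evoked pupil response (PSC units).

    Mean over [choice, choice + 0.65 s] minus the mean over the 0.25 s
    preceding trial onset; trials whose windows exceed the trace are NaN.
    """
    x = np.asarray(clean.samples, dtype=float)
    n = len(x)
    fs = clean.fs
    tpr = np.full(len(choice_times), np.nan)
    for i, (ct, ot) in enumerate(zip(choice_times, trial_onsets)):
        if not (np.isfinite(ct) and np.isfinite(ot)):
            continue
        r0 = int(round((ct + response_window[0]) * fs))
        r1 = int(round((ct + response_window[1]) * fs))
        b0 = int(round((ot - baseline_window) * fs))
        b1 = int(round(ot * fs))
        if r0 < 0 or r1 > n or b0 < 0 or b1 > n or r1 <= r0 or b1 <= b0:
            continue
        tpr[i] = x[r0:r1].mean() - x[b0:b1].mean()
    return tpr


def blockwise_pupil(trace: PupilTrace) -> np.ndarray:
    """Per-block mean of the blink-interpolated pupil in raw units (pre-PSC)."""
    interp = interpolate_missing(trace)
    x = interp.samples
    out = []
    for (t0, t1) in trace.block_bounds:
        i0, i1 = int(t0 * trace.fs), int(t1 * trace.fs)
        out.append(float(np.mean(x[i0:i1])))
    return np.array(out)


def detect_rpeaks(
    ecg: EcgTrace,
    refractory: float = 0.25,
    percentile: float = 98.0,
    window_s: float = 10.0,
) -> np.ndarray:
    """Adaptive-threshold R-peak detection.

    The threshold at each sample is a fraction of the running
    ``percentile`` of |signal| over a ``window_s`` neighbourhood; peaks
    must clear it and be separated by the refractory period.
    """
    if ecg.fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    x = np.asarray(ecg.samples, dtype=float)
    n = len(x)
    w = int(window_s * ecg.fs)
    # coarse running percentile on strided segments, interpolated
    seg_starts = np.arange(0, n, w)
    seg_vals = np.array([np.percentile(np.abs(x[s: s + w]), percentile) for s in seg_starts])
    centers = seg_starts + w / 2.0
    thresh = np.interp(np.arange(n), centers, seg_vals)
    if np.all(thresh < 5 * np.std(x) / 50):  # essentially flat signal
        return np.array([])
    peaks, _ = find_peaks(x, height=0.5 * thresh, distance=int(refractory * ecg.fs))
    return peaks / ecg.fs


def blockwise_heart_rate(ecg: EcgTrace, peak_times: np.ndarray | None = None) -> np.ndarray:
    """Per-block heart rate in beats/min: detected R-peaks divided by time."""
    if peak_times is None:
        peak_times = detect_rpeaks(ecg)
    out = []
    for (t0, t1) in ecg.block_bounds:
        count = int(np.sum((peak_times >= t0) & (peak_times < t1)))
        out.append(60.0 * count / (t1 - t0))
    return np.array(out)


# ---------------------------------------------------------------------------
# pupil binning
# ---------------------------------------------------------------------------

def bin_trials_by_tpr(
    trials: pd.DataFrame,
    tpr_col: str = "tpr",
    n_bins: int = 8,
    metrics: tuple = ("repeat", "correct", "rt"),
) -> pd.DataFrame:
    """Equal-count quantile bins of the task-evoked pupil response per participant.

    Returns one row per participant x bin with the mean of each behavioural
    metric in the bin, the bin's mean tpr, and a demeaned bin index
    ``P`` suitable for mixed-model regression.
    """
    df = trials.dropna(subset=[tpr_col])
    rows = []
    for pid, sub in df.groupby("participant_id"):
        if n_bins > max(len(sub) // 10, 1):
            raise ValueError(
                f"n_bins={n_bins} too fine for {len(sub)} trials of {pid}"
            )
        ranks = sub[tpr_col].rank(method="first")
        bins = np.floor((ranks - 1) / len(sub) * n_bins).astype(int)
        for b in range(n_bins):
            sel = sub[bins == b]
            row = {
                "participant_id": pid,
                "bin": b,
                "P": b - (n_bins - 1) / 2.0,
                "tpr": float(sel[tpr_col].mean()),
                "n_trials": int(len(sel)),
            }
            for m in metrics:
                if m in sel.columns:
                    row[m] = float(sel[m].mean())
            rows.append(row)
    return pd.DataFrame(rows)
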