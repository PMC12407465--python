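"""Synthetic cohort generator with known ground truth.

Emulates the study conditions of a within-subject pharmacology experiment on
choice history bias: each participant completes four sessions crossing drug
(placebo vs. atomoxetine, a noradrenaline reuptake inhibitor) with
stimulus-response mapping; sessions consist of 160-trial blocks with
mini-breaks every 40 trials and exact 50/50 left/right signal
counterbalancing within each block; choices and response times come from a
diffusion observer whose starting point and drift bias depend on the
previous choice.  The active drug shrinks the history shift of the drift
bias (configurable to the starting point instead, for falsification tests),
elevates pupil size and heart rate, and single-trial decision-related pupil
dilations couple negatively to the tendency to repeat.  Pupil traces carry
blink/saccade artifacts; ECG traces carry ground-truth R-peak times.

Everything is deterministic given one global seed, which fans out to
per-participant and per-session child seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from histbias.ddm import DDMParams

__all__ = [
    "TaskDesign",
    "WeibullPsychometric",
    "ObserverSpec",
    "CohortSpec",
    "PupilTrace",
    "EcgTrace",
    "CohortDataset",
    "pupil_irf",
    "generate_trial_sequence",
    "simulate_observer",
    "simulate_first_passages",
    "run_quest_staircase",
    "simulate_fixed_block",
    "synthesize_pupil",
    "synthesize_ecg",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TaskDesign:
    """Block and timing structure of the two-alternative contrast task."""

    trials_per_block: int = 160
    minibreak_every: int = 40
    n_blocks_per_session: int = 6
    iti_range: tuple = (0.6, 1.4)
    max_rt: float = 3.0
    feedback_delay: float = 0.050
    feedback_range: tuple = (0.25, 1.4)
    n_strength_levels: int = 2
    minibreak_duration: float = 10.0

    def validate(self) -> None:
        if self.trials_per_block <= 0 or self.minibreak_every <= 0:
            raise ValueError("block structure counts must be positive")
        if self.trials_per_block % self.minibreak_every != 0:
            raise ValueError(
                f"trials_per_block ({self.trials_per_block}) must be divisible "
                f"by minibreak_every ({self.minibreak_every})"
            )
        if self.trials_per_block % 2 != 0:
            raise ValueError("trials_per_block must be even for 50/50 counterbalancing")
        if not self.iti_range[0] < self.iti_range[1]:
            raise ValueError("iti_range must satisfy low < high")
        if self.max_rt <= 0:
            raise ValueError("max_rt must be positive")


@dataclass
class WeibullPsychometric:
    """2AFC Weibull psychometric function.

    P(correct | x) = guess + (1 - guess - lapse) * (1 - exp(-(x/threshold)^slope))
    """

    threshold: float = 0.1
    slope: float = 3.5
    lapse: float = 0.01
    guess: float = 0.5

    def validate(self) -> None:
        if self.threshold <= 0 or self.slope <= 0:
            raise ValueError("threshold and slope must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")

    def p_correct(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.guess + (1.0 - self.guess - self.lapse) * (
            1.0 - np.exp(-((np.maximum(x, 0.0) / self.threshold) ** self.slope))
        )

    def level_for(self, target_p: float) -> float:
        """Invert the psychometric function analytically."""
        q = (target_p - self.guess) / (1.0 - self.guess - self.lapse)
        if not 0.0 < q < 1.0:
            raise ValueError(f"target accuracy {target_p} not attainable")
        return self.threshold * (-np.log1p(-q)) ** (1.0 / self.slope)


@dataclass
class ObserverSpec:
    """Ground truth for one synthetic participant.

    ``ddm_placebo`` are the diffusion parameters under placebo; under the
    drug, the history shift of the modulated bias parameter is multiplied by
    ``(1 - drug_bias_shrinkage)``.  ``pupil_coupling`` is subtracted from the
    decision-related dilation amplitude on repeat trials, planting a
    negative pupil-repetition association.
    """

    ddm_placebo: DDMParams = field(default_factory=DDMParams)
    drug_bias_shrinkage: float = 0.5
    drug_modulates: str = "vbias"  # or "z"
    psychometric: WeibullPsychometric = field(default_factory=WeibullPsychometric)
    pupil_coupling: float = 1.5
    drug_pupil_offset: float = 120.0
    drug_hr_offset: float = 5.0
    mean_hr: float = 65.0
    pupil_mean: float = 1200.0
    blink_rate: float = 3.0 / 60.0
    saccade_rate: float = 10.0 / 60.0
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.drug_bias_shrinkage <= 1.0:
            raise ValueError("drug_bias_shrinkage must lie in [0, 1]")
        if self.drug_modulates not in ("vbias", "z"):
            raise ValueError("drug_modulates must be 'vbias' or 'z'")
        self.ddm_placebo.validate()
        self.psychometric.validate()

    def ddm_truth(self, drug: str) -> DDMParams:
        """Diffusion parameters for one drug condition."""
        self.validate()
        if drug == "placebo":
            return self.ddm_placebo
        if drug != "atomoxetine":
            raise ValueError(f"unknown drug condition {drug!r}")
        p = dataclasses.replace(self.ddm_placebo)
        keep = 1.0 - self.drug_bias_shrinkage
        if self.drug_modulates == "vbias":
            mean = 0.5 * (p.vbias_prev_left + p.vbias_prev_right)
            half = 0.5 * (p.vbias_prev_right - p.vbias_prev_left) * keep
            p.vbias_prev_left, p.vbias_prev_right = mean - half, mean + half
        else:
            mean = 0.5 * (p.z_prev_left + p.z_prev_right)
            half = 0.5 * (p.z_prev_right - p.z_prev_left) * keep
            p.z_prev_left, p.z_prev_right = mean - half, mean + half
        return p


@dataclass
class CohortSpec:
    """Population distributions from which per-participant ground truth is drawn.

    Defaults produce mostly repetition-favouring drift-bias history shifts
    with a minority of alternators (roughly a 4:1 split), starting points
    weakly repelled from the previous choice, and accuracies near 74%/81%
    for the weak/strong signal at the default boundary separation.
    """

    a_mean: float = 1.4
    a_sd: float = 0.12
    v_weak_mean: float = 0.75
    v_weak_sd: float = 0.12
    v_strong_mean: float = 1.05
    v_strong_sd: float = 0.15
    t0_mean: float = 0.30
    t0_sd: float = 0.03
    z_shift_mean: float = -0.03
    z_shift_sd: float = 0.03
    vbias_shift_mean: float = 0.30
    vbias_shift_sd: float = 0.35
    vbias_mean_sd: float = 0.08
    drug_bias_shrinkage: float = 0.5
    drug_modulates: str = "vbias"
    pupil_coupling: float = 1.5
    drug_pupil_offset_mean: float = 120.0
    drug_pupil_offset_sd: float = 60.0
    drug_hr_offset_mean: float = 5.0
    drug_hr_offset_sd: float = 2.0

    def draw_observer(self, rng: np.random.Generator, seed: int) -> ObserverSpec:
        z_shift = rng.normal(self.z_shift_mean, self.z_shift_sd)
        z_shift = float(np.clip(z_shift, -0.3, 0.3))
        vb_shift = rng.normal(self.vbias_shift_mean, self.vbias_shift_sd)
        vb_mean = rng.normal(0.0, self.vbias_mean_sd)
        params = DDMParams(
            a=float(np.clip(rng.normal(self.a_mean, self.a_sd), 0.8, 3.0)),
            v_weak=float(np.clip(rng.normal(self.v_weak_mean, self.v_weak_sd), 0.2, 3.0)),
            v_strong=float(np.clip(rng.normal(self.v_strong_mean, self.v_strong_sd), 0.3, 4.0)),
            t0=float(np.clip(rng.normal(self.t0_mean, self.t0_sd), 0.15, 0.5)),
            z_prev_left=0.5 - z_shift / 2.0,
            z_prev_right=0.5 + z_shift / 2.0,
            vbias_prev_left=vb_mean - vb_shift / 2.0,
            vbias_prev_right=vb_mean + vb_shift / 2.0,
        )
        return ObserverSpec(
            ddm_placebo=params,
            drug_bias_shrinkage=self.drug_bias_shrinkage,
            drug_modulates=self.drug_modulates,
            pupil_coupling=self.pupil_coupling,
            drug_pupil_offset=float(rng.normal(self.drug_pupil_offset_mean, self.drug_pupil_offset_sd)),
            drug_hr_offset=float(rng.normal(self.drug_hr_offset_mean, self.drug_hr_offset_sd)),
            mean_hr=float(rng.normal(65.0, 5.0)),
            pupil_mean=float(rng.normal(1200.0, 150.0)),
            rng_seed=seed,
        )


@dataclass
class PupilTrace:
    """Sampled pupil time series with artifact and task-event annotations.

    ``samples`` are NaN inside blink intervals and finite elsewhere; all
    event times are seconds from trace start.
    """

    fs: float
    samples: np.ndarray
    blink_intervals: list
    saccade_times: list
    trial_onsets: np.ndarray
    choice_times: np.ndarray
    feedback_times: np.ndarray
    block_bounds: list = field(default_factory=list)  # (start, end) seconds per block

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def copy_with(self, samples: np.ndarray) -> "PupilTrace":
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float))

    def to_csv(self, path: str | Path) -> None:
        """Write (time, value) CSV plus a JSON sidecar with events and fs.

        Missing (blink) samples become empty fields; the sidecar at
        ``<path>.events.json`` carries everything needed to reconstruct the
        annotations.
        """
        path = Path(path)
        t = np.arange(len(self.samples)) / self.fs
        pd.DataFrame({"time": t, "value": self.samples}).to_csv(path, index=False)
        sidecar = {
            "fs": self.fs,
            "blink_intervals": [list(b) for b in self.blink_intervals],
            "saccade_times": list(self.saccade_times),
            "trial_onsets": np.asarray(self.trial_onsets, dtype=float).tolist(),
            "choice_times": np.asarray(self.choice_times, dtype=float).tolist(),
            "feedback_times": np.asarray(self.feedback_times, dtype=float).tolist(),
            "block_bounds": [list(b) for b in self.block_bounds],
        }
        with open(path.with_suffix(path.suffix + ".events.json"), "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PupilTrace":
        path = Path(path)
        df = pd.read_csv(path)
        with open(path.with_suffix(path.suffix + ".events.json")) as fh:
            sc = json.load(fh)
        return cls(
            fs=float(sc["fs"]),
            samples=df["value"].to_numpy(dtype=float),
            blink_intervals=[tuple(b) for b in sc["blink_intervals"]],
            saccade_times=list(sc["saccade_times"]),
            trial_onsets=np.asarray(sc["trial_onsets"], dtype=float),
            choice_times=np.asarray(sc["choice_times"], dtype=float),
            feedback_times=np.asarray(sc["feedback_times"], dtype=float),
            block_bounds=[tuple(b) for b in sc["block_bounds"]],
        )


@dataclass
class EcgTrace:
    fs: float
    samples: np.ndarray
    true_rpeak_times: np.ndarray
    block_bounds: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


# ---------------------------------------------------------------------------
# trial sequences
# ---------------------------------------------------------------------------

def generate_trial_sequence(
    design: TaskDesign,
    n_blocks: int,
    seed: int,
    participant_id: str = "p00",
    session_id: int = 1,
    drug: str = "placebo",
    mapping: str = "ipsi",
) -> pd.DataFrame:
    """Stimulus side, strength and timing scaffold for ``n_blocks`` blocks.

    Within every block exactly half the trials carry the signal on the right,
    in random order; signal strength is randomised 50/50 independently.
    Response-dependent fields (choice, rt, event times) are left missing.
    """
    design.validate()
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    npb = design.trials_per_block
    rows = []
    for b in range(n_blocks):
        sides = np.repeat([-1, 1], npb // 2)
        rng.shuffle(sides)
        strengths = rng.choice(["weak", "strong"], size=npb)
        itis = rng.uniform(*design.iti_range, size=npb)
        first_after_break = np.zeros(npb, dtype=bool)
        first_after_break[:: design.minibreak_every] = True
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "session_id": session_id,
                    "drug": drug,
                    "mapping": mapping,
                    "block": b,
                    "trial_in_block": np.arange(npb),
                    "stimulus_side": sides.astype(int),
                    "strength": strengths,
                    "iti": itis,
                    "prev_choice_available": ~first_after_break,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    for col in ("choice", "rt", "correct", "prev_choice", "prev_correct",
                "onset_time", "choice_time", "feedback_time", "repeat"):
        df[col] = np.nan
    return df


# ---------------------------------------------------------------------------
# diffusion simulation
# ---------------------------------------------------------------------------

def simulate_first_passages(
    a: float,
    z: float,
    mu: float,
    n: int,
    dt: float = 0.001,
    max_t: float = 10.0,
    seed: int | np.random.Generator = 0,
    c: float = 1.0,
    bridge: bool = True,
) -> tuple:
    """Euler-Maruyama first-passage simulation for ``n`` independent paths.

    Returns (choices, first_passage_times); choice +1 for the upper bound,
    -1 for the lower, 0 with time NaN for paths still unabsorbed at
    ``max_t``.  With ``bridge=True`` a diffusion-bridge crossing probability
    is applied within each step, removing the leading discretisation bias of
    the plain scheme.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(np.ceil(max_t / dt))
    x = np.full(n, z * a, dtype=float)
    alive = np.arange(n)
    choices = np.zeros(n, dtype=int)
    fpt = np.full(n, np.nan)
    sq = c * np.sqrt(dt)
    for step in range(n_steps):
        m = alive.size
        if m == 0:
            break
        x_old = x[alive]
        x_new = x_old + mu * dt + sq * rng.standard_normal(m)
        t_now = (step + 1) * dt
        hit_up = x_new >= a
        hit_lo = (~hit_up) & (x_new <= 0.0)
        if bridge:
            interior = ~(hit_up | hit_lo)
            if interior.any():
                xo, xn = x_old[interior], x_new[interior]
                with np.errstate(over="ignore"):
                    p_up = np.exp(-2.0 * (a - xo) * (a - xn) / (c**2 * dt))
                    p_lo = np.exp(-2.0 * xo * xn / (c**2 * dt))
                u = rng.random(xo.size)
                b_up = u < p_up
                b_lo = (~b_up) & (u < p_up + p_lo)
                idx = np.flatnonzero(interior)
                hit_up[idx[b_up]] = True
                hit_lo[idx[b_lo]] = True
        done = hit_up | hit_lo
        if done.any():
            gids = alive[done]
            choices[gids] = np.where(hit_up[done], 1, -1)
            fpt[gids] = t_now
            alive = alive[~done]
            x[alive] = x_new[~done]
        else:
            x[alive] = x_new
    return choices, fpt


def _fp_single(rng, a, z, mu, dt, n_steps, c=1.0, bridge=True, chunk=768):
    """First passage of one path; returns (choice, time) with choice 0 on timeout."""
    x0 = z * a
    sq = c * np.sqrt(dt)
    step0 = 0
    while step0 < n_steps:
        m = min(chunk, n_steps - step0)
        inc = mu * dt + sq * rng.standard_normal(m)
        x = x0 + np.cumsum(inc)
        xprev = np.concatenate(([x0], x[:-1]))
        hit_up = x >= a
        hit_lo = x <= 0.0
        hit = hit_up | hit_lo
        if bridge:
            interior = ~hit
            with np.errstate(over="ignore"):
                p_up = np.where(interior, np.exp(-2.0 * np.maximum(a - xprev, 0) * np.maximum(a - x, 0) / (c**2 * dt)), 0.0)
                p_lo = np.where(interior, np.exp(-2.0 * np.maximum(xprev, 0) * np.maximum(x, 0) / (c**2 * dt)), 0.0)
            u = rng.random(m)
            b_up = interior & (u < p_up)
            b_lo = interior & (~b_up) & (u < p_up + p_lo)
            hit_up = hit_up | b_up
            hit_lo = hit_lo | b_lo
            hit = hit_up | hit_lo
        if hit.any():
            k = int(np.argmax(hit))
            t = (step0 + k + 1) * dt
            return (1 if hit_up[k] else -1), t
        x0 = x[-1]
        step0 += m
    return 0, np.nan


def simulate_observer(
    trials: pd.DataFrame,
    spec: ObserverSpec,
    dt: float = 0.001,
    seed: int | None = None,
) -> pd.DataFrame:
    """Complete a trial table with diffusion-observer choices and RTs.

    Integrates dy = (s*v + v_bias) dt + c dW from y(0) = z*a until a bound
    or the response deadline; the starting point and drift bias on each
    trial are selected by the most recent available choice (neutral means
    when none is available).  Also fills event times (trial onset, choice,
    feedback) used by the physiology synthesis.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.002:
        raise ValueError("dt must be <= 2 ms for acceptable discretisation error")
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    df = trials.copy().reset_index(drop=True)
    design = TaskDesign()  # timing constants for feedback/ITI bookkeeping

    out_choice = np.full(len(df), np.nan)
    out_rt = np.full(len(df), np.nan)
    out_prev = np.zeros(len(df))
    out_onset = np.full(len(df), np.nan)
    out_choice_t = np.full(len(df), np.nan)
    out_feedback_t = np.full(len(df), np.nan)
    avail = df["prev_choice_available"].to_numpy().copy()

    params_by_drug = {d: spec.ddm_truth(d) for d in df["drug"].unique()}

    for (pid, ses), idx in df.groupby(["participant_id", "session_id"], sort=True).groups.items():
        idx = np.asarray(idx)
        sub = df.loc[idx]
        p = params_by_drug[sub["drug"].iloc[0]]
        n_steps = int(np.ceil(max(design.max_rt - p.t0, dt) / dt))
        clock = 0.0
        last_block = None
        last_choice = np.nan
        for j, i in enumerate(idx):
            row = sub.iloc[j]
            if row["block"] != last_block:
                last_block = row["block"]
                last_choice = np.nan
            structural = bool(avail[i])
            usable = structural and np.isfinite(last_choice)
            avail[i] = usable
            prev = int(last_choice) if usable else 0
            out_prev[i] = prev

            if row["trial_in_block"] > 0 and row["trial_in_block"] % design.minibreak_every == 0:
                clock += design.minibreak_duration
            clock += row["iti"]
            out_onset[i] = clock

            mu = p.effective_drift(int(row["stimulus_side"]), row["strength"], prev)
            choice, fpt = _fp_single(rng, p.a, p.z(prev), mu, dt, n_steps)
            rt = fpt + p.t0 if choice != 0 else np.nan
            if choice != 0 and rt <= design.max_rt:
                out_choice[i] = choice
                out_rt[i] = rt
                out_choice_t[i] = clock + rt
                out_feedback_t[i] = clock + rt + design.feedback_delay
                clock += rt + design.feedback_delay + rng.uniform(*design.feedback_range)
                last_choice = choice
            else:  # no response within the deadline
                out_choice_t[i] = clock + design.max_rt
                clock += design.max_rt + rng.uniform(*design.feedback_range)
                last_choice = np.nan

    df["choice"] = out_choice
    df["rt"] = out_rt
    df["correct"] = np.where(np.isnan(out_choice), np.nan,
                             (out_choice == df["stimulus_side"]).astype(float))
    df["prev_choice"] = out_prev.astype(int)
    df["prev_choice_available"] = avail.astype(bool)
    df["onset_time"] = out_onset
    df["choice_time"] = out_choice_t
    df["feedback_time"] = out_feedback_t
    df["repeat"] = np.where(
        df["prev_choice_available"] & np.isfinite(df["choice"]),
        (df["choice"] == df["prev_choice"]).astype(float), np.nan,
    )
    # repeat indicator of the following trial, aligned to the current one
    df["repeat_next"] = df.groupby(["participant_id", "session_id"])["repeat"].shift(-1)
    # previous-trial feedback context (for the available previous trial)
    prev_correct = np.full(len(df), np.nan)
    correct = df["correct"].to_numpy()
    for (pid, ses, b), idx in df.groupby(["participant_id", "session_id", "block"], sort=True).groups.items():
        idx = np.asarray(idx)
        last_corr = np.nan
        for i in idx:
            if df.at[i, "prev_choice_available"]:
                prev_correct[i] = last_corr
            if np.isfinite(correct[i]):
                last_corr = correct[i]
            else:
                last_corr = np.nan
    df["prev_correct"] = prev_correct
    return df


# ---------------------------------------------------------------------------
# Quest staircase
# ---------------------------------------------------------------------------

def run_quest_staircase(
    psychometric: WeibullPsychometric,
    target_p: float,
    n_trials: int = 200,
    seed: int = 0,
    prior_center: float = 0.15,
    prior_sd_log10: float = 1.0,
) -> float:
    """Bayesian adaptive staircase targeting a given percent correct.

    Maintains a grid posterior over the Weibull threshold (log10 units,
    slope/lapse/guess assumed known), places every trial at the
    information-optimal ("sweet point") intensity under the current
    posterior-mean threshold, and updates with the simulated observer's
    Bernoulli response.  Returns the level that yields ``target_p`` under
    the converged threshold estimate (contrast difference).
    """
    if not 0.5 < target_p < 1.0:
        raise ValueError("target_p must lie in (0.5, 1)")
    if n_trials < 40:
        raise ValueError("n_trials must be >= 40 for convergence")
    psychometric.validate()
    rng = np.random.default_rng(seed)

    log_grid = np.linspace(np.log10(prior_center) - 1.5, np.log10(prior_center) + 1.5, 400)
    thresholds = 10.0 ** log_grid
    log_post = -0.5 * ((log_grid - np.log10(prior_center)) / prior_sd_log10) ** 2

    assumed = dataclasses.replace(psychometric)
    q = (target_p - assumed.guess) / (1.0 - assumed.guess - assumed.lapse)
    level_scale = (-np.log1p(-q)) ** (1.0 / assumed.slope)

    # placement maximising Fisher information about the log threshold:
    # I(u) = (u p'(u))^2 / (p (1 - p)) on the threshold-relative intensity u
    u_grid = np.linspace(0.2, 3.0, 561)
    p_u = assumed.guess + (1.0 - assumed.guess - assumed.lapse) * (
        1.0 - np.exp(-(u_grid**assumed.slope))
    )
    dp_u = np.gradient(p_u, u_grid)
    p_safe = np.clip(p_u, 1e-9, 1.0 - 1e-9)
    info = (u_grid * dp_u) ** 2 / (p_safe * (1.0 - p_safe))
    u_opt = float(u_grid[np.argmax(info)])

    for _ in range(n_trials):
        post = np.exp(log_post - log_post.max())
        t_hat = 10.0 ** float(np.sum(log_grid * post) / np.sum(post))
        x = t_hat * u_opt
        p_true = float(psychometric.p_correct(x))
        correct = rng.random() < p_true
        p_grid = assumed.guess + (1.0 - assumed.guess - assumed.lapse) * (
            1.0 - np.exp(-((x / thresholds) ** assumed.slope))
        )
        p_grid = np.clip(p_grid, 1e-6, 1.0 - 1e-6)
        log_post += np.log(p_grid if correct else 1.0 - p_grid)

    post = np.exp(log_post - log_post.max())
    t_hat = 10.0 ** float(np.sum(log_grid * post) / np.sum(post))
    return float(t_hat * level_scale)


def simulate_fixed_block(
    psychometric: WeibullPsychometric, level: float, n_trials: int, seed: int = 0
) -> float:
    """Accuracy of the simulated observer over fixed trials at one level."""
    rng = np.random.default_rng(seed)
    p = float(psychometric.p_correct(level))
    return float(np.mean(rng.random(n_trials) < p))


# ---------------------------------------------------------------------------
# physiology synthesis
# ---------------------------------------------------------------------------

def pupil_irf(t, shape: float = 10.1, t_max: float = 0.93) -> np.ndarray:
    """Canonical gamma-family pupil impulse response, peak-normalised to 1."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (t[pos] ** shape) * np.exp(-shape * t[pos] / t_max)
    peak = (t_max**shape) * np.exp(-shape)
    return out / peak


def default_blink_kernel(t) -> np.ndarray:
    """Biphasic artifact response following a blink (percent-of-mean units)."""
    return -0.8 * pupil_irf(t, shape=3.0, t_max=0.4) + 0.5 * pupil_irf(t, shape=6.0, t_max=1.8)


def default_saccade_kernel(t) -> np.ndarray:
    return -0.3 * pupil_irf(t, shape=4.0, t_max=0.6) + 0.15 * pupil_irf(t, shape=7.0, t_max=2.2)


def _add_kernel(samples, fs, times, amps, kernel_samples):
    """Add ``amps[i] * kernel`` starting at ``times[i]`` into ``samples`` in place."""
    L = len(kernel_samples)
    n = len(samples)
    for t, a in zip(np.atleast_1d(times), np.atleast_1d(amps)):
        if not np.isfinite(t):
            continue
        i0 = int(round(t * fs))
        if i0 >= n:
            continue
        i1 = min(i0 + L, n)
        samples[i0:i1] += a * kernel_samples[: i1 - i0]


def synthesize_pupil(
    trials: pd.DataFrame,
    spec: ObserverSpec,
    fs: float = 100.0,
    seed: int = 0,
    dilation_base: float = 10.0,
    dilation_noise_sd: float = 3.0,
    constriction_amp: float = -5.0,
    feedback_amp: float = 6.0,
    blink_kernel=default_blink_kernel,
    saccade_kernel=default_saccade_kernel,
    blink_rate: float | None = None,
    kernel_window: float = 6.0,
    decision_lead: float = 0.5,
) -> PupilTrace:
    """Session pupil trace: task-locked components, artifacts, blinks.

    The decision-related dilation amplitude on each completed trial is
    ``dilation_base - pupil_coupling * repeat + noise``, so a positive
    ``pupil_coupling`` plants smaller dilations on repeat trials.  Its
    driving input starts ``decision_lead`` seconds before the button press
    (the decision forms before the report), so the response peaks shortly
    after the choice and the feedback-locked dilation follows roughly half a
    second later.  Blink and
    saccade artifact responses (kernels anchored at blink end / saccade
    time) are superimposed for the deconvolution round-trip, and samples
    inside blinks are dropped (NaN).  Atomoxetine sessions are offset by
    ``drug_pupil_offset`` raw units.
    """
    if fs < 20:
        raise ValueError("fs must be >= 20 Hz")
    spec.validate()
    if trials["participant_id"].nunique() > 1 or trials["session_id"].nunique() > 1:
        raise ValueError("synthesize_pupil expects a single session")
    rng = np.random.default_rng(seed)
    df = trials
    dur = float(np.nanmax(df["choice_time"].to_numpy())) + 5.0
    n = int(round(dur * fs))
    kt = np.arange(int(kernel_window * fs)) / fs
    k_dil = pupil_irf(kt)

    base = spec.pupil_mean + (spec.drug_pupil_offset if df["drug"].iloc[0] == "atomoxetine" else 0.0)
    # slow arousal drift: heavily smoothed white noise
    slow = np.convolve(rng.standard_normal(n), np.ones(int(20 * fs)) / np.sqrt(20 * fs), mode="same")
    samples = base + 8.0 * slow + 1.0 * rng.standard_normal(n)

    onsets = df["onset_time"].to_numpy()
    choices_t = df["choice_time"].to_numpy()
    feedback_t = df["feedback_time"].to_numpy()
    repeat = np.nan_to_num(df["repeat"].to_numpy(), nan=0.0)
    completed = np.isfinite(df["rt"].to_numpy())

    _add_kernel(samples, fs, onsets, np.full(len(df), constriction_amp), k_dil)
    dil_amp = dilation_base - spec.pupil_coupling * repeat + rng.normal(0, dilation_noise_sd, len(df))
    dil_times = np.maximum(choices_t - decision_lead, onsets)
    _add_kernel(samples, fs, np.where(completed, dil_times, np.nan), dil_amp, k_dil)
    _add_kernel(samples, fs, feedback_t, np.full(len(df), feedback_amp), k_dil)

    # artifacts
    rate = spec.blink_rate if blink_rate is None else blink_rate
    n_blinks = rng.poisson(rate * dur)
    blink_starts = np.sort(rng.uniform(1.0, max(dur - kernel_window - 1.0, 2.0), n_blinks))
    # enforce minimal separation so dropout intervals do not merge
    blink_starts = blink_starts[np.diff(blink_starts, prepend=-10.0) > 1.0]
    blink_durs = rng.uniform(0.1, 0.3, len(blink_starts))
    blink_intervals = [(float(s), float(s + d)) for s, d in zip(blink_starts, blink_durs)]
    n_sacc = rng.poisson(spec.saccade_rate * dur)
    saccade_times = np.sort(rng.uniform(1.0, max(dur - kernel_window - 1.0, 2.0), n_sacc))

    kb = blink_kernel(kt)
    ks = saccade_kernel(kt)
    blink_ends = np.array([e for _, e in blink_intervals])
    scale = base / 100.0  # artifact kernels are in percent-of-mean units
    _add_kernel(samples, fs, blink_ends, np.full(len(blink_ends), scale), kb)
    _add_kernel(samples, fs, saccade_times, np.full(len(saccade_times), scale), ks)

    for s, e in blink_intervals:
        samples[int(s * fs): int(e * fs) + 1] = np.nan

    # block bounds from trial events
    block_bounds = []
    for b, sub in df.groupby("block"):
        t0 = float(sub["onset_time"].min()) - 0.5
        t1 = float(np.nanmax(sub[["choice_time", "feedback_time"]].to_numpy())) + 1.0
        block_bounds.append((max(t0, 0.0), min(t1, dur)))

    return PupilTrace(
        fs=fs,
        samples=samples,
        blink_intervals=blink_intervals,
        saccade_times=[float(t) for t in saccade_times],
        trial_onsets=onsets,
        choice_times=choices_t,
        feedback_times=feedback_t,
        block_bounds=block_bounds,
    )


def synthesize_ecg(
    duration: float,
    mean_hr: float,
    spec: ObserverSpec | None = None,
    fs: float = 250.0,
    seed: int = 0,
    ibi_jitter_sd: float = 0.04,
    noise_sd: float = 0.05,
    drug: str = "placebo",
    block_bounds: list | None = None,
) -> EcgTrace:
    """Quasi-periodic R-peak train with jitter and additive noise.

    Atomoxetine adds ``drug_hr_offset`` beats/min.  True R-peak times are
    stored as ground truth for detector validation.
    """
    if not 40.0 <= mean_hr <= 120.0:
        raise ValueError("mean_hr must lie in [40, 120] bpm")
    rng = np.random.default_rng(seed)
    hr = mean_hr + (spec.drug_hr_offset if (spec is not None and drug == "atomoxetine") else 0.0)
    mean_ibi = 60.0 / hr
    n_beats = int(duration / mean_ibi * 1.3) + 10
    ibis = np.clip(rng.normal(mean_ibi, ibi_jitter_sd, n_beats), 0.4, 1.5)
    peaks = np.cumsum(ibis)
    peaks = peaks[peaks < duration - 0.05]
    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    samples = noise_sd * rng.standard_normal(n)
    width = 0.012
    for p in peaks:
        i0 = max(int((p - 5 * width) * fs), 0)
        i1 = min(int((p + 5 * width) * fs), n)
        samples[i0:i1] += np.exp(-0.5 * ((tt[i0:i1] - p) / width) ** 2)
    return EcgTrace(fs=fs, samples=samples, true_rpeak_times=peaks,
                    block_bounds=block_bounds or [])


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """Synthetic cohort: trial tables, per-participant ground truth, design.

    Physiological traces are generated lazily per session (deterministic in
    the cohort seed) to keep memory bounded.
    """

    trials: pd.DataFrame
    specs: dict
    design: TaskDesign
    seed: int

    @property
    def ground_truth(self) -> dict:
        ledger = {}
        for pid, spec in self.specs.items():
            ledger[pid] = {
                "ddm_placebo": spec.ddm_placebo.to_dict(),
                "ddm_atomoxetine": spec.ddm_truth("atomoxetine").to_dict(),
                "drug_bias_shrinkage": spec.drug_bias_shrinkage,
                "drug_modulates": spec.drug_modulates,
                "pupil_coupling": spec.pupil_coupling,
                "drug_pupil_offset": spec.drug_pupil_offset,
                "drug_hr_offset": spec.drug_hr_offset,
            }
        return ledger

    def session_physio(self, participant_id: str, session_id: int,
                       fs_pupil: float = 100.0, fs_ecg: float = 250.0) -> tuple:
        """Deterministically synthesize (PupilTrace, EcgTrace) for one session."""
        spec = self.specs[participant_id]
        sub = self.trials[(self.trials["participant_id"] == participant_id)
                          & (self.trials["session_id"] == session_id)]
        if sub.empty:
            raise KeyError(f"no trials for {participant_id} session {session_id}")
        child = int(np.random.SeedSequence(
            [self.seed, int(participant_id[1:]), session_id, 7]).generate_state(1)[0] % (2**31))
        pupil = synthesize_pupil(sub, spec, fs=fs_pupil, seed=child)
        ecg = synthesize_ecg(pupil.duration, spec.mean_hr, spec, fs=fs_ecg,
                             seed=child + 1, drug=sub["drug"].iloc[0],
                             block_bounds=pupil.block_bounds)
        return pupil, ecg

    # -- serialisation -----------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(path / "trials.csv", index=False)
        with open(path / "ground_truth.json", "w") as fh:
            json.dump({"seed": self.seed, "design": dataclasses.asdict(self.design),
                       "participants": self.ground_truth}, fh, indent=1)

    @staticmethod
    def load_trials(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(Path(path) / "trials.csv")


def generate_cohort(
    n_participants: int = 19,
    design: TaskDesign | None = None,
    spec_distribution: CohortSpec | None = None,
    seed: int = 0,
    dt: float = 0.001,
) -> CohortDataset:
    """Generate a full synthetic cohort with known ground truth.

    Each participant completes 4 sessions crossing drug (placebo vs.
    atomoxetine) with stimulus-response mapping, in randomised session
    order.  Per-participant diffusion and physiology parameters are drawn
    from ``spec_distribution``; one global seed fans out to child seeds for
    every participant and session.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    design = design or TaskDesign()
    design.validate()
    dist = spec_distribution or CohortSpec()
    root = np.random.SeedSequence(seed)
    part_seeds = root.spawn(n_participants)

    all_trials = []
    specs = {}
    conditions = [("placebo", "ipsi"), ("placebo", "contra"),
                  ("atomoxetine", "ipsi"), ("atomoxetine", "contra")]
    for i, ss in enumerate(part_seeds):
        pid = f"p{i:02d}"
        rng = np.random.default_rng(ss)
        obs_seed = int(ss.generate_state(1)[0] % (2**31))
        spec = dist.draw_observer(rng, seed=obs_seed)
        specs[pid] = spec
        order = rng.permutation(4)
        for ses_idx, cond_i in enumerate(order, start=1):
            drug, mapping = conditions[cond_i]
            seq_seed = int(np.random.SeedSequence([seed, i, ses_idx, 1]).generate_state(1)[0] % (2**31))
            sim_seed = int(np.random.SeedSequence([seed, i, ses_idx, 2]).generate_state(1)[0] % (2**31))
            seq = generate_trial_sequence(
                design, design.n_blocks_per_session, seq_seed,
                participant_id=pid, session_id=ses_idx, drug=drug, mapping=mapping,
            )
            all_trials.append(simulate_observer(seq, spec, dt=dt, seed=sim_seed))
    trials = pd.concat(all_trials, ignore_index=True)
    return CohortDataset(trials=trials, specs=specs, design=design, seed=seed)
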