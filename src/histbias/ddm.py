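"""History-conditioned drift-diffusion model: densities, likelihood, fitting.

The decision variable accumulates noisy evidence,

    dy = (s * v + v_bias) dt + c dW,      y(0) = z * a,

with stimulus category ``s`` in {-1, +1}, drift rate ``v`` (one value per
signal-strength level), an evidence-independent drift bias ``v_bias``, noise
scale ``c`` (fixed to 1, the usual identifiability convention), boundary
separation ``a`` and a relative starting point ``z``.  Accumulation
terminates at 0 ("left") or ``a`` ("right"); the response time is the
first-passage time plus a non-decision time ``t0``.  Both bias parameters
(``z`` and ``v_bias``) are conditioned on the previous choice, which is how
the model expresses choice history bias: the *history shift* of a bias
parameter is its previous-"right" minus previous-"left" difference, positive
values meaning attraction toward the previous choice.

First-passage-time densities use the classic series expansions for the
Wiener diffusion with two absorbing bounds, switching adaptively between the
small-time and large-time representation per evaluation point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

__all__ = [
    "DDMParams",
    "DDMFit",
    "FitConfig",
    "HistoryShifts",
    "wfpt_density",
    "fpt_density",
    "choice_probability",
    "negative_loglik",
    "fit_session",
    "history_shifts",
    "predict",
]

_SERIES_TOL = 1e-8
LIK_FLOOR = 1e-10


@dataclass
class DDMParams:
    """Parameter vector of the history-conditioned diffusion model.

    ``z_prev_left``/``z_prev_right`` are starting-point fractions of ``a``
    used when the previous available choice was "left"/"right";
    ``vbias_prev_left``/``vbias_prev_right`` are the corresponding drift
    biases (evidence units per second).
    """

    a: float = 1.4
    v_weak: float = 0.8
    v_strong: float = 1.1
    t0: float = 0.3
    z_prev_left: float = 0.5
    z_prev_right: float = 0.5
    vbias_prev_left: float = 0.0
    vbias_prev_right: float = 0.0
    c: float = 1.0

    def validate(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation must be positive, got {self.a}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")
        for name in ("z_prev_left", "z_prev_right"):
            z = getattr(self, name)
            if not 0.0 < z < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {z}")
        if self.c <= 0:
            raise ValueError("noise scale must be positive")

    def drift(self, strength: str) -> float:
        if strength == "weak":
            return self.v_weak
        if strength == "strong":
            return self.v_strong
        raise ValueError(f"unknown strength level {strength!r}")

    def z(self, prev_choice: int) -> float:
        """Starting-point fraction given the previous choice (-1 left, +1 right, 0 none)."""
        if prev_choice == -1:
            return self.z_prev_left
        if prev_choice == 1:
            return self.z_prev_right
        return 0.5 * (self.z_prev_left + self.z_prev_right)

    def vbias(self, prev_choice: int) -> float:
        if prev_choice == -1:
            return self.vbias_prev_left
        if prev_choice == 1:
            return self.vbias_prev_right
        return 0.5 * (self.vbias_prev_left + self.vbias_prev_right)

    def effective_drift(self, s: int, strength: str, prev_choice: int) -> float:
        return s * self.drift(strength) + self.vbias(prev_choice)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DDMParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class HistoryShifts:
    """Previous-right minus previous-left difference of the two bias parameters.

    Positive values = attraction toward the previous choice (the upper bound
    codes "right").
    """

    z_shift: float
    vbias_shift: float


@dataclass
class DDMFit:
    params: DDMParams
    loglik: float
    n_trials: int
    converged: bool
    n_starts: int
    start_logliks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "start_logliks": list(self.start_logliks),
        }


@dataclass
class FitConfig:
    """Optimisation settings for :func:`fit_session`.

    ``n_starts`` Latin-hypercube restarts of a bounded quasi-Newton search;
    the first start is a moment-based heuristic rather than a random draw.
    """

    n_starts: int = 10
    seed: int = 0
    max_rt: float = 3.0
    bounds_a: tuple = (0.3, 6.0)
    bounds_v: tuple = (0.0, 8.0)
    bounds_z: tuple = (0.05, 0.95)
    bounds_vbias: tuple = (-4.0, 4.0)
    t0_lower: float = 0.05
    init_params: "DDMParams | None" = None  # warm start replacing the heuristic


# ---------------------------------------------------------------------------
# first-passage-time densities
# ---------------------------------------------------------------------------

def _wfpt_standard(u: np.ndarray, w, tol: float = _SERIES_TOL) -> np.ndarray:
    """Density of first passage through the LOWER bound at normalised time ``u``
    for a zero-drift diffusion on (0, 1) started at fraction ``w``.

    ``w`` may be a scalar or an array aligned with ``u``.  Per evaluation
    point, picks whichever of the small-time and large-time series needs
    fewer terms for absolute error ``tol``.
    """
    u = np.asarray(u, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), u.shape)
    out = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return out
    up = u[pos]
    wp = w[pos]

    # terms needed (Navarro & Fuss 2009 style bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(-2.0 * up * np.log(2.0 * tol * np.sqrt(2.0 * np.pi * up)))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * up) * tol < 1.0, ks, 2.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * up * tol) / (np.pi**2 * up), 0.0))
        kl = np.where(np.pi * up * tol < 1.0, np.maximum(kl, 1.0 / (np.pi * np.sqrt(up))), 1.0 / (np.pi * np.sqrt(up)))
    use_small = ks < kl

    res = np.empty_like(up)

    if np.any(use_small):
        us = up[use_small]
        ws = wp[use_small]
        K = int(np.ceil(np.max(ks[use_small])))
        ks_range = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 1)
        terms = (ws + 2.0 * ks_range[:, None]) * np.exp(
            -((ws + 2.0 * ks_range[:, None]) ** 2) / (2.0 * us[None, :])
        )
        res[use_small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * us**3)

    if np.any(~use_small):
        ul = up[~use_small]
        wl = wp[~use_small]
        K = int(np.ceil(np.max(kl[~use_small])))
        k_range = np.arange(1, K + 1)
        terms = (
            k_range[:, None]
            * np.exp(-(k_range[:, None] ** 2) * np.pi**2 * ul[None, :] / 2.0)
            * np.sin(k_range[:, None] * np.pi * wl)
        )
        res[~use_small] = np.pi * terms.sum(axis=0)

    out[pos] = np.maximum(res, 0.0)
    return out


def wfpt_density(t, v, a: float, z, c: float = 1.0) -> np.ndarray:
    """Defective density of absorption at the LOWER bound at decision time ``t``.

    ``t`` is time after the non-decision period; ``v`` and ``z`` may be
    scalars or arrays aligned with ``t``.  Scales the standard (a=1, v=0)
    series: f(t|v,a,z) = a^-2 exp(-v a z - v^2 t / 2) f0(t/a^2 | z).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    v = np.asarray(v, dtype=float)
    z = np.asarray(z, dtype=float)
    if c != 1.0:  # rescale evidence units so the noise is unit variance
        a = a / c
        v = v / c
    u = t / a**2
    f0 = _wfpt_standard(u, z)
    with np.errstate(over="ignore"):
        out = f0 / a**2 * np.exp(np.clip(-v * a * z - v**2 * t / 2.0, -745.0, 700.0))
    return out


def fpt_density(params: DDMParams, s: int, strength: str, prev_choice: int, t) -> tuple:
    """Defective first-passage densities (upper, lower) at response time ``t``.

    ``t`` includes the non-decision time; the density is evaluated at
    ``t - t0`` and is 0 for ``t <= t0``.  Upper bound = "right" choice.
    """
    params.validate()
    t = np.atleast_1d(np.asarray(t, dtype=float))
    mu = params.effective_drift(s, strength, prev_choice)
    z = params.z(prev_choice)
    td = t - params.t0
    lower = wfpt_density(td, mu, params.a, z, params.c)
    upper = wfpt_density(td, -mu, params.a, 1.0 - z, params.c)
    return upper, lower


def _p_upper(mu: float, a: float, z: float, c: float = 1.0) -> float:
    """Analytic absorption probability at the upper bound."""
    x0 = z * a
    if abs(mu) < 1e-12:
        return z
    k = 2.0 * mu / c**2
    # guard overflow for large |k a|
    num = -np.expm1(-k * x0)
    den = -np.expm1(-k * a)
    return float(num / den)


def choice_probability(params: DDMParams, s: int, strength: str, prev_choice: int) -> float:
    """Probability of a "right" (upper-bound) choice under the model."""
    params.validate()
    mu = params.effective_drift(s, strength, prev_choice)
    return _p_upper(mu, params.a, params.z(prev_choice), params.c)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _trial_arrays(trials: pd.DataFrame) -> dict:
    """Flat per-trial arrays for vectorised likelihood evaluation."""
    required = {"stimulus_side", "strength", "prev_choice", "choice", "rt"}
    missing = required - set(trials.columns)
    if missing:
        raise KeyError(f"trial table lacks columns: {sorted(missing)}")
    df = trials.dropna(subset=["choice", "rt"])
    rt = df["rt"].to_numpy(dtype=float)
    if (rt <= 0).any():
        raise ValueError("all response times must be positive")
    return {
        "rt": rt,
        "s": df["stimulus_side"].to_numpy(dtype=float),
        "strong": (df["strength"].to_numpy() == "strong"),
        # previous choice -1/0/+1 -> index 0/1/2 into (left, neutral, right)
        "prev_idx": (df["prev_choice"].to_numpy(dtype=int) + 1),
        "upper": (df["choice"].to_numpy(dtype=float) == 1.0),
        "n": len(df),
    }


def _nll_arrays(arr: dict, params: DDMParams, floor: float) -> float:
    """Vectorised -log L: the observed bound's defective density per trial.

    Absorption at the lower bound of a diffusion with drift v started at
    fraction z equals absorption at the upper bound with drift -v started
    at 1 - z, so the upper-bound trials are folded into one density call.
    """
    zs = np.array([params.z_prev_left, params.z(0), params.z_prev_right])
    vbs = np.array([params.vbias_prev_left, params.vbias(0), params.vbias_prev_right])
    v = np.where(arr["strong"], params.v_strong, params.v_weak)
    mu = arr["s"] * v + vbs[arr["prev_idx"]]
    z = zs[arr["prev_idx"]]
    # mirror the upper-bound trials
    mu_eff = np.where(arr["upper"], -mu, mu)
    z_eff = np.where(arr["upper"], 1.0 - z, z)
    dens = wfpt_density(arr["rt"] - params.t0, mu_eff, params.a, z_eff, params.c)
    return -float(np.sum(np.log(np.maximum(dens, floor))))


def negative_loglik(trials: pd.DataFrame, params: DDMParams, floor: float = LIK_FLOOR) -> float:
    """Continuous negative log-likelihood of observed (choice, rt) pairs.

    The density of the bound matching the observed choice is evaluated at
    each trial's response time; per-trial densities are floored at ``floor``
    to keep the objective finite for response times the model cannot reach
    (e.g. rt below the non-decision time).
    """
    params.validate()
    return _nll_arrays(_trial_arrays(trials), params, floor)


def _unpack(theta: np.ndarray) -> DDMParams:
    return DDMParams(
        a=theta[0], v_weak=theta[1], v_strong=theta[2], t0=theta[3],
        z_prev_left=theta[4], z_prev_right=theta[5],
        vbias_prev_left=theta[6], vbias_prev_right=theta[7],
    )


def fit_session(trials: pd.DataFrame, config: FitConfig | None = None) -> DDMFit:
    """Fit the 8 free parameters to one session (or any pooled trial set).

    Free quantities: a, v_weak, v_strong, t0, z for each previous-choice
    context, v_bias for each previous-choice context.  Bounded L-BFGS-B from
    one heuristic start plus seeded Latin-hypercube restarts; the best
    optimum is returned together with per-start diagnostics.
    """
    cfg = config or FitConfig()
    df = trials.dropna(subset=["choice", "rt"])
    if df.empty:
        raise ValueError("no completed trials to fit")
    n = len(df)
    min_rt = float(df["rt"].min())
    arrays = _trial_arrays(df)

    t0_hi = max(cfg.t0_lower + 1e-3, min_rt - 1e-3)
    bounds = [
        cfg.bounds_a,
        cfg.bounds_v,
        cfg.bounds_v,
        (cfg.t0_lower, t0_hi),
        cfg.bounds_z,
        cfg.bounds_z,
        cfg.bounds_vbias,
        cfg.bounds_vbias,
    ]

    def objective(theta: np.ndarray) -> float:
        params = _unpack(theta)
        try:
            params.validate()
        except ValueError:
            return 1e12
        return _nll_arrays(arrays, params, LIK_FLOOR)

    if cfg.init_params is not None:
        p0 = cfg.init_params
        starts = [np.array([p0.a, p0.v_weak, p0.v_strong, p0.t0,
                            p0.z_prev_left, p0.z_prev_right,
                            p0.vbias_prev_left, p0.vbias_prev_right])]
    else:
        # heuristic start: accuracy-matched drift at a nominal boundary
        acc = float((df["choice"] == df["stimulus_side"]).mean())
        acc = min(max(acc, 0.55), 0.95)
        a0 = 1.5
        v0 = np.log(acc / (1 - acc)) / a0
        starts = [np.array([a0, 0.8 * v0, 1.2 * v0, min(0.6 * min_rt, 0.3), 0.5, 0.5, 0.0, 0.0])]

    if cfg.n_starts > 1:
        sampler = qmc.LatinHypercube(d=8, seed=cfg.seed)
        unit = sampler.random(cfg.n_starts - 1)
        lo = np.array([0.6, 0.2, 0.4, cfg.t0_lower, 0.3, 0.3, -1.0, -1.0])
        hi = np.array([3.0, 2.5, 3.5, t0_hi, 0.7, 0.7, 1.0, 1.0])
        hi[3] = min(hi[3], t0_hi)
        for row in qmc.scale(unit, lo, hi):
            starts.append(row)

    best = None
    start_nlls = []
    any_converged = False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-9})
        start_nlls.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    params = _unpack(best.x)
    return DDMFit(
        params=params,
        loglik=-float(best.fun),
        n_trials=n,
        converged=any_converged,
        n_starts=len(starts),
        start_logliks=[-v for v in start_nlls],
    )


def history_shifts(fit: DDMFit | DDMParams) -> HistoryShifts:
    """Extract the previous-right minus previous-left bias differences."""
    p = fit.params if isinstance(fit, DDMFit) else fit
    return HistoryShifts(
        z_shift=p.z_prev_right - p.z_prev_left,
        vbias_shift=p.vbias_prev_right - p.vbias_prev_left,
    )


# ---------------------------------------------------------------------------
# model predictions
# ---------------------------------------------------------------------------

def predict(
    fit: DDMFit | DDMParams,
    trials: pd.DataFrame,
    rt_grid: np.ndarray | None = None,
    n_quantiles: int = 5,
) -> dict:
    """Model-predicted defective RT densities and conditional response function.

    For every condition present in ``trials`` the defective upper/lower
    densities are evaluated on ``rt_grid``; measured and predicted trials
    are then pooled into RT quantile bins and the fraction of "right"
    choices per bin is reported for both (the conditional response
    function).
    """
    p = fit.params if isinstance(fit, DDMFit) else fit
    p.validate()
    if rt_grid is None:
        rt_grid = np.linspace(1e-3, 3.0, 600)
    rt_grid = np.asarray(rt_grid, dtype=float)

    df = trials.dropna(subset=["choice", "rt"])
    densities = {}
    weights = {}
    for (s, strength, prev), sub in df.groupby(["stimulus_side", "strength", "prev_choice"], observed=True):
        key = (int(s), str(strength), int(prev))
        upper, lower = fpt_density(p, *key, rt_grid)
        densities[key] = {"t": rt_grid, "upper": upper, "lower": lower}
        weights[key] = len(sub)

    # conditional response function, pooled over conditions
    edges = np.quantile(df["rt"], np.linspace(0, 1, n_quantiles + 1))
    edges[0], edges[-1] = 0.0, np.inf
    measured_frac = []
    for i in range(n_quantiles):
        sel = (df["rt"] >= edges[i]) & (df["rt"] < edges[i + 1])
        sub = df[sel]
        measured_frac.append(float((sub["choice"] == 1).mean()) if len(sub) else np.nan)

    dt = rt_grid[1] - rt_grid[0]
    pred_frac = []
    finite_edges = np.quantile(df["rt"], np.linspace(0, 1, n_quantiles + 1))
    for i in range(n_quantiles):
        lo_e = finite_edges[i] if i > 0 else 0.0
        hi_e = finite_edges[i + 1] if i < n_quantiles - 1 else np.inf
        sel = (rt_grid >= lo_e) & (rt_grid < hi_e)
        up_mass = low_mass = 0.0
        for key, d in densities.items():
            w = weights[key]
            up_mass += w * float(np.sum(d["upper"][sel]) * dt)
            low_mass += w * float(np.sum(d["lower"][sel]) * dt)
        tot = up_mass + low_mass
        pred_frac.append(up_mass / tot if tot > 0 else np.nan)

    return {
        "densities": densities,
        "quantile_edges": finite_edges,
        "measured_right_fraction": np.array(measured_frac),
        "predicted_right_fraction": np.array(pred_frac),
    }
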