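"""Statistics battery for within-subject drug designs.

Covers the procedures used to analyse a placebo-controlled crossover study
of choice history bias: paired t tests with a default (JZS) Bayes factor,
2x2 repeated-measures ANOVA, Pearson correlations with percentile bootstrap
confidence intervals, two label-permutation procedures (a
regression-to-the-mean control for baseline-vs-change correlations and a
test for the difference of two dependent correlations), and a sequential
random-intercept mixed-model comparison (constant -> linear -> quadratic in
the pupil-bin predictor) decided by BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "StatResult",
    "LmmComparison",
    "paired_t",
    "jzs_bayes_factor",
    "rm_anova_2x2",
    "pearson_with_bootstrap",
    "perm_reversion_to_mean",
    "perm_corr_difference",
    "lmm_bin_analysis",
]


@dataclass
class StatResult:
    """Container for one test: named statistic, df, p, optional CI / null draws."""

    name: str
    statistic: float
    df: float | tuple | None = None
    p: float | None = None
    ci: tuple | None = None
    ci_level: float | None = None
    null_distribution: np.ndarray | None = None
    n_resamples: int | None = None
    flags: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "ci": list(self.ci) if self.ci is not None else None,
            "ci_level": self.ci_level,
            "n_resamples": self.n_resamples,
            "flags": list(self.flags),
            **self.extra,
        }


@dataclass
class LmmComparison:
    """Sequential random-intercept model comparison over pupil bins."""

    beta0: float
    beta1: float
    beta2: float
    random_intercept_var: float
    residual_var: float
    bic_constant: float
    bic_model1: float
    bic_model2: float
    selected: str
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# t test and Bayes factor
# ---------------------------------------------------------------------------

def paired_t(x, y) -> StatResult:
    """Two-tailed paired-sample t test (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    sd = d.std(ddof=1)
    flags = []
    if sd == 0.0:
        flags.append("zero variance of differences")
        t = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = sps.ttest_rel(x, y)
    return StatResult(name="t", statistic=float(t), df=n - 1, p=float(p), flags=flags)


def jzs_bayes_factor(t: float, n: int, scale: float = np.sqrt(2) / 2.0) -> float:
    """Default Bayes factor (BF10) for a one-sample / paired t test.

    Marginal likelihood of the observed t under a Cauchy prior with the
    given scale on the standardised effect size, divided by the point-null
    likelihood; both terms via the noncentral-t density, the numerator by
    adaptive quadrature over the prior.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1

    def integrand(delta):
        return sps.nct.pdf(t, nu, delta * np.sqrt(n)) * sps.cauchy.pdf(delta, 0.0, scale)

    num, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    if not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise RuntimeError("Bayes factor integration failed to converge")
    den = sps.t.pdf(t, nu)
    return float(num / den)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_2x2(
    table: pd.DataFrame,
    dv: str = "value",
    within: tuple = ("drug", "strength"),
    subject: str = "participant_id",
) -> dict:
    """2x2 within-subject ANOVA: main effects and interaction, df = (1, n-1).

    Expects one observation per subject x cell of the complete balanced
    design.  Each effect is tested against its own subject-by-effect
    interaction error term (the univariate repeated-measures decomposition).
    """
    fa, fb = within
    df = table[[subject, fa, fb, dv]].dropna()
    levels_a = sorted(df[fa].unique())
    levels_b = sorted(df[fb].unique())
    subjects = sorted(df[subject].unique())
    n = len(subjects)
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("both within factors must have exactly 2 levels")
    cells = df.pivot_table(index=subject, columns=[fa, fb], values=dv)
    if cells.isna().any().any() or cells.shape != (n, 4):
        raise ValueError("design must be complete: one value per subject per cell")

    y = cells.to_numpy().reshape(n, 2, 2)  # subject x A x B
    grand = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    out = {}
    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_as = 2 * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    for name, ss_eff, ss_err in (
        (fa, ss_a, ss_as),
        (fb, ss_b, ss_bs),
        (f"{fa}:{fb}", ss_ab, ss_abs),
    ):
        df1, df2 = 1, n - 1
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ms_err == 0.0:
            F = 0.0 if ms_eff == 0.0 else np.inf
            p = 1.0 if ms_eff == 0.0 else 0.0
        else:
            F = ms_eff / ms_err
            p = float(sps.f.sf(F, df1, df2))
        out[name] = StatResult(name="F", statistic=float(F), df=(df1, df2), p=p)
    return out


# ---------------------------------------------------------------------------
# correlations, bootstrap, permutations
# ---------------------------------------------------------------------------

def pearson_with_bootstrap(
    x, y, n_boot: int = 5000, coverage: float = 0.68, seed: int = 0
) -> StatResult:
    """Pearson r with parametric two-tailed p and a percentile bootstrap CI.

    Participants (pairs) are resampled with replacement; the CI is the
    percentile interval of the bootstrap r distribution at the requested
    coverage (68% by convention for error bars).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    flags = []
    if np.std(x) == 0 or np.std(y) == 0:
        return StatResult(name="r", statistic=np.nan, p=np.nan,
                          flags=["constant input: correlation undefined"])
    r, p = sps.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx]
    xb = xb - xb.mean(axis=1, keepdims=True)
    yb = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xb**2).sum(axis=1) * (yb**2).sum(axis=1))
    valid = denom > 0
    rb = (xb * yb).sum(axis=1)[valid] / denom[valid]
    alpha = (1.0 - coverage) / 2.0
    ci = (float(np.quantile(rb, alpha)), float(np.quantile(rb, 1.0 - alpha)))
    return StatResult(
        name="r", statistic=float(r), df=n - 2, p=float(p),
        ci=ci, ci_level=coverage, n_resamples=n_boot, flags=flags,
    )


def _corr_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of X with the matching row of y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        return (Xc * yc).sum(axis=1) / denom


def perm_reversion_to_mean(
    placebo_vals,
    drug_vals,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "less",
) -> StatResult:
    """Permutation control for regression to the mean.

    The observed statistic is the across-participant correlation between
    the baseline (placebo) value and the drug-minus-placebo change.  The
    null distribution repeats the correlation with the two condition labels
    independently swapped per participant, which preserves regression to
    the mean while destroying any true baseline-change association.  The
    p-value is the proportion of permuted correlations at or below the
    observed one (``alternative='less'``; 'greater' and 'two-sided' are
    available).
    """
    pl = np.asarray(placebo_vals, dtype=float)
    dr = np.asarray(drug_vals, dtype=float)
    if pl.shape != dr.shape or pl.ndim != 1:
        raise ValueError("condition vectors must be paired 1-d arrays")
    n = len(pl)
    delta = dr - pl
    flags = []
    if np.allclose(delta, 0.0):
        return StatResult(name="r", statistic=np.nan, p=np.nan, n_resamples=n_perm,
                          flags=["drug equals placebo: change scores all zero"])
    r_obs = float(sps.pearsonr(pl, delta)[0])

    rng = np.random.default_rng(seed)
    swap = rng.random((n_perm, n)) < 0.5
    base_perm = np.where(swap, dr[None, :], pl[None, :])
    delta_perm = np.where(swap, -delta[None, :], delta[None, :])
    r_null = _corr_rows(base_perm, delta_perm)
    r_null = r_null[np.isfinite(r_null)]
    m = len(r_null)
    if alternative == "less":
        p = (1.0 + np.sum(r_null <= r_obs)) / (1.0 + m)
    elif alternative == "greater":
        p = (1.0 + np.sum(r_null >= r_obs)) / (1.0 + m)
    elif alternative == "two-sided":
        med = np.median(r_null)
        p = (1.0 + np.sum(np.abs(r_null - med) >= abs(r_obs - med))) / (1.0 + m)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return StatResult(
        name="r", statistic=r_obs, p=float(p),
        null_distribution=r_null, n_resamples=m, flags=flags,
    )


def perm_corr_difference(
    shift,
    z_shift,
    vb_shift,
    n_perm: int = 10000,
    seed: int = 0,
) -> StatResult:
    """Difference between two dependent correlations, by label permutation.

    Tests Delta r = r(shift, vb_shift) - r(shift, z_shift), where ``shift``
    is the per-participant drug-induced change in the behavioural measure
    and the other two arguments are the candidate model parameters.  The
    null swaps the drug/placebo labels per participant, which flips the
    sign of that participant's change score; two-tailed p.
    """
    s = np.asarray(shift, dtype=float)
    zs = np.asarray(z_shift, dtype=float)
    vs = np.asarray(vb_shift, dtype=float)
    if not (s.shape == zs.shape == vs.shape) or s.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    n = len(s)
    d_obs = float(sps.pearsonr(s, vs)[0] - sps.pearsonr(s, zs)[0])
    rng = np.random.default_rng(seed)
    signs = np.where(rng.random((n_perm, n)) < 0.5, 1.0, -1.0)
    s_perm = signs * s[None, :]
    d_null = _corr_rows(s_perm, np.broadcast_to(vs, s_perm.shape)) - _corr_rows(
        s_perm, np.broadcast_to(zs, s_perm.shape)
    )
    d_null = d_null[np.isfinite(d_null)]
    m = len(d_null)
    p = (1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1.0 + m)
    return StatResult(name="delta_r", statistic=d_obs, p=float(p),
                      null_distribution=d_null, n_resamples=m)


# ---------------------------------------------------------------------------
# mixed-model bin analysis
# ---------------------------------------------------------------------------

def _fit_mixed(y, X, groups, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        try:
            return model.fit(reml=reml, maxiter=200, disp=False)
        except np.linalg.LinAlgError:
            return model.fit(reml=reml, method="powell", maxiter=500, disp=False)


def _bic_ml(y, X, groups) -> float:
    """BIC from a maximum-likelihood refit (REML criteria are not comparable
    across fixed-effect structures)."""
    res = _fit_mixed(y, X, groups, reml=False)
    k = X.shape[1] + 2  # fixed effects + intercept variance + residual variance
    return float(-2.0 * res.llf + k * np.log(len(y)))


def lmm_bin_analysis(
    binned: pd.DataFrame,
    y: str = "repeat",
    pupil_bin: str = "P",
    subject: str = "participant_id",
    delta_bic: float = 10.0,
) -> LmmComparison:
    """Sequential random-intercept regression on the (demeaned) pupil bin.

    Fits y ~ 1, y ~ 1 + P, and y ~ 1 + P + P^2 with participant random
    intercepts.  REML fits provide the reported coefficients and variance
    components; model selection advances from constant to linear to
    quadratic only when the richer model's maximum-likelihood BIC is lower
    by more than ``delta_bic``.
    """
    df = binned.dropna(subset=[y, pupil_bin]).copy()
    if df.groupby(subject)[pupil_bin].nunique().min() < 2:
        raise ValueError("need at least 2 bins per participant")
    P = df[pupil_bin].to_numpy(dtype=float)
    P = P - P.mean()
    yv = df[y].to_numpy(dtype=float)
    groups = df[subject].to_numpy()

    X0 = np.ones((len(df), 1))
    X1 = np.column_stack([np.ones(len(df)), P])
    X2 = np.column_stack([np.ones(len(df)), P, P**2])

    flags = []
    try:
        bic0 = _bic_ml(yv, X0, groups)
        bic1 = _bic_ml(yv, X1, groups)
        bic2 = _bic_ml(yv, X2, groups)
    except Exception as exc:  # noqa: BLE001 - optimizer failure is a data condition
        raise RuntimeError(f"mixed-model fit failed: {exc}") from exc

    # serial hierarchical selection; each richer model must undercut the
    # current best BIC by more than delta_bic (a pure inverted-U can win the
    # quadratic step directly even when the linear term adds nothing)
    selected, X_sel, bic_best = "constant", X0, bic0
    if bic1 < bic_best - delta_bic:
        selected, X_sel, bic_best = "linear", X1, bic1
    if bic2 < bic_best - delta_bic:
        selected, X_sel, bic_best = "quadratic", X2, bic2

    res = _fit_mixed(yv, X_sel, groups, reml=True)
    if not res.converged:
        flags.append("REML fit did not fully converge")
    fe = np.asarray(res.fe_params, dtype=float)
    beta0 = float(fe[0])
    beta1 = float(fe[1]) if len(fe) > 1 else 0.0
    beta2 = float(fe[2]) if len(fe) > 2 else 0.0
    return LmmComparison(
        beta0=beta0,
        beta1=beta1,
        beta2=beta2,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        bic_constant=bic0,
        bic_model1=bic1,
        bic_model2=bic2,
        selected=selected,
        flags=flags,
    )
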