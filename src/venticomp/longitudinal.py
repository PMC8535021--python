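"""Longitudinal statistics for repeated-measures ventilation data.

Per-inflation parameters (PIP, PEEP, eV_T, leak) observed over the breath
index form a panel: subjects (ventilation sequences) by ordinal time. This
module provides the analysis layer used to compare manikin and newborn
ventilation:

* median/IQR summaries per group;
* one-way random-effects panel regression (Swamy-Arora feasible GLS) of a
  parameter on the recipient contrast, with a Newey-West (Bartlett-kernel)
  heteroscedasticity- and autocorrelation-consistent variance for the
  contrast, serial correlation being pervasive in breath-by-breath data;
* LOESS trend curves (span 0.5, local linear, tricube weights) over breath
  index, restricted to indices observed in at least five subjects;
* dynamical correlation for multivariate longitudinal data: each subject's
  pair of trajectories is centred, detrended against the cross-subject mean
  curve, scaled to unit L2 norm, and the inner product averaged across
  subjects, with a subject-resampling bootstrap for CIs and p-values;
* pooled Pearson correlation (reported for comparability, though biased by
  autocorrelation) and a 2x2 chi-square for obstruction occurrence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pairing import StudyGroups

__all__ = [
    "PanelFitResult",
    "TrendCurve",
    "DynCorrResult",
    "build_panel",
    "summarize_median_iqr",
    "newey_west_vcov",
    "default_nw_lag",
    "fit_random_effects_panel",
    "loess_trend",
    "dynamical_correlation",
    "bootstrap_dyncorr",
    "pearson_r",
    "chi_square_obstruction",
    "adf_stationarity_screen",
]

PARAMETERS = ("pip", "peep", "ev_t", "leak")

_PARAM_COLUMNS = {"pip": "pip_mbar", "peep": "peep_mbar",
                  "ev_t": "evt_ml_kg", "leak": "leak_pct"}


def build_panel(groups: StudyGroups) -> pd.DataFrame:
    """Long-format panel from the four analysis groups.

    One row per (subject, breath_index, parameter): columns ``subject_id``,
    ``breath_index`` (1-based ordinal), ``parameter``, ``value``, ``group``
    (M/B) and ``duration_class`` (S/L). Breaths with a flagged missing leak
    contribute no leak row but keep their pressure/volume rows.
    """
    rows = []
    for gname, seqs in groups.groups.items():
        recipient, cls = gname[0], gname[1]
        for seq in seqs:
            for b in seq.breaths:
                values = {"pip": b.pip, "peep": b.peep, "ev_t": b.ev_t,
                          "leak": b.leak_pct}
                for param, v in values.items():
                    if not math.isfinite(v):
                        continue
                    rows.append((seq.episode_id, b.index, param, v,
                                 recipient, cls))
    return pd.DataFrame(rows, columns=["subject_id", "breath_index",
                                       "parameter", "value", "group",
                                       "duration_class"])


def summarize_median_iqr(panel: pd.DataFrame,
                         parameter: str | None = None) -> pd.DataFrame:
    """Median and IQR of pooled per-breath values, per group.

    ``panel`` is the long table from :func:`build_panel`. Returns one row per
    (group, duration_class, parameter) with the pooled median and the
    interquartile range (Q3 - Q1).
    """
    df = panel if parameter is None else panel[panel.parameter == parameter]
    if len(df) == 0:
        raise ValueError("no values to summarise")
    out = []
    for (g, c, p), sub in df.groupby(["group", "duration_class", "parameter"]):
        v = sub["value"].to_numpy()
        q1, q3 = np.percentile(v, [25, 75])
        out.append({"group": g, "duration_class": c, "parameter": p,
                    "median": float(np.median(v)), "iqr": float(q3 - q1),
                    "n": len(v)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Panel random effects with Newey-West variance
# ---------------------------------------------------------------------------

def default_nw_lag(t: float) -> int:
    """Standard rule-of-thumb truncation lag, floor(4 * (T/100)^(2/9))."""
    return int(math.floor(4.0 * (t / 100.0) ** (2.0 / 9.0)))


def newey_west_vcov(X: np.ndarray, residuals: np.ndarray, lag: int,
                    groups: np.ndarray | None = None) -> np.ndarray:
    """Newey-West HAC covariance of OLS/GLS coefficient estimates.

    Bartlett kernel weights ``w_j = 1 - j/(lag+1)``; ``lag=0`` reduces to the
    heteroscedasticity-only (White) estimator. With ``groups`` given, lagged
    cross-products are accumulated within each group's ordered series only
    (no leakage across subjects). Positive semi-definite by construction of
    the Bartlett kernel.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(residuals) == X.shape[1]:
        X = X.T
    e = np.asarray(residuals, dtype=float)
    n, k = X.shape
    if len(e) != n:
        raise ValueError("residuals and X must have the same length")
    if lag < 0:
        raise ValueError("lag must be non-negative")
    if groups is None:
        group_ids = np.zeros(n, dtype=int)
    else:
        group_ids = np.asarray(groups)
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    for g in pd.unique(group_ids):
        idx = np.nonzero(group_ids == g)[0]
        if lag >= len(idx) and len(idx) > 1:
            raise ValueError("lag must be smaller than the series length")
        Xg = X[idx]
        eg = e[idx]
        Ze = Xg * eg[:, None]
        meat += Ze.T @ Ze
        for j in range(1, min(lag, len(idx) - 1) + 1):
            w = 1.0 - j / (lag + 1.0)
            gamma = Ze[j:].T @ Ze[:-j]
            meat += w * (gamma + gamma.T)
    return bread @ meat @ bread


@dataclass
class PanelFitResult:
    """Result of the one-way random-effects group comparison."""

    coef: float  # group contrast (e.g. B - M), parameter units
    se: float  # Newey-West HAC standard error
    p_value: float
    t_stat: float
    intercept: float
    sigma2_u: float  # between-subject variance component
    sigma2_e: float  # within-subject variance component
    method: str  # "swamy-arora" or "pooled-ols"
    nw_lag: int
    n_subjects: int
    n_obs: int
    contrast_label: str = ""  # e.g. "M-B": coef is first level minus second


def fit_random_effects_panel(panel: pd.DataFrame, parameter: str,
                             contrast: str = "group",
                             duration_class: str | None = None,
                             nw_lag: int | None = None) -> PanelFitResult:
    """One-way random-effects comparison of a ventilatory parameter.

    Model: ``value_it = alpha + beta * contrast_i + u_i + e_it`` with subject
    random intercepts ``u_i``. Variance components are estimated by the
    Swamy-Arora method (within residuals for ``sigma2_e``, the between
    regression for ``sigma2_u``), the data quasi-demeaned by
    ``theta_i = 1 - sqrt(sigma2_e / (sigma2_e + T_i * sigma2_u))`` and the
    coefficients obtained by OLS on the transformed data (feasible GLS).
    The contrast is coded second-sorted-level minus first (``contrast_label``
    records it, e.g. "M-B"). The
    contrast's variance uses the Newey-West estimator on the quasi-demeaned
    residuals, accumulated within subjects, to absorb residual serial
    correlation and heteroscedasticity; p-values are two-sided from a
    t-distribution with (n_subjects - 2) degrees of freedom. Degenerate
    variance components fall back to pooled OLS with a warning.
    """
    df = panel[panel.parameter == parameter]
    if duration_class is not None:
        df = df[df.duration_class == duration_class]
    df = df.dropna(subset=["value"])
    levels = sorted(df[contrast].unique())
    if len(levels) != 2:
        raise ValueError(f"contrast {contrast!r} must have exactly 2 levels, "
                         f"found {levels}")
    subj = df.groupby("subject_id")
    n_subj = subj.ngroups
    arm_sizes = df.groupby(contrast)["subject_id"].nunique()
    if (arm_sizes < 2).any():
        raise ValueError("need at least 2 subjects per arm")

    y = df["value"].to_numpy(dtype=float)
    g = (df[contrast] == levels[1]).to_numpy(dtype=float)
    sid = df["subject_id"].to_numpy()
    n_obs = len(y)

    # Swamy-Arora variance components. The contrast regressor is constant
    # within subject, so the within residuals are just deviations from
    # subject means.
    y_mean = subj["value"].transform("mean").to_numpy()
    e_within = y - y_mean
    t_i = subj.size().to_numpy(dtype=float)
    sigma2_e = float(e_within @ e_within) / max(n_obs - n_subj, 1)

    means = df.groupby("subject_id").agg(
        ybar=("value", "mean"), g=(contrast, "first")).reset_index()
    gb = (means["g"] == levels[1]).to_numpy(dtype=float)
    Xb = np.column_stack([np.ones(n_subj), gb])
    yb = means["ybar"].to_numpy()
    beta_b, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
    resid_b = yb - Xb @ beta_b
    s2_between = float(resid_b @ resid_b) / max(n_subj - 2, 1)
    sigma2_u = s2_between - sigma2_e * float(np.mean(1.0 / t_i))

    if sigma2_u <= 0 or not math.isfinite(sigma2_u):
        warnings.warn("degenerate between-subject variance; falling back to "
                      "pooled OLS", stacklevel=2)
        sigma2_u = 0.0
        method = "pooled-ols"
        theta = pd.Series(0.0, index=means["subject_id"])
    else:
        method = "swamy-arora"
        theta = pd.Series(
            1.0 - np.sqrt(sigma2_e / (sigma2_e + t_i * sigma2_u)),
            index=subj.size().index)

    th = theta.loc[sid].to_numpy()
    # quasi-demean: z_it = z_it - theta_i * zbar_i (contrast & intercept are
    # constant within subject, so their means are themselves)
    y_t = y - th * y_mean
    const_t = 1.0 - th
    g_t = g * (1.0 - th)
    X_t = np.column_stack([const_t, g_t])
    beta, *_ = np.linalg.lstsq(X_t, y_t, rcond=None)
    resid = y_t - X_t @ beta

    if nw_lag is None:
        nw_lag = default_nw_lag(float(np.mean(t_i)))
    nw_lag = min(nw_lag, int(t_i.min()) - 1) if t_i.min() > 1 else 0
    # subjects appear in contiguous blocks ordered by breath index
    order = np.lexsort((df["breath_index"].to_numpy(), sid))
    vcov = newey_west_vcov(X_t[order], resid[order], nw_lag, groups=sid[order])
    se = float(np.sqrt(vcov[1, 1]))
    t_stat = float(beta[1] / se) if se > 0 else float("inf")
    dof = max(n_subj - 2, 1)
    p = 2.0 * stats.t.sf(abs(t_stat), dof)
    return PanelFitResult(coef=float(beta[1]), se=se, p_value=float(p),
                          t_stat=t_stat, intercept=float(beta[0]),
                          sigma2_u=float(sigma2_u), sigma2_e=float(sigma2_e),
                          method=method, nw_lag=int(nw_lag),
                          n_subjects=int(n_subj), n_obs=int(n_obs),
                          contrast_label=f"{levels[1]}-{levels[0]}")


# ---------------------------------------------------------------------------
# LOESS trend curves
# ---------------------------------------------------------------------------

@dataclass
class TrendCurve:
    """Smoothed mean trajectory of one parameter over breath index."""

    breath_index: np.ndarray
    smoothed_mean: np.ndarray
    standard_error: np.ndarray
    n_subjects_at_index: np.ndarray
    parameter: str = ""
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "breath_index": self.breath_index,
            "smoothed_mean": self.smoothed_mean,
            "standard_error": self.standard_error,
            "n_subjects": self.n_subjects_at_index,
        })


def _loess_fit_at(x: np.ndarray, y: np.ndarray, x0: float,
                  q: int) -> tuple[float, float]:
    """Local linear fit with tricube weights at x0 using q nearest points."""
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:q]
    xd, yd, dd = x[idx], y[idx], d[idx]
    dmax = dd.max()
    if dmax == 0:
        return float(np.mean(yd)), float(np.std(yd, ddof=1) / np.sqrt(len(yd))
                                         if len(yd) > 1 else 0.0)
    w = (1.0 - (dd / dmax) ** 3) ** 3
    w = np.clip(w, 1e-12, None)
    X = np.column_stack([np.ones(len(xd)), xd - x0])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ yd)
    fit = float(coef[0])
    # SE of the local mean from the weighted residual variance
    resid = yd - X @ coef
    dof = max(w.sum() ** 2 / (w ** 2).sum() - 2.0, 1.0)
    s2 = float((w * resid ** 2).sum() / w.sum()) * (len(xd) / dof) \
        if len(xd) > 2 else 0.0
    l_vec = WX @ np.linalg.solve(XtWX, np.array([1.0, 0.0]))
    se = math.sqrt(max(s2, 0.0) * float(l_vec @ l_vec))
    return fit, se


def loess_trend(panel: pd.DataFrame, parameter: str,
                group: str | None = None,
                duration_class: str | None = None,
                span: float = 0.5, min_subjects: int = 5) -> TrendCurve:
    """LOESS-smoothed mean trajectory over breath index.

    Only breath indices observed in at least ``min_subjects`` subjects are
    retained (before smoothing and in the output grid). The smoother is
    local linear with tricube weights over the nearest ``span`` fraction of
    the pooled points, evaluated at each retained integer breath index; the
    standard error comes from the local weighted residual variance.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    df = panel[panel.parameter == parameter]
    if group is not None:
        df = df[df.group == group]
    if duration_class is not None:
        df = df[df.duration_class == duration_class]
    df = df.dropna(subset=["value"])
    counts = df.groupby("breath_index")["subject_id"].nunique()
    keep = counts[counts >= min_subjects].index
    df = df[df.breath_index.isin(keep)]
    grid = np.sort(keep.to_numpy())
    if len(grid) < 3:
        raise ValueError("fewer than 3 breath indices retained")
    x = df["breath_index"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    q = max(int(math.ceil(span * len(x))), 3)
    fits = np.empty(len(grid))
    ses = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        fits[i], ses[i] = _loess_fit_at(x, y, float(x0), q)
    n_at = counts.loc[grid].to_numpy()
    return TrendCurve(breath_index=grid.astype(int), smoothed_mean=fits,
                      standard_error=ses, n_subjects_at_index=n_at,
                      parameter=parameter, group="" if group is None else group)


# ---------------------------------------------------------------------------
# Dynamical correlation
# ---------------------------------------------------------------------------

@dataclass
class DynCorrResult:
    """Dynamical correlation estimate with bootstrap CI and p-value."""

    rho: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    n_bootstrap: int = 0
    pair: tuple[str, str] = ("", "")
    subject_rhos: np.ndarray | None = None


def _curves_matrix(panel: pd.DataFrame, parameter: str,
                   subjects: list | None = None) -> pd.DataFrame:
    df = panel[panel.parameter == parameter].dropna(subset=["value"])
    wide = df.pivot_table(index="subject_id", columns="breath_index",
                          values="value", aggfunc="mean")
    if subjects is not None:
        wide = wide.loc[[s for s in subjects if s in wide.index]]
    return wide


def _dyncorr_point(X: np.ndarray, Y: np.ndarray,
                   remove_mean_trend: bool = True
                   ) -> tuple[float, np.ndarray]:
    """Core dynamical correlation on aligned subject-by-time matrices."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if remove_mean_trend:
        Xc = Xc - Xc.mean(axis=0, keepdims=True)
        Yc = Yc - Yc.mean(axis=0, keepdims=True)
    nx = np.linalg.norm(Xc, axis=1)
    ny = np.linalg.norm(Yc, axis=1)
    ok = (nx > 0) & (ny > 0)
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} subject(s) with "
                      "zero-variance curves", stacklevel=2)
    if not np.any(ok):
        raise ValueError("no subject with non-degenerate curves")
    rhos = np.einsum("ij,ij->i", Xc[ok] / nx[ok, None], Yc[ok] / ny[ok, None])
    return float(np.mean(rhos)), rhos


def dynamical_correlation(panel: pd.DataFrame, parameter_x: str,
                          parameter_y: str, group: str | None = None,
                          duration_class: str | None = None,
                          min_shared: int = 3,
                          remove_mean_trend: bool = True) -> DynCorrResult:
    """Dynamical correlation between two parameters' trajectories.

    Subjects' X and Y curves are aligned on the breath indices shared by all
    retained subjects (unequal lengths handled by truncation to the common
    grid). Each curve is centred by its time average, optionally detrended
    against the cross-subject mean curve, and scaled to unit L2 norm; the
    subject-level inner products are averaged. The result lies in [-1, 1]:
    identical curves give +1, sign-flipped curves -1.
    """
    df = panel
    if group is not None:
        df = df[df.group == group]
    if duration_class is not None:
        df = df[df.duration_class == duration_class]
    wx = _curves_matrix(df, parameter_x)
    wy = _curves_matrix(df, parameter_y)
    subjects = wx.index.intersection(wy.index)
    wx, wy = wx.loc[subjects], wy.loc[subjects]
    cols = wx.columns[wx.notna().all(axis=0)].intersection(
        wy.columns[wy.notna().all(axis=0)])
    if len(cols) < min_shared:
        raise ValueError(f"only {len(cols)} shared breath indices; "
                         f"need >= {min_shared}")
    rho, rhos = _dyncorr_point(wx[cols].to_numpy(), wy[cols].to_numpy(),
                               remove_mean_trend=remove_mean_trend)
    return DynCorrResult(rho=rho, pair=(parameter_x, parameter_y),
                         subject_rhos=rhos)


def bootstrap_dyncorr(panel: pd.DataFrame, parameter_x: str,
                      parameter_y: str, group: str | None = None,
                      duration_class: str | None = None,
                      n_boot: int = 1000, seed: int = 0,
                      remove_mean_trend: bool = True) -> DynCorrResult:
    """Dynamical correlation with subject-resampling bootstrap.

    Subjects are resampled with replacement ``n_boot`` times (default 1000);
    the 95% CI is the percentile interval of the resampled estimates and the
    p-value for rho = 0 is twice the proportion of resamples whose sign is
    opposite to the point estimate, floored at ``1/n_boot``.
    """
    df = panel
    if group is not None:
        df = df[df.group == group]
    if duration_class is not None:
        df = df[df.duration_class == duration_class]
    wx = _curves_matrix(df, parameter_x)
    wy = _curves_matrix(df, parameter_y)
    subjects = wx.index.intersection(wy.index)
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for the bootstrap")
    wx, wy = wx.loc[subjects], wy.loc[subjects]
    cols = wx.columns[wx.notna().all(axis=0)].intersection(
        wy.columns[wy.notna().all(axis=0)])
    if len(cols) < 3:
        raise ValueError("fewer than 3 shared breath indices")
    X = wx[cols].to_numpy()
    Y = wy[cols].to_numpy()
    rho, rhos = _dyncorr_point(X, Y, remove_mean_trend=remove_mean_trend)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b], _ = _dyncorr_point(X[idx], Y[idx],
                                         remove_mean_trend=remove_mean_trend)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    opposite = np.mean(boots <= 0) if rho > 0 else np.mean(boots >= 0)
    p = max(min(2.0 * float(opposite), 1.0), 1.0 / n_boot)
    return DynCorrResult(rho=rho, ci_low=float(ci_low), ci_high=float(ci_high),
                         p_value=p, n_bootstrap=n_boot,
                         pair=(parameter_x, parameter_y), subject_rhos=rhos)


# ---------------------------------------------------------------------------
# Pooled Pearson correlation and obstruction chi-square
# ---------------------------------------------------------------------------

def pearson_r(panel: pd.DataFrame, parameter_x: str, parameter_y: str,
              group: str | None = None,
              duration_class: str | None = None) -> tuple[float, float]:
    """Pooled per-breath Pearson correlation (r, p).

    Pools all (subject, breath) pairs where both parameters are observed.
    Reported for comparability with conventional analyses; the repeated-
    measures autocorrelation biases its p-value, which is why the dynamical
    correlation is the primary measure.
    """
    df = panel
    if group is not None:
        df = df[df.group == group]
    if duration_class is not None:
        df = df[df.duration_class == duration_class]
    wide = df.pivot_table(index=["subject_id", "breath_index"],
                          columns="parameter", values="value")
    if parameter_x not in wide or parameter_y not in wide:
        raise ValueError("parameter not present in panel")
    sub = wide[[parameter_x, parameter_y]].dropna()
    if len(sub) < 2:
        raise ValueError("need at least 2 complete pairs")
    x = sub[parameter_x].to_numpy()
    y = sub[parameter_y].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in pooled values")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def chi_square_obstruction(n_obstructed_manikin: int, n_manikin: int,
                           n_obstructed_baby: int, n_baby: int,
                           yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square comparing obstruction occurrence between arms.

    2x2 table of (obstructed, not obstructed) x (manikin, baby); no
    continuity correction by default (Yates available by flag). Returns
    (statistic, p_value) with 1 degree of freedom.
    """
    if min(n_obstructed_manikin, n_obstructed_baby) < 0:
        raise ValueError("counts must be non-negative")
    if n_obstructed_manikin > n_manikin or n_obstructed_baby > n_baby:
        raise ValueError("obstructed count exceeds group size")
    table = np.array([
        [n_obstructed_manikin, n_manikin - n_obstructed_manikin],
        [n_obstructed_baby, n_baby - n_obstructed_baby]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def adf_stationarity_screen(panel: pd.DataFrame, parameter: str,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Optional augmented Dickey-Fuller screen per subject series.

    The panel models assume stationary within-subject errors; this screen
    logs a warning for subjects whose series fail to reject a unit root. It
    is advisory only and gates nothing.
    """
    from statsmodels.tsa.stattools import adfuller
    df = panel[panel.parameter == parameter].dropna(subset=["value"])
    out = []
    for sid, sub in df.groupby("subject_id"):
        v = sub.sort_values("breath_index")["value"].to_numpy()
        if len(v) < 8 or np.ptp(v) == 0:
            out.append({"subject_id": sid, "p_value": float("nan"),
                        "stationary": None})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = adfuller(v, autolag="AIC")[1]
        out.append({"subject_id": sid, "p_value": float(p),
                    "stationary": bool(p < alpha)})
    res = pd.DataFrame(out)
    n_fail = int((res["stationary"] == False).sum())  # noqa: E712
    if n_fail:
        warnings.warn(f"{n_fail} subject series for {parameter!r} did not "
                      "reject a unit root; panel comparisons assume "
                      "stationary errors", stacklevel=2)
    return res
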