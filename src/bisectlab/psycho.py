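"""Psychometric (cumulative Gumbel) and chronometric analyses.

The proportion of "long" classifications as a function of stimulus
duration is fit with a cumulative Gumbel on log duration,
F(d) = 1 - exp(-exp((log d - alpha) / beta)), the natural choice for a
log-spaced duration set.  On the log axis this is a binomial GLM with a
complementary log-log link, fit here by batched Fisher scoring so that
bootstrap resamples and sliding windows can be fit thousands at a time.

The fit yields the bisection point BP = F^{-1}(0.5), the difference
limen DL = (theta75 - theta25)/2 and the coefficient of variation
CV = DL/BP; threshold uncertainty comes from a bias-corrected parametric
bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

# log(-log(1-p)) for the 25/50/75% thresholds
_C25 = np.log(-np.log(0.75))
_C50 = np.log(np.log(2.0))
_C75 = np.log(-np.log(0.25))

_B1_MAX = 200.0  # slope cap under complete separation
_B1_MIN = 1e-3   # below this the curve is flat: no measurable crossing


@dataclass
class PsychometricFit:
    """Cumulative-Gumbel fit summary (durations in seconds)."""

    location: float  # exp(alpha): duration at which F = 1 - 1/e
    scale: float     # beta, in log-duration units
    bp: float
    theta25: float
    theta75: float
    dl: float
    cv: float
    n_per_level: np.ndarray
    durations: np.ndarray
    proportions: np.ndarray
    converged: bool
    log_axis: bool = True
    boot_ci: dict | None = None
    coefs: tuple = field(default=(np.nan, np.nan), repr=False)
    bp_se: float = np.nan  # delta-method SE from the Fisher information

    def predict(self, d) -> np.ndarray:
        """Fitted probability of a "long" classification at duration d."""
        x = np.log(np.asarray(d, float)) if self.log_axis else np.asarray(d, float)
        b0, b1 = self.coefs
        return -np.expm1(-np.exp(b0 + b1 * x))


def filter_rt(trials: pd.DataFrame, lo: float = 0.100, hi: float = 1.000) -> pd.DataFrame:
    """Keep trials with lo <= RT <= hi (inclusive); logs the removal count.

    The default 100-1000 ms band removes premature and late responses
    that would contaminate trial-history analyses.
    """
    if lo >= hi:
        raise ValueError("require lo < hi")
    rt = trials["rt_s"]
    if rt.isna().any():
        raise ValueError("filter_rt requires RT on every candidate row")
    keep = (rt >= lo) & (rt <= hi)
    n_removed = int((~keep).sum())
    logger.info("filter_rt: removed %d of %d trials outside [%g, %g] s",
                n_removed, len(trials), lo, hi)
    out = trials[keep].reset_index(drop=True)
    out.attrs["n_removed_rt_filter"] = n_removed
    return out


def proportions_from_trials(trials: pd.DataFrame):
    """Per-level (proportion "long", count, duration) from a trial table."""
    grp = trials.groupby("duration_s")["choice"]
    durations = np.array(sorted(trials["duration_s"].unique()))
    n = grp.size().reindex(durations).to_numpy()
    k = grp.apply(lambda c: (c == "long").sum()).reindex(durations).to_numpy()
    return k / n, n.astype(int), durations


def _batch_cloglog(k: np.ndarray, n: np.ndarray, x: np.ndarray,
                   max_iter: int = 60):
    """Batched binomial cloglog MLE: k,n are (B, L); x is (L,).

    Returns (b0, b1) each (B,).  Fisher scoring with step halving; the
    slope is capped at +/-_B1_MAX under complete separation (the
    likelihood is then flat in the capped direction and thresholds stay
    bracketed by the data).
    """
    k = np.atleast_2d(np.asarray(k, float))
    n = np.atleast_2d(np.asarray(n, float))
    B, L = k.shape
    x = np.asarray(x, float)
    # init from least squares on the linearized link
    pt = (k + 0.5) / (n + 1.0)
    y = np.log(-np.log1p(-pt))
    xc = x - x.mean()
    b1 = (y @ xc) / (xc @ xc)
    b1 = np.clip(b1, 0.05, _B1_MAX)
    b0 = y.mean(axis=1) - b1 * x.mean()

    def nll(b0, b1):
        eta = b0[:, None] + b1[:, None] * x[None, :]
        ee = np.exp(np.clip(eta, -30, 30))
        logp = np.log(np.clip(-np.expm1(-ee), 1e-300, None))
        return -(k * logp + (n - k) * (-ee)).sum(axis=1)

    f_cur = nll(b0, b1)
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30, 30)
        ee = np.exp(eta)
        p = np.clip(-np.expm1(-ee), 1e-12, 1 - 1e-12)
        dp = np.exp(eta - ee)
        r = (k - n * p) / (p * (1 - p)) * dp
        w = n * dp * dp / (p * (1 - p))
        u0, u1 = r.sum(axis=1), r @ x
        i00, i01, i11 = w.sum(axis=1), w @ x, w @ (x * x)
        det = np.clip(i00 * i11 - i01 * i01, 1e-30, None)
        s0 = (i11 * u0 - i01 * u1) / det
        s1 = (-i01 * u0 + i00 * u1) / det
        step = np.ones(B)
        for _ in range(8):
            nb0, nb1 = b0 + step * s0, np.clip(b1 + step * s1, -_B1_MAX, _B1_MAX)
            f_new = nll(nb0, nb1)
            worse = f_new > f_cur + 1e-12
            if not worse.any():
                break
            step = np.where(worse, step / 2, step)
        improved = f_new <= f_cur
        b0 = np.where(improved, nb0, b0)
        b1 = np.where(improved, nb1, b1)
        f_cur = np.minimum(f_new, f_cur)
        if np.max(np.abs(np.concatenate([u0, u1]))) < 1e-8 * (1 + n.sum()):
            break
    return b0, b1


def _thresholds(b0, b1, log_axis: bool = True):
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t25, bp, t75 = ((c - b0) / b1 for c in (_C25, _C50, _C75))
        if log_axis:
            t25, bp, t75 = np.exp(t25), np.exp(bp), np.exp(t75)
    return t25, bp, t75


def fit_gumbel(
    proportions_long: np.ndarray,
    n_per_level: np.ndarray,
    durations: np.ndarray,
    min_per_level: int = 8,
    enforce_min: bool = True,
    log_axis: bool = True,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gumbel fit of choice proportions.

    A fit with no measurable crossing (all-identical responses, or a
    slope indistinguishable from flat) is returned with
    ``converged=False`` and missing thresholds.
    """
    p = np.asarray(proportions_long, float)
    n = np.asarray(n_per_level, float)
    d = np.asarray(durations, float)
    if not (p.shape == n.shape == d.shape):
        raise ValueError("proportions, counts and durations must align")
    if len(d) < 2:
        raise ValueError("need >= 2 duration levels")
    if enforce_min and np.any(n < min_per_level):
        raise ValueError(
            f"levels with fewer than {min_per_level} trials; pass "
            "enforce_min=False to fit anyway")
    k = p * n
    x = np.log(d) if log_axis else d
    b0, b1 = _batch_cloglog(k[None, :], n[None, :], x)
    b0, b1 = float(b0[0]), float(b1[0])
    degenerate = np.all(k == 0) or np.all(k == n) or b1 <= _B1_MIN
    with np.errstate(all="ignore"):
        t25, bp, t75 = (float(v) for v in _thresholds(b0, b1, log_axis))
        if b1 > 0:
            loc = float(np.exp(-b0 / b1)) if log_axis else -b0 / b1
            scale = 1.0 / b1
        else:
            loc = scale = np.nan
    converged = (not degenerate) and np.isfinite(bp) and bp > 0
    bp_se = np.nan
    if not converged:
        t25 = bp = t75 = dl = cv = np.nan
    else:
        dl = (t75 - t25) / 2.0
        cv = dl / bp
        bp_se = _bp_se_delta(b0, b1, k, n, x, log_axis)
    return PsychometricFit(
        location=loc, scale=scale, bp=bp, theta25=t25, theta75=t75,
        dl=dl, cv=cv, n_per_level=n.astype(int), durations=d,
        proportions=p, converged=converged, log_axis=log_axis,
        coefs=(b0, b1), bp_se=bp_se,
    )


def _bp_se_delta(b0: float, b1: float, k, n, x, log_axis: bool) -> float:
    """Delta-method SE of the bisection point from the Fisher information."""
    eta = np.clip(b0 + b1 * x, -30, 30)
    ee = np.exp(eta)
    p = np.clip(-np.expm1(-ee), 1e-12, 1 - 1e-12)
    dp = np.exp(eta - ee)
    w = n * dp * dp / (p * (1 - p))
    info = np.array([[w.sum(), w @ x], [w @ x, w @ (x * x)]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.nan
    u = (_C50 - b0) / b1  # log-bp (or bp on a linear axis)
    grad = np.array([-1.0 / b1, -u / b1])
    var_u = float(grad @ cov @ grad)
    if var_u < 0:
        return np.nan
    return float(np.sqrt(var_u) * (np.exp(u) if log_axis else 1.0))


def fit_gumbel_trials(trials: pd.DataFrame, **kw) -> PsychometricFit:
    """Convenience wrapper: fit directly from a trial table."""
    p, n, d = proportions_from_trials(trials)
    return fit_gumbel(p, n, d, **kw)


def thresholds_bootstrap(
    fit: PsychometricFit,
    n_boot: int = 1999,
    seed: int | None = None,
    ci: float = 0.95,
) -> dict:
    """Bias-corrected parametric bootstrap intervals for the thresholds.

    Responses are resampled from the fitted curve (binomial at each
    level), refit in one batch, and per-threshold intervals are the
    bias-corrected percentile bounds.  The interval dict is also stored
    on ``fit.boot_ci``.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    rng = np.random.default_rng(seed)
    p_hat = fit.predict(fit.durations)
    n = fit.n_per_level.astype(int)
    k_star = rng.binomial(n[None, :], p_hat[None, :], size=(n_boot, len(n)))
    x = np.log(fit.durations) if fit.log_axis else fit.durations
    b0s, b1s = _batch_cloglog(k_star, np.broadcast_to(n, k_star.shape), x)
    t25s, bps, t75s = _thresholds(b0s, b1s, fit.log_axis)
    zq = ndtri(0.5 + ci / 2.0)
    out = {"n_boot": int(n_boot), "ci": ci}
    for name, stars, point in (
        ("theta25", t25s, fit.theta25),
        ("bp", bps, fit.bp),
        ("theta75", t75s, fit.theta75),
    ):
        stars = stars[np.isfinite(stars)]
        frac_below = np.clip((stars < point).mean(), 1e-6, 1 - 1e-6)
        z0 = ndtri(frac_below)
        lo_q = ndtr(2 * z0 - zq)
        hi_q = ndtr(2 * z0 + zq)
        out[name] = (float(np.quantile(stars, lo_q)),
                     float(np.quantile(stars, hi_q)))
    fit.boot_ci = out
    return out


@dataclass
class ChronometricCurve:
    """Per-duration mean RT (regardless of choice) with standard errors."""

    durations: np.ndarray
    mean_rt: np.ndarray
    se_rt: np.ndarray
    n: np.ndarray


def chronometric(trials: pd.DataFrame,
                 expected_durations: np.ndarray | None = None) -> ChronometricCurve:
    """Mean and standard error of RT for each duration level.

    Levels with a single trial report a missing standard error; expected
    levels absent from the data are omitted with a warning.
    """
    grp = trials.groupby("duration_s")["rt_s"]
    durations = np.array(sorted(trials["duration_s"].unique()))
    if expected_durations is not None:
        missing = set(np.round(expected_durations, 9)) - set(np.round(durations, 9))
        if missing:
            warnings.warn(f"no trials at duration(s) {sorted(missing)}; omitted")
    mean = grp.mean().reindex(durations).to_numpy()
    n = grp.size().reindex(durations).to_numpy()
    sd = grp.std(ddof=1).reindex(durations).to_numpy()
    se = np.where(n > 1, sd / np.sqrt(n), np.nan)
    return ChronometricCurve(durations=durations, mean_rt=mean, se_rt=se,
                             n=n.astype(int))
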