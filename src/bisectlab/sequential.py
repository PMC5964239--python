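"""Trial-history analyses: carryover of the bisection point and BP dynamics.

A first-order counterbalanced design permits conditioning the
psychometric fit on the previous trial: a *perceptual* carryover effect
appears as a positive slope of the bisection point (BP) across the seven
possible prior durations, and a *decisional* effect as a BP difference
between trials following a "short" versus a "long" response.  A sliding
window over the session tracks whether a BP shift is sustained (memory
pattern) or transient (clock pattern).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import psycho
from .design import TrialSequence, NULL_LABEL


@dataclass
class CarryoverResult:
    """BP conditioned on prior duration and prior response."""

    prior_durations: np.ndarray
    bp_by_prior: np.ndarray
    slope: float
    slope_se: float
    slope_ci: tuple
    decisional_delta: float  # bp after "short" minus bp after "long"
    fits: dict


@dataclass
class SlidingBPSeries:
    """BP per sliding window, with smoothing and sufficiency flags."""

    window: int
    centers: np.ndarray
    bp: np.ndarray
    smoothed_bp: np.ndarray
    insufficient: np.ndarray


def add_prior_choice(trials: pd.DataFrame) -> pd.DataFrame:
    """Annotate each trial with the previous trial's response.

    The predecessor is the row at ``trial_index - 1``; trials following
    a null (or opening a session) get a missing prior choice.
    """
    out = trials.sort_values("trial_index").reset_index(drop=True)
    by_index = dict(zip(out["trial_index"], out["choice"]))
    prior = [
        by_index.get(ti - 1, pd.NA) if not null else pd.NA
        for ti, null in zip(out["trial_index"], out["prior_was_null"])
    ]
    out["prior_choice"] = prior
    return out


def carryover_bp(
    trials: pd.DataFrame,
    min_per_level: int = 4,
    alpha: float = 0.05,
) -> CarryoverResult:
    """Quantify perceptual and decisional carryover of the bisection point.

    One psychometric fit per prior-duration bin (trials following nulls
    excluded); the perceptual effect is the OLS slope of BP on prior
    duration, reported with its standard error and confidence interval.
    Bins in which any present-duration level falls below
    ``min_per_level`` trials, or whose fit does not converge, are dropped
    with a warning; with fewer than 3 usable bins the slope is missing.

    The bin threshold defaults to 4 rather than the global-fit minimum of
    8: a counterbalanced session supplies exactly ``reps`` trials per
    (prior, present) cell, so after RT filtering a full-count requirement
    would discard nearly every bin.
    """
    usable = trials[trials["prior_duration_s"].notna() & ~trials["prior_was_null"]]
    if len(usable) == 0:
        raise ValueError("no trials with prior-duration annotations")
    fits = {}
    priors, bps, ses = [], [], []
    for prior_d, df in usable.groupby("prior_duration_s"):
        p, n, d = psycho.proportions_from_trials(df)
        if np.any(n < min_per_level):
            warnings.warn(
                f"prior bin {prior_d:.3f}s dropped: a duration level has "
                f"fewer than {min_per_level} trials")
            continue
        fit = psycho.fit_gumbel(p, n, d, min_per_level=min_per_level,
                                enforce_min=False)
        fits[float(prior_d)] = fit
        if fit.converged and np.isfinite(fit.bp_se):
            priors.append(float(prior_d))
            bps.append(fit.bp)
            ses.append(fit.bp_se)
        else:
            warnings.warn(f"prior bin {prior_d:.3f}s dropped: fit did not converge")
    priors, bps, ses = np.asarray(priors), np.asarray(bps), np.asarray(ses)
    if len(priors) >= 3:
        # weighted least squares with per-bin BP variances known from the
        # Fisher information; a z interval is then exact to first order
        w = 1.0 / ses**2
        xb = np.sum(w * priors) / w.sum()
        sxx = np.sum(w * (priors - xb) ** 2)
        slope = float(np.sum(w * (priors - xb) * bps) / sxx)
        slope_se = float(np.sqrt(1.0 / sxx))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        ci = (slope - zcrit * slope_se, slope + zcrit * slope_se)
    else:
        slope = slope_se = np.nan
        ci = (np.nan, np.nan)

    # decisional effect: split by the previous trial's response
    with_choice = add_prior_choice(trials)
    delta = np.nan
    split = {}
    for resp in ("short", "long"):
        df = with_choice[with_choice["prior_choice"] == resp]
        if len(df) == 0:
            continue
        p, n, d = psycho.proportions_from_trials(df)
        f = psycho.fit_gumbel(p, n, d, enforce_min=False)
        if f.converged:
            split[resp] = f.bp
    if len(split) == 2:
        delta = split["short"] - split["long"]
    return CarryoverResult(
        prior_durations=priors, bp_by_prior=bps, slope=slope,
        slope_se=slope_se, slope_ci=ci, decisional_delta=float(delta),
        fits=fits,
    )


def sliding_bp(
    trials: pd.DataFrame,
    window: int = 131,
    step: int = 1,
    smooth: int = 10,
    min_per_level: int = 8,
) -> SlidingBPSeries:
    """Bisection point within a sliding window of trials.

    Trials are taken in ``trial_index`` order; every window of
    ``window`` consecutive trials is fit in one batched pass.  Windows
    in which any duration level has fewer than ``min_per_level`` trials
    are flagged ``insufficient`` (their BP is still reported when the
    fit converges, but flagged — never silently trusted).  Smoothing is
    a centered moving average of length ``smooth`` with edge truncation.
    """
    df = trials.sort_values("trial_index").reset_index(drop=True)
    n_trials = len(df)
    if window > n_trials:
        raise ValueError(f"window ({window}) exceeds trial count ({n_trials})")
    durations = np.array(sorted(df["duration_s"].unique()))
    L = len(durations)
    lut = {d: i for i, d in enumerate(durations)}
    lev = df["duration_s"].map(lut).to_numpy()
    is_long = (df["choice"] == "long").to_numpy()
    onehot_n = np.zeros((n_trials, L))
    onehot_n[np.arange(n_trials), lev] = 1.0
    onehot_k = onehot_n * is_long[:, None]
    cn = np.vstack([np.zeros(L), np.cumsum(onehot_n, axis=0)])
    ck = np.vstack([np.zeros(L), np.cumsum(onehot_k, axis=0)])
    starts = np.arange(0, n_trials - window + 1, step)
    n_mat = cn[starts + window] - cn[starts]
    k_mat = ck[starts + window] - ck[starts]
    insufficient = (n_mat < min_per_level).any(axis=1)
    x = np.log(durations)
    # avoid 0/0 in empty levels by fitting only levels with trials:
    # a zero-count level contributes nothing to the likelihood
    b0, b1 = psycho._batch_cloglog(k_mat, n_mat, x)
    _, bp, _ = psycho._thresholds(b0, b1)
    bp = np.where(b1 > psycho._B1_MIN, bp, np.nan)
    centers = df["trial_index"].to_numpy()[starts + window // 2]
    smoothed = (
        pd.Series(bp).rolling(smooth, center=True, min_periods=1).mean().to_numpy()
    )
    return SlidingBPSeries(window=window, centers=centers, bp=bp,
                           smoothed_bp=smoothed, insufficient=insufficient)


def minimum_window(sequence, min_per_level: int = 8) -> int:
    """Smallest window length guaranteeing enough trials of every duration.

    For a realized sequence (nulls excluded — analysis windows slide
    over stimulus trials), returns the smallest w such that *every*
    contiguous window of w trials contains at least ``min_per_level``
    occurrences of every duration label.  Raises if even the full
    sequence cannot satisfy the requirement.
    """
    if isinstance(sequence, TrialSequence):
        labels = [lab for lab in sequence.labels if lab != NULL_LABEL]
    else:
        labels = [lab for lab in sequence if lab != NULL_LABEL]
    uniq = sorted(set(labels))
    n = len(labels)
    lut = {lab: i for i, lab in enumerate(uniq)}
    lev = np.array([lut[lab] for lab in labels])
    onehot = np.zeros((n, len(uniq)), dtype=np.int64)
    onehot[np.arange(n), lev] = 1
    csum = np.vstack([np.zeros(len(uniq), dtype=np.int64), np.cumsum(onehot, axis=0)])

    def ok(w: int) -> bool:
        if w > n:
            return False
        starts = np.arange(0, n - w + 1)
        counts = csum[starts + w] - csum[starts]
        return bool((counts >= min_per_level).all())

    if not ok(n):
        raise ValueError(
            "no window length satisfies the per-level minimum "
            f"({min_per_level}) in this sequence")
    lo, hi = 1, n  # ok(hi) is True; invariant: ok(lo-1) is False
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return int(lo)
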