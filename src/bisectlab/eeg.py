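"""Morlet time-frequency maps, power regression, cluster permutation tests.

Single-channel analysis pipeline: complex Morlet convolution (EEGLAB-style
cycle growth), optional single-trial baseline division, per-pixel ordinary
least-squares regression of power on a trial regressor, and family-wise
error control via the maximum-cluster-size permutation statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage, stats

_CONN8 = np.ones((3, 3), dtype=int)  # 8-neighborhood in the freq x time plane


@dataclass
class Epochs:
    """Epoched multichannel data: channel x time x trial, plus metadata."""

    data: np.ndarray
    sample_rate: float
    window: tuple
    trial_meta: pd.DataFrame
    channel_names: list = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_ch, n_t, n_trials = self.data.shape
        expected = int(round((self.window[1] - self.window[0]) * self.sample_rate))
        if n_t != expected:
            raise ValueError(
                f"time axis has {n_t} samples, window implies {expected}")
        if len(self.trial_meta) != n_trials:
            raise ValueError("trial_meta length must equal trial count")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(n_ch)]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1]) / self.sample_rate

    def save(self, path) -> None:
        """Write to HDF5 (float32 array + JSON metadata sidecar attribute)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype("<f4"))
            f.attrs["meta"] = json.dumps({
                "sample_rate": self.sample_rate,
                "window": list(self.window),
                "channel_names": list(self.channel_names),
                "trial_meta": self.trial_meta.to_dict(orient="list"),
                "info": self.info,
            })

    @classmethod
    def load(cls, path) -> "Epochs":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            meta = json.loads(f.attrs["meta"])
        return cls(
            data=data,
            sample_rate=meta["sample_rate"],
            window=tuple(meta["window"]),
            trial_meta=pd.DataFrame(meta["trial_meta"]),
            channel_names=meta["channel_names"],
            info=meta.get("info", {}),
        )


@dataclass
class TFMap:
    """Per-trial (or averaged) power: [trial x] frequency x time."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline_mode: str = "none"
    valid: np.ndarray | None = None  # freq x time, False at wavelet edges
    trial_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class ClusterResult:
    """Pixelwise statistics with permutation-corrected cluster inference."""

    stat_map: np.ndarray
    cluster_masks: np.ndarray  # labeled int array, 0 = background
    cluster_stats: pd.DataFrame
    p_values: np.ndarray
    n_permutations: int
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        """Boolean map of pixels in clusters with p < alpha."""
        sig = np.zeros_like(self.stat_map, dtype=bool)
        for cid, p in zip(self.cluster_stats["cluster_id"], self.p_values):
            if p < self.alpha:
                sig |= self.cluster_masks == cid
        return sig


def log_freqs(f_min: float = 10.0, f_max: float = 40.0, n: int = 100) -> np.ndarray:
    """Log-spaced analysis frequencies (Hz)."""
    return np.geomspace(f_min, f_max, n)


def wavelet_cycles(freqs: np.ndarray, cycles_base: float = 3.0,
                   scaling: float = 0.5) -> np.ndarray:
    """EEGLAB-style [c0, s] cycle schedule.

    The cycle count interpolates between a constant-cycle wavelet (s=0)
    and a linear growth proportional to frequency (s=1):
    cycles(f) = c0 + s * (c0 * f / f0 - c0), with f0 the lowest analyzed
    frequency.  s=0.5 therefore widens the wavelet half as fast as the
    frequency rises.
    """
    freqs = np.asarray(freqs, dtype=float)
    f0 = freqs.min()
    return cycles_base + scaling * (cycles_base * freqs / f0 - cycles_base)


def morlet_tf(
    epochs: Epochs,
    freqs: np.ndarray | None = None,
    cycles_base: float = 3.0,
    scaling: float = 0.5,
    channel: int | str = 0,
) -> TFMap:
    """Per-trial Morlet wavelet power for one channel.

    Uses complex Morlet convolution (via MNE's array interface) with the
    cycle schedule of :func:`wavelet_cycles`.  Edge samples whose wavelet
    support (half-width cycles(f)/(2f)) extends beyond the epoch are
    marked invalid in ``valid`` rather than trimmed.
    """
    from mne.time_frequency import tfr_array_morlet

    if freqs is None:
        freqs = log_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if isinstance(channel, str):
        channel = epochs.channel_names.index(channel)
    n_cycles = wavelet_cycles(freqs, cycles_base, scaling)
    half_support = n_cycles / (2.0 * freqs)
    epoch_len = epochs.window[1] - epochs.window[0]
    too_long = half_support * 2 > epoch_len
    if np.any(too_long):
        f_bad = freqs[too_long][0]
        raise ValueError(
            f"epoch of {epoch_len:.3f}s too short for the wavelet at "
            f"{f_bad:.2f} Hz (support {2 * half_support[too_long][0]:.3f}s)")
    # (n_epochs, n_channels, n_times) layout expected by mne
    x = np.transpose(epochs.data[[channel]], (2, 0, 1)).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = tfr_array_morlet(
            x, sfreq=epochs.sample_rate, freqs=freqs, n_cycles=n_cycles,
            output="power", zero_mean=True,
        )[:, 0]  # -> (n_trials, n_freqs, n_times)
    times = epochs.times
    valid = np.ones((len(freqs), len(times)), dtype=bool)
    for i, h in enumerate(half_support):
        valid[i] = (times - times[0] >= h) & (times[-1] - times >= h)
    return TFMap(power=power, freqs=freqs, times=times,
                 valid=valid, trial_meta=epochs.trial_meta)


def baseline_divide(tf: TFMap, window: tuple = (-0.2, 0.0)) -> TFMap:
    """Single-trial baseline division per frequency.

    Every trial's power is divided by that trial's mean power in the
    baseline window, frequency by frequency — robust to single noisy
    trials compared with dividing by the trial-averaged baseline.
    Trials with zero baseline power at any frequency are dropped with a
    warning.
    """
    if tf.power.ndim != 3:
        raise ValueError("baseline division requires per-trial power")
    lo, hi = window
    sel = (tf.times >= lo) & (tf.times <= hi)
    if not sel.any():
        raise ValueError("baseline window outside the epoch")
    base = tf.power[:, :, sel].mean(axis=2)  # trial x freq
    good = (base > 0).all(axis=1)
    if not good.all():
        warnings.warn(f"excluding {int((~good).sum())} trial(s) with zero "
                      "baseline power")
    power = tf.power[good] / base[good][:, :, None]
    meta = tf.trial_meta[good].reset_index(drop=True) if tf.trial_meta is not None else None
    return TFMap(power=power, freqs=tf.freqs, times=tf.times,
                 baseline_mode="single_trial_division", valid=tf.valid,
                 trial_meta=meta)


def duration_regression(tf: TFMap, regressor: str = "present_duration",
                        values: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel OLS slope of single-trial power on a duration regressor.

    ``regressor`` selects the present or prior trial duration from the
    map's trial metadata (trials with a missing prior duration — e.g.
    following a null trial — are excluded), or pass ``values`` directly.
    Returns a frequency x time slope map in power units per second.
    """
    if tf.power.ndim != 3:
        raise ValueError("regression requires per-trial power")
    if values is None:
        col = {"present_duration": "duration_s",
               "prior_duration": "prior_duration_s"}[regressor]
        values = tf.trial_meta[col].to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    values, power = values[keep], tf.power[keep]
    if len(np.unique(values)) < 3:
        raise ValueError("need >= 3 distinct regressor values")
    x = values - values.mean()
    return np.tensordot(x, power, axes=(0, 0)) / (x @ x)


def cluster_permutation(
    maps: np.ndarray,
    n_perm: int = 2000,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.05,
    statistic: str = "size",
    seed: int | None = None,
) -> ClusterResult:
    """One-sample cluster-based permutation test of per-subject maps vs 0.

    Pixelwise one-sample t statistics are thresholded two-tailed at
    ``cluster_forming_p``; 8-connected suprathreshold regions (positive
    and negative pooled) are scored by size (pixel count) or mass
    (summed |t|), and compared with a max-statistic null built by
    per-subject sign flipping.  Cluster p-values use the add-one
    estimator (number of permutation maxima >= observed + 1) / (n_perm + 1).

    A paired two-condition contrast is run by passing per-subject A-B
    difference maps (see :func:`condition_contrast`): sign flipping of
    differences is equivalent to swapping condition labels per subject.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[0] < 2:
        raise ValueError("need a (n_subjects, n_freqs, n_times) stack, n >= 2")
    if n_perm < 1.0 / alpha:
        warnings.warn("n_perm below 1/alpha; p-values cannot reach alpha")
    n_subj = maps.shape[0]
    df = n_subj - 1
    t_crit = stats.t.ppf(1.0 - cluster_forming_p / 2.0, df)
    rng = np.random.default_rng(seed)

    def t_map(x):
        m = x.mean(axis=0)
        se = x.std(axis=0, ddof=1) / np.sqrt(n_subj)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, m / se, 0.0)
        return t

    def clusters_of(t):
        labels = np.zeros(t.shape, dtype=int)
        out = []
        next_id = 1
        for sign in (1, -1):
            lab, n = ndimage.label(sign * t > t_crit, structure=_CONN8)
            for k in range(1, n + 1):
                mask = lab == k
                labels[mask] = next_id
                stat = int(mask.sum()) if statistic == "size" \
                    else float(np.abs(t[mask]).sum())
                out.append((next_id, sign, stat, mask))
                next_id += 1
        return labels, out

    t_obs = t_map(maps)
    labels, clus = clusters_of(t_obs)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        tp = t_map(maps * flips[:, None, None])
        _, pclus = clusters_of(tp)
        if pclus:
            null_max[i] = max(c[2] for c in pclus)
    rows, pvals = [], []
    for cid, sign, stat, mask in clus:
        p = (np.sum(null_max >= stat) + 1.0) / (n_perm + 1.0)
        fsel = np.where(mask.any(axis=1))[0]
        tsel = np.where(mask.any(axis=0))[0]
        rows.append({
            "cluster_id": cid, "sign": sign, "stat": stat,
            "freq_lo_idx": int(fsel.min()), "freq_hi_idx": int(fsel.max()),
            "time_lo_idx": int(tsel.min()), "time_hi_idx": int(tsel.max()),
            "p": p,
        })
        pvals.append(p)
    return ClusterResult(
        stat_map=t_obs, cluster_masks=labels,
        cluster_stats=pd.DataFrame(
            rows, columns=["cluster_id", "sign", "stat", "freq_lo_idx",
                           "freq_hi_idx", "time_lo_idx", "time_hi_idx", "p"]),
        p_values=np.asarray(pvals), n_permutations=n_perm, alpha=alpha,
    )


def condition_contrast(maps_a: np.ndarray, maps_b: np.ndarray,
                       subjects_a=None, subjects_b=None) -> np.ndarray:
    """Per-subject A-B difference maps for the paired cluster design."""
    maps_a, maps_b = np.asarray(maps_a, float), np.asarray(maps_b, float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("condition map stacks must have matching shapes")
    if subjects_a is not None and list(subjects_a) != list(subjects_b):
        raise ValueError("subject lists differ between conditions")
    return maps_a - maps_b


def choice_contrast_maps(tf: TFMap, choices: np.ndarray) -> np.ndarray:
    """Mean power for "long"-response minus "short"-response trials."""
    choices = np.asarray(choices)
    is_long = choices == "long"
    if is_long.all() or (~is_long).all():
        raise ValueError("need both response categories")
    return tf.power[is_long].mean(axis=0) - tf.power[~is_long].mean(axis=0)
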