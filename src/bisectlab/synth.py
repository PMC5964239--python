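"""Synthetic bisection behavior and EEG epochs from the two-stage model.

Stage one is a noisy temporal accumulator: during a stimulus of duration
T it integrates dx = A dt + m sqrt(A) dB, so the endpoint x(T) has mean
A*T and variance m^2*A*T — the scalar-timing property that longer
intervals are remembered more variably.  With the rate normalized to the
criterion duration (A = 1/boundary_ref) the endpoint is 1 at the
categorical boundary.

Stage two is the decision diffusion of :mod:`bisectlab.ddm`: the stage-one
endpoint sets the starting point (affine map with clipping) and, compared
against the current categorical boundary, the drift direction.  The
boundary itself can leak toward the previous trial's duration
(``carryover_gain``), which produces the bisection-point carryover
pattern the sequential analyses measure.

The EEG generator implants a band-limited oscillation whose single-trial
power is linear in a chosen regressor (present or prior duration) on top
of 1/f background noise, for end-to-end testing of the time-frequency
regression and cluster statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ddm import DDMParams
from ._wfpt import simulate_paths
from .eeg import Epochs


@dataclass(frozen=True)
class FirstStageParams:
    """Accumulator rate A (1/s), noise coefficient m, criterion (s)."""

    A: float
    m: float
    boundary_ref: float = 0.52

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("accumulation rate A must be positive")
        if self.m < 0:
            raise ValueError("noise coefficient m must be non-negative")


@dataclass(frozen=True)
class GenerativeSpec:
    """Full generative chain for one bisection dataset.

    ``decision`` supplies the baseline decision parameters; per-trial
    drift and starting point are derived from the stage-one endpoint:
    z = clip(0.5 + kappa*(x - 1), 0.05, 0.95) and
    v = v_scale*(x - A*boundary).  ``a_mod`` raises the boundary
    separation with the expected distance from the criterion, so the
    separation dips for mid-range durations, and ``t0_slope`` lets
    non-decision time fall linearly with duration.
    ``carryover_gain`` leaks the categorical boundary toward the prior
    trial's duration.
    """

    first_stage: FirstStageParams
    decision: DDMParams
    carryover_gain: float = 0.0
    rt_floor: float = 0.0
    seed: int = 0
    kappa: float = 0.35
    v_scale: float = 4.0
    a_mod: float = 0.4
    t0_slope: float = -0.1
    z_clip: tuple = (0.05, 0.95)
    learning_rate: float = 0.0  # optional delta-rule update of A

    def __post_init__(self) -> None:
        if not 0.0 <= self.carryover_gain <= 1.0:
            raise ValueError("carryover_gain must lie in [0, 1]")
        if self.rt_floor < 0:
            raise ValueError("rt_floor must be non-negative")


def default_generative_spec(seed: int = 0, carryover_gain: float = 0.0,
                            **overrides) -> GenerativeSpec:
    """Reference generative settings for the 300-900 ms bisection task."""
    fs = FirstStageParams(A=1.0 / 0.52, m=0.2, boundary_ref=0.52)
    dec = DDMParams(a=1.1, v=0.0, t0=0.25, z=0.5, sz=0.0)
    return GenerativeSpec(first_stage=fs, decision=dec,
                          carryover_gain=carryover_gain, seed=seed, **overrides)


def simulate_first_stage(params: FirstStageParams, T: float, dt: float,
                         rng: np.random.Generator, n: int = 1):
    """Euler-Maruyama endpoint(s) x(T) of the stage-one accumulator.

    The step is adjusted to divide T exactly, so with m = 0 the endpoint
    is A*T to machine precision.  Returns a scalar for n=1.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if dt <= 0 or dt > T:
        raise ValueError("require 0 < dt <= T")
    n_steps = max(1, round(T / dt))
    dt_eff = T / n_steps
    x = np.full(n, 0.0)
    scale = params.m * np.sqrt(params.A)
    for _ in range(n_steps):
        x = x + params.A * dt_eff + scale * np.sqrt(dt_eff) * rng.standard_normal(n)
    return float(x[0]) if n == 1 else x


def simulate_decision(params: DDMParams, rng: np.random.Generator,
                      n: int = 1, dt: float = 1e-3):
    """First-passage simulation of the decision stage.

    Returns (choice, decision_time) — scalars for n=1, arrays otherwise.
    Choice is "long" for upper-boundary absorption; decision time does
    not include t0.
    """
    hit, t = simulate_paths(
        np.full(n, params.v), np.full(n, params.a), np.full(n, params.z),
        dt, 30.0, int(rng.integers(2**31)),
    )
    choice = np.where(hit, "long", "short")
    if n == 1:
        return str(choice[0]), float(t[0])
    return choice, t


def simulate_bisection_dataset(design: pd.DataFrame, spec: GenerativeSpec,
                               dt: float = 1e-3) -> pd.DataFrame:
    """Fill a designed trial table with simulated choices and RTs.

    The categorical boundary starts at ``first_stage.boundary_ref`` and,
    when ``carryover_gain`` g > 0, is updated after every stimulus trial
    as boundary <- (1-g)*boundary + g*duration, so the decision on each
    trial is referenced to a criterion pulled toward recent history.
    """
    if spec.carryover_gain > 0 and design["prior_duration_s"].isna().all() \
            and len(design) > 1:
        raise ValueError(
            "carryover_gain > 0 requires transition-annotated designs")
    rng = np.random.default_rng(spec.seed)
    fs = spec.first_stage
    out = design.copy().reset_index(drop=True)
    n = len(out)
    durations = out["duration_s"].to_numpy(dtype=float)
    # stage-one endpoints: the Euler-Maruyama endpoint is exactly
    # Gaussian, so sample it directly from its law N(A*T, m^2*A*T)
    x = fs.A * durations + fs.m * np.sqrt(fs.A * durations) * rng.standard_normal(n)
    boundary = fs.boundary_ref
    g = spec.carryover_gain
    v = np.empty(n)
    a = np.empty(n)
    t0 = np.empty(n)
    z = np.empty(n)
    for i in range(n):
        z[i] = np.clip(0.5 + spec.kappa * (x[i] - 1.0), *spec.z_clip)
        v[i] = spec.v_scale * (x[i] - fs.A * boundary)
        a[i] = spec.decision.a + spec.a_mod * abs(fs.A * durations[i] - 1.0)
        t0[i] = max(0.01, spec.decision.t0
                    + spec.t0_slope * (durations[i] - fs.boundary_ref))
        if g > 0:
            boundary = (1.0 - g) * boundary + g * durations[i]
    hit, t_dec = simulate_paths(v, a, z, dt, 30.0, int(rng.integers(2**31)))
    out["choice"] = np.where(hit, "long", "short")
    out["rt_s"] = t_dec + t0 + spec.rt_floor
    return out


def simulate_subjects(
    n_subjects: int,
    design: pd.DataFrame,
    spec: GenerativeSpec,
    subject_sd: dict | None = None,
) -> pd.DataFrame:
    """Stack datasets for several subjects with jittered generative settings.

    ``subject_sd`` gives the between-subject SD of selected generative
    fields (default: a 0.1, t0 0.02, kappa 0.04).  Each subject draws an
    independent simulation seed from ``spec.seed``.
    """
    sd = {"a": 0.1, "t0": 0.02, "kappa": 0.04}
    if subject_sd:
        sd.update(subject_sd)
    rng = np.random.default_rng(spec.seed)
    frames = []
    from dataclasses import replace
    for s in range(n_subjects):
        dec = replace(
            spec.decision,
            a=max(0.3, spec.decision.a + sd["a"] * rng.standard_normal()),
            t0=max(0.05, spec.decision.t0 + sd["t0"] * rng.standard_normal()),
        )
        sub_spec = replace(
            spec, decision=dec,
            kappa=max(0.05, spec.kappa + sd["kappa"] * rng.standard_normal()),
            seed=int(rng.integers(2**31)),
        )
        df = simulate_bisection_dataset(design, sub_spec)
        df.insert(0, "subject", f"s{s:02d}")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# EEG epochs


@dataclass(frozen=True)
class EEGEffectSpec:
    """Implanted band-power effect riding on 1/f background noise."""

    n_trials: int = 70
    n_channels: int = 4
    sample_rate: float = 250.0
    epoch_window: tuple = (-0.4, 1.0)
    effect_band: tuple = (17.0, 23.0)
    effect_window: tuple = (0.3, 0.9)
    slope_per_second: float = 1.0
    noise_exponent: float = 1.0
    snr: float = 0.5

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window
        if not t0 < 0 < t1:
            raise ValueError("epoch window must straddle stimulus onset")
        e0, e1 = self.effect_window
        if e0 < t0 or e1 > t1:
            raise ValueError("effect window must lie inside the epoch")


def _one_over_f_noise(shape, exponent, sample_rate, rng):
    """Gaussian noise with amplitude spectrum f^(-exponent/2), unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    amp = np.ones_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def simulate_eeg_epochs(
    spec: EEGEffectSpec,
    durations: np.ndarray,
    rng: np.random.Generator | int | None = None,
    prior_durations: np.ndarray | None = None,
    regressor: str = "present_duration",
) -> Epochs:
    """Simulate epochs whose band power covaries with a duration regressor.

    Oscillatory bursts at the center of ``effect_band``, Hann-windowed
    over ``effect_window``, are added to unit-variance 1/f noise.  The
    single-trial oscillation power is snr*(1 + slope_per_second*(r - r̄))
    with r the chosen regressor, clipped at zero, so a per-pixel
    regression of wavelet power on r recovers a positive slope inside
    the implanted region.  A Gaussian channel topography (stored in the
    metadata) weights the effect across channels.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) != spec.n_trials:
        raise ValueError("durations length must equal n_trials")
    if prior_durations is not None and len(prior_durations) != spec.n_trials:
        raise ValueError("prior_durations length must equal n_trials")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reg = durations if regressor == "present_duration" else prior_durations
    if reg is None:
        raise ValueError("prior_durations required for regressor='prior_duration'")
    t0, t1 = spec.epoch_window
    n_times = int(round((t1 - t0) * spec.sample_rate))
    times = t0 + np.arange(n_times) / spec.sample_rate
    data = _one_over_f_noise(
        (spec.n_channels, spec.n_trials, n_times), spec.noise_exponent,
        spec.sample_rate, rng,
    )
    f_osc = 0.5 * (spec.effect_band[0] + spec.effect_band[1])
    e0, e1 = spec.effect_window
    env = np.zeros(n_times)
    inside = (times >= e0) & (times <= e1)
    env[inside] = np.hanning(inside.sum())
    topo = np.exp(-0.5 * ((np.arange(spec.n_channels)
                           - (spec.n_channels - 1) / 2) / 1.5) ** 2)
    power = np.clip(spec.snr * (1.0 + spec.slope_per_second * (reg - reg.mean())), 0.0, None)
    phase = rng.uniform(0, 2 * np.pi, spec.n_trials)
    osc = np.sin(2 * np.pi * f_osc * times[None, :] + phase[:, None]) * env[None, :]
    data += (topo[:, None, None] * np.sqrt(2.0 * power)[None, :, None]
             * osc[None, :, :])
    meta = pd.DataFrame({
        "duration_s": durations,
        "prior_duration_s": (prior_durations if prior_durations is not None
                             else np.full(spec.n_trials, np.nan)),
    })
    info = {
        "effect_spec": asdict(spec),
        "topography": topo.tolist(),
        "oscillation_hz": f_osc,
    }
    return Epochs(
        data=np.transpose(data, (0, 2, 1)).astype(np.float32),
        sample_rate=spec.sample_rate,
        window=spec.epoch_window,
        trial_meta=meta,
        channel_names=[f"ch{i}" for i in range(spec.n_channels)],
        info=info,
    )
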