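"""Second-stage decision diffusion: likelihood, hierarchical fit, diagnostics.

The decision stage of the two-stage timing model is a standard Wiener
diffusion between a lower ("short") and upper ("long") boundary separated
by ``a``, starting at relative position ``z``, drifting at ``v`` (positive
toward "long"), with non-decision time ``t0`` and uniform starting-point
variability of range ``sz``.  The diffusion coefficient is fixed at 1; all
other parameters absorb the scale.

Estimation is hierarchical Bayes: subject-level parameters are drawn from
truncated-normal group distributions and sampled with adaptive
random-walk Metropolis-within-Gibbs.  Convergence is diagnosed with a
between/within-chain variance-ratio statistic, models are compared with
the deviance information criterion, and fits are validated by posterior
predictive simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import ndtr

from ._wfpt import (
    GL_NODES,
    GL_WEIGHTS,
    loglik_trials,
    prob_upper,
    simulate_paths,
    wfpt_pdf,
)

PARAM_NAMES = ("a", "v", "t0", "z")

# admissible sampling regions and weakly-informative group priors
_BOUNDS = {
    "a": (0.1, 5.0),
    "v": (-12.0, 12.0),
    "t0": (0.005, 0.8),
    "z": (0.03, 0.97),
    "sz": (0.0, 0.5),
}
_MU_PRIOR = {  # (mean, sd) of the normal prior on the group mean
    "a": (1.5, 1.5),
    "v": (0.0, 3.0),
    "t0": (0.3, 0.3),
    "z": (0.5, 0.3),
    "sz": (0.1, 0.2),
}
_SIGMA_SCALE = {  # half-normal scale of the group sd prior
    "a": 0.5,
    "v": 1.0,
    "t0": 0.15,
    "z": 0.15,
    "sz": 0.1,
}


@dataclass(frozen=True)
class DDMParams:
    """Decision-stage parameters (diffusion coefficient fixed at 1)."""

    a: float
    v: float
    t0: float
    z: float = 0.5
    sz: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be non-negative")
        if not 0 < self.z < 1:
            raise ValueError("relative starting point z must lie in (0, 1)")
        if self.sz < 0 or self.z - self.sz / 2 <= 0 or self.z + self.sz / 2 >= 1:
            raise ValueError("sz must be >= 0 with z +/- sz/2 inside (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Which factors each parameter varies by, and MCMC settings."""

    varies_by: dict = field(default_factory=dict)
    n_chains: int = 4
    n_samples: int = 5000
    n_burn: int = 2000
    seed: int = 0
    fit_sz: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_samples < 1 or self.n_burn < 0:
            raise ValueError("samples must be positive and burn non-negative")
        for p, factors in self.varies_by.items():
            if p not in PARAM_NAMES + ("sz",):
                raise ValueError(f"unknown parameter {p!r}")
            for f in factors:
                if f not in ("duration", "phase", "session"):
                    raise ValueError(f"unknown factor {f!r}")


def wfpt_density(t, boundary: str, params: DDMParams, err: float = 1e-10):
    """Defective first-passage density at the named boundary at clock time t.

    ``t`` includes the non-decision time; the density is zero for
    t <= t0.  With sz > 0 the density is averaged over the uniform
    starting-point range by Gauss-Legendre quadrature.
    """
    if boundary not in ("short", "long"):
        raise ValueError("boundary must be 'short' or 'long'")
    upper = boundary == "long"
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    for i, ti in enumerate(t):
        td = ti - params.t0
        if td <= 0:
            continue
        if params.sz <= 0:
            out[i] = wfpt_pdf(td, upper, params.v, params.a, params.z, err)
        else:
            acc = 0.0
            for xq, wq in zip(GL_NODES, GL_WEIGHTS):
                acc += wq * wfpt_pdf(
                    td, upper, params.v, params.a, params.z + params.sz * xq, err
                )
            out[i] = acc
    return float(out[0]) if scalar else out


def boundary_mass(boundary: str, params: DDMParams) -> float:
    """Closed-form total absorption probability at the named boundary."""
    p_long = prob_upper(params.v, params.a, params.z)
    return p_long if boundary == "long" else 1.0 - p_long


def boundary_mass_numeric(boundary: str, params: DDMParams, t_max: float = 80.0) -> float:
    """Numerically integrated boundary mass (oracle for the closed form)."""
    return quad(
        lambda t: wfpt_density(t, boundary, params), params.t0, params.t0 + t_max,
        limit=300,
    )[0]


def _param_arrays(trials: pd.DataFrame, params: dict, cells: dict) -> dict:
    """Expand per-cell parameter values into per-trial arrays."""
    out = {}
    for p in params:
        idx = cells[p]["trial_cell"]
        out[p] = np.asarray(params[p], dtype=float)[idx]
    return out


def loglik(
    trials: pd.DataFrame,
    params: DDMParams | dict,
    cells: dict | None = None,
    err: float = 1e-8,
) -> float:
    """Summed log-likelihood of choices and RTs under the diffusion model.

    ``params`` is either a single :class:`DDMParams` applied to every
    trial, or a dict of per-cell value arrays accompanied by ``cells``
    (per-parameter trial->cell index maps, as built by the fitter).
    Returns 0.0 for an empty table; -inf (with a diagnostic warning) if
    any RT is at or below its trial's non-decision time.
    """
    if len(trials) == 0:
        return 0.0
    rt = trials["rt_s"].to_numpy(dtype=float)
    is_long = (trials["choice"].to_numpy() == "long").astype(np.bool_)
    n = len(rt)
    if isinstance(params, DDMParams):
        arrs = {
            "a": np.full(n, params.a),
            "v": np.full(n, params.v),
            "t0": np.full(n, params.t0),
            "z": np.full(n, params.z),
            "sz": np.full(n, params.sz),
        }
    else:
        arrs = _param_arrays(trials, params, cells)
        arrs.setdefault("sz", np.zeros(n))
    bad = rt <= arrs["t0"]
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} trial(s) with RT <= t0 (indices "
            f"{list(np.flatnonzero(bad)[:10])}); log-likelihood is -inf"
        )
        return -np.inf
    ll = loglik_trials(
        rt, is_long, arrs["v"], arrs["a"], arrs["t0"], arrs["z"], arrs["sz"],
        GL_NODES, GL_WEIGHTS, err,
    )
    return float(ll.sum())


def gelman_rubin(chains) -> float | dict:
    """Between/within-chain variance-ratio convergence statistic.

    ``chains`` is an (n_chains, n_samples) array, or a dict of such
    arrays (a dict is returned in kind).  The statistic is
    sqrt(1 + (B/n)/W): exactly 1 for identical chains, > 1 when chain
    means disagree relative to within-chain spread.
    """
    if isinstance(chains, dict):
        return {k: gelman_rubin(v) for k, v in chains.items()}
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = x.shape[1]
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0 if b_over_n == 0 else np.inf
    return float(np.sqrt(1.0 + b_over_n / w))


# --------------------------------------------------------------------------
# hierarchical sampler

def _build_cells(trials: pd.DataFrame, varies_by: dict, fit_sz: bool) -> dict:
    """Per-parameter cell structure: trial->cell index and cell labels."""
    factor_col = {"duration": "duration_s", "phase": "phase", "session": "session"}
    cells = {}
    names = PARAM_NAMES + (("sz",) if fit_sz else ())
    for p in names:
        factors = tuple(varies_by.get(p, ()))
        if not factors:
            cells[p] = {
                "labels": [()],
                "trial_cell": np.zeros(len(trials), dtype=np.int64),
            }
            continue
        cols = [factor_col[f] for f in factors]
        key = pd.MultiIndex.from_frame(trials[cols])
        labels = sorted(key.unique())
        lut = {lab: i for i, lab in enumerate(labels)}
        cells[p] = {
            "labels": labels,
            "trial_cell": np.asarray([lut[k] for k in key], dtype=np.int64),
        }
    return cells


@dataclass
class PosteriorSummary:
    """Posterior tables, convergence diagnostics and model-fit metrics."""

    group: pd.DataFrame
    subject: pd.DataFrame
    rhat: dict
    dic: float
    pd_eff: float
    converged: bool
    traces: dict = field(repr=False, default_factory=dict)
    deviance_trace: np.ndarray = field(repr=False, default=None)
    spec: ModelSpec = None
    cells: dict = field(repr=False, default_factory=dict)
    subjects: list = field(default_factory=list)
    data: pd.DataFrame = field(repr=False, default=None)


class _SubjectData:
    __slots__ = ("rt", "is_long", "cell_idx", "cell_trials", "min_rt",
                 "min_rt_t0_cell")

    def __init__(self, df: pd.DataFrame, cells: dict, row_index: np.ndarray):
        self.rt = df["rt_s"].to_numpy(dtype=float)
        self.is_long = (df["choice"].to_numpy() == "long").astype(np.bool_)
        self.min_rt = float(self.rt.min())
        self.cell_idx = {p: cells[p]["trial_cell"][row_index] for p in cells}
        # trial indices per cell, for slice updates
        self.cell_trials = {
            p: [np.flatnonzero(self.cell_idx[p] == c) for c in range(len(cells[p]["labels"]))]
            for p in cells
        }
        # t0 in a cell is bounded by the fastest RT in that cell only
        self.min_rt_t0_cell = [
            float(self.rt[rows].min()) if len(rows) else np.inf
            for rows in self.cell_trials["t0"]
        ]


def _halfnorm_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2 - math.log(scale)


def _truncnorm_logpdf(x: float, mu: float, sd: float, lo: float, hi: float) -> float:
    if x <= lo or x >= hi:
        return -np.inf
    zn = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
    if zn <= 0:
        return -np.inf
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - math.log(zn)


class _Sampler:
    """One MCMC chain over subject- and group-level parameters."""

    def __init__(self, subjects, cells, spec, rng, err=1e-7):
        self.subjects = subjects
        self.cells = cells
        self.spec = spec
        self.rng = rng
        self.err = err
        self.pnames = list(cells)
        self.n_subj = len(subjects)
        # overdispersed init
        self.mu = {}
        self.sigma = {}
        self.theta = {}
        start = {"a": 1.5, "v": 0.0, "t0": 0.15, "z": 0.5, "sz": 0.1}
        for p in self.pnames:
            nc = len(cells[p]["labels"])
            lo, hi = _BOUNDS[p]
            jitter = {"a": 0.4, "v": 0.8, "t0": 0.05, "z": 0.1, "sz": 0.05}[p]
            self.mu[p] = np.clip(
                start[p] + jitter * rng.standard_normal(nc), lo + 1e-3, hi - 1e-3
            )
            self.sigma[p] = np.full(nc, _SIGMA_SCALE[p] / 2) * np.exp(
                0.3 * rng.standard_normal(nc)
            )
            self.theta[p] = np.clip(
                self.mu[p][None, :] + 0.5 * self.sigma[p][None, :]
                * rng.standard_normal((self.n_subj, nc)),
                lo + 1e-3,
                hi - 1e-3,
            )
        # per-subject t0 cannot exceed the fastest RT of its cell
        for s, sub in enumerate(self.subjects):
            self.theta["t0"][s] = np.minimum(
                self.theta["t0"][s], 0.9 * np.asarray(sub.min_rt_t0_cell))
        self.prop = {
            p: np.full((self.n_subj, len(cells[p]["labels"])),
                       {"a": 0.15, "v": 0.3, "t0": 0.02, "z": 0.05, "sz": 0.05}[p])
            for p in self.pnames
        }
        self.prop_mu = {p: np.full(len(cells[p]["labels"]), 0.1) for p in self.pnames}
        self.prop_sig = {p: np.full(len(cells[p]["labels"]), 0.3) for p in self.pnames}
        self.ll = [self._subject_ll(s) for s in range(self.n_subj)]

    def _trial_arrays(self, s: int, rows=None):
        sub = self.subjects[s]
        sel = slice(None) if rows is None else rows
        arrs = {}
        for p in self.pnames:
            arrs[p] = self.theta[p][s][sub.cell_idx[p][sel]]
        if "sz" not in arrs:
            arrs["sz"] = np.zeros(len(sub.rt) if rows is None else len(rows))
        return arrs

    def _subject_ll(self, s: int, rows=None) -> np.ndarray:
        sub = self.subjects[s]
        arrs = self._trial_arrays(s, rows)
        sel = slice(None) if rows is None else rows
        return loglik_trials(
            sub.rt[sel], sub.is_long[sel], arrs["v"], arrs["a"], arrs["t0"],
            arrs["z"], arrs["sz"], GL_NODES, GL_WEIGHTS, self.err,
        )

    def _bounds_for(self, p: str, s: int, c: int = 0) -> tuple[float, float]:
        lo, hi = _BOUNDS[p]
        if p == "t0":
            hi = min(hi, self.subjects[s].min_rt_t0_cell[c] - 1e-4)
        return lo, hi

    def sweep(self, adapt: bool):
        rng = self.rng
        accept_rate = 0.35
        for p in self.pnames:
            nc = len(self.cells[p]["labels"])
            for s in range(self.n_subj):
                sub = self.subjects[s]
                for c in range(nc):
                    rows = sub.cell_trials[p][c]
                    cur = self.theta[p][s, c]
                    lo, hi = self._bounds_for(p, s, c)
                    prop_sd = self.prop[p][s, c]
                    cand = cur + prop_sd * rng.standard_normal()
                    lp_cur = _truncnorm_logpdf(
                        cur, self.mu[p][c], self.sigma[p][c], lo, hi)
                    lp_cand = _truncnorm_logpdf(
                        cand, self.mu[p][c], self.sigma[p][c], lo, hi)
                    accepted = False
                    if np.isfinite(lp_cand):
                        ll_cur = self.ll[s][rows].sum() if len(rows) else 0.0
                        self.theta[p][s, c] = cand
                        ll_new = self._subject_ll(s, rows) if len(rows) else np.zeros(0)
                        delta = (ll_new.sum() - ll_cur) + (lp_cand - lp_cur)
                        if np.log(rng.random()) < delta:
                            self.ll[s][rows] = ll_new
                            accepted = True
                        else:
                            self.theta[p][s, c] = cur
                    if adapt:
                        self.prop[p][s, c] *= np.exp(
                            0.05 * ((1.0 if accepted else 0.0) - accept_rate))
            # group-level updates (no data likelihood, subject values only)
            for c in range(nc):
                self._update_group(p, c, adapt)

    def _group_logpost(self, p: str, mu: float, sigma: float, vals) -> float:
        lo, hi = _BOUNDS[p]
        mu_m, mu_s = _MU_PRIOR[p]
        lp = -0.5 * ((mu - mu_m) / mu_s) ** 2
        lp += _halfnorm_logpdf(sigma, _SIGMA_SCALE[p])
        if not np.isfinite(lp):
            return -np.inf
        zn = ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma)
        if zn <= 0:
            return -np.inf
        lp += np.sum(-0.5 * ((vals - mu) / sigma) ** 2) \
            - len(vals) * (math.log(sigma) + math.log(zn))
        return lp

    def _update_group(self, p: str, c: int, adapt: bool):
        rng = self.rng
        vals = self.theta[p][:, c]
        accept_rate = 0.44
        # mean
        cur_lp = self._group_logpost(p, self.mu[p][c], self.sigma[p][c], vals)
        cand = self.mu[p][c] + self.prop_mu[p][c] * rng.standard_normal()
        cand_lp = self._group_logpost(p, cand, self.sigma[p][c], vals)
        acc = np.isfinite(cand_lp) and np.log(rng.random()) < cand_lp - cur_lp
        if acc:
            self.mu[p][c] = cand
            cur_lp = cand_lp
        if adapt:
            self.prop_mu[p][c] *= np.exp(0.05 * ((1.0 if acc else 0.0) - accept_rate))
        # scale, random walk on the log (with Jacobian)
        step = self.prop_sig[p][c] * rng.standard_normal()
        cand_sig = self.sigma[p][c] * math.exp(step)
        cand_lp = self._group_logpost(p, self.mu[p][c], cand_sig, vals) \
            + math.log(cand_sig / self.sigma[p][c])
        acc = np.isfinite(cand_lp) and np.log(rng.random()) < cand_lp - cur_lp
        if acc:
            self.sigma[p][c] = cand_sig
        if adapt:
            self.prop_sig[p][c] *= np.exp(0.05 * ((1.0 if acc else 0.0) - accept_rate))

    def deviance(self) -> float:
        return -2.0 * sum(l.sum() for l in self.ll)


def fit_hierarchical(trials: pd.DataFrame, spec: ModelSpec) -> PosteriorSummary:
    """Hierarchical Bayesian fit of the decision diffusion across subjects.

    ``trials`` must have columns subject, duration_s, choice, rt_s (plus
    phase/session when referenced by ``spec.varies_by``).  Subject-level
    parameters are pooled through truncated-normal group distributions;
    chains are initialized overdispersed and the fit is reproducible for
    a fixed ``spec.seed``.  A fit with any group-level rhat > 1.1 is
    returned with ``converged=False``.
    """
    subjects_ids = sorted(trials["subject"].unique())
    if len(subjects_ids) < 2:
        raise ValueError("hierarchical fit requires >= 2 subjects")
    cells = _build_cells(trials, spec.varies_by, spec.fit_sz)
    subs = []
    for sid in subjects_ids:
        mask = (trials["subject"] == sid).to_numpy()
        subs.append(_SubjectData(trials[mask], cells, np.flatnonzero(mask)))

    keep = spec.n_samples - spec.n_burn
    if keep <= 0:
        raise ValueError("n_samples must exceed n_burn")
    pnames = list(cells)
    traces: dict[str, np.ndarray] = {}
    subj_traces: dict[str, np.ndarray] = {}
    dev_trace = np.empty((spec.n_chains, keep))
    for ch in range(spec.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) % (2**31), ch]))
        smp = _Sampler(subs, cells, spec, rng)
        for it in range(spec.n_samples):
            smp.sweep(adapt=it < spec.n_burn)
            if it >= spec.n_burn:
                k = it - spec.n_burn
                for p in pnames:
                    for c, lab in enumerate(cells[p]["labels"]):
                        name = _pname(p, lab)
                        traces.setdefault(
                            name, np.empty((spec.n_chains, keep)))[ch, k] = smp.mu[p][c]
                        traces.setdefault(
                            name + "_sd", np.empty((spec.n_chains, keep)))[ch, k] = smp.sigma[p][c]
                        for s in range(len(subs)):
                            subj_traces.setdefault(
                                f"{name}[s{s}]", np.empty((spec.n_chains, keep))
                            )[ch, k] = smp.theta[p][s, c]
                dev_trace[ch, k] = smp.deviance()

    rhat = {k: gelman_rubin(v) for k, v in traces.items()} if spec.n_chains > 1 else {}
    group_rows = []
    for name, tr in traces.items():
        flat = tr.ravel()
        group_rows.append({
            "name": name, "mean": flat.mean(), "sd": flat.std(ddof=1),
            "q2.5": np.quantile(flat, 0.025), "q50": np.quantile(flat, 0.5),
            "q97.5": np.quantile(flat, 0.975), "rhat": rhat.get(name, np.nan),
        })
    subj_rows = []
    for name, tr in subj_traces.items():
        flat = tr.ravel()
        subj_rows.append({
            "name": name, "mean": flat.mean(), "sd": flat.std(ddof=1),
            "q2.5": np.quantile(flat, 0.025), "q97.5": np.quantile(flat, 0.975),
        })
    group = pd.DataFrame(group_rows).set_index("name")
    subject = pd.DataFrame(subj_rows).set_index("name")

    # DIC: mean deviance plus effective parameter count
    d_bar = float(dev_trace.mean())
    theta_bar = {
        p: np.array([
            [subject.loc[f"{_pname(p, lab)}[s{s}]", "mean"]
             for c, lab in enumerate(cells[p]["labels"])]
            for s in range(len(subs))
        ])
        for p in pnames
    }
    d_hat = 0.0
    for s, sub in enumerate(subs):
        arrs = {p: theta_bar[p][s][sub.cell_idx[p]] for p in pnames}
        if "sz" not in arrs:
            arrs["sz"] = np.zeros(len(sub.rt))
        d_hat += -2.0 * loglik_trials(
            sub.rt, sub.is_long, arrs["v"], arrs["a"], arrs["t0"], arrs["z"],
            arrs["sz"], GL_NODES, GL_WEIGHTS, 1e-7,
        ).sum()
    pd_eff = d_bar - float(d_hat)
    dic_val = d_bar + pd_eff

    converged = all(r <= 1.1 for r in rhat.values()) if rhat else True
    if not converged:
        warnings.warn("fit did not converge: max rhat = %.3f" % max(rhat.values()))
    return PosteriorSummary(
        group=group, subject=subject, rhat=rhat, dic=dic_val, pd_eff=pd_eff,
        converged=converged, traces=traces, deviance_trace=dev_trace, spec=spec,
        cells=cells, subjects=subjects_ids, data=trials,
    )


def _pname(p: str, label) -> str:
    if label == ():
        return p
    return p + "(" + ",".join(str(x) for x in label) + ")"


def dic(fit: PosteriorSummary) -> float:
    """Deviance information criterion of a hierarchical fit."""
    if not fit.converged:
        warnings.warn("DIC computed on a non-converged fit")
    return fit.dic


def posterior_predictive(
    fit: PosteriorSummary,
    n_datasets: int = 500,
    seed: int = 0,
    quantiles=(0.1, 0.5, 0.9),
) -> dict:
    """Simulate datasets at posterior-mean parameters and compare patterns.

    For every duration level, the observed proportion of "long" choices
    and RT quantiles are compared with the 2.5-97.5% envelope across
    ``n_datasets`` simulated datasets.  Returns observed statistics, the
    envelopes, and the fraction of statistics falling inside.
    """
    data = fit.data
    durations = np.sort(data["duration_s"].unique())
    obs_prop = np.array([
        (data.loc[data["duration_s"] == d, "choice"] == "long").mean()
        for d in durations
    ])
    obs_rtq = np.array([
        np.quantile(data.loc[data["duration_s"] == d, "rt_s"], quantiles)
        for d in durations
    ])

    theta = {
        p: {
            (s, lab): fit.subject.loc[f"{_pname(p, lab)}[s{i}]", "mean"]
            for i, s in enumerate(fit.subjects)
            for lab in fit.cells[p]["labels"]
        }
        for p in fit.cells
    }
    sim_prop = np.empty((n_datasets, len(durations)))
    sim_rtq = np.empty((n_datasets, len(durations), len(quantiles)))
    rng = np.random.default_rng(seed)
    # per-trial parameter arrays are fixed at posterior means; only the
    # diffusion noise is re-drawn per dataset
    v = np.empty(len(data))
    a = np.empty(len(data))
    t0 = np.empty(len(data))
    z = np.empty(len(data))
    for p, arr in (("v", v), ("a", a), ("t0", t0), ("z", z)):
        cell_idx = fit.cells[p]["trial_cell"]
        labels = fit.cells[p]["labels"]
        for i, (sid, ci) in enumerate(zip(data["subject"], cell_idx)):
            arr[i] = theta[p][(sid, labels[ci])]
    dvals = data["duration_s"].to_numpy()
    for k in range(n_datasets):
        hit, t = simulate_paths(v, a, z, 1e-3, 20.0, int(rng.integers(2**31)))
        rt = t + t0
        for j, d in enumerate(durations):
            m = dvals == d
            sim_prop[k, j] = hit[m].mean()
            sim_rtq[k, j] = np.quantile(rt[m], quantiles)
    prop_lo, prop_hi = np.quantile(sim_prop, [0.025, 0.975], axis=0)
    rtq_lo, rtq_hi = np.quantile(sim_rtq, [0.025, 0.975], axis=0)
    inside = np.concatenate([
        ((obs_prop >= prop_lo) & (obs_prop <= prop_hi)),
        ((obs_rtq >= rtq_lo) & (obs_rtq <= rtq_hi)).ravel(),
    ])
    return {
        "n_datasets": n_datasets,
        "durations": durations,
        "observed_prop_long": obs_prop,
        "prop_envelope": (prop_lo, prop_hi),
        "observed_rt_quantiles": obs_rtq,
        "rt_envelope": (rtq_lo, rtq_hi),
        "fraction_inside": float(inside.mean()),
    }


def fit_mle(trials: pd.DataFrame, varies_by: dict | None = None) -> dict:
    """Per-subject maximum-likelihood fit (non-hierarchical fallback).

    Returns {subject: {param_name: value}} maximizing the summed WFPT
    log-likelihood with a Nelder-Mead search from a moment-based start.
    """
    from scipy.optimize import minimize

    varies_by = varies_by or {}
    out = {}
    for sid, df in trials.groupby("subject"):
        cells = _build_cells(df, varies_by, fit_sz=False)
        sub = _SubjectData(df, cells, np.arange(len(df)))
        sizes = {p: len(cells[p]["labels"]) for p in PARAM_NAMES}
        x0 = np.concatenate([
            np.full(sizes["a"], 1.5), np.zeros(sizes["v"]),
            np.full(sizes["t0"], 0.6 * sub.min_rt), np.full(sizes["z"], 0.5),
        ])

        def unpack(x):
            o, vals = 0, {}
            for p in PARAM_NAMES:
                vals[p] = x[o:o + sizes[p]]
                o += sizes[p]
            return vals

        def nll(x):
            vals = unpack(x)
            for p in PARAM_NAMES:
                lo, hi = _BOUNDS[p]
                hi = min(hi, sub.min_rt - 1e-4) if p == "t0" else hi
                if np.any(vals[p] <= lo) or np.any(vals[p] >= hi):
                    return 1e12
            arrs = {p: vals[p][sub.cell_idx[p]] for p in PARAM_NAMES}
            ll = loglik_trials(
                sub.rt, sub.is_long, arrs["v"], arrs["a"], arrs["t0"],
                arrs["z"], np.zeros(len(sub.rt)), GL_NODES, GL_WEIGHTS, 1e-7,
            ).sum()
            return -ll if np.isfinite(ll) else 1e12

        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-4, "fatol": 1e-4})
        vals = unpack(res.x)
        out[sid] = {
            _pname(p, lab): float(vals[p][c])
            for p in PARAM_NAMES
            for c, lab in enumerate(cells[p]["labels"])
        }
        out[sid]["_nll"] = float(res.fun)
    return out
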