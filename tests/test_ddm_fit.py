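"""Likelihood plumbing, MCMC diagnostics, DIC and posterior predictive."""

import numpy as np
import pandas as pd
import pytest

from bisectlab import ddm
from bisectlab._wfpt import simulate_paths


def _dataset(n_subj=4, n_trials=150, a=1.3, v=0.8, t0=0.25, z=0.55, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subj):
        hit, t = simulate_paths(np.full(n_trials, v), np.full(n_trials, a),
                                np.full(n_trials, z), 1e-3, 30.0,
                                int(rng.integers(2**31)))
        frames.append(pd.DataFrame({
            "subject": f"s{s}", "duration_s": 0.52,
            "choice": np.where(hit, "long", "short"), "rt_s": t + t0,
        }))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def small_fit():
    trials = _dataset(seed=31)
    spec = ddm.ModelSpec(n_chains=2, n_samples=500, n_burn=200, seed=5)
    return trials, ddm.fit_hierarchical(trials, spec)


class TestLoglik:
    def test_empty_table_is_zero(self):
        empty = pd.DataFrame(columns=["rt_s", "choice"])
        assert ddm.loglik(empty, ddm.DDMParams(1.5, 0.5, 0.2)) == 0.0

    def test_sz_zero_reduces_to_plain_product(self):
        trials = _dataset(n_subj=1, n_trials=50, seed=2)
        p0 = ddm.DDMParams(1.3, 0.8, 0.2, 0.55, sz=0.0)
        manual = sum(
            np.log(ddm.wfpt_density(rt, ch, p0))
            for rt, ch in zip(trials["rt_s"], trials["choice"])
        )
        assert ddm.loglik(trials, p0) == pytest.approx(manual, rel=1e-9)

    def test_rt_below_t0_gives_minus_inf_with_diagnostic(self):
        trials = _dataset(n_subj=1, n_trials=20, seed=3)
        bad = ddm.DDMParams(1.3, 0.8, t0=float(trials["rt_s"].min()) + 0.01)
        with pytest.warns(UserWarning, match="RT <= t0"):
            assert ddm.loglik(trials, bad) == -np.inf

    def test_generative_parameters_dominate_perturbed(self):
        hits = 0
        for s in range(10):
            trials = _dataset(n_subj=1, n_trials=300, seed=100 + s)
            base = ddm.loglik(trials, ddm.DDMParams(1.3, 0.8, 0.25, 0.55))
            worse = ddm.loglik(
                trials, ddm.DDMParams(1.3 * 1.2, 0.8 * 0.8, 0.25 * 0.8,
                                      min(0.95, 0.55 * 1.2)))
            hits += base > worse
        assert hits == 10


class TestGelmanRubin:
    def test_identical_chains_exactly_one(self):
        c = np.random.default_rng(0).standard_normal((1, 500))
        assert ddm.gelman_rubin(np.vstack([c, c])) == pytest.approx(1.0, abs=1e-12)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.standard_normal(1000), 5 + rng.standard_normal(1000)])
        assert ddm.gelman_rubin(x) > 1.5

    def test_independent_stationary_chains_near_one(self):
        rng = np.random.default_rng(2)
        good = sum(
            ddm.gelman_rubin(rng.standard_normal((2, 1000))) < 1.01
            for _ in range(100)
        )
        assert good >= 95

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            ddm.gelman_rubin(np.zeros((1, 100)))

    def test_dict_input_returns_dict(self):
        rng = np.random.default_rng(3)
        out = ddm.gelman_rubin({"a": rng.standard_normal((2, 100))})
        assert set(out) == {"a"}


class TestHierarchicalFit:
    def test_posterior_near_generative_values(self, small_fit):
        _, fit = small_fit
        assert fit.group.loc["a", "mean"] == pytest.approx(1.3, rel=0.15)
        assert fit.group.loc["v", "mean"] == pytest.approx(0.8, rel=0.35)
        assert fit.group.loc["t0", "mean"] == pytest.approx(0.25, abs=0.03)
        assert fit.group.loc["z", "mean"] == pytest.approx(0.55, abs=0.06)

    def test_reproducible_under_fixed_seed(self):
        trials = _dataset(n_subj=2, n_trials=60, seed=8)
        spec = ddm.ModelSpec(n_chains=2, n_samples=120, n_burn=50, seed=77)
        f1 = ddm.fit_hierarchical(trials, spec)
        f2 = ddm.fit_hierarchical(trials, spec)
        pd.testing.assert_frame_equal(f1.group, f2.group)
        assert f1.dic == f2.dic

    def test_requires_two_subjects(self):
        trials = _dataset(n_subj=1)
        with pytest.raises(ValueError):
            ddm.fit_hierarchical(trials, ddm.ModelSpec())

    def test_rhat_reported_per_group_parameter(self, small_fit):
        _, fit = small_fit
        assert {"a", "v", "t0", "z"} <= set(fit.rhat)
        assert all(r >= 1.0 - 1e-9 for r in fit.rhat.values())


class TestDIC:
    def test_true_model_preferred_over_collapsed(self):
        """Data with a real condition difference in drift: the model letting
        v vary by phase should win DIC most of the time."""
        wins = 0
        for s in range(5):
            rng = np.random.default_rng(50 + s)
            frames = []
            for i in range(4):
                for phase, v in (("baseline", 0.3), ("stimulation", 1.2)):
                    hit, t = simulate_paths(
                        np.full(120, v), np.full(120, 1.3), np.full(120, 0.5),
                        1e-3, 30.0, int(rng.integers(2**31)))
                    frames.append(pd.DataFrame({
                        "subject": f"s{i}", "duration_s": 0.52, "phase": phase,
                        "choice": np.where(hit, "long", "short"),
                        "rt_s": t + 0.25}))
            trials = pd.concat(frames, ignore_index=True)
            rich = ddm.fit_hierarchical(trials, ddm.ModelSpec(
                varies_by={"v": ("phase",)}, n_chains=2, n_samples=400,
                n_burn=150, seed=s))
            poor = ddm.fit_hierarchical(trials, ddm.ModelSpec(
                n_chains=2, n_samples=400, n_burn=150, seed=s))
            wins += ddm.dic(rich) < ddm.dic(poor)
        assert wins >= 4

    def test_duplicated_data_doubles_mean_deviance(self, small_fit):
        trials, fit = small_fit
        doubled = pd.concat([
            trials,
            trials.assign(subject=trials["subject"] + "_b"),
        ], ignore_index=True)
        spec = ddm.ModelSpec(n_chains=2, n_samples=500, n_burn=200, seed=5)
        fit2 = ddm.fit_hierarchical(doubled, spec)
        d1 = fit.deviance_trace.mean()
        d2 = fit2.deviance_trace.mean()
        assert d2 == pytest.approx(2 * d1, rel=0.03)

    def test_effective_parameters_positive(self, small_fit):
        _, fit = small_fit
        assert fit.pd_eff > 0


class TestPosteriorPredictive:
    def test_default_count_honored_and_self_consistent(self, small_fit):
        _, fit = small_fit
        ppc = ddm.posterior_predictive(fit, n_datasets=100, seed=1)
        assert ppc["n_datasets"] == 100
        assert ppc["fraction_inside"] >= 0.95

    def test_misspecified_z_detected(self):
        """Forcing a symmetric start on z-shifted data pushes the observed
        choice proportion outside the simulated envelope."""
        trials = _dataset(n_subj=4, n_trials=400, z=0.75, seed=9)
        spec = ddm.ModelSpec(n_chains=2, n_samples=400, n_burn=150, seed=2)
        fit = ddm.fit_hierarchical(trials, spec)
        # overwrite the fitted starting point with the misspecified value
        for s in range(4):
            fit.subject.loc[f"z[s{s}]", "mean"] = 0.5
        ppc = ddm.posterior_predictive(fit, n_datasets=100, seed=3)
        lo, hi = ppc["prop_envelope"]
        obs = ppc["observed_prop_long"]
        assert (obs < lo).any() or (obs > hi).any()


def test_mle_fallback_recovers_parameters():
    trials = _dataset(n_subj=2, n_trials=400, seed=21)
    out = ddm.fit_mle(trials)
    for sid, est in out.items():
        assert est["a"] == pytest.approx(1.3, rel=0.2)
        assert est["t0"] == pytest.approx(0.25, abs=0.04)
        assert est["z"] == pytest.approx(0.55, abs=0.08)
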