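import warnings

import numpy as np
import pytest

from bisectlab import design, psycho, synth

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def stimulus_set():
    return design.make_stimulus_set(0.3, 0.9, 7)


@pytest.fixture(scope="session")
def annotated_design(stimulus_set):
    seq = design.generate_sequence(7, 8, include_null=True, seed=11)
    return design.annotate_transitions(seq, stimulus_set)


@pytest.fixture(scope="session")
def simulated_trials(annotated_design):
    """One default-condition simulated session, RT-filtered."""
    spec = synth.default_generative_spec(seed=101)
    filled = synth.simulate_bisection_dataset(annotated_design, spec)
    return psycho.filter_rt(filled)


@pytest.fixture(scope="session")
def gumbel_sample():
    """Binomial draws from a known log-Gumbel curve (bp* = 0.55 s)."""
    rng = np.random.default_rng(202)
    d = np.geomspace(0.3, 0.9, 7)
    beta = 0.15
    b1 = 1.0 / beta
    b0 = np.log(np.log(2)) - b1 * np.log(0.55)
    p_true = -np.expm1(-np.exp(b0 + b1 * np.log(d)))
    n = np.full(7, 64)
    k = rng.binomial(n, p_true)
    return {"durations": d, "n": n, "k": k, "p_true": p_true, "bp_true": 0.55}
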