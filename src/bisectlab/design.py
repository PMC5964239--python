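"""Stimulus sets and first-order counterbalanced trial sequences.

A temporal-bisection session presents one of ``n_levels`` log-spaced
durations on every trial.  Because trial-history (carryover) analyses
condition on the *previous* trial's duration, the presentation order is
first-order counterbalanced: every ordered pair of labels (including a
NULL "empty" label that creates no-stimulus transitions) occurs equally
often.  Such an order is an Eulerian circuit on the complete transition
multigraph, which this module realizes with a seeded Hierholzer walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NULL_LABEL = "NULL"

#: Canonical column order of a trial table on disk.
TABLE_COLUMNS = [
    "trial_index",
    "duration_s",
    "prior_duration_s",
    "prior_was_null",
    "session",
    "phase",
    "choice",
    "rt_s",
]


@dataclass(frozen=True)
class StimulusSet:
    """A geometrically (log-) spaced set of test durations, in seconds."""

    durations: np.ndarray
    t_min: float
    t_max: float
    n_levels: int
    geometric_mean: float

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        if d.size != self.n_levels:
            raise ValueError("durations length does not match n_levels")
        if not np.all(np.diff(d) > 0):
            raise ValueError("durations must be strictly increasing")
        ratios = d[1:] / d[:-1]
        if not np.allclose(ratios, ratios[0], rtol=1e-9):
            raise ValueError("durations are not log-spaced")

    def labels(self) -> list[str]:
        return [f"d{i + 1}" for i in range(self.n_levels)]

    def label_to_duration(self) -> dict[str, float]:
        return dict(zip(self.labels(), self.durations))


@dataclass(frozen=True)
class TrialSequence:
    """A cyclic label sequence with uniform ordered-pair transition counts.

    ``labels`` is reported linearly (cut at a random position); transition
    counts are taken cyclically, i.e. including the wrap-around pair, so
    every entry of ``transition_counts`` equals ``reps_per_transition``.
    """

    labels: list[str]
    alphabet: list[str]
    reps_per_transition: int
    transition_counts: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_null(self) -> int:
        return sum(1 for lab in self.labels if lab == NULL_LABEL)

    @property
    def n_stimulus_trials(self) -> int:
        return len(self.labels) - self.n_null


def make_stimulus_set(t_min: float, t_max: float, n_levels: int) -> StimulusSet:
    """Build the log-spaced duration set between ``t_min`` and ``t_max``.

    The geometric mean of a log-spaced set equals sqrt(t_min * t_max); for
    the canonical 300-900 ms set of seven durations this is 520 ms, the
    implicit categorical standard of the bisection task.
    """
    if t_min <= 0 or t_max <= t_min:
        raise ValueError("require 0 < t_min < t_max")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    durations = np.geomspace(t_min, t_max, n_levels)
    # pin endpoints exactly
    durations[0], durations[-1] = t_min, t_max
    gm = float(np.exp(np.mean(np.log(durations))))
    return StimulusSet(durations, float(t_min), float(t_max), int(n_levels), gm)


def _eulerian_circuit(n_nodes: int, reps: int, rng: np.random.Generator) -> list[int]:
    """Seeded Hierholzer walk on the complete transition multigraph.

    Every ordered node pair (self-loops included) appears ``reps`` times as
    an edge; the graph is connected and every node has equal in/out degree,
    so an Eulerian circuit always exists.
    """
    # remaining[i][j] = number of unused i->j edges
    remaining = np.full((n_nodes, n_nodes), reps, dtype=int)
    out_deg = remaining.sum(axis=1)
    start = int(rng.integers(n_nodes))
    stack = [start]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if out_deg[v] > 0:
            choices = np.flatnonzero(remaining[v])
            w = int(rng.choice(choices, p=remaining[v, choices] / out_deg[v]))
            remaining[v, w] -= 1
            out_deg[v] -= 1
            stack.append(w)
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    # circuit visits n_nodes^2 * reps edges; drop the repeated terminal node
    return circuit[:-1]


def generate_sequence(
    n_duration_labels: int,
    reps_per_transition: int,
    include_null: bool = True,
    seed: int | np.random.Generator | None = None,
) -> TrialSequence:
    """Generate a first-order counterbalanced (de Bruijn-like) trial order.

    Returns a cyclic sequence over ``n_duration_labels`` duration labels,
    plus a NULL label when ``include_null``, in which every ordered label
    pair occurs exactly ``reps_per_transition`` times.  The circuit is cut
    at a random position for linear presentation; transition counts are
    computed cyclically so they remain exactly uniform.
    """
    if n_duration_labels < 1:
        raise ValueError("need at least one duration label")
    if reps_per_transition < 1:
        raise ValueError("reps_per_transition must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = [f"d{i + 1}" for i in range(n_duration_labels)]
    if include_null:
        alphabet = alphabet + [NULL_LABEL]
    n = len(alphabet)
    nodes = _eulerian_circuit(n, reps_per_transition, rng)
    cut = int(rng.integers(len(nodes)))
    nodes = nodes[cut:] + nodes[:cut]
    labels = [alphabet[i] for i in nodes]
    counts = np.zeros((n, n), dtype=int)
    for i, a in enumerate(nodes):
        counts[a, nodes[(i + 1) % len(nodes)]] += 1
    return TrialSequence(labels, alphabet, int(reps_per_transition), counts)


def annotate_transitions(
    sequence: TrialSequence,
    stimuli: StimulusSet,
    session: str = "alpha",
    phase: str = "baseline",
) -> pd.DataFrame:
    """Expand a label sequence into a trial table with predecessor columns.

    NULL rows are dropped from the returned table; a stimulus trial whose
    predecessor was NULL keeps ``prior_was_null=True`` and a missing
    ``prior_duration_s`` so carryover analyses can exclude it.  The first
    trial of the linear sequence likewise has no predecessor.
    """
    mapping = stimuli.label_to_duration()
    unknown = {lab for lab in sequence.labels if lab != NULL_LABEL} - set(mapping)
    if unknown:
        raise KeyError(f"sequence labels not in stimulus set: {sorted(unknown)}")
    rows = []
    prev: str | None = None
    for idx, lab in enumerate(sequence.labels):
        if lab != NULL_LABEL:
            prior_null = prev == NULL_LABEL
            prior = mapping[prev] if (prev is not None and not prior_null) else np.nan
            rows.append(
                {
                    "trial_index": idx,
                    "duration_s": mapping[lab],
                    "prior_duration_s": prior,
                    "prior_was_null": bool(prior_null),
                    "session": session,
                    "phase": phase,
                    "choice": pd.NA,
                    "rt_s": np.nan,
                }
            )
        prev = lab
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV with empty fields for missing values."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read a trial table CSV written by :func:`write_table`."""
    table = pd.read_csv(path, encoding="utf-8")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    table["prior_was_null"] = table["prior_was_null"].astype(bool)
    table["choice"] = table["choice"].astype("object").where(table["choice"].notna(), pd.NA)
    return table[TABLE_COLUMNS]
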