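"""Shared fixtures and the independent microsimulation oracle."""

from __future__ import annotations

import numpy as np
import pytest

from statincea import ModelConfig, builtin_table1
from statincea.markov import age_band_for, build_transition_matrix


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture()
def default_cfg():
    return ModelConfig()


def microsimulate(p, strategy, cfg, n_individuals, seed):
    """Individual-level Monte Carlo oracle for the cohort trace.

    Simulates ``n_individuals`` independent patients through the same
    per-age transition matrices the cohort engine uses (state counts are
    advanced with multinomial draws, which is distributionally identical
    to per-patient categorical sampling) and returns the empirical
    occupancy proportions per cycle.  Written against the matrices only,
    independently of the cohort recursion it checks.
    """
    rng = np.random.default_rng(seed)
    n_cycles = cfg.n_cycles
    counts = np.zeros((n_cycles, 5), dtype=np.int64)
    counts[0, 0] = n_individuals
    for t in range(n_cycles - 1):
        age = cfg.start_age + t
        m = build_transition_matrix(p, strategy, age, cfg).entries
        nxt = np.zeros(5, dtype=np.int64)
        for s in range(5):
            if counts[t, s]:
                nxt += rng.multinomial(counts[t, s], m[s])
        counts[t + 1] = nxt
    return counts / n_individuals
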