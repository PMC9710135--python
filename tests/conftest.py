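"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from dietmeth.simulate import SimulationConfig, simulate_cohort, simulate_liver_panel


def brute_force_calls(delta: pd.DataFrame, threshold: float, fraction: float) -> list[str]:
    """Exhaustive per-probe counting loop, written independently of the caller.

    For each probe, walk the patients one by one, count signed exceedances
    among non-missing deltas, and call a direction when its count reaches
    ceil(fraction * evaluable_n).
    """
    out = []
    for _, row in delta.iterrows():
        n_hyper = n_hypo = n_avail = 0
        for value in row:
            if value != value:  # NaN
                continue
            n_avail += 1
            if value >= threshold:
                n_hyper += 1
            elif value <= -threshold:
                n_hypo += 1
        if n_avail == 0:
            out.append("none")
            continue
        bar = math.ceil(round(fraction * n_avail, 9))
        if n_hyper >= bar:
            out.append("hyper")
        elif n_hypo >= bar:
            out.append("hypo")
        else:
            out.append("none")
    return out


def pearson_chi2_loop(contingency: np.ndarray) -> float:
    """Brute-force Pearson chi-square: sum (O-E)^2 / E over every cell."""
    observed = np.asarray(contingency, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    stat = 0.0
    for i in range(observed.shape[0]):
        for j in range(observed.shape[1]):
            stat += (observed[i, j] - expected[i, j]) ** 2 / expected[i, j]
    return stat


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast cohort: 800 probes, 40 hyper + 10 hypo planted, study-design defaults."""
    return SimulationConfig(
        n_probes=800,
        n_planted_hyper=40,
        n_planted_hypo=10,
        n_liver_per_grade={0: 20, 1: 20, 2: 20, 3: 20},
        n_healthy_liver=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def liver_panel(small_config, cohort):
    _, _, _, truth = cohort
    return simulate_liver_panel(small_config, truth)


@pytest.fixture()
def tiny_betas() -> pd.DataFrame:
    return pd.DataFrame(
        [[0.1, 0.2], [0.5, 0.6], [0.8, 0.9]],
        index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
        columns=["s1", "s2"],
    )
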