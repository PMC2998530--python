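"""Shared fixtures.

The two session-scoped fixtures run the expensive simulation protocols once
(the differential-gene sweep and the noise-sensitivity study) and are shared
by the acceptance-style tests.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lowdim.benchmark import simulation_study, summarize_simulation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=15,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: differential-gene counts swept by the simulation study
SWEEP_COUNTS = (10, 50, 100, 150, 200, 300, 400, 500)
SWEEP_REPLICATES = 20


@pytest.fixture(scope="session")
def simulation_sweep():
    """Mean 2-D loo-cv accuracy per (method, differential-gene count).

    Full-size generator conditions (50 samples x 10,000 genes, rho = 0.2,
    shift +0.6), 20 replicate datasets per count, PCA / LLE / Isomap at
    d = 2 with the neighbor count picked by a small loo-cv sweep.
    """
    table = simulation_study(SWEEP_COUNTS, SWEEP_REPLICATES, seed=1)
    return summarize_simulation(table)


@pytest.fixture(scope="session")
def noise_sensitivity():
    """Mean accuracy per (method, noise variance) at n_diff = 300.

    Twelve replicate datasets; each is scaled onto [0, 1] and corrupted with
    i.i.d. Gaussian noise of the given variance before embedding.
    """
    out = {}
    for variance in (0.0, 0.1, 0.2):
        table = simulation_study(
            [300], 12, methods=("PCA", "IM"), seed=2, noise_variance=variance
        )
        means = table.groupby("method")["accuracy"].mean()
        for method, acc in means.items():
            out.setdefault(method, {})[variance] = float(acc)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
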