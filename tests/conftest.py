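"""Shared fixtures.

The session-scoped fixtures run the expensive simulation campaigns once:
a widefield reference graph (25 images per pattern x density cell) and a
fresh 50-replicate-per-cell campaign used by the validation-surface tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import tilestats as ts
from tilestats.fitting import PATTERN_ORDER, build_reference_graph
from tilestats.pipeline import simulate_and_analyze

REF_DENSITIES = [1.0, 3.0, 5.0, 7.0]


@pytest.fixture(scope="session")
def wf_reference():
    """Widefield reference graph: 5 pattern classes x 4 density levels."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference_graph(
            densities=REF_DENSITIES, n_images=25, seed=0
        )


def _campaign(pattern: str, density: float, n: int, seed0: int, reference=None):
    """Fresh simulated replicates (seeded independently of the reference)."""
    cfg = ts.AnalysisConfig(correction_method="accuracy_calibrated")
    alphas, betas, inhs, rhos = [], [], [], []
    for i in range(n):
        res = simulate_and_analyze(
            pattern, density, config=cfg, seed=seed0 + i
        )
        if res.fit is not None and res.fit.valid:
            alphas.append(res.fit.shape)
            betas.append(res.fit.scale)
            rhos.append(res.density.rho)
            if reference is not None:
                inh = ts.inhomogeneity(res.fit, res.density, reference)
                inhs.append(inh.value)
    return {
        "alpha": np.array(alphas),
        "beta": np.array(betas),
        "inh": np.array(inhs),
        "rho": np.array(rhos),
    }


@pytest.fixture(scope="session")
def pattern_stats(wf_reference):
    """50 fresh replicates per pattern class at density ~5 tiles/um^2."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            pat: _campaign(pat, 5.0, 50, 50_000 + 1000 * k, wf_reference)
            for k, pat in enumerate(PATTERN_ORDER)
        }


@pytest.fixture(scope="session")
def random_density_stats():
    """50 fresh random-pattern replicates at each density level 1..7."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            d: _campaign("random", d, 50, 70_000 + 1000 * k)
            for k, d in enumerate(REF_DENSITIES)
        }
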