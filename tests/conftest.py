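"""Shared fixtures: seeded simulation runs reused across test modules.

The flagship run reproduces the study conditions (growth layer 14 cell
widths, ~30-cell-wide periodic box, enough labelled lineages for stable
spectra); the small run is a fast configuration for unit-level checks.
Both are session-scoped because the mechanical simulation dominates the
suite's runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from crowdclone import SimConfig, run

FLAGSHIP = dict(
    box_width=30.0,
    lambda_depth=14.0,
    label_rate=0.06,
    stop_divisions=50000,
    seed=42,
)

SMALL = dict(
    box_width=10.0,
    lambda_depth=5.0,
    label_rate=0.1,
    stop_divisions=1200,
    seed=101,
)


@pytest.fixture(scope="session")
def flagship_run():
    """Uniform-growth run at the study scale (lambda = 14 sigma)."""
    return run(SimConfig(**FLAGSHIP))


@pytest.fixture(scope="session")
def small_run():
    """Fast run (lambda = 5 sigma) for unit-level and invariant checks."""
    return run(SimConfig(**SMALL))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
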