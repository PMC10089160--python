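"""Continuum crowding-model predictions and a well-mixed Luria-Delbruck
clone-size generator.

The crowding model describes neutral clones founded at depth ``delta``
behind a front with a uniform-growth layer of depth ``lambda``: the clone
grows by the same relative amount as the column of cells in front of it
before being pushed out of the layer, giving a final size

    n = lambda / delta,

valid from one cell width behind the front (n = lambda/sigma) down to the
back of the layer (n = 1).  With mutations arising uniformly per division,
delta is uniform on (0, lambda] and the induced clone-size density is
P(n) = n^-2, i.e. a cumulative distribution P(size > n) = 1/n — the same
1/n frequency law as the classic Luria-Delbruck fluctuation test in
well-mixed populations, here produced by a purely mechanical mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class CrowdingModel:
    """Growth-layer geometry: layer depth ``lambda_depth``, cell width ``sigma``."""

    lambda_depth: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_depth <= 0 or self.sigma <= 0:
            raise ValueError("lambda_depth and sigma must be positive")
        if self.n_max < 1:
            raise ValueError("lambda_depth/sigma must be >= 1")

    @property
    def n_max(self) -> float:
        """Largest nonsurfing clone size, lambda/sigma (birth one cell behind
        the front)."""
        return self.lambda_depth / self.sigma


def predicted_clone_size(model: CrowdingModel, delta) -> np.ndarray | float:
    """Final clone size lambda/delta for a clone founded at depth delta.

    Valid for sigma <= delta <= lambda: shallower births are surfing clones,
    deeper births never grow.
    """
    d = np.asarray(delta, dtype=float)
    if np.any(d < model.sigma) or np.any(d > model.lambda_depth):
        raise ValueError("delta must lie in [sigma, lambda_depth]")
    out = model.lambda_depth / d
    return float(out) if np.isscalar(delta) else out


def clone_size_density(model: CrowdingModel, n, mode: str = "normalized"):
    """Clone-size probability density ~ n^-2 on [1, lambda/sigma].

    ``mode='normalized'`` scales by C = 1/(1 - sigma/lambda) so the density
    integrates to 1 over the support; ``mode='ideal'`` returns the bare n^-2.
    """
    nn = np.asarray(n, dtype=float)
    if np.any(nn < 1) or np.any(nn > model.n_max):
        raise ValueError("n must lie in [1, lambda/sigma]")
    dens = nn ** -2.0
    if mode == "normalized":
        dens = dens / (1.0 - model.sigma / model.lambda_depth)
    elif mode != "ideal":
        raise ValueError(f"unknown mode {mode!r}")
    return float(dens) if np.isscalar(n) else dens


def clone_size_cumulative(model: CrowdingModel, n, mode: str = "normalized"):
    """P(clone size > n): 1/n (ideal) or its upper-truncated normalization.

    Normalized mode: (1/n - sigma/lambda)/(1 - sigma/lambda), which is 0 at
    n = lambda/sigma.
    """
    nn = np.asarray(n, dtype=float)
    if np.any(nn < 1) or np.any(nn > model.n_max):
        raise ValueError("n must lie in [1, lambda/sigma]")
    if mode == "ideal":
        cum = 1.0 / nn
    elif mode == "normalized":
        r = model.sigma / model.lambda_depth
        cum = (1.0 / nn - r) / (1.0 - r)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(cum) if np.isscalar(n) else cum


def sample_crowding_clone_sizes(model: CrowdingModel, n_draws: int,
                                rng=None) -> np.ndarray:
    """Monte-Carlo clone sizes: delta ~ Uniform(0, lambda], n = lambda/delta.

    Mutations proportional to growth make birth depth uniform over the
    layer; pushing the uniform through n = lambda/delta realizes the n^-2
    density (support [1, inf); sizes above lambda/sigma correspond to births
    within one cell of the front, i.e. the surfing domain).
    """
    rng = np.random.default_rng(rng)
    u = rng.random(n_draws)
    delta = model.lambda_depth * (1.0 - u)  # uniform on (0, lambda]
    delta = np.where(delta <= 0, model.lambda_depth * 1e-12, delta)
    return model.lambda_depth / delta


# ---------------------------------------------------------------------------
# Luria-Delbruck fluctuation-test generator
# ---------------------------------------------------------------------------

@dataclass
class LDConfig:
    """Well-mixed fluctuation-test parameters.

    The population doubles synchronously from ``n_initial`` to ``n_final``
    (rounded up to a whole number of doublings); mutations arise at rate
    ``mu`` per wild-type division.  ``mode='deterministic'`` gives each
    clone founded in generation g of G the exact size 2^(G-g);
    ``mode='stochastic'`` grows each clone as a continuous-time Yule
    (pure-birth) process over the remaining generations, whose exact size
    law is Geometric with mean 2^(G-g).
    """

    n_initial: int
    n_final: int
    mu: float
    mode: str = "deterministic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_final > self.n_initial >= 1):
            raise ValueError("need n_final > n_initial >= 1")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_generations(self) -> int:
        return math.ceil(math.log2(self.n_final / self.n_initial))

    @property
    def realized_n_final(self) -> int:
        return self.n_initial * 2 ** self.n_generations


def simulate_luria_delbruck(config: LDConfig, rng=None) -> np.ndarray:
    """Clone sizes of one fluctuation-test culture.

    In each generation g = 1..G the wild-type population doubles and new
    mutant clones arise as Poisson(mu * wild-type divisions).  Mutant cells
    double each generation; wild-type divisions are reduced by the standing
    mutant count, so mutants do not contribute new founding events.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G = config.n_generations
    sizes: list[float] = []
    mutants = 0.0  # standing mutant cells (expected, deterministic doubling)
    founded_per_gen = np.zeros(G, dtype=np.int64)
    for g in range(1, G + 1):
        pop_before = config.n_initial * 2 ** (g - 1)
        wt_divisions = max(pop_before - mutants, 0.0)
        k = rng.poisson(config.mu * wt_divisions)
        founded_per_gen[g - 1] = k
        mutants = 2.0 * mutants + k
    for g in range(1, G + 1):
        k = int(founded_per_gen[g - 1])
        if k == 0:
            continue
        if config.mode == "deterministic":
            sizes.extend([2.0 ** (G - g)] * k)
        else:
            # Yule growth over (G-g) doublings: exact Geometric law with
            # mean 2^(G-g)
            p = 2.0 ** -(G - g)
            if p >= 1.0:
                sizes.extend([1.0] * k)
            else:
                sizes.extend(rng.geometric(p, size=k).astype(float))
    return np.asarray(sizes, dtype=float)


def simulate_luria_delbruck_replicates(config: LDConfig, replicates: int,
                                       rng=None) -> list[np.ndarray]:
    """Independent fluctuation-test cultures sharing one seeded stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [simulate_luria_delbruck(config, rng) for _ in range(replicates)]


def ld_expected_count(n, mu: float, n_final: float):
    """Classic expected number of clones of size >= n: mu * N / n.

    The deterministic-mode amplitude (and the amplitude used for mutation-
    rate estimation from the 1/n regime of a clone-count spectrum).
    """
    nn = np.asarray(n, dtype=float)
    if np.any(nn < 1):
        raise ValueError("n must be >= 1")
    out = mu * n_final / nn
    return float(out) if np.isscalar(n) else out
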