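"""Clone-size spectra: cumulative distributions, log-binned densities, and
maximum-likelihood power-law exponents.

All cumulative curves use the ">= n" convention: the value reported at n is
the fraction (or number) of clones/colonies whose size is at least n.  The
power-law exponent is reported in the cumulative convention: a clone-size
spectrum following the 1/n law has ``exponent_magnitude`` ~ 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

CONVENTION = ">="


class InsufficientDataError(ValueError):
    """Raised when too few sizes fall inside the requested fit range."""


class DegenerateDataError(ValueError):
    """Raised when all in-range sizes are identical."""


@dataclass
class Spectrum:
    """A multiset of clone sizes plus sampling metadata.

    ``sizes`` are clone sizes in cells (possibly rescaled estimates of true
    sizes); frequencies are ``sizes / n_total``.  ``weight`` is the
    clone-count multiplier applied when converting subsample counts to
    whole-population clone counts (1 for unrescaled spectra).
    """

    sizes: np.ndarray
    n_total: int
    n_sample: int | None = None
    strategy: str = "whole"
    kind: str = "per-clone"
    weight: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.n_sample is None:
            self.n_sample = self.n_total
        if self.n_sample > self.n_total:
            raise ValueError("n_sample cannot exceed n_total")
        if self.sizes.size and np.any(self.sizes < 1):
            raise ValueError("clone sizes must be >= 1")

    @property
    def frequencies(self) -> np.ndarray:
        return self.sizes / self.n_total

    def cumulative_count(self, n) -> np.ndarray:
        """Estimated number of whole-population clones of size >= n."""
        nn = np.atleast_1d(np.asarray(n, dtype=float))
        s = np.sort(self.sizes)
        counts = len(s) - np.searchsorted(s, nn, side="left")
        out = counts * self.weight
        return out if np.ndim(n) else float(out[0])

    def cumulative_count_at_freq(self, f) -> np.ndarray:
        return self.cumulative_count(np.asarray(f, dtype=float) * self.n_total)


@dataclass
class PowerLawFit:
    """Maximum-likelihood fit of a (truncated) power-law tail.

    ``exponent_magnitude`` is the magnitude of the cumulative exponent:
    cumulative ~ n^(-exponent_magnitude); the density exponent is
    ``exponent_magnitude + 1``.
    """

    exponent_magnitude: float
    n_min: float
    n_max: float
    stderr: float
    n_points: int


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def empirical_cumulative(sizes) -> tuple[np.ndarray, np.ndarray]:
    """(n, fraction of clones with size >= n) at each distinct observed size."""
    s = np.asarray(sizes, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one clone size")
    s = np.sort(s)
    uniq = np.unique(s)
    frac = (len(s) - np.searchsorted(s, uniq, side="left")) / len(s)
    return uniq, frac


def colonies_cumulative(cfu_counts, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """(n, fraction of replicates carrying at least n mutants).

    Per-colony form of the fluctuation test: each replicate contributes its
    mutant CFU count; replicates with zero mutants enter the denominator
    only.  ``grid`` defaults to a log-spaced grid from 1 to the maximum
    count (always including 1).
    """
    c = np.asarray(cfu_counts, dtype=float)
    if c.size == 0:
        raise ValueError("need at least one replicate")
    if np.any(c < 0):
        raise ValueError("CFU counts must be non-negative")
    cmax = c.max()
    if grid is None:
        if cmax < 1:
            grid = np.array([1.0])
        else:
            grid = np.unique(np.round(
                np.geomspace(1.0, cmax, num=min(200, max(2, int(cmax))))
            ))
    grid = np.asarray(grid, dtype=float)
    s = np.sort(c)
    frac = (len(s) - np.searchsorted(s, grid, side="left")) / len(s)
    return grid, frac


def log_binned_density(sizes, bins_per_decade: int = 8
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram on logarithmic bins: (geometric centers, density).

    Counts per bin are divided by the linear bin width and the total count,
    so the densities integrate to ~1; empty bins are omitted.
    """
    s = np.asarray(sizes, dtype=float)
    if s.size == 0:
        raise ValueError("need at least one size")
    if np.any(s < 1):
        raise ValueError("sizes must be >= 1")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    lo = np.floor(np.log10(s.min()) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(s.max()) * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    nbins = int(round((hi - lo) * bins_per_decade))
    edges = 10 ** np.linspace(lo, hi, nbins + 1)
    counts, _ = np.histogram(s, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / widths / len(s)
    keep = counts > 0
    return centers[keep], dens[keep]


def _trunc_mean_log(beta: float, a: float, b: float) -> float:
    """E[ln n] under density ~ n^-beta truncated to [a, b]."""
    t = 1.0 - beta
    la, lb = np.log(a), np.log(b)
    if abs(t) < 1e-9:
        return (lb * lb - la * la) / (2.0 * (lb - la))
    # integrals computed with a common factor a^t pulled out for stability
    r = (b / a) ** t
    z = (r - 1.0) / t  # Z / a^t
    zl = (r * (t * lb - 1.0) - (t * la - 1.0)) / (t * t)  # int ln n / a^t
    return zl / z


def fit_powerlaw_exponent(sizes, n_min: float, n_max: float,
                          discrete: bool | str = "auto") -> PowerLawFit:
    """Upper-truncated continuous MLE (Hill-type) power-law exponent.

    Fits a density ~ n^-beta to the sizes inside [n_min, n_max] by
    conditional maximum likelihood (root of the mean-log equation, solved by
    bracketed one-dimensional root finding, tolerance 1e-8) and reports the
    cumulative-convention magnitude beta - 1 with the Hill standard error
    (beta - 1)/sqrt(m).

    For integer-valued sizes (clone counts) on a narrow range the continuous
    approximation is badly biased; ``discrete`` applies the standard
    half-integer continuity correction (support widened to
    [n_min - 1/2, n_max + 1/2]).  The default ``"auto"`` applies it exactly
    when every in-range size is an integer.
    """
    if n_min >= n_max:
        raise ValueError("n_min must be < n_max")
    s = np.asarray(sizes, dtype=float)
    s = s[(s >= n_min) & (s <= n_max)]
    m = len(s)
    if m < 10:
        raise InsufficientDataError(
            f"only {m} sizes in [{n_min}, {n_max}]; need >= 10"
        )
    if np.all(s == s[0]):
        raise DegenerateDataError("all in-range sizes identical")
    if discrete == "auto":
        discrete = bool(np.all(s == np.round(s)))
    a, b = (n_min - 0.5, n_max + 0.5) if discrete else (n_min, n_max)
    a = max(a, 0.5)
    target = float(np.mean(np.log(s)))

    def f(beta: float) -> float:
        return _trunc_mean_log(beta, a, b) - target

    lo, hi = -10.0, 60.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:  # data mean-log at a support edge; clamp
        beta = hi if abs(fhi) < abs(flo) else lo
    else:
        beta = brentq(f, lo, hi, xtol=1e-8)
    alpha = beta - 1.0
    return PowerLawFit(
        exponent_magnitude=float(alpha), n_min=float(n_min),
        n_max=float(n_max), stderr=float(abs(alpha) / np.sqrt(m)),
        n_points=m,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cfu_table(path) -> pd.DataFrame:
    """CFU table TSV with columns colony_id, cfu_count."""
    df = pd.read_csv(path, sep="\t")
    missing = {"colony_id", "cfu_count"} - set(df.columns)
    if missing:
        raise ValueError(f"CFU table missing columns: {sorted(missing)}")
    if (df["cfu_count"] < 0).any():
        raise ValueError("CFU counts must be non-negative")
    return df


def write_spectrum(path, n, fraction, meta: dict | None = None) -> None:
    """Spectrum TSV (n, cumulative_fraction) plus a JSON metadata sidecar."""
    df = pd.DataFrame({"n": n, "cumulative_fraction": fraction})
    df.to_csv(path, sep="\t", index=False)
    sidecar = dict(meta or {})
    sidecar.setdefault("convention", CONVENTION)
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=str)


def sample_truncated_powerlaw(alpha_cum: float, a: float, b: float,
                              size: int, rng=None) -> np.ndarray:
    """Draws from a density ~ n^-(alpha_cum+1) truncated to [a, b].

    Inverse-CDF sampling; useful as a synthetic benchmark for the exponent
    estimator (and as the continuous analogue of the clone-size laws).
    """
    rng = np.random.default_rng(rng)
    beta = alpha_cum + 1.0
    u = rng.random(size)
    t = 1.0 - beta
    if abs(t) < 1e-12:
        return a * (b / a) ** u
    return (a ** t + u * (b ** t - a ** t)) ** (1.0 / t)
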