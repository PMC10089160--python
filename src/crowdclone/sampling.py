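"""Spatial subsampling of labelled cell snapshots and spectrum rescaling.

Two sampling strategies mirror what is practical in sequencing of
structured populations: *random* (every cell kept independently with
probability p, the analogue of whole-population sequencing at finite
coverage) and *region* (all cells in a contiguous rectangle, the analogue
of a spatially targeted biopsy).  Because crowding keeps clones spatially
contiguous, an in-region clone count estimates the true clone size
directly, and only the total population size and the sampled cell count
are needed to place a region subsample on the whole-population scale; a
random subsample instead estimates true sizes by inflating counts by 1/p.
Combining a deep-bulk region (nonsurfing-dominated), a front segment and a
random sample reconstructs the full clone-size spectrum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum

logger = logging.getLogger(__name__)


class EmptySampleWarning(UserWarning):
    """Issued when a sampling region contains no cells."""


@dataclass
class SampleRegion:
    """Specification of a spatial sample.

    ``strategy='random'`` keeps each cell independently with probability
    ``fraction`` (seeded).  ``strategy='region'`` keeps exactly the cells
    whose (x, depth-from-front) fall inside the rectangle
    ``x_range`` x ``depth_range`` (depth measured down from the column-wise
    front height, in the same units as the snapshot, i.e. sigma).
    """

    strategy: str
    fraction: float | None = None
    x_range: tuple[float, float] | None = None
    depth_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy == "random":
            if self.fraction is None or not (0.0 < self.fraction <= 1.0):
                raise ValueError("random strategy needs 0 < fraction <= 1")
        elif self.strategy == "region":
            if self.depth_range is None:
                raise ValueError("region strategy needs depth_range")
            if self.depth_range[0] < 0 or self.depth_range[1] <= self.depth_range[0]:
                raise ValueError("depth_range must be [lo, hi) with 0 <= lo < hi")
            if self.x_range is not None and self.x_range[1] <= self.x_range[0]:
                raise ValueError("x_range must be increasing")
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")


def snapshot_front_heights(snapshot: pd.DataFrame, column_width: float = 1.0
                           ) -> tuple[np.ndarray, float]:
    """Column-wise material surface of a cell snapshot.

    Heights are the top edges of the highest disks (mother or bud) per
    column, in units of the cell width; matches the front definition used
    during simulation.
    """
    x = snapshot["x"].to_numpy(dtype=float)
    y = snapshot["y"].to_numpy(dtype=float)
    rm = 0.5
    ncols = max(1, int(np.ceil((x.max() + 1e-9) / column_width)))
    width = ncols * column_width
    col = np.minimum((x / column_width).astype(int), ncols - 1)
    heights = np.full(ncols, -np.inf)
    np.maximum.at(heights, col, y + rm)
    if "theta" in snapshot.columns and "bud_radius" in snapshot.columns:
        th = snapshot["theta"].to_numpy(dtype=float)
        rb = snapshot["bud_radius"].to_numpy(dtype=float)
        hasbud = rb > 0
        bx = np.mod(x[hasbud] + (rm + rb[hasbud]) * np.cos(th[hasbud]), width)
        btop = y[hasbud] + (rm + rb[hasbud]) * np.sin(th[hasbud]) + rb[hasbud]
        bcol = np.minimum((bx / column_width).astype(int), ncols - 1)
        np.maximum.at(heights, bcol, btop)
    # empty columns: take the taller of the nearest non-empty neighbours
    if np.any(~np.isfinite(heights)):
        good = np.flatnonzero(np.isfinite(heights))
        for c in np.flatnonzero(~np.isfinite(heights)):
            heights[c] = heights[good[np.argmin(np.abs(good - c))]]
    return heights, column_width


def draw_sample(snapshot: pd.DataFrame, region: SampleRegion
                ) -> tuple[pd.DataFrame, int]:
    """Apply a sampling strategy to a labelled cell snapshot.

    Returns the subsample (rows of the snapshot) and the sampled cell
    count.  An empty result triggers :class:`EmptySampleWarning` rather
    than an error.
    """
    for colname in ("x", "y", "clone_label"):
        if colname not in snapshot.columns:
            raise ValueError(f"snapshot missing column {colname!r}")
    heights, colw = snapshot_front_heights(snapshot)
    x = snapshot["x"].to_numpy(dtype=float)
    y = snapshot["y"].to_numpy(dtype=float)
    col = np.minimum((x / colw).astype(int), len(heights) - 1)
    depth = heights[col] - y
    if region.strategy == "random":
        rng = np.random.default_rng(region.seed)
        keep = rng.random(len(snapshot)) < region.fraction
    else:
        lo, hi = region.depth_range
        keep = (depth >= lo) & (depth < hi)
        if region.x_range is not None:
            keep &= (x >= region.x_range[0]) & (x < region.x_range[1])
    sub = snapshot[keep].copy()
    sub["depth_from_front"] = depth[keep]
    if len(sub) == 0:
        warnings.warn("sampling region contains no cells", EmptySampleWarning)
    return sub, len(sub)


def spectrum_from_sample(sub: pd.DataFrame, n_sample: int, n_total: int,
                         region: SampleRegion,
                         containment_margin: float = 1.0) -> Spectrum:
    """Per-clone spectrum of a subsample: counts of each label present.

    For the region strategy, clones with sampled cells within
    ``containment_margin`` (cell widths) of a depth boundary are dropped:
    the region estimator assumes the whole clone is contained, and clones
    sliced by the boundary (surfing streaks crossing the band) would enter
    with the full region count multiplier while carrying only a slice of
    their true size.  The number dropped is recorded in the metadata.
    """
    lab = sub["clone_label"] if len(sub) else pd.Series([], dtype=object)
    lab = lab[lab.astype(str) != "unlabeled"]
    meta = {"region": dataclass_to_dict(region)}
    if region.strategy == "region" and len(lab) and \
            "depth_from_front" in sub.columns:
        lo, hi = region.depth_range
        depth = sub.loc[lab.index, "depth_from_front"]
        touching = (depth < lo + containment_margin) \
            | (depth >= hi - containment_margin)
        sliced = set(lab[touching])
        meta["n_clones_dropped_at_boundary"] = len(sliced)
        lab = lab[~lab.isin(sliced)]
    counts = lab.value_counts().to_numpy(dtype=float)
    return Spectrum(sizes=counts, n_total=n_total, n_sample=n_sample,
                    strategy=region.strategy, kind="per-clone", meta=meta)


def dataclass_to_dict(region: SampleRegion) -> dict:
    return {
        "strategy": region.strategy, "fraction": region.fraction,
        "x_range": list(region.x_range) if region.x_range else None,
        "depth_range": list(region.depth_range) if region.depth_range else None,
        "seed": region.seed,
    }


def rescale_spectrum(sub: Spectrum) -> Spectrum:
    """Put a subsample spectrum on the whole-population scale.

    Region strategy: clones are spatially contiguous, so in-region counts
    estimate true sizes directly (f = n_s / n_total) and the clone-count
    axis is multiplied by n_total / n_sample.  Random strategy: true sizes
    are estimated as n_s / p, and the count axis is unchanged (random
    sampling sees every clone above its detection limit).  A whole-
    population spectrum is returned unchanged.
    """
    if sub.n_sample is None or sub.n_total is None:
        raise ValueError("subsample spectrum missing n_sample/n_total metadata")
    meta = dict(sub.meta)
    if sub.strategy == "region" or sub.strategy == "whole":
        factor = sub.n_total / sub.n_sample if sub.n_sample else 1.0
        meta["count_multiplier"] = factor
        meta["size_multiplier"] = 1.0
        return Spectrum(sizes=sub.sizes.copy(), n_total=sub.n_total,
                        n_sample=sub.n_sample, strategy=sub.strategy,
                        kind=sub.kind, weight=sub.weight * factor, meta=meta)
    if sub.strategy == "random":
        p = sub.n_sample / sub.n_total
        if "region" in meta and meta["region"].get("fraction"):
            p = meta["region"]["fraction"]  # the design fraction, if known
        meta["count_multiplier"] = 1.0
        meta["size_multiplier"] = 1.0 / p
        # detection limit: below ~3 sampled cells per clone the inflated
        # size estimate n_s/p is dominated by Poisson noise and the curve
        # overstates clone counts near 1/(p N)
        meta["valid_freq_min"] = 3.0 / (p * sub.n_total)
        return Spectrum(sizes=sub.sizes / p, n_total=sub.n_total,
                        n_sample=sub.n_sample, strategy=sub.strategy,
                        kind=sub.kind, weight=sub.weight, meta=meta)
    raise ValueError(f"unknown strategy {sub.strategy!r}")


def unrescale_spectrum(scaled: Spectrum) -> Spectrum:
    """Exact inverse of :func:`rescale_spectrum` (round-trip check)."""
    meta = dict(scaled.meta)
    cf = meta.pop("count_multiplier", 1.0)
    sf = meta.pop("size_multiplier", 1.0)
    return Spectrum(sizes=scaled.sizes / sf, n_total=scaled.n_total,
                    n_sample=scaled.n_sample, strategy=scaled.strategy,
                    kind=scaled.kind, weight=scaled.weight / cf, meta=meta)


@dataclass
class MergedSpectrum:
    """Concatenation of rescaled spectra on a common frequency scale."""

    curve: pd.DataFrame  # columns: frequency, cumulative_count, source
    n_total: int
    diagnostics: list = field(default_factory=list)

    def cumulative_count_at_freq(self, f) -> np.ndarray:
        """Merged cumulative clone count at the given frequencies.

        Where several sources cover a frequency, their estimates are
        combined by geometric mean.
        """
        f = np.atleast_1d(np.asarray(f, dtype=float))
        out = np.zeros(len(f))
        for i, fi in enumerate(f):
            vals = []
            for src, grp in self.curve.groupby("source"):
                fmin, fmax = grp["frequency"].min(), grp["frequency"].max()
                if fmin <= fi <= fmax:
                    # step-function evaluation of this source's curve
                    sel = grp[grp["frequency"] >= fi]
                    if len(sel):
                        vals.append(max(sel["cumulative_count"].max(), 1e-300))
            out[i] = np.exp(np.mean(np.log(vals))) if vals else np.nan
        return out


def reconstruct_full_spectrum(rescaled: list[Spectrum]) -> MergedSpectrum:
    """Merge rescaled spectra into one whole-population cumulative curve.

    Each input contributes its cumulative clone-count curve evaluated at
    its own observed frequencies; curves are concatenated and ordered by
    frequency.  On overlapping frequency ranges, the pairwise ratio of the
    curves is reported as an agreement diagnostic; a disagreement beyond a
    factor 2 logs a warning but is not an error.
    """
    if not rescaled:
        raise ValueError("need at least one spectrum")
    n_tot = rescaled[0].n_total
    for sp in rescaled[1:]:
        if sp.n_total != n_tot:
            raise ValueError("incompatible n_total across spectra")
    frames = []
    for idx, sp in enumerate(rescaled):
        if sp.sizes.size == 0:
            continue
        f = np.unique(sp.frequencies)
        fmin = sp.meta.get("valid_freq_min", 0.0)
        fmax = sp.meta.get("valid_freq_max", np.inf)
        f = f[(f >= fmin) & (f <= fmax)]
        if f.size == 0:
            continue
        counts = sp.cumulative_count(f * sp.n_total)
        frames.append(pd.DataFrame({
            "frequency": f, "cumulative_count": counts,
            "source": f"{sp.strategy}[{idx}]",
        }))
    if not frames:
        curve = pd.DataFrame(columns=["frequency", "cumulative_count", "source"])
        return MergedSpectrum(curve=curve, n_total=n_tot)
    curve = pd.concat(frames).sort_values("frequency").reset_index(drop=True)
    # overlap diagnostics
    diagnostics = []
    srcs = curve["source"].unique()
    for i in range(len(srcs)):
        for j in range(i + 1, len(srcs)):
            a = curve[curve["source"] == srcs[i]]
            b = curve[curve["source"] == srcs[j]]
            lo = max(a["frequency"].min(), b["frequency"].min())
            hi = min(a["frequency"].max(), b["frequency"].max())
            if lo >= hi:
                continue
            grid = np.geomspace(lo, hi, 9)
            av = _step_eval(a, grid)
            bv = _step_eval(b, grid)
            ok = (av > 0) & (bv > 0)
            if not np.any(ok):
                continue
            ratio = av[ok] / bv[ok]
            diagnostics.append({
                "sources": (srcs[i], srcs[j]),
                "freq_range": (float(lo), float(hi)),
                "median_ratio": float(np.median(ratio)),
                "max_log2_ratio": float(np.max(np.abs(np.log2(ratio)))),
            })
            if np.max(np.abs(np.log2(ratio))) > 1.0:
                logger.warning(
                    "overlap disagreement beyond factor 2 between %s and %s",
                    srcs[i], srcs[j],
                )
    return MergedSpectrum(curve=curve, n_total=n_tot, diagnostics=diagnostics)


def _step_eval(df: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    f = df["frequency"].to_numpy()
    c = df["cumulative_count"].to_numpy()
    order = np.argsort(f)
    f, c = f[order], c[order]
    out = np.zeros(len(grid))
    for i, g in enumerate(grid):
        sel = c[f >= g]
        out[i] = sel.max() if len(sel) else 0.0
    return out


def estimate_mutation_rate(spectrum: Spectrum, model: str = "crowding",
                           fit_range: tuple[float, float] | None = None
                           ) -> tuple[float, float]:
    """Estimate the per-division mutation (labelling) rate from the 1/n regime.

    Least-squares fit of the cumulative clone count M(n) to (mu * N)/n over
    the declared range, evaluated at the distinct observed sizes; returns
    (mu_hat, stderr).  ``model`` selects the default range: 'well-mixed'
    fits from n = 1, 'crowding' from n = 2 (the n = 1 bin of a crowded
    population piles up clones born near the back of the growth layer).
    """
    if model not in ("well-mixed", "crowding"):
        raise ValueError(f"unknown model {model!r}")
    sizes = spectrum.sizes
    if sizes.size == 0:
        raise ValueError("empty spectrum")
    if fit_range is None:
        lo = 1.0 if model == "well-mixed" else 2.0
        fit_range = (lo, float(sizes.max()))
    grid = np.unique(sizes[(sizes >= fit_range[0]) & (sizes <= fit_range[1])])
    if grid.size == 0:
        raise ValueError("no clone sizes inside the 1/n fit range")
    M = np.asarray(spectrum.cumulative_count(grid), dtype=float)
    xs = 1.0 / grid
    # M(n) ~ A / n  ->  A = sum(M * x) / sum(x^2)
    A = float(np.sum(M * xs) / np.sum(xs * xs))
    resid = M - A * xs
    dof = max(len(grid) - 1, 1)
    var_A = float(np.sum(resid ** 2) / dof / np.sum(xs * xs))
    mu_hat = A / spectrum.n_total
    return mu_hat, np.sqrt(var_A) / spectrum.n_total
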