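"""Off-lattice mechanical simulation of a crowded, expanding cell front.

Cells are modelled as 2D budding particles: a mother disk of fixed radius
``sigma/2`` rigidly attached to a bud disk that grows from radius 0 up to
``sigma/2``, at which point the bud detaches and becomes a new cell.  Cells
repel on contact through linear (Hookean) springs and move with overdamped
dynamics (velocity proportional to force, drag proportional to cell area).
Only cells within a depth ``lambda_depth`` of the advancing front grow; deeper
cells are in stationary phase, and cells far behind the front are frozen out
of the force computation entirely.  The horizontal direction is periodic, so
the population expands as a flat front moving in +y.

The module exposes the configuration type (:class:`SimConfig`), the population
state, the elementary operations (:func:`init_population`,
:func:`compute_forces`, :func:`front_profile`, :func:`step`) and the top-level
driver :func:`run`, which couples the mechanics to the clone-labelling
machinery in :mod:`crowdclone.lineage`.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml
from numba import njit

logger = logging.getLogger(__name__)

_GROWTH_TABLE_SIZE = 256
#: status codes returned by the inner integration kernel
_STATUS_MAXSTEPS = 0
_STATUS_DIVISION = 1
_STATUS_UNSTABLE = 2

UNLABELED = -1


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


class InstabilityError(RuntimeError):
    """Raised when disk overlaps exceed sigma/2.

    Usually means the time step is too large or the contact spring too soft
    for the imposed growth rate; reduce ``dt`` or increase
    ``spring_constant``.
    """


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All physical and population parameters of a simulation run.

    Lengths are in the same unit as ``sigma`` (by default the cell width is
    the unit of length).  Times are in units where ``growth_rate`` sets the
    generation time ``ln 2 / growth_rate``.

    Parameters
    ----------
    sigma:
        Cell (mother-disk) width.  The unit of length.
    lambda_depth:
        Depth of the growth layer behind the front; only cells closer than
        this (vertical, column-wise distance) to the front grow.
    box_width:
        Horizontal extent; periodic boundary conditions.
    growth_rate:
        Exponential area growth rate of a growing cell.  Generation time is
        ``ln 2 / growth_rate``.
    dt:
        Integration time step.  If ``None`` a stable default is derived from
        the stiffness: ``dt = 0.1 * damping * area_min / spring_constant`` so
        that a free overlap relaxes over >= 10 steps.
    spring_constant:
        Linear contact stiffness (force per unit overlap).
    damping:
        Drag coefficient per unit disk area (overdamped dynamics).
    label_rate:
        Per-division probability that a newborn of an unlabeled mother is
        assigned a fresh clone label (neutral-mutation analogue).
    selection_s:
        Relative growth-rate advantage of labeled cells: labeled cells grow
        at rate ``g * (1 + selection_s)``.  Default 0 (neutral labels).
    growth_profile:
        ``"uniform"`` for a constant growth rate across the layer, or a
        sequence of ``(depth, rate)`` pairs tabulating g(depth) on
        ``[0, lambda_depth]`` (linearly interpolated).
    bud_rule:
        ``"polar"`` (bud retains mother orientation) or ``"random"``
        (uniform angle at birth).
    relabel_policy:
        ``"always"`` (default): any newborn can found a new clone
        (infinite-alleles mutation at constant rate per division);
        ``"unlabeled-only"``: only newborns of unlabeled mothers can
        (irreversible colour switch; founding saturates once a clone fixes
        at the front).
    removal_depth:
        Depth behind the front beyond which cells are frozen and dropped
        from the force computation.  Default ``lambda_depth + 6 * sigma``.
    stop_divisions:
        Total number of divisions after which the run ends.
    seed:
        Seed of the single random stream (labelling draws, bud angles).
    """

    sigma: float = 1.0
    lambda_depth: float = 14.0
    box_width: float = 30.0
    growth_rate: float = 1.0
    dt: float | None = None
    spring_constant: float = 1000.0
    damping: float = 1.0
    label_rate: float = 0.05
    selection_s: float = 0.0
    growth_profile: object = "uniform"
    bud_rule: str = "polar"
    relabel_policy: str = "always"
    removal_depth: float | None = None
    stop_divisions: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.lambda_depth < self.sigma:
            raise ConfigurationError("lambda_depth must be >= sigma")
        if self.box_width < 4 * self.sigma:
            raise ConfigurationError("box_width must be >= 4*sigma")
        if self.growth_rate <= 0:
            raise ConfigurationError("growth_rate must be positive")
        if self.spring_constant <= 0 or self.damping <= 0:
            raise ConfigurationError("spring_constant and damping must be positive")
        if self.dt is None:
            area_min = math.pi * (self.sigma / 2.0) ** 2
            self.dt = 0.1 * self.damping * area_min / self.spring_constant
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not (0.0 <= self.label_rate <= 1.0):
            raise ConfigurationError("label_rate must be in [0, 1]")
        if self.removal_depth is None:
            self.removal_depth = self.lambda_depth + 6.0 * self.sigma
        if self.removal_depth <= self.lambda_depth:
            raise ConfigurationError("removal_depth must exceed lambda_depth")
        if self.bud_rule not in ("polar", "random"):
            raise ConfigurationError(f"unknown bud_rule {self.bud_rule!r}")
        if self.relabel_policy not in ("always", "unlabeled-only"):
            raise ConfigurationError(
                f"unknown relabel_policy {self.relabel_policy!r}"
            )
        if self.stop_divisions < 0:
            raise ConfigurationError("stop_divisions must be >= 0")
        # validate / tabulate the growth profile
        self._growth_table()

    @property
    def generation_time(self) -> float:
        return math.log(2.0) / self.growth_rate

    def _growth_table(self) -> np.ndarray:
        """Growth rate g(depth) sampled on a regular grid over [0, lambda)."""
        depths = (np.arange(_GROWTH_TABLE_SIZE) + 0.5) * (
            self.lambda_depth / _GROWTH_TABLE_SIZE
        )
        if isinstance(self.growth_profile, str):
            if self.growth_profile != "uniform":
                raise ConfigurationError(
                    f"unknown growth_profile {self.growth_profile!r}"
                )
            return np.full(_GROWTH_TABLE_SIZE, float(self.growth_rate))
        prof = np.asarray(self.growth_profile, dtype=float)
        if prof.ndim != 2 or prof.shape[1] != 2 or prof.shape[0] < 2:
            raise ConfigurationError(
                "growth_profile must be 'uniform' or a sequence of (depth, rate) pairs"
            )
        if np.any(prof[:, 1] < 0):
            raise ConfigurationError("growth profile rates must be non-negative")
        order = np.argsort(prof[:, 0])
        prof = prof[order]
        return np.interp(depths, prof[:, 0], prof[:, 1])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not isinstance(d["growth_profile"], str):
            d["growth_profile"] = [list(map(float, p)) for p in d["growth_profile"]]
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a flat key-value YAML configuration file; unknown keys rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    """View of one budding cell: a mother disk plus an attached bud."""

    cell_id: int
    mother_center: tuple[float, float]
    orientation: float
    mother_radius: float
    bud_radius: float
    clone_label: int  # UNLABELED (-1) means unlabeled
    growing: bool
    birth_time: float

    @property
    def bud_center(self) -> tuple[float, float]:
        r = self.mother_radius + self.bud_radius
        return (
            self.mother_center[0] + r * math.cos(self.orientation),
            self.mother_center[1] + r * math.sin(self.orientation),
        )


@dataclass
class FrontProfile:
    """Column-wise front height h(x): per-column material surface.

    The height of a column is the top edge of the highest disk (mother or
    bud) whose center falls in it; depths of cells are measured from this
    surface to their mother centers.
    """

    column_edges: np.ndarray
    heights: np.ndarray

    @property
    def column_width(self) -> float:
        return float(self.column_edges[1] - self.column_edges[0])

    def column_of(self, x: float) -> int:
        ncols = len(self.heights)
        return int(x // self.column_width) % ncols

    def depth_of(self, x: float, y: float) -> float:
        """Vertical distance from the front, floored at zero."""
        return max(self.heights[self.column_of(x)] - y, 0.0)

    @property
    def mean_height(self) -> float:
        return float(np.mean(self.heights))


class PopulationState:
    """Array-backed population: live (force-carrying) and frozen cells.

    Live cells occupy the leading ``n_live`` entries of the capacity arrays;
    frozen cells (deeper than ``removal_depth``) are moved to append-only
    frozen arrays but keep their clone membership and positions.
    """

    _FIELDS = ("x", "y", "theta", "rb", "label", "cell_id", "birth_time")

    def __init__(self, config: SimConfig, capacity: int = 256):
        self.config = config
        self.time = 0.0
        self.n_divisions = 0
        self.n_live = 0
        self.front: FrontProfile | None = None
        cap = capacity
        self.x = np.zeros(cap)
        self.y = np.zeros(cap)
        self.theta = np.zeros(cap)
        self.rb = np.zeros(cap)
        self.label = np.full(cap, UNLABELED, dtype=np.int64)
        self.cell_id = np.zeros(cap, dtype=np.int64)
        self.birth_time = np.zeros(cap)
        self.growing = np.ones(cap, dtype=np.bool_)
        self._frozen: dict[str, list] = {f: [] for f in self._FIELDS}
        # recently frozen cells kept as a static contact floor under the
        # live region (purged once well below removal_depth)
        self._static: dict[str, np.ndarray] = {
            f: np.empty(0) for f in ("x", "y", "theta", "rb")
        }
        self.next_cell_id = 0

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_frozen(self) -> int:
        return len(self._frozen["x"])

    @property
    def n_cells(self) -> int:
        """Number of cells ever created (live + frozen)."""
        return self.n_live + self.n_frozen

    def _ensure_capacity(self, n: int) -> None:
        if n <= len(self.x):
            return
        newcap = max(n, 2 * len(self.x))
        for name in self._FIELDS + ("growing",):
            arr = getattr(self, name)
            grown = np.zeros(newcap, dtype=arr.dtype)
            grown[: len(arr)] = arr
            setattr(self, name, grown)

    def add_cell(
        self,
        x: float,
        y: float,
        theta: float,
        rb: float,
        label: int,
        birth_time: float,
        growing: bool = True,
    ) -> int:
        i = self.n_live
        self._ensure_capacity(i + 1)
        self.x[i] = x % self.config.box_width
        self.y[i] = y
        self.theta[i] = theta
        self.rb[i] = rb
        self.label[i] = label
        self.cell_id[i] = self.next_cell_id
        self.birth_time[i] = birth_time
        self.growing[i] = growing
        self.next_cell_id += 1
        self.n_live = i + 1
        return i

    def freeze(self, indices: np.ndarray) -> None:
        """Move the given live rows into frozen storage (order-preserving).

        Frozen cells keep their record (position, label) and additionally
        join the static contact floor so live cells above keep resting on
        them.
        """
        if len(indices) == 0:
            return
        keep = np.ones(self.n_live, dtype=bool)
        keep[indices] = False
        for name in ("x", "y", "theta", "rb"):
            arr = getattr(self, name)
            self._static[name] = np.concatenate(
                [self._static[name], arr[indices]]
            )
        for name in self._FIELDS:
            arr = getattr(self, name)
            self._frozen[name].extend(arr[indices].tolist())
            arr[: keep.sum()] = arr[: self.n_live][keep]
        self.growing[: keep.sum()] = self.growing[: self.n_live][keep]
        self.n_live = int(keep.sum())

    @property
    def n_static(self) -> int:
        return len(self._static["x"])

    def purge_static(self, min_y: float) -> None:
        """Drop static floor cells whose y lies below ``min_y``."""
        keep = self._static["y"] >= min_y
        if not np.all(keep):
            for name in self._static:
                self._static[name] = self._static[name][keep]

    # -- views --------------------------------------------------------------

    def cells(self, include_frozen: bool = True) -> Iterator[Cell]:
        rm = self.config.sigma / 2.0
        for i in range(self.n_live):
            yield Cell(
                int(self.cell_id[i]), (float(self.x[i]), float(self.y[i])),
                float(self.theta[i]), rm, float(self.rb[i]),
                int(self.label[i]), bool(self.growing[i]), float(self.birth_time[i]),
            )
        if include_frozen:
            fz = self._frozen
            for j in range(self.n_frozen):
                yield Cell(
                    int(fz["cell_id"][j]), (float(fz["x"][j]), float(fz["y"][j])),
                    float(fz["theta"][j]), rm, float(fz["rb"][j]),
                    int(fz["label"][j]), False, float(fz["birth_time"][j]),
                )

    def all_labels(self) -> np.ndarray:
        """Clone label of every cell ever created (live then frozen)."""
        return np.concatenate([
            self.label[: self.n_live],
            np.asarray(self._frozen["label"], dtype=np.int64),
        ])

    def snapshot_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name in self._FIELDS:
            out[name] = np.concatenate([
                getattr(self, name)[: self.n_live],
                np.asarray(self._frozen[name], dtype=getattr(self, name).dtype),
            ])
        out["growing"] = np.concatenate([
            self.growing[: self.n_live],
            np.zeros(self.n_frozen, dtype=bool),
        ])
        return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _front_heights(x, y, theta, rb, n, rm, ncols, colw, box_w, heights):
    """Per-column material surface: max top edge of any disk in the column.

    Using disk top edges (not mother centers) keeps the surface continuous
    through divisions — the newborn's top edge coincides with the bud top
    it replaces — and tracks the actual material interface the continuum
    model measures depths from.
    """
    for c in range(ncols):
        heights[c] = -1.0e30
    for i in range(n):
        c = int(x[i] / colw)
        if c >= ncols:
            c = ncols - 1
        if c < 0:
            c = 0
        top = y[i] + rm
        if top > heights[c]:
            heights[c] = top
        if rb[i] > 0.0:
            bx = (x[i] + (rm + rb[i]) * math.cos(theta[i])) % box_w
            btop = y[i] + (rm + rb[i]) * math.sin(theta[i]) + rb[i]
            cb = int(bx / colw)
            if cb >= ncols:
                cb = ncols - 1
            if cb < 0:
                cb = 0
            if btop > heights[cb]:
                heights[cb] = btop
    # empty columns: maximum of the two nearest non-empty neighbours (periodic)
    for c in range(ncols):
        if heights[c] > -1.0e29:
            continue
        left = -1.0e30
        right = -1.0e30
        for off in range(1, ncols):
            cc = (c - off) % ncols
            if heights[cc] > -1.0e29:
                left = heights[cc]
                break
        for off in range(1, ncols):
            cc = (c + off) % ncols
            if heights[cc] > -1.0e29:
                right = heights[cc]
                break
        heights[c] = max(left, right)


@njit(cache=True, fastmath=True)
def _pair_forces(x, y, theta, rb, cell_id, n_live, n_tot, sigma, box_w,
                 k_spring, fx, fy, tq):
    """Hookean contact forces between disks of distinct cells.

    Entries ``[n_live:n_tot]`` are static obstacles (recently frozen cells
    forming the floor of the live region): they exert forces on live cells
    but receive none and do not move.  Returns (max_overlap,
    n_coincident); static-static contacts are ignored.  Forces act along
    disk center lines; the torque on a cell is taken about its area
    centroid.
    """
    rm = 0.5 * sigma
    n = n_tot
    for i in range(n_live):
        fx[i] = 0.0
        fy[i] = 0.0
        tq[i] = 0.0
    # build disk list: mother disks always, bud disks when rb > 0
    nd = 0
    for i in range(n):
        nd += 1
        if rb[i] > 0.0:
            nd += 1
    dx_ = np.empty(nd)
    dy_ = np.empty(nd)
    dr_ = np.empty(nd)
    dc_ = np.empty(nd, dtype=np.int64)
    offx = np.empty(nd)  # offset of disk center from its cell centroid
    offy = np.empty(nd)
    ymin = 1.0e30
    ymax = -1.0e30
    k = 0
    for i in range(n):
        ux = math.cos(theta[i])
        uy = math.sin(theta[i])
        ri2 = rm * rm
        rb2 = rb[i] * rb[i]
        area_frac = rb2 / (ri2 + rb2)  # centroid offset fraction along axis
        coff = (rm + rb[i]) * area_frac
        # mother disk
        dx_[k] = x[i]
        dy_[k] = y[i]
        dr_[k] = rm
        dc_[k] = i
        offx[k] = -coff * ux
        offy[k] = -coff * uy
        if y[i] < ymin:
            ymin = y[i]
        if y[i] > ymax:
            ymax = y[i]
        k += 1
        if rb[i] > 0.0:
            bx = x[i] + (rm + rb[i]) * ux
            by = y[i] + (rm + rb[i]) * uy
            dx_[k] = bx % box_w
            dy_[k] = by
            dr_[k] = rb[i]
            dc_[k] = i
            offx[k] = (rm + rb[i]) * ux - coff * ux
            offy[k] = (rm + rb[i]) * uy - coff * uy
            if by < ymin:
                ymin = by
            if by > ymax:
                ymax = by
            k += 1
    # spatial grid with cell size >= sigma (max interaction distance)
    nxg = int(box_w / sigma)
    if nxg < 1:
        nxg = 1
    gw = box_w / nxg
    ymin -= sigma
    nyg = int((ymax - ymin) / sigma) + 2
    head = np.full(nxg * nyg, -1, dtype=np.int64)
    nxt = np.empty(nd, dtype=np.int64)
    gix = np.empty(nd, dtype=np.int64)
    giy = np.empty(nd, dtype=np.int64)
    for d in range(nd):
        cx = int(dx_[d] / gw)
        if cx >= nxg:
            cx = nxg - 1
        cy = int((dy_[d] - ymin) / sigma)
        if cy >= nyg:
            cy = nyg - 1
        if cy < 0:
            cy = 0
        gix[d] = cx
        giy[d] = cy
        g = cy * nxg + cx
        nxt[d] = head[g]
        head[g] = d
    max_ov = 0.0
    n_coinc = 0
    half_w = 0.5 * box_w
    for d in range(nd):
        ci = dc_[d]
        for oy in range(-1, 2):
            cy = giy[d] + oy
            if cy < 0 or cy >= nyg:
                continue
            for ox in range(-1, 2):
                cx = (gix[d] + ox) % nxg
                e = head[cy * nxg + cx]
                while e >= 0:
                    if e > d and dc_[e] != ci and (
                        ci < n_live or dc_[e] < n_live
                    ):
                        ddx = dx_[e] - dx_[d]
                        if ddx > half_w:
                            ddx -= box_w
                        elif ddx < -half_w:
                            ddx += box_w
                        ddy = dy_[e] - dy_[d]
                        rsum = dr_[d] + dr_[e]
                        d2 = ddx * ddx + ddy * ddy
                        if d2 < rsum * rsum:
                            dist = math.sqrt(d2)
                            if dist < 1.0e-9:
                                # deterministic fallback direction by cell id
                                if cell_id[ci] < cell_id[dc_[e]]:
                                    nx_v = 1.0
                                else:
                                    nx_v = -1.0
                                ny_v = 0.0
                                n_coinc += 1
                            else:
                                nx_v = ddx / dist
                                ny_v = ddy / dist
                            ov = rsum - dist
                            if ov > max_ov:
                                max_ov = ov
                            f = k_spring * ov
                            cj = dc_[e]
                            # force on d is -f * n (n points d -> e)
                            if ci < n_live:
                                fx[ci] -= f * nx_v
                                fy[ci] -= f * ny_v
                                tq[ci] += (offx[d] * (-f * ny_v)
                                           - offy[d] * (-f * nx_v))
                            if cj < n_live:
                                fx[cj] += f * nx_v
                                fy[cj] += f * ny_v
                                tq[cj] += (offx[e] * (f * ny_v)
                                           - offy[e] * (f * nx_v))
                    e = nxt[e]
    return max_ov, n_coinc


@njit(cache=True, fastmath=True)
def _advance(x, y, theta, rb, label, growing, cell_id, n,
             sx, sy, stheta, srb, ns,
             time0, max_steps, sigma, box_w, dt, k_spring, damping,
             lambda_depth, sel_s, g_table, heights, delta):
    """Integrate up to max_steps; stop early on a pending division.

    ``sx..srb`` are static floor cells (recently frozen) that enter the
    contact forces but never move.  Returns (status, steps_done, time,
    max_overlap_seen, n_coincident).
    """
    rm = 0.5 * sigma
    ncols = int(round(box_w / sigma))
    if ncols < 1:
        ncols = 1
    colw = box_w / ncols
    ntab = g_table.shape[0]
    n_tot = n + ns
    cx = np.empty(n_tot)
    cy = np.empty(n_tot)
    cth = np.empty(n_tot)
    crb = np.empty(n_tot)
    cid = np.empty(n_tot, dtype=np.int64)
    for j in range(ns):
        cx[n + j] = sx[j]
        cy[n + j] = sy[j]
        cth[n + j] = stheta[j]
        crb[n + j] = srb[j]
        cid[n + j] = -1 - j  # unique, distinct from live ids
    for i in range(n):
        cx[i] = x[i]
        cy[i] = y[i]
        cth[i] = theta[i]
        crb[i] = rb[i]
        cid[i] = cell_id[i]
    fx = np.empty(n)
    fy = np.empty(n)
    tq = np.empty(n)
    t = time0
    steps = 0
    max_ov_seen = 0.0
    n_coinc_tot = 0
    status = _STATUS_MAXSTEPS
    for _ in range(max_steps):
        _front_heights(cx, cy, cth, crb, n, rm, ncols, colw, box_w, heights)
        for i in range(n):
            c = int(cx[i] / colw)
            if c >= ncols:
                c = ncols - 1
            dpt = heights[c] - cy[i]
            delta[i] = dpt if dpt > 0.0 else 0.0
        max_ov, n_coinc = _pair_forces(
            cx, cy, cth, crb, cid, n, n_tot, sigma, box_w, k_spring,
            fx, fy, tq
        )
        n_coinc_tot += n_coinc
        if max_ov > max_ov_seen:
            max_ov_seen = max_ov
        if max_ov > 0.5 * sigma:
            status = _STATUS_UNSTABLE
            break
        div_pending = False
        for i in range(n):
            area = math.pi * (rm * rm + crb[i] * crb[i])
            inv = 1.0 / (damping * area)
            ux = math.cos(cth[i])
            uy = math.sin(cth[i])
            coff = (rm + crb[i]) * (crb[i] * crb[i]) / (rm * rm + crb[i] * crb[i])
            # translate the centroid
            cx[i] += dt * fx[i] * inv
            cy[i] += dt * fy[i] * inv
            # rotate about the centroid
            dth = dt * tq[i] / (damping * area * rm * rm)
            if dth != 0.0:
                ccx = cx[i] + coff * ux
                ccy = cy[i] + coff * uy
                relx = cx[i] - ccx
                rely = cy[i] - ccy
                cdt = math.cos(dth)
                sdt = math.sin(dth)
                cx[i] = ccx + cdt * relx - sdt * rely
                cy[i] = ccy + sdt * relx + cdt * rely
                cth[i] += dth
            cx[i] = cx[i] % box_w
            # growth: only inside the growth layer
            if growing[i] and delta[i] < lambda_depth:
                gi = int(delta[i] / lambda_depth * ntab)
                if gi >= ntab:
                    gi = ntab - 1
                g = g_table[gi]
                if label[i] >= 0 and sel_s != 0.0:
                    g = g * (1.0 + sel_s)
                if g > 0.0:
                    fgrow = math.exp(g * dt) - 1.0
                    rb2 = crb[i] * crb[i] + (rm * rm + crb[i] * crb[i]) * fgrow
                    crb[i] = math.sqrt(rb2)
                    if crb[i] >= rm:
                        crb[i] = rm
                        div_pending = True
        t += dt
        steps += 1
        if div_pending:
            status = _STATUS_DIVISION
            break
    for i in range(n):
        x[i] = cx[i]
        y[i] = cy[i]
        theta[i] = cth[i]
        rb[i] = crb[i]
    return status, steps, t, max_ov_seen, n_coinc_tot


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def init_population(config: SimConfig, rng=None) -> PopulationState:
    """One row of touching, unlabeled, growing cells spanning the box at y=0.

    Without an ``rng`` every cell starts as a fresh newborn (bud radius 0)
    oriented straight up on a regular row.  With an ``rng``, division
    phases (bud sizes), orientations and horizontal positions are jittered
    — :func:`run` does this to break the artificial symmetry of a
    deterministic starting row, which would otherwise grow as a columnar
    crystal of non-interacting, synchronously dividing vertical stacks
    instead of a disordered front.
    """
    ncells = int(config.box_width // config.sigma)
    if ncells < 1:
        raise ConfigurationError("box_width must accommodate at least one cell")
    state = PopulationState(config, capacity=max(256, 4 * ncells))
    rm = config.sigma / 2.0
    for i in range(ncells):
        rb = 0.0
        x = (i + 0.5) * config.sigma
        th = math.pi / 2.0
        if rng is not None:
            # overlap-free disorder: random cycle phases and <= 0.2 sigma
            # of positional jitter (max initial overlap 0.4 sigma, well
            # under the instability bound); orientational disorder then
            # develops through contact torques
            age = rng.random()  # uniform phase of the doubling cycle
            rb = rm * math.sqrt(2.0 ** age - 1.0)
            x += rng.uniform(-0.2, 0.2) * config.sigma
        state.add_cell(
            x=x, y=0.0, theta=th, rb=rb, label=UNLABELED, birth_time=0.0,
        )
    return state


def compute_forces(state: PopulationState, config: SimConfig):
    """Net force (fx, fy) and torque on every live cell.

    Contact forces are pairwise linear repulsions between overlapping disks
    of distinct cells (minimum image across the periodic boundary); each
    cell's disk forces are reduced to one net force plus a torque about the
    cell's area centroid.
    """
    n = state.n_live
    ns = state.n_static
    fx = np.zeros(n)
    fy = np.zeros(n)
    tq = np.zeros(n)
    if n == 0:
        return fx, fy, tq
    st = state._static
    xs = np.concatenate([state.x[:n], st["x"]])
    ys = np.concatenate([state.y[:n], st["y"]])
    ths = np.concatenate([state.theta[:n], st["theta"]])
    rbs = np.concatenate([state.rb[:n], st["rb"]])
    cids = np.concatenate([
        state.cell_id[:n], -1 - np.arange(ns, dtype=np.int64)
    ])
    max_ov, n_coinc = _pair_forces(
        xs, ys, ths, rbs, cids, n, n + ns, config.sigma, config.box_width,
        config.spring_constant, fx, fy, tq,
    )
    if n_coinc:
        logger.warning("%d coincident disk centers; deterministic fallback used",
                       n_coinc)
    return fx, fy, tq


def front_profile(state: PopulationState, config: SimConfig) -> FrontProfile:
    """Column-wise front height over live cells (column width ~ sigma)."""
    n = state.n_live
    if n == 0:
        raise ValueError("front profile requires at least one cell")
    ncols = max(1, int(round(config.box_width / config.sigma)))
    colw = config.box_width / ncols
    heights = np.empty(ncols)
    _front_heights(state.x[:n], state.y[:n], state.theta[:n], state.rb[:n],
                   n, config.sigma / 2.0, ncols, colw, config.box_width,
                   heights)
    edges = np.arange(ncols + 1) * colw
    prof = FrontProfile(column_edges=edges, heights=heights)
    state.front = prof
    return prof


def _process_divisions(state: PopulationState, config: SimConfig, rng,
                       registry=None) -> int:
    """Divide every cell whose bud reached sigma/2, in cell-id order.

    The bud becomes a new cell (bud_radius 0); orientation follows
    ``bud_rule``; the labelling hook is invoked once per newborn.  Random
    draws per newborn occur in a fixed order: labelling first, then the bud
    angle (only for the 'random' rule).
    """
    rm = config.sigma / 2.0
    ready = np.flatnonzero(state.rb[: state.n_live] >= rm - 1e-12)
    if len(ready) == 0:
        return 0
    order = ready[np.argsort(state.cell_id[ready], kind="stable")]
    front = state.front
    ndiv = 0
    for i in order:
        ux = math.cos(state.theta[i])
        uy = math.sin(state.theta[i])
        bx = (state.x[i] + (rm + state.rb[i]) * ux) % config.box_width
        by = state.y[i] + (rm + state.rb[i]) * uy
        mother_label = int(state.label[i])
        state.rb[i] = 0.0
        # fixed draw order: labelling, then bud angle
        newborn_label = mother_label
        record = None
        if registry is not None:
            record = registry.maybe_label(
                mother_label, bx, by, front, state.time, rng
            )
            if record is not None:
                newborn_label = record.label
            elif newborn_label >= 0:
                registry.note_inheritance(newborn_label)
        else:
            rng.random()  # keep the stream layout identical without a registry
        if config.bud_rule == "random":
            newtheta = rng.uniform(0.0, 2.0 * math.pi)
        else:
            newtheta = state.theta[i]
        j = state.add_cell(bx, by, newtheta, 0.0, newborn_label, state.time)
        state.growing[j] = True
        state.n_divisions += 1
        ndiv += 1
    return ndiv


def step(state: PopulationState, config: SimConfig, rng=None, registry=None,
         n_steps: int = 1) -> PopulationState:
    """Advance the state by up to ``n_steps`` integration steps (in place).

    Stops early when a division becomes pending, processes the division(s),
    and returns.  Raises :class:`InstabilityError` on excessive overlap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = state.n_live
    heights = np.empty(max(1, int(round(config.box_width / config.sigma))))
    delta = np.empty(n)
    st = state._static
    status, steps, t, max_ov, n_coinc = _advance(
        state.x, state.y, state.theta, state.rb, state.label, state.growing,
        state.cell_id, n, st["x"], st["y"], st["theta"], st["rb"],
        state.n_static, state.time, n_steps, config.sigma, config.box_width,
        config.dt, config.spring_constant, config.damping, config.lambda_depth,
        config.selection_s, config._growth_table(), heights, delta,
    )
    state.time = t
    if n_coinc:
        logger.warning("%d coincident disk centers; deterministic fallback used",
                       n_coinc)
    if status == _STATUS_UNSTABLE:
        raise InstabilityError(
            f"overlap {max_ov:.3g} exceeded sigma/2; reduce dt or stiffen contacts"
        )
    ncols = len(heights)
    edges = np.arange(ncols + 1) * (config.box_width / ncols)
    state.front = FrontProfile(column_edges=edges, heights=heights.copy())
    if status == _STATUS_DIVISION:
        _process_divisions(state, config, rng, registry)
    return state


@dataclass
class SimulationResult:
    """Outcome of :func:`run`: final state, clone records, front time series."""

    config: SimConfig
    state: PopulationState
    clones: list = field(default_factory=list)
    front_series: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n_divisions(self) -> int:
        return self.state.n_divisions

    @property
    def cells_created(self) -> int:
        return self.state.n_cells


def run(config: SimConfig, progress: bool = False) -> SimulationResult:
    """Run a full simulation until ``stop_divisions`` divisions occurred.

    Couples the mechanics to clone labelling/tracking; freezes cells deeper
    than ``removal_depth``; records the mean front height once per generation
    after a 5-generation transient.  Fully reproducible given the seed.
    """
    from .lineage import CloneRegistry

    rng = np.random.default_rng(config.seed)
    state = init_population(config, rng=rng)
    registry = CloneRegistry(config)
    gtable = config._growth_table()
    ncols = max(1, int(round(config.box_width / config.sigma)))
    colw = config.box_width / ncols
    heights = np.empty(ncols)
    edges = np.arange(ncols + 1) * colw
    gen_t = config.generation_time
    chunk = max(1, int(0.25 * gen_t / config.dt))
    next_record = 5.0 * gen_t
    series: list[tuple[float, float]] = []
    rm = config.sigma / 2.0
    while state.n_divisions < config.stop_divisions:
        n = state.n_live
        delta = np.empty(n)
        st = state._static
        status, steps, t, max_ov, n_coinc = _advance(
            state.x, state.y, state.theta, state.rb, state.label,
            state.growing, state.cell_id, n, st["x"], st["y"], st["theta"],
            st["rb"], state.n_static, state.time, chunk,
            config.sigma, config.box_width, config.dt, config.spring_constant,
            config.damping, config.lambda_depth, config.selection_s, gtable,
            heights, delta,
        )
        state.time = t
        if status == _STATUS_UNSTABLE:
            raise InstabilityError(
                f"overlap {max_ov:.3g} exceeded sigma/2 at t={t:.4g}; "
                "reduce dt or stiffen contacts"
            )
        state.front = FrontProfile(column_edges=edges, heights=heights.copy())
        if state.time >= next_record:
            series.append((state.time, float(np.mean(heights))))
            next_record += gen_t
        if status == _STATUS_DIVISION:
            _process_divisions(state, config, rng, registry)
            # freeze deep cells (cannot grow again; keeps force set small)
            nl = state.n_live
            col = np.minimum(
                (state.x[:nl] / colw).astype(np.int64), ncols - 1
            )
            depth = heights[col] - state.y[:nl]
            deep = np.flatnonzero(depth > config.removal_depth)
            if len(deep) > 0:
                state.growing[:nl][deep] = False
                registry.note_freeze(
                    state.label[:nl][deep], state.rb[:nl][deep], rm
                )
                state.freeze(deep)
                state.purge_static(
                    float(np.max(heights))
                    - (config.removal_depth + 4.0 * config.sigma)
                )
                nl = state.n_live
                col = np.minimum(
                    (state.x[:nl] / colw).astype(np.int64), ncols - 1
                )
                depth = heights[col] - state.y[:nl]
            # finalize clones with no member left in the growth layer
            in_layer = depth < config.lambda_depth
            labels_in_layer = np.unique(
                state.label[:nl][in_layer & (state.label[:nl] >= 0)]
            )
            registry.finalize_step(
                labels_in_layer, state.time,
                live_labels=state.label[:nl], live_rb=state.rb[:nl], rm=rm,
            )
        if progress and status == _STATUS_DIVISION and state.n_divisions % 2000 < 2:
            logger.info(
                "t=%.1f gen, divisions=%d, live=%d, clones=%d",
                state.time / gen_t, state.n_divisions, state.n_live,
                len(registry.records),
            )
    registry.close(
        state.time,
        live_labels=state.label[: state.n_live],
        live_rb=state.rb[: state.n_live],
    )
    return SimulationResult(
        config=config, state=state, clones=registry.records,
        front_series=np.asarray(series).reshape(-1, 2),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_snapshot(result_or_state, config: SimConfig, path) -> None:
    """Cell snapshot TSV: one row per cell ever created, positions in sigma."""
    import pandas as pd

    state = getattr(result_or_state, "state", result_or_state)
    arr = state.snapshot_arrays()
    lab = arr["label"]
    lab_col = np.where(lab >= 0, lab.astype(object), "unlabeled")
    df = pd.DataFrame({
        "cell_id": arr["cell_id"],
        "x": arr["x"] / config.sigma,
        "y": arr["y"] / config.sigma,
        "theta": arr["theta"],
        "bud_radius": arr["rb"] / config.sigma,
        "clone_label": lab_col,
        "growing": arr["growing"].astype(int),
        "birth_time": arr["birth_time"] / config.generation_time,
    })
    df.to_csv(path, sep="\t", index=False)


def write_front_series(result: SimulationResult, path) -> None:
    """Front-height time series TSV (time in generations, height in sigma)."""
    import pandas as pd

    cfg = result.config
    df = pd.DataFrame({
        "time": result.front_series[:, 0] / cfg.generation_time,
        "mean_height": result.front_series[:, 1] / cfg.sigma,
    })
    df.to_csv(path, sep="\t", index=False)


def front_speed_fit(result: SimulationResult) -> tuple[float, float]:
    """Linear fit of mean front height vs time: returns (speed, R^2)."""
    ts = result.front_series
    if len(ts) < 3:
        raise ValueError("need at least 3 recorded front heights")
    t, h = ts[:, 0], ts[:, 1]
    slope, intercept = np.polyfit(t, h, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((h - pred) ** 2))
    ss_tot = float(np.sum((h - np.mean(h)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2
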