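"""Clone labelling, tracking and surfing/nonsurfing classification.

Newborn cells are labelled with a fresh clone identifier with probability
``label_rate`` at division, mimicking neutral mutations (or a heritable
colour switch) whose rate is proportional to the growth rate.  Each labelled
lineage is tracked until no member remains inside the growth layer, at which
point its size is frozen: cells outside the layer no longer divide, so the
clone has reached its final size ("washout").  Clones founded within one
cell width of the front are classified as surfing; all others are
nonsurfing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mechsim import UNLABELED, Cell, FrontProfile, SimConfig

logger = logging.getLogger(__name__)


@dataclass
class CloneRecord:
    """One labelled lineage.

    ``birth_delta`` is the vertical distance from the front at the labelling
    instant.  ``final_size`` is the clone's size once no member is in the
    growth layer, in area-equivalent cells: the total member area in units
    of the newborn area, rounded.  Washout interrupts members mid-cycle,
    so the raw cell count systematically undershoots the clone's area
    growth by the mean mid-cycle area factor; the area-equivalent count
    (the same measure as using clone area as a size proxy) is phase-free.
    The raw member count is kept in ``final_cell_count``.  ``surfing`` means the clone arose within one
    cell width of the front (boundary inclusive).  ``active`` clones still
    had members in the growth layer when the run ended; their size is
    censored and they are excluded from spectra by default.
    """

    label: int
    birth_time: float
    birth_x: float
    birth_y: float
    birth_delta: float
    final_size: int = 1
    final_cell_count: int = 1
    surfing: bool = False
    active: bool = True
    finalized_time: float | None = None


def classify_clone(record: CloneRecord, sigma: float) -> str:
    """'surfing' iff the clone arose within one cell width of the front."""
    if record.birth_delta < 0:
        raise ValueError("birth_delta must be non-negative")
    return "surfing" if record.birth_delta <= sigma else "nonsurfing"


class CloneRegistry:
    """Bookkeeping for labelling events and clone sizes during a run.

    Under the default policy (``relabel_policy='always'``) every newborn
    founds a new clone with probability ``label_rate`` regardless of the
    mother's state, the infinite-alleles analogue of a constant mutation
    rate per division: a cell's clone is the most recent founding event on
    its ancestry, so clones remain disjoint and founding never saturates.
    ``relabel_policy='unlabeled-only'`` restricts founding to newborns of
    unlabeled mothers (an irreversible colour switch); note that in a
    finite box a surfing clone eventually fixes at the front and founding
    then stops.  Exactly one uniform draw is consumed per division, whether
    or not a label is assigned, keeping the random stream layout
    independent of the labelling outcome.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self.records: list[CloneRecord] = []
        self._by_label: dict[int, CloneRecord] = {}
        self._sizes: dict[int, int] = {}
        # area (in newborn units) of members already frozen out of the
        # force set (their bud phase can no longer change)
        self._adj_frozen: dict[int, float] = {}
        self._active: set[int] = set()
        self.next_label = 0

    # -- hooks called by the simulation driver ------------------------------

    def maybe_label(self, mother_label: int, x: float, y: float,
                    front: FrontProfile, time: float, rng) -> CloneRecord | None:
        u = rng.random()
        if u >= self.config.label_rate:
            return None
        policy = getattr(self.config, "relabel_policy", "always")
        if policy == "unlabeled-only" and mother_label != UNLABELED:
            return None
        delta = front.depth_of(x, y) if front is not None else 0.0
        rec = CloneRecord(
            label=self.next_label, birth_time=time, birth_x=x, birth_y=y,
            birth_delta=delta, final_size=1,
            surfing=delta <= self.config.sigma, active=True,
        )
        self.next_label += 1
        self.records.append(rec)
        self._by_label[rec.label] = rec
        self._sizes[rec.label] = 1
        self._adj_frozen[rec.label] = 0.0
        self._active.add(rec.label)
        return rec

    def note_inheritance(self, label: int) -> None:
        if label in self._sizes and label in self._active:
            self._sizes[label] += 1

    def note_freeze(self, labels: np.ndarray, bud_radii: np.ndarray,
                    rm: float) -> None:
        """Record the area of cells leaving the force set for good."""
        for lab, rb in zip(labels, bud_radii):
            lab = int(lab)
            if lab in self._adj_frozen:
                self._adj_frozen[lab] += 1.0 + (rb / rm) ** 2

    def _adjusted_size(self, lab: int, live_labels, live_rb, rm: float) -> int:
        """Area-equivalent size: total member area in newborn units,
        rounded.  Summing areas before rounding keeps sub-cell resolution;
        mother and daughter reset their bud phases together at division,
        so per-member thresholds would cross in lockstep and make odd
        counts artificially rare."""
        area = self._adj_frozen.get(lab, 0.0)
        if live_labels is not None:
            mem = live_labels == lab
            if np.any(mem):
                area += float(np.sum(1.0 + (live_rb[mem] / rm) ** 2))
        return max(int(round(area)), 1)

    def finalize_step(self, labels_in_layer: np.ndarray, time: float,
                      live_labels=None, live_rb=None,
                      rm: float | None = None) -> None:
        """Finalize every active clone with no member left in the layer.

        ``live_labels``/``live_rb`` are the label and bud-radius arrays of
        the cells still in the force set, used to evaluate the
        area-equivalent size of members not yet frozen.
        """
        still = set(int(l) for l in labels_in_layer)
        done = self._active - still
        if rm is None:
            rm = self.config.sigma / 2.0
        for lab in done:
            rec = self._by_label[lab]
            rec.final_cell_count = self._sizes[lab]
            rec.final_size = self._adjusted_size(lab, live_labels, live_rb, rm)
            rec.active = False
            rec.finalized_time = time
        self._active -= done

    def close(self, time: float, live_labels=None, live_rb=None) -> None:
        """End of run: clones still in the layer stay flagged active
        (censored) but carry their current size."""
        rm = self.config.sigma / 2.0
        for lab in self._active:
            rec = self._by_label[lab]
            rec.final_cell_count = self._sizes[lab]
            rec.final_size = self._adjusted_size(lab, live_labels, live_rb, rm)


def label_newborn(newborn: Cell, front: FrontProfile, config: SimConfig,
                  time: float, rng, registry: CloneRegistry | None = None,
                  mother_label: int = UNLABELED) -> CloneRecord | None:
    """Labelling hook for a single newborn (one call per division event).

    With probability ``label_rate`` — and only when the mother is unlabeled —
    assigns a fresh clone label and returns the new :class:`CloneRecord`
    with ``birth_delta`` measured against the current front profile;
    otherwise returns ``None`` (the newborn inherits the mother's label).
    """
    if registry is None:
        registry = CloneRegistry(config)
    x, y = newborn.mother_center
    if not (0.0 <= x <= config.box_width):
        raise RuntimeError("newborn outside the periodic box")
    return registry.maybe_label(mother_label, x, y, front, time, rng)


def finalize_clones(result, include_active: bool = False) -> list[CloneRecord]:
    """Finalized clone records of a completed run.

    Clones still active at the end of the run are censored and excluded
    unless ``include_active`` is set (their current size is then reported).
    """
    recs = [r for r in result.clones if include_active or not r.active]
    return recs


def clone_sizes(result, kind: str = "all", include_active: bool = False) -> np.ndarray:
    """Final sizes of finalized clones, optionally restricted to a class.

    ``kind`` is 'all', 'surfing' or 'nonsurfing'.
    """
    recs = finalize_clones(result, include_active=include_active)
    if kind == "surfing":
        recs = [r for r in recs if r.surfing]
    elif kind == "nonsurfing":
        recs = [r for r in recs if not r.surfing]
    elif kind != "all":
        raise ValueError(f"unknown clone kind {kind!r}")
    return np.array([r.final_size for r in recs], dtype=float)


def write_clone_table(result, path) -> None:
    """Clone table TSV; distances in units of sigma, time in generations."""
    import pandas as pd

    cfg = result.config
    recs = result.clones
    df = pd.DataFrame({
        "label": [r.label for r in recs],
        "birth_time": [r.birth_time / cfg.generation_time for r in recs],
        "birth_x": [r.birth_x / cfg.sigma for r in recs],
        "birth_y": [r.birth_y / cfg.sigma for r in recs],
        "birth_delta": [r.birth_delta / cfg.sigma for r in recs],
        "final_size": [r.final_size for r in recs],
        "final_cell_count": [r.final_cell_count for r in recs],
        "surfing": [int(r.surfing) for r in recs],
        "active": [int(r.active) for r in recs],
    })
    df.to_csv(path, sep="\t", index=False)


def read_clone_table(path):
    """Read a clone table TSV written by :func:`write_clone_table`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"label", "birth_delta", "final_size", "surfing", "active"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clone table missing columns: {sorted(missing)}")
    return df
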