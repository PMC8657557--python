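"""Quantification of functional assays from binary masks and FOV counts.

Four readouts:

* percent wound closure from time-paired scratch-assay masks,
* spheroid invasion area (growth of the occupied halo) in square microns,
* mean +/- SEM of per-high-powered-field-of-view (HP-FOV) transwell
  counts,
* BrdU-positive fraction of total nuclei.

Masks are binary occupancy grids (1 = cells / occupied).  Out-of-range
results (cells retracting, halo shrinking) are clipped or floored in the
returned value but preserved raw and flagged for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure


@dataclass
class AssayMask:
    """Binary occupancy grid for one assay timepoint."""

    grid: np.ndarray
    pixel_size_um: float = 1.0
    timepoint: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        self.grid = g.astype(np.uint8)

    @property
    def occupied_px(self) -> int:
        return int(self.grid.sum())

    @property
    def free_px(self) -> int:
        return int(self.grid.size - self.grid.sum())


@dataclass
class WoundClosureResult:
    percent: float  # clipped to [0, 100]
    raw_percent: float
    flagged: bool
    wound_px_t0: int
    wound_px_t: int


@dataclass
class InvasionResult:
    area_um2: float  # floored at 0
    raw_area_um2: float
    flagged: bool


@dataclass
class FovSummary:
    mean: float
    sem: float
    n_fov: int
    flagged: bool = field(default=False)  # True when SEM undefined (n=1)


def _check_dims(m0: AssayMask, mt: AssayMask) -> None:
    if m0.grid.shape != mt.grid.shape:
        raise ValueError(
            f"mask dimensions differ: {m0.grid.shape} vs {mt.grid.shape}"
        )


def wound_region(mask_t0: AssayMask) -> np.ndarray:
    """Boolean window of the wound: largest cell-free connected component.

    The scratch is the dominant empty region at t0; tracking the same
    window at later timepoints measures closure rather than unrelated
    gaps between cells.
    """
    free = mask_t0.grid == 0
    if not free.any():
        raise ValueError("no cell-free area at t0 — zero initial wound")
    labels = measure.label(free, connectivity=1)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    return labels == counts.argmax()


def wound_closure(mask_t0: AssayMask, mask_t: AssayMask) -> WoundClosureResult:
    """Percent wound closure between t0 and t.

    closure% = 100 * (A_wound(t0) - A_wound(t)) / A_wound(t0), where the
    wound area at t is the cell-free area remaining inside the t0 wound
    window.  Values outside [0, 100] (retraction or over-closure) are
    clipped in ``percent`` and flagged.
    """
    _check_dims(mask_t0, mask_t)
    window = wound_region(mask_t0)
    a0 = int(window.sum())
    if a0 == 0:
        raise ValueError("zero initial wound area")
    at = int(((mask_t.grid == 0) & window).sum())
    raw = 100.0 * (a0 - at) / a0
    clipped = float(np.clip(raw, 0.0, 100.0))
    return WoundClosureResult(
        percent=clipped,
        raw_percent=raw,
        flagged=not (0.0 <= raw <= 100.0),
        wound_px_t0=a0,
        wound_px_t=at,
    )


def spheroid_invasion(mask_t0: AssayMask, mask_t: AssayMask) -> InvasionResult:
    """Area invaded into the matrix between t0 and t, in square microns.

    Difference in occupied pixels scaled by the squared pixel size.
    Negative growth is floored at 0 and flagged.
    """
    _check_dims(mask_t0, mask_t)
    if mask_t0.occupied_px == 0:
        raise ValueError("empty spheroid mask at t0")
    px2 = mask_t0.pixel_size_um**2
    raw = (mask_t.occupied_px - mask_t0.occupied_px) * px2
    return InvasionResult(
        area_um2=float(max(raw, 0.0)), raw_area_um2=float(raw), flagged=raw < 0
    )


def fov_summary(counts, n_fov: int | None = None) -> FovSummary:
    """Mean and SEM of per-FOV counts (SEM = sample SD / sqrt(n)).

    With a single FOV the SEM is undefined; it is reported as 0 with the
    result flagged.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("no FOV counts")
    if n_fov is not None and n_fov != c.size:
        raise ValueError(f"expected {n_fov} FOVs, got {c.size}")
    if c.size == 1:
        return FovSummary(mean=float(c[0]), sem=0.0, n_fov=1, flagged=True)
    sem = float(c.std(ddof=1) / np.sqrt(c.size))
    return FovSummary(mean=float(c.mean()), sem=sem, n_fov=int(c.size))


def brdu_fraction(brdu_positive: int, total_nuclei: int) -> float:
    """Percent of BrdU-positive cells among total (DAPI+) nuclei."""
    if total_nuclei <= 0:
        raise ValueError("total nuclei must be positive")
    if brdu_positive < 0 or brdu_positive > total_nuclei:
        raise ValueError(
            f"positive count {brdu_positive} outside [0, {total_nuclei}]"
        )
    return 100.0 * brdu_positive / total_nuclei


def count_mask_objects(mask: AssayMask) -> int:
    """Number of connected occupied components (e.g. nuclei) in a mask."""
    labels = measure.label(mask.grid, connectivity=1)
    return int(labels.max())
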