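"""Cell-shape roundness scoring and three-class morphology calls.

Each cell is summarised by the ratio of its actual outline area (AA) to
the area of the circle whose diameter is the cell's longest axis (the
expected area, EA = pi * (d/2)**2 with d the maximum Feret diameter).
The score lies in (0, 1]: 1 for a perfect circle (epithelial-like), near
0 for a thin spindle (mesenchymal-like).

Class cutoffs are derived from control populations: the epithelial cutoff
is the epithelial-control mean minus one sample SD, the mesenchymal cutoff
the mesenchymal-control mean plus one sample SD.  Cells scoring at or
above the epithelial cutoff are called epithelial, at or below the
mesenchymal cutoff mesenchymal, and anything between "mixed" — the
signature of a partial-EMT population.  Boundary scores are classified
inclusively; both cutoff rules are explicit in :func:`classify_cells`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from shapely.geometry import Polygon

CLASSES = ("epithelial", "mixed", "mesenchymal")


@dataclass(frozen=True)
class CellOutline:
    """Closed polygon boundary of a single cell, in pixel units.

    ``vertices`` is an (n, 2) array of ordered (x, y) points; the closing
    edge from the last vertex back to the first is implicit.
    """

    cell_id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs an (n>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def validate(self) -> None:
        poly = self.polygon()
        if not poly.is_valid:
            raise ValueError(f"outline {self.cell_id!r} is self-intersecting")
        if poly.area <= 0:
            raise ValueError(f"outline {self.cell_id!r} has zero area")


@dataclass(frozen=True)
class MorphologyCutoffs:
    """Score thresholds separating the three morphology classes."""

    epithelial_cut: float
    mesenchymal_cut: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mesenchymal_cut < self.epithelial_cut <= 1.0:
            raise ValueError(
                "need 0 < mesenchymal_cut < epithelial_cut <= 1, got "
                f"({self.epithelial_cut:.4g}, {self.mesenchymal_cut:.4g}); "
                "control populations overlap — use better-separated controls"
            )


@dataclass
class MorphologyReport:
    """Per-cell scores/classes and the population class percentages."""

    cells: pd.DataFrame  # columns: score, morphology_class
    percentages: dict[str, float]
    cutoffs: MorphologyCutoffs

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"class percentages sum to {total}, not 100")


def feret_diameter(vertices: np.ndarray) -> float:
    """Maximum pairwise distance between boundary points.

    Computed on the convex hull (the maximum is always attained between
    hull vertices), which keeps the pairwise search small for dense
    outlines.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) > 8:
        try:
            v = v[ConvexHull(v).vertices]
        except Exception:  # degenerate (collinear) input: brute force below
            pass
    return float(pdist(v).max())


def roundness_score(outline: CellOutline) -> float:
    """AA/EA roundness of one cell, in (0, 1].

    AA is the polygon (shoelace) area; EA = pi * (d/2)**2 with d the
    maximum Feret diameter of the outline.  Scores are clipped to 1 from
    above (discretized circles can overshoot by floating-point noise).
    """
    poly = outline.polygon()
    if not poly.is_valid:
        raise ValueError(f"outline {outline.cell_id!r} is self-intersecting")
    area = poly.area
    if area <= 0:
        raise ValueError(f"outline {outline.cell_id!r} has zero area")
    d = feret_diameter(outline.vertices)
    if d <= 0:
        raise ValueError(f"outline {outline.cell_id!r} has zero diameter")
    expected = np.pi * (d / 2.0) ** 2
    return float(min(area / expected, 1.0))


def derive_cutoffs(
    epithelial_scores, mesenchymal_scores
) -> MorphologyCutoffs:
    """Control-derived class cutoffs: mean(epi) - SD and mean(mes) + SD.

    SD is the sample standard deviation (ddof=1).  Raises if the
    resulting cutoffs overlap, which indicates the control populations do
    not separate round from spindle cells.
    """
    epi = np.asarray(epithelial_scores, dtype=float)
    mes = np.asarray(mesenchymal_scores, dtype=float)
    if epi.size < 2 or mes.size < 2:
        raise ValueError("need at least 2 control scores per population")
    epi_cut = float(epi.mean() - epi.std(ddof=1))
    mes_cut = float(mes.mean() + mes.std(ddof=1))
    return MorphologyCutoffs(epithelial_cut=epi_cut, mesenchymal_cut=mes_cut)


def classify_cells(scores, cutoffs: MorphologyCutoffs) -> MorphologyReport:
    """Call each cell epithelial / mixed / mesenchymal and summarise.

    ``scores`` may be a sequence or a mapping/Series keyed by cell id.
    score >= epithelial_cut -> epithelial; score <= mesenchymal_cut ->
    mesenchymal; otherwise mixed.
    """
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValueError("no scores to classify")
    if s.index.dtype.kind in "iu" and (s.index == range(len(s))).all():
        s.index = [f"cell_{i:04d}" for i in range(len(s))]
    calls = np.where(
        s.values >= cutoffs.epithelial_cut,
        "epithelial",
        np.where(s.values <= cutoffs.mesenchymal_cut, "mesenchymal", "mixed"),
    )
    cells = pd.DataFrame({"score": s, "morphology_class": calls})
    counts = cells["morphology_class"].value_counts()
    pct = {c: 100.0 * counts.get(c, 0) / len(cells) for c in CLASSES}
    return MorphologyReport(cells=cells, percentages=pct, cutoffs=cutoffs)


def score_outlines(outlines) -> pd.Series:
    """Roundness score per outline, indexed by cell id."""
    return pd.Series(
        {o.cell_id: roundness_score(o) for o in outlines}, name="score"
    )
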