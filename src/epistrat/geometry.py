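"""Interphase morphometrics of basal-layer cells.

Cells of the epidermal basal layer are represented by their segmented
outline in the basal (XY) plane plus an apical-basal height.  This module
computes the standard shape descriptors used to relate interphase geometry
to mitotic spindle orientation: cross-sectional area, height, the longest
planar axis (the "width" of the height:width ratio), the elongation
nematic, polygon (neighbour-number) class, packing density, mitotic index
and section thickness, together with the per-division alignment between
the division axis and the interphase long axis (Hertwig's rule).

Conventions: lengths in micrometres, angles in degrees; axial orientations
(headless directions) are reported modulo 180 degrees; the image plane is
y-down, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon as _ShPolygon
from shapely.strtree import STRtree

__all__ = [
    "CellShape",
    "FieldOfView",
    "polygon_area",
    "polygon_centroid",
    "cell_height",
    "longest_planar_axis",
    "height_width_ratio",
    "elongation_nematic",
    "polygon_class_distribution",
    "density",
    "proliferation_rate",
    "tissue_thickness",
    "hertwig_alignment",
    "axial_difference",
    "neighbor_counts_from_polygons",
]


class InvalidShapeError(ValueError):
    """Raised for degenerate or self-intersecting polygons."""


def _as_vertices(polygon) -> np.ndarray:
    v = np.asarray(polygon, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise InvalidShapeError("polygon needs >= 3 two-dimensional vertices")
    if not np.all(np.isfinite(v)):
        raise InvalidShapeError("polygon vertices must be finite")
    return v


def _validated(polygon) -> _ShPolygon:
    v = _as_vertices(polygon)
    p = _ShPolygon(v)
    if not p.is_valid or p.area <= 0.0:
        raise InvalidShapeError("polygon is self-intersecting or has zero area")
    return p


@dataclass
class CellShape:
    """One interphase basal cell.

    ``polygon`` is the ordered outline in the basal plane (μm); ``height``
    the apical-basal extent (μm); ``frame`` the interphase frame the shape
    was taken from (just before mitotic rounding, when known).
    """

    cell_id: str
    polygon: np.ndarray
    height: float
    neighbor_count: int | None = None
    frame: int | None = None

    def __post_init__(self):
        self.polygon = _as_vertices(self.polygon)
        if self.height is not None and self.height < 0:
            raise ValueError("height must be >= 0")

    @property
    def area(self) -> float:
        return polygon_area(self.polygon)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.polygon)


@dataclass
class FieldOfView:
    """A rectangular tissue region with its segmented cells."""

    field_id: str
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    cells: list[CellShape] = field(default_factory=list)
    mitotic_ids: set[str] = field(default_factory=set)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.bounds
        return (x1 - x0) * (y1 - y0)

    def interior_cells(self, tol: float = 1e-6) -> list[CellShape]:
        """Cells whose outline does not touch the field boundary.

        Boundary-clipped polygons bias shape statistics, so interior cells
        are the population for area/elongation/neighbour summaries, while
        every cell still counts toward density.
        """
        x0, y0, x1, y1 = self.bounds
        out = []
        for c in self.cells:
            v = c.polygon
            if (
                v[:, 0].min() > x0 + tol
                and v[:, 0].max() < x1 - tol
                and v[:, 1].min() > y0 + tol
                and v[:, 1].max() < y1 - tol
            ):
                out.append(c)
        return out


# ---------------------------------------------------------------------------
# scalar shape descriptors


def _signed_area_centroid(v: np.ndarray) -> tuple[float, float, float]:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.concatenate([x[1:], x[:1]]), np.concatenate([y[1:], y[:1]])
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if a == 0.0:
        raise InvalidShapeError("degenerate polygon")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return a, cx, cy


def polygon_area(polygon, validate: bool = True) -> float:
    """Planimetric (shoelace) area of a simple polygon, μm²."""
    if validate:
        return _validated(polygon).area
    a, _, _ = _signed_area_centroid(_as_vertices(polygon))
    return abs(a)


def polygon_centroid(polygon) -> np.ndarray:
    _, cx, cy = _signed_area_centroid(_as_vertices(polygon))
    return np.array([cx, cy])


def cell_height(apical_z: float, basal_z: float) -> float:
    """Apical-surface to basement-membrane distance, μm."""
    h = float(apical_z) - float(basal_z)
    if h < 0:
        raise ValueError("apical surface below basement membrane (negative height)")
    return h


def longest_planar_axis(polygon, method: str = "chord", validate: bool = True) -> tuple[float, float]:
    """Longest planar (XY) axis of a cell outline.

    Returns ``(length_um, orientation_deg)`` with the orientation axial,
    in [0, 180).  ``method="chord"`` (default) takes the literal longest
    vertex-to-vertex chord; ``method="ellipse"`` returns the major axis of
    the area-equivalent ellipse from the second-moment tensor.
    """
    v = _as_vertices(polygon)
    if validate:
        _validated(v)
    if method == "ellipse":
        mag, axis = elongation_nematic(v)
        mu = _central_second_moments(v)
        lam1 = 0.5 * (mu[0] + mu[1] + np.hypot(mu[0] - mu[1], 2 * mu[2]))
        return float(4.0 * np.sqrt(lam1)), axis
    if method != "chord":
        raise ValueError(f"unknown method {method!r}")
    diff = v[:, None, :] - v[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    dx, dy = v[j] - v[i]
    return float(np.sqrt(d2[i, j])), float(np.degrees(np.arctan2(dy, dx)) % 180.0)


def height_width_ratio(shape: CellShape, method: str = "chord") -> float:
    """Height over longest planar axis (H:W), dimensionless."""
    width, _ = longest_planar_axis(shape.polygon, method=method)
    if width <= 0:
        raise InvalidShapeError("zero-width cell")
    return float(shape.height) / width


def _central_second_moments(v: np.ndarray) -> tuple[float, float, float]:
    """Area-normalised central second moments (μxx, μyy, μxy) of a polygon."""
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.concatenate([x[1:], x[:1]]), np.concatenate([y[1:], y[:1]])
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if a == 0:
        raise InvalidShapeError("degenerate polygon")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    ixx = ((x**2 + x * xn + xn**2) * cross).sum() / (12.0 * a) - cx**2
    iyy = ((y**2 + y * yn + yn**2) * cross).sum() / (12.0 * a) - cy**2
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / (24.0 * a) - cx * cy
    return float(ixx), float(iyy), float(ixy)


def elongation_nematic(polygon, validate: bool = True) -> tuple[float, float]:
    """Cell-elongation nematic from the second-moment (shape) tensor.

    magnitude = 100·(λ₁−λ₂)/(λ₁+λ₂) with λᵢ the eigenvalues of the
    area-normalised central second-moment tensor; axis is the major
    eigenvector orientation in degrees, axial in [0, 180).  The ×100 scale
    puts values for moderately elongated cells in the tens.  A circle
    yields 0; an ellipse with axis ratio a/b has magnitude
    100·(a²−b²)/(a²+b²).
    """
    v = _as_vertices(polygon)
    if validate:
        _validated(v)
    ixx, iyy, ixy = _central_second_moments(v)
    tr = ixx + iyy
    if tr <= 0:
        raise InvalidShapeError("degenerate polygon")
    diff = np.hypot(ixx - iyy, 2 * ixy)
    magnitude = 100.0 * diff / tr
    axis = 0.5 * np.degrees(np.arctan2(2 * ixy, ixx - iyy)) % 180.0
    return float(magnitude), float(axis)


# ---------------------------------------------------------------------------
# field-level statistics


def polygon_class_distribution(fov: FieldOfView) -> pd.DataFrame:
    """Histogram of neighbour numbers (polygon classes) over interior cells.

    Classes are 4, 5, 6, 7 and "8+" as customarily plotted for epithelial
    packing; cells with unknown neighbour counts are skipped.
    """
    counts = {k: 0 for k in ["4", "5", "6", "7", "8+"]}
    total = 0
    for c in fov.interior_cells():
        if c.neighbor_count is None:
            continue
        n = int(c.neighbor_count)
        if n < 4:
            key = "4"  # 3-sided interior cells are segmentation artefacts; fold down
        elif n >= 8:
            key = "8+"
        else:
            key = str(n)
        counts[key] += 1
        total += 1
    df = pd.DataFrame({"polygon_class": list(counts), "count": list(counts.values())})
    df["proportion"] = df["count"] / total if total else 0.0
    return df


def density(fov: FieldOfView, reference_area: float = 1200.0) -> float:
    """Cells per ``reference_area`` μm² (centroid-in-bounds counting)."""
    if fov.area <= 0:
        raise ValueError("field has zero area")
    x0, y0, x1, y1 = fov.bounds
    n = 0
    for c in fov.cells:
        cx, cy = c.centroid
        if x0 <= cx <= x1 and y0 <= cy <= y1:
            n += 1
    return n * reference_area / fov.area


def proliferation_rate(fov: FieldOfView) -> float:
    """Mitotic cells as a percentage of all cells in the field."""
    if not fov.cells:
        raise ValueError("empty field")
    ids = {c.cell_id for c in fov.cells}
    return 100.0 * len(fov.mitotic_ids & ids) / len(ids)


def tissue_thickness(mask: np.ndarray, px_size: float) -> float:
    """Thickness of a tissue cross-section: foreground area / lateral extent.

    ``mask`` is a 2D binary XZ/sagittal section (rows = depth, columns =
    lateral position); thickness = (area in μm²) / (lateral foreground
    span in μm), i.e. the mean thickness over the imaged length.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2 or not m.any():
        raise ValueError("mask must be a non-empty 2D binary image")
    cols = np.flatnonzero(m.any(axis=0))
    extent_px = cols[-1] - cols[0] + 1
    return (m.sum() * px_size**2) / (extent_px * px_size)


# ---------------------------------------------------------------------------
# neighbour topology from segmented polygons


def neighbor_counts_from_polygons(
    polygons: dict[str, np.ndarray], tol: float = 0.1
) -> dict[str, int]:
    """Neighbour numbers from shared polygon edges.

    Two cells are neighbours when their outlines share boundary of positive
    length after snapping within ``tol`` μm (segmentation outlines rarely
    coincide exactly).
    """
    ids = list(polygons)
    shapes = [_validated(polygons[i]).buffer(tol / 2.0) for i in ids]
    tree = STRtree(shapes)
    counts = {i: 0 for i in ids}
    for k, s in enumerate(shapes):
        for j in tree.query(s):
            j = int(j)
            if j <= k:
                continue
            inter = s.intersection(shapes[j])
            # require genuine shared edge, not a corner touch
            if inter.area > tol**2:
                counts[ids[k]] += 1
                counts[ids[j]] += 1
    return counts


# ---------------------------------------------------------------------------
# Hertwig's rule: division axis vs interphase long axis


def axial_difference(a_deg: float, b_deg: float) -> float:
    """Smallest angle between two axial (mod-180°) orientations, in [0, 90]."""
    d = abs(a_deg - b_deg) % 180.0
    return min(d, 180.0 - d)


def hertwig_alignment(
    events: pd.DataFrame,
    shapes: dict[str, CellShape],
    width_method: str = "chord",
) -> tuple[pd.DataFrame, dict]:
    """Relate each division to its mother's interphase geometry.

    ``events`` needs columns ``mother_id``, ``angle_deg``, ``category`` and
    ``xy_axis_deg``; ``shapes`` maps mother_id to the pre-rounding
    CellShape.  Returns a per-event table with the interphase H:W ratio and
    Δxy (axial difference between the planar division axis and the longest
    planar axis) plus a summary: per-category H:W means, the Spearman rank
    correlation between H:W and division angle (one-sided, positive
    direction: taller/narrower cells divide more perpendicularly), and the
    mean Δxy of planar divisions.
    """
    rows = []
    skipped = 0
    for ev in events.itertuples(index=False):
        shape = shapes.get(ev.mother_id)
        if shape is None:
            skipped += 1
            continue
        width, orient = longest_planar_axis(shape.polygon, method=width_method)
        rows.append(
            {
                "mother_id": ev.mother_id,
                "angle_deg": ev.angle_deg,
                "category": ev.category,
                "hw_ratio": shape.height / width,
                "long_axis_deg": orient,
                "dxy_deg": axial_difference(ev.xy_axis_deg, orient),
            }
        )
    per_event = pd.DataFrame(rows)
    summary: dict = {"n": len(per_event), "n_unmatched": skipped}
    if (
        len(per_event) >= 3
        and per_event["hw_ratio"].nunique() > 1
        and per_event["angle_deg"].nunique() > 1
    ):
        rho, p_two = stats.spearmanr(per_event["hw_ratio"], per_event["angle_deg"])
        p_one = p_two / 2.0 if rho > 0 else 1.0 - p_two / 2.0
        summary["spearman_rho"] = float(rho)
        summary["spearman_p_one_sided"] = float(p_one)
    summary["hw_mean_by_category"] = (
        per_event.groupby("category")["hw_ratio"].mean().to_dict() if len(per_event) else {}
    )
    planar = per_event[per_event["category"] == "planar"] if len(per_event) else per_event
    summary["mean_dxy_planar_deg"] = (
        float(planar["dxy_deg"].mean()) if len(planar) else float("nan")
    )
    return per_event, summary
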