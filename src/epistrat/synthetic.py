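"""Synthetic basal-layer generator with known ground truth.

Every quantity the analysis modules measure — division angles and
categories, positional fates, cell areas/heights/elongations, packing
density, junctional polarity — is generated here from explicit parameters
(:class:`~epistrat.config.SimulationConfig`), so the whole pipeline is
verifiable by parameter recovery without any microscopy data.

What is emulated: a rectangular field of view of the basal layer packed as
a centroidal-relaxed Voronoi tessellation (two Lloyd iterations give
realistic polygon-class distributions without a mechanics engine);
truncated-Gaussian apical-basal heights; nuclear tracks at a fixed frame
interval with divisions whose telophase daughter separation encodes the
sampled division axis; fates realised as z-trajectories relative to a
basal/suprabasal threshold shared with the analyser; and edge-intensity
fields whose per-cell nematic is (m, φ₀) in expectation.

Division angles come from one of two laws.  Mixture mode draws the
category (planar/oblique/perpendicular) from configured weights and the
angle uniformly (or sine-weighted, for a 3D-isotropic null) within the
category's bounds.  Hertwig mode divides along the interphase 3D long
axis: the longest planar chord when the cell is wider than tall
(elevation 0°), the apical-basal axis when taller than wide (elevation
90°), plus wrapped Gaussian noise — so taller, narrower cells divide more
perpendicularly, the long-axis rule in three dimensions.

All randomness flows from per-stage generators derived from the single
config seed; a fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from .config import SimulationConfig, InvalidConfigError
from .division import classify_angle
from .geometry import (
    CellShape,
    FieldOfView,
    elongation_nematic,
    longest_planar_axis,
    polygon_area,
    polygon_centroid,
)

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "generate_field",
    "sample_division_angle",
    "sample_divisions",
    "emit_tracks",
    "emit_edge_intensities",
    "simulate",
    "render_label_mask",
]

_CATEGORY_BOUNDS = {"planar": (0.0, 20.0), "oblique": (20.0, 70.0), "perpendicular": (70.0, 90.0)}
_CATEGORIES = ("planar", "oblique", "perpendicular")

# fixed per-stage rng streams so each emission is deterministic in the seed
_STREAMS = {"field": 11, "divisions": 23, "tracks": 37, "edges": 53}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stage]]))


@dataclass
class GroundTruth:
    """The generating parameters realised per cell and per division.

    ``polarity_magnitude``/``polarity_axis_deg`` are the *realised* tissue
    nematic — the resultant of the per-cell nematics (magnitude m, the
    drawn per-cell axes) over the measurable (interior) cells.  Per-cell
    axis scatter attenuates this below the configured m by the wrapped-
    Gaussian factor e^(−2σ²); comparing an estimate to m itself would
    conflate that dispersion with estimator error.
    """

    cells: pd.DataFrame  # cell_id, height, area, elongation, axis, neighbors, polarity axis
    divisions: pd.DataFrame  # mother_id, frame, true angle/category/fate/xy axis
    polarity_magnitude: float
    polarity_axis_deg: float
    basal_threshold: float
    config: dict


@dataclass
class SyntheticDataset:
    field: FieldOfView
    truth: GroundTruth
    tracks: pd.DataFrame
    divisions: pd.DataFrame
    edges: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# packing


def _bounded_voronoi(points: np.ndarray, bounds) -> tuple[list[np.ndarray], dict[int, int]]:
    """Voronoi cells clipped to a rectangle, via boundary mirroring.

    Reflecting the generators across each field edge makes every interior
    region finite with the rectangle edges as cell walls.  Returns the
    polygon (vertex array) per input point and the neighbour count per
    input point derived from shared Voronoi ridges between real points.
    """
    x0, y0, x1, y1 = bounds
    mirrored = [points]
    for refl in (
        lambda p: np.column_stack([2 * x0 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([2 * x1 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y0 - p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y1 - p[:, 1]]),
    ):
        mirrored.append(refl(points))
    vor = Voronoi(np.vstack(mirrored))
    n = len(points)
    polys: list[np.ndarray] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:  # cannot happen with mirrored generators
            raise RuntimeError("unbounded Voronoi region despite boundary mirroring")
        verts = vor.vertices[region]
        # regions are convex: angular sort about the mean gives a valid ring;
        # mirrored generators place boundary walls exactly on the rectangle,
        # so clipping reduces to clamping float round-off
        center = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - center[1], verts[:, 0] - center[0]))
        verts = verts[order]
        verts[:, 0] = np.clip(verts[:, 0], x0, x1)
        verts[:, 1] = np.clip(verts[:, 1], y0, y1)
        polys.append(verts)
    neighbors = {i: 0 for i in range(n)}
    for a, b in vor.ridge_points:
        if a < n and b < n:
            neighbors[int(a)] += 1
            neighbors[int(b)] += 1
    return polys, neighbors


def generate_field(config: SimulationConfig, field_id: str = "field0") -> tuple[FieldOfView, GroundTruth]:
    """Generate one field of view: packed cells with heights and truth table.

    The cell count is the deterministic round of density × area (so the
    realised density always matches the target); packing is a Voronoi
    tessellation of uniform points relaxed by ``config.lloyd_iterations``
    Lloyd steps and clipped to the field rectangle.
    """
    config.validate()
    rng = _rng(config, "field")
    bounds = (0.0, 0.0, config.field_width, config.field_height)
    n_cells = int(round(config.target_density * config.field_area / 100.0))
    if n_cells < 4:
        raise InvalidConfigError("field too small: fewer than 4 cells at the target density")
    points = np.column_stack(
        [
            rng.uniform(0, config.field_width, n_cells),
            rng.uniform(0, config.field_height, n_cells),
        ]
    )
    for _ in range(config.lloyd_iterations):
        polys, _ = _bounded_voronoi(points, bounds)
        points = np.array([polygon_centroid(p) for p in polys])
    polys, neighbors = _bounded_voronoi(points, bounds)

    heights = rng.normal(config.height_mean, config.height_sd, n_cells)
    heights = np.clip(heights, 1.0, None)

    # per-cell true polarity axis (wrapped Gaussian scatter about the tissue axis)
    cell_axes = (
        config.polarity_axis + rng.normal(0.0, config.polarity_axis_noise_sd, n_cells)
    ) % 180.0

    cells, truth_rows = [], []
    for i in range(n_cells):
        cid = f"c{i:04d}"
        shape = CellShape(
            cell_id=cid, polygon=polys[i], height=float(heights[i]),
            neighbor_count=int(neighbors[i]),
        )
        cells.append(shape)
        mag, ax = elongation_nematic(polys[i], validate=False)
        width, orient = longest_planar_axis(polys[i], validate=False)
        cx, cy = polygon_centroid(polys[i])
        truth_rows.append(
            {
                "cell_id": cid,
                "height_um": float(heights[i]),
                "area_um2": polygon_area(polys[i], validate=False),
                "width_um": width,
                "long_axis_deg": orient,
                "elongation_magnitude": mag,
                "elongation_axis_deg": ax,
                "neighbor_count": int(neighbors[i]),
                "polarity_axis_deg": float(cell_axes[i]),
                "centroid_x_um": float(cx),
                "centroid_y_um": float(cy),
            }
        )
    n_mitotic = int(round(config.mitotic_fraction * n_cells))
    mitotic = set(
        f"c{i:04d}" for i in rng.choice(n_cells, size=n_mitotic, replace=False)
    )
    fov = FieldOfView(field_id=field_id, bounds=bounds, cells=cells, mitotic_ids=mitotic)
    cells_df = pd.DataFrame(truth_rows)
    interior_ids = {c.cell_id for c in fov.interior_cells()}
    measurable = cells_df[cells_df["cell_id"].isin(interior_ids)]
    z = config.polarity_magnitude * np.mean(
        np.exp(2j * np.radians(measurable["polarity_axis_deg"].to_numpy()))
    ) if len(measurable) else 0.0j
    truth = GroundTruth(
        cells=cells_df,
        divisions=pd.DataFrame(),
        polarity_magnitude=float(abs(z)),
        polarity_axis_deg=float(np.degrees(np.angle(z)) / 2.0 % 180.0),
        basal_threshold=config.basal_threshold,
        config=config.to_dict(),
    )
    return fov, truth


# ---------------------------------------------------------------------------
# division-angle sampling


def _reflect_into_range(theta: float) -> float:
    """Reflect an angle into [0, 90] at both boundaries."""
    theta = abs(theta) % 360.0
    if theta > 180.0:
        theta = 360.0 - theta
    if theta > 90.0:
        theta = 180.0 - theta
    return theta


def sample_division_angle(
    config: SimulationConfig,
    rng: np.random.Generator,
    cell_long_axis_3d: np.ndarray | None = None,
) -> float:
    """Draw one division elevation angle in degrees on [0, 90].

    Mixture mode draws the category from ``config.angle_mixture`` and the
    angle within the category bounds (uniform, or sine-weighted for the
    3D-isotropic null).  Hertwig mode requires the interphase 3D long-axis
    direction and returns its elevation plus wrapped Gaussian noise,
    reflected into [0, 90].
    """
    if config.hertwig_mode:
        if cell_long_axis_3d is None:
            raise ValueError("hertwig mode requires the cell's 3D long-axis direction")
        u = np.asarray(cell_long_axis_3d, dtype=float)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValueError("long-axis direction must be non-zero")
        elev = np.degrees(np.arcsin(min(abs(u[2]) / norm, 1.0)))
        return _reflect_into_range(elev + rng.normal(0.0, config.hertwig_noise_sd))
    cat = _CATEGORIES[rng.choice(3, p=np.asarray(config.angle_mixture, dtype=float))]
    lo, hi = _CATEGORY_BOUNDS[cat]
    if config.within_bin_law == "uniform":
        return float(rng.uniform(lo, hi))
    # isotropic: elevation density ∝ cos θ, i.e. sin θ uniform
    slo, shi = np.sin(np.radians([lo, hi]))
    return float(np.degrees(np.arcsin(rng.uniform(slo, shi))))


def sample_divisions(
    fov: FieldOfView, config: SimulationConfig, truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Choose dividing cells and their true angles, axes, frames and fates."""
    rng = _rng(config, "divisions")
    ids = [c.cell_id for c in fov.cells]
    if config.n_divisions is None:
        mothers = sorted(fov.mitotic_ids)
    else:
        if config.n_divisions > len(ids):
            raise InvalidConfigError("more divisions requested than cells in the field")
        mothers = sorted(rng.choice(ids, size=config.n_divisions, replace=False))
    max_frame = config.n_frames - 1 - config.fate_window_frames
    if max_frame < 1:
        raise InvalidConfigError("movie too short: no valid division frames")
    by_id = {c.cell_id: c for c in fov.cells}
    rows = []
    for m in mothers:
        cell = by_id[m]
        frame = int(rng.integers(1, max_frame + 1))
        if config.hertwig_mode:
            width, orient = longest_planar_axis(cell.polygon, validate=False)
            if cell.height > width:
                axis3d = np.array([0.0, 0.0, 1.0])
                azimuth = rng.uniform(0.0, 180.0)  # vertical axis: azimuth undefined
            else:
                rad = np.radians(orient)
                axis3d = np.array([np.cos(rad), np.sin(rad), 0.0])
                azimuth = (orient + rng.normal(0.0, config.hertwig_noise_sd)) % 180.0
            angle = sample_division_angle(config, rng, axis3d)
        else:
            angle = sample_division_angle(config, rng)
            azimuth = rng.uniform(0.0, 180.0)
        cat = classify_angle(angle)
        p_sym = dict(zip(_CATEGORIES, config.fate_given_angle))[cat]
        fate = "symmetric" if rng.random() < p_sym else "asymmetric"
        rows.append(
            {
                "mother_id": m,
                "daughter_a_id": f"{m}_a",
                "daughter_b_id": f"{m}_b",
                "division_frame": frame,
                "angle_deg": float(angle),
                "category": cat,
                "fate": fate,
                "xy_axis_deg": float(azimuth),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "mother_id", "daughter_a_id", "daughter_b_id", "division_frame",
            "angle_deg", "category", "fate", "xy_axis_deg",
        ],
    )
    if truth is not None:
        truth.divisions = df.copy()
    return df


# ---------------------------------------------------------------------------
# track emission


def emit_tracks(
    fov: FieldOfView, divisions: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Nuclear-centroid tracks realising the sampled divisions and fates.

    Mother tracks run from frame 0 to the division frame; the two daughter
    tracks begin the next frame, separated by ``daughter_separation`` along
    the sampled 3D division axis, and run to the end of the movie.
    Suprabasal daughters of asymmetric divisions cross the basal threshold
    within 3 frames and stay above it; all other daughters relax back to
    basal nuclear z.  Division frames whose 1.5 h fate window does not fit
    in the movie are rejected.
    """
    rng = _rng(config, "tracks")
    n_frames = config.n_frames
    window = config.fate_window_frames
    div_by_mother = {}
    if len(divisions):
        for r in divisions.itertuples(index=False):
            d = int(r.division_frame)
            if d < 1 or d + window > n_frames - 1:
                raise ValueError(
                    f"division at frame {d} leaves no room for the {window}-frame fate window"
                )
            div_by_mother[r.mother_id] = r

    basal_z = {
        c.cell_id: max(0.5, rng.normal(config.basal_nuclear_z, config.basal_nuclear_z_sd))
        for c in fov.cells
    }
    z_sup = config.basal_threshold + config.suprabasal_margin
    sep = config.daughter_separation

    cols: dict[str, list] = {k: [] for k in ("cell_id", "frame", "xyz", "is_mitotic", "mother_id")}

    def _append(cell_id, mother_id, frames, xyz, mitotic_frame=None):
        xyz = np.array(xyz, dtype=float)
        if config.xy_noise_sd > 0:
            xyz[:, :2] += rng.normal(0.0, config.xy_noise_sd, (len(frames), 2))
        if config.z_noise_sd > 0:
            xyz[:, 2] += rng.normal(0.0, config.z_noise_sd, len(frames))
        cols["cell_id"].append(np.full(len(frames), cell_id, dtype=object))
        cols["frame"].append(np.asarray(frames, dtype=int))
        cols["xyz"].append(xyz)
        mit = (
            np.asarray(frames) >= mitotic_frame
            if mitotic_frame is not None
            else np.zeros(len(frames), dtype=bool)
        )
        cols["is_mitotic"].append(mit)
        cols["mother_id"].append(np.full(len(frames), mother_id, dtype=object))

    for cell in fov.cells:
        cid = cell.cell_id
        cx, cy = polygon_centroid(cell.polygon)
        z0 = basal_z[cid]
        ev = div_by_mother.get(cid)
        last = int(ev.division_frame) if ev is not None else n_frames - 1
        frames = np.arange(0, last + 1)
        xyz = np.column_stack(
            [np.full(len(frames), cx), np.full(len(frames), cy), np.full(len(frames), z0)]
        )
        _append(cid, None, frames, xyz, mitotic_frame=(last - 1 if ev is not None else None))
        if ev is None:
            continue

        theta = np.radians(ev.angle_deg)
        psi = np.radians(ev.xy_axis_deg)
        u = np.array([np.cos(theta) * np.cos(psi), np.cos(theta) * np.sin(psi), np.sin(theta)])
        d = int(ev.division_frame)
        dframes = np.arange(d + 1, n_frames)
        start_a = np.array([cx, cy, z0]) + 0.5 * sep * u
        start_b = np.array([cx, cy, z0]) - 0.5 * sep * u
        if ev.fate == "asymmetric":
            if start_a[2] > start_b[2]:
                sup = "a"
            elif start_b[2] > start_a[2]:
                sup = "b"
            else:
                sup = "a" if rng.random() < 0.5 else "b"
        else:
            sup = None

        for tag, start in (("a", start_a), ("b", start_b)):
            z_traj = np.full(len(dframes), z0)
            if sup == tag:
                # ramp to the suprabasal level by the 3rd post-division frame
                ramp = np.linspace(start[2], z_sup, min(3, len(dframes)))
                z_traj[: len(ramp)] = ramp
                z_traj[len(ramp):] = z_sup
            else:
                # relax back to the basal nuclear level over 2 frames
                ramp = np.linspace(start[2], z0, min(3, len(dframes)))
                z_traj[: len(ramp)] = ramp
            xyz = np.column_stack(
                [np.full(len(dframes), start[0]), np.full(len(dframes), start[1]), z_traj]
            )
            _append(f"{cid}_{tag}", cid, dframes, xyz)

    frames_all = np.concatenate(cols["frame"])
    xyz_all = np.vstack(cols["xyz"])
    df = pd.DataFrame(
        {
            "field_id": fov.field_id,
            "cell_id": np.concatenate(cols["cell_id"]),
            "frame": frames_all,
            "t_min": frames_all * config.frame_interval,
            "x_um": xyz_all[:, 0],
            "y_um": xyz_all[:, 1],
            "z_um": xyz_all[:, 2],
            "is_mitotic": np.concatenate(cols["is_mitotic"]),
            "mother_id": np.concatenate(cols["mother_id"]),
        }
    )
    return df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# junctional polarity emission


def emit_edge_intensities(
    fov: FieldOfView, config: SimulationConfig, truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Boundary intensity samples with a cos 2φ polarity modulation.

    Sample intensity at boundary-normal angle φ is
    baseline·(1 + 2m·cos 2(φ − φ_cell)) + noise (clipped at 0), where
    φ_cell is the cell's true axis (tissue axis plus per-cell scatter from
    the field stage).  The factor 2 matches the nematic estimator's
    convention (a pure 1 + cos 2φ modulation has magnitude 1/2), so the
    per-cell nematic recovered by the polarity module is (m, φ_cell) in
    expectation; for m > 0.5 the clipping at 0 makes recovery saturate
    below m.

    Only interior cells emit samples: cells clipped by the field rectangle
    have artificial straight edges that are not cell-cell junctions, and
    their axis-aligned normals would systematically contaminate the
    nematic — mirroring segmentation practice, where boundary-touching
    cells are excluded from shape and polarity statistics.
    """
    rng = _rng(config, "edges")
    m = config.polarity_magnitude
    if truth is not None and len(truth.cells):
        axis_by_id = dict(zip(truth.cells["cell_id"], truth.cells["polarity_axis_deg"]))
    else:
        axis_by_id = {
            c.cell_id: (config.polarity_axis + rng.normal(0, config.polarity_axis_noise_sd))
            % 180.0
            for c in fov.cells
        }
    ids, angles, intensities = [], [], []
    for cell in fov.interior_cells():
        phi0 = np.radians(axis_by_id[cell.cell_id])
        v = cell.polygon
        # ensure counter-clockwise orientation for consistent outward normals
        x, y = v[:, 0], v[:, 1]
        if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
            v = v[::-1]
        edges = np.roll(v, -1, axis=0) - v
        lengths = np.hypot(edges[:, 0], edges[:, 1])
        keep = lengths > 0
        normals = np.degrees(np.arctan2(-edges[:, 0], edges[:, 1]))  # outward, CCW polygon
        n_samples = np.maximum(
            1, np.round(lengths[keep] / config.edge_sample_spacing).astype(int)
        )
        phi = np.repeat(np.radians(normals[keep]), n_samples)
        base = config.intensity_baseline * (1.0 + 2.0 * m * np.cos(2.0 * (phi - phi0)))
        vals = base + rng.normal(
            0.0, config.intensity_noise_sd * config.intensity_baseline, len(phi)
        )
        ids.append(np.full(len(phi), cell.cell_id, dtype=object))
        angles.append(np.degrees(phi) % 360.0)
        intensities.append(np.clip(vals, 0.0, None))
    return pd.DataFrame(
        {
            "cell_id": np.concatenate(ids) if ids else [],
            "normal_angle_deg": np.concatenate(angles) if angles else [],
            "intensity": np.concatenate(intensities) if intensities else [],
        }
    )


# ---------------------------------------------------------------------------
# one-call orchestration


def simulate(
    config: SimulationConfig, field_id: str = "field0", with_edges: bool = True
) -> SyntheticDataset:
    """Generate a complete synthetic dataset: field, tracks, divisions, edges.

    ``with_edges=False`` skips junctional-intensity emission when only
    tracks/divisions are needed (e.g. angle-recovery sweeps).
    """
    fov, truth = generate_field(config, field_id=field_id)
    divisions = sample_divisions(fov, config, truth)
    tracks = emit_tracks(fov, divisions, config)
    edges = (
        emit_edge_intensities(fov, config, truth)
        if with_edges
        else pd.DataFrame(columns=["cell_id", "normal_angle_deg", "intensity"])
    )
    return SyntheticDataset(
        field=fov, truth=truth, tracks=tracks, divisions=divisions, edges=edges, config=config
    )


def render_label_mask(fov: FieldOfView, um_per_px: float = 0.25) -> np.ndarray:
    """Rasterise the field as a 16-bit label mask (0 = background).

    Cell ``c0000`` gets label 1, etc.; image convention y-down, origin
    top-left, pixel size ``um_per_px``.
    """
    from skimage.draw import polygon as _draw_polygon

    x0, y0, x1, y1 = fov.bounds
    h = int(np.ceil((y1 - y0) / um_per_px))
    w = int(np.ceil((x1 - x0) / um_per_px))
    mask = np.zeros((h, w), dtype=np.uint16)
    for label, cell in enumerate(fov.cells, start=1):
        rr, cc = _draw_polygon(
            (cell.polygon[:, 1] - y0) / um_per_px,
            (cell.polygon[:, 0] - x0) / um_per_px,
            shape=mask.shape,
        )
        mask[rr, cc] = label
    return mask
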