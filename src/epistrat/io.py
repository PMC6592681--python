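"""File formats and validation.

All tables are plain CSV with suffixed units in the column names
(lengths ``_um`` in micrometres, times ``_min`` in minutes, angles
``_deg`` in degrees); polygons travel as a JSON table of vertex lists in
the basal plane (y-down image convention); label masks are 16-bit TIFF
with 0 = background.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CellShape, FieldOfView

__all__ = [
    "write_tracks_csv", "read_tracks_csv",
    "write_divisions_csv", "read_divisions_csv",
    "write_polygons_json", "read_polygons_json",
    "write_edges_csv", "read_edges_csv",
    "write_label_mask_tiff", "read_label_mask_tiff",
    "field_from_label_mask", "validate_tracks",
]

TRACK_COLUMNS = [
    "field_id", "cell_id", "frame", "t_min", "x_um", "y_um", "z_um",
    "is_mitotic", "mother_id",
]


def write_tracks_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in TRACK_COLUMNS if c in df.columns])


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "mother_id": str, "field_id": str})
    missing = {"cell_id", "frame", "x_um", "y_um", "z_um"} - set(df.columns)
    if missing:
        raise ValueError(f"tracks file {path} missing columns {sorted(missing)}")
    return df


def write_divisions_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_divisions_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"mother_id": str, "daughter_a_id": str, "daughter_b_id": str}
    )


def write_edges_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_edges_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    missing = {"cell_id", "normal_angle_deg", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"edge-sample file {path} missing columns {sorted(missing)}")
    return df


def write_polygons_json(fov: FieldOfView, path) -> None:
    """Cell outlines + heights as a JSON table (μm, basal plane, y-down)."""
    payload = {
        "field_id": fov.field_id,
        "bounds_um": list(fov.bounds),
        "units": "um",
        "mitotic_ids": sorted(fov.mitotic_ids),
        "cells": [
            {
                "cell_id": c.cell_id,
                "vertices_um": np.asarray(c.polygon).tolist(),
                "height_um": c.height,
                "neighbor_count": c.neighbor_count,
            }
            for c in fov.cells
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_polygons_json(path) -> FieldOfView:
    payload = json.loads(Path(path).read_text())
    cells = [
        CellShape(
            cell_id=c["cell_id"],
            polygon=np.asarray(c["vertices_um"], dtype=float),
            height=float(c.get("height_um") or 0.0),
            neighbor_count=c.get("neighbor_count"),
        )
        for c in payload["cells"]
    ]
    return FieldOfView(
        field_id=payload.get("field_id", "field0"),
        bounds=tuple(payload["bounds_um"]),
        cells=cells,
        mitotic_ids=set(payload.get("mitotic_ids", [])),
    )


def write_label_mask_tiff(mask: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_label_mask_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def field_from_label_mask(
    mask: np.ndarray,
    um_per_px: float,
    heights: dict[int, float] | None = None,
    field_id: str = "field0",
) -> FieldOfView:
    """Extract cell polygons from a 16-bit label mask.

    Each positive label becomes one cell; the outline is the outer contour
    of the label's pixel set, converted to μm (y-down, origin top-left).
    ``heights`` optionally maps label → apical-basal height in μm.
    """
    from skimage import measure

    mask = np.asarray(mask)
    cells = []
    for label in np.unique(mask):
        if label == 0:
            continue
        binary = mask == label
        contours = measure.find_contours(binary.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # outer contour (rows, cols)
        poly = np.column_stack([contour[:, 1], contour[:, 0]]) * um_per_px
        if len(poly) < 3:
            continue
        # decimate contour pixels to a manageable vertex count
        step = max(1, len(poly) // 100)
        poly = poly[::step]
        cells.append(
            CellShape(
                cell_id=f"c{int(label):04d}",
                polygon=poly,
                height=float(heights.get(int(label), 0.0)) if heights else 0.0,
            )
        )
    h, w = mask.shape
    return FieldOfView(
        field_id=field_id, bounds=(0.0, 0.0, w * um_per_px, h * um_per_px), cells=cells
    )


# ---------------------------------------------------------------------------
# validation


def validate_tracks(df: pd.DataFrame) -> list[dict]:
    """Structural checks on a tracks table; violations are the output.

    Checks: required unit-suffixed columns, strictly increasing frames per
    cell, finite coordinates, and lineage consistency (a mother's track
    ends before her daughters' begin).
    """
    violations: list[dict] = []
    required = {"cell_id", "frame", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        violations.append(
            {"kind": "schema", "detail": f"missing unit-suffixed columns {sorted(missing)}"}
        )
        return violations
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(coords), axis=1)
    for idx in np.flatnonzero(bad):
        violations.append(
            {"kind": "non_finite", "cell_id": str(df.iloc[idx]["cell_id"]), "row": int(idx)}
        )
    spans: dict[str, tuple[int, int]] = {}
    for cell_id, g in df.groupby("cell_id", sort=False):
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            violations.append({"kind": "non_monotone_frames", "cell_id": str(cell_id)})
        spans[str(cell_id)] = (int(frames.min()), int(frames.max()))
    if "mother_id" in df.columns:
        mothers = (
            df[["cell_id", "mother_id"]].dropna().drop_duplicates().astype(str)
        )
        for cell_id, mother_id in mothers.itertuples(index=False):
            if mother_id in spans and cell_id in spans:
                if spans[mother_id][1] >= spans[cell_id][0]:
                    violations.append(
                        {
                            "kind": "lineage",
                            "cell_id": cell_id,
                            "detail": f"mother {mother_id} persists past daughter start",
                        }
                    )
    return violations
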