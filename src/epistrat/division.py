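"""Division-orientation and positional-fate analysis of tracked nuclei.

The elevation of a basal-cell division is the angle Θ between the two
daughter-nucleus centroids at telophase and the plane of the basal layer
(z = 0 at the basement membrane, apical positive):

    Θ = arcsin(|Δz| / ‖Δ‖),   Θ ∈ [0°, 90°].

Divisions are categorised as planar (Θ ≤ 20°), oblique (20° < Θ ≤ 70°) or
perpendicular (70° < Θ ≤ 90°).  Positional fate is scored over a tracking
window after division (90 min by default): symmetric when both daughters
remain basal, asymmetric when exactly one moves and stays suprabasal.
Spindles rotate while chromatids are still on the metaphase plate, so the
angle is only measured once both daughter nuclei exist as separate
objects (the telophase proxy): the first frame at which both daughter
tracks are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NucleusTrack",
    "DivisionEvent",
    "AngleSample",
    "division_angle",
    "classify_angle",
    "select_measurement_frame",
    "assign_fate",
    "angle_fate_table",
    "angular_histogram",
    "estimate_basal_threshold",
    "analyze_tracks",
    "tracks_from_dataframe",
    "CATEGORIES",
]

CATEGORIES = ("planar", "oblique", "perpendicular")

PLANAR_MAX_DEG = 20.0
OBLIQUE_MAX_DEG = 70.0


class DegenerateGeometryError(ValueError):
    """Coincident daughter centroids: no division axis exists."""


class IncompleteEventError(ValueError):
    """Daughter tracks never co-present; angle cannot be measured."""


class InconsistentLineageError(ValueError):
    """Mother track persists after its daughters appear."""


@dataclass
class NucleusTrack:
    """Time series of one nucleus' 3D centroid.

    z is measured from the basement-membrane plane (z = 0), apical
    positive; positions in μm, frames strictly increasing integers.
    """

    cell_id: str
    frames: np.ndarray
    positions: np.ndarray  # (n, 3)
    mother_id: str | None = None
    frame_interval: float = 10.0  # minutes

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frames.ndim != 1 or self.positions.shape != (len(self.frames), 3):
            raise ValueError("frames must be 1D and positions (n, 3)")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def position_at(self, frame: int) -> np.ndarray | None:
        idx = np.searchsorted(self.frames, frame)
        if idx < len(self.frames) and self.frames[idx] == frame:
            return self.positions[idx]
        return None

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])


@dataclass
class DivisionEvent:
    mother_id: str
    daughter_a_id: str
    daughter_b_id: str
    division_frame: int
    angle_deg: float
    category: str
    xy_axis_deg: float
    fate: str = "indeterminate"
    fate_reason: str = ""


@dataclass
class AngleSample:
    """A labelled collection of division angles on [0°, 90°]."""

    label: str
    angles_deg: np.ndarray
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.size < 1:
            raise ValueError("AngleSample needs at least one angle")
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg > 90):
            raise ValueError("angles must lie in [0, 90] degrees")

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)


# ---------------------------------------------------------------------------
# elementary operations


def division_angle(p_a, p_b) -> float:
    """Elevation angle (degrees, [0, 90]) of the daughter-daughter axis.

    Symmetric in the argument order and invariant to in-plane rotation
    and translation.
    """
    d = np.asarray(p_b, dtype=float) - np.asarray(p_a, dtype=float)
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise DegenerateGeometryError("coincident daughter centroids")
    return float(np.degrees(np.arcsin(min(abs(d[2]) / norm, 1.0))))


def division_xy_axis(p_a, p_b) -> float:
    """Planar (azimuthal) orientation of the division axis, axial in [0, 180)."""
    d = np.asarray(p_b, dtype=float) - np.asarray(p_a, dtype=float)
    if d[0] == 0.0 and d[1] == 0.0:
        return float("nan")  # purely vertical axis: azimuth undefined
    return float(np.degrees(np.arctan2(d[1], d[0])) % 180.0)


def classify_angle(theta: float) -> str:
    """planar (Θ ≤ 20°), oblique (20° < Θ ≤ 70°), perpendicular (70° < Θ ≤ 90°)."""
    if not 0.0 <= theta <= 90.0:
        raise ValueError(f"angle {theta} outside [0, 90] degrees")
    if theta <= PLANAR_MAX_DEG:
        return "planar"
    if theta <= OBLIQUE_MAX_DEG:
        return "oblique"
    return "perpendicular"


def select_measurement_frame(
    mother: NucleusTrack | None,
    daughter_a: NucleusTrack,
    daughter_b: NucleusTrack,
) -> int:
    """First frame at which both daughter centroids exist (telophase proxy)."""
    common = np.intersect1d(daughter_a.frames, daughter_b.frames)
    if common.size == 0:
        raise IncompleteEventError(
            f"daughters {daughter_a.cell_id}/{daughter_b.cell_id} never co-present"
        )
    frame = int(common[0])
    if mother is not None and mother.last_frame >= frame:
        raise InconsistentLineageError(
            f"mother {mother.cell_id} persists to frame {mother.last_frame}, "
            f"daughters co-present from frame {frame}"
        )
    return frame


def _daughter_suprabasal(
    track: NucleusTrack,
    window_frames: np.ndarray,
    basal_threshold: float,
    min_run: int = 2,
) -> tuple[bool, bool]:
    """(is_suprabasal, window_complete) for one daughter over the fate window.

    A daughter is scored suprabasal when its nuclear z exceeds the basal
    threshold for a persistence run of at least ``min_run`` consecutive
    frames within the window *and* at the window's final frame — a guard
    against single-frame z jitter.
    """
    z = []
    for f in window_frames:
        p = track.position_at(int(f))
        if p is None:
            return False, False
        z.append(p[2])
    above = np.asarray(z) > basal_threshold
    if not above[-1]:
        return False, True
    best, run = 0, 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best >= min_run, True


def assign_fate(
    daughter_a: NucleusTrack,
    daughter_b: NucleusTrack,
    division_frame: int,
    basal_threshold: float,
    window_min: float = 90.0,
    frame_interval: float | None = None,
) -> tuple[str, str]:
    """Positional fate of a division: symmetric / asymmetric / indeterminate.

    Both daughters are followed for ``window_min`` minutes after the
    division frame.  Symmetric: both remain basal; asymmetric: exactly one
    moves (and stays) suprabasal; both suprabasal is flagged separately and
    excluded from the dichotomy.  Missing frames inside the window give
    fate "indeterminate" with a reason.
    """
    dt = frame_interval if frame_interval is not None else daughter_a.frame_interval
    n_window = int(np.ceil(window_min / dt))
    window = np.arange(division_frame + 1, division_frame + 1 + n_window)
    sup_a, ok_a = _daughter_suprabasal(daughter_a, window, basal_threshold)
    sup_b, ok_b = _daughter_suprabasal(daughter_b, window, basal_threshold)
    if not (ok_a and ok_b):
        return "indeterminate", "incomplete tracking window"
    if sup_a and sup_b:
        return "both_suprabasal", "both daughters left the basal layer"
    if sup_a or sup_b:
        return "asymmetric", ""
    return "symmetric", ""


# ---------------------------------------------------------------------------
# sample-level summaries


def angle_fate_table(events: pd.DataFrame | list[DivisionEvent]) -> pd.DataFrame:
    """3×2 contingency of division category × positional fate.

    Rows are the orientation categories; columns symmetric/asymmetric
    counts plus row proportions.  Indeterminate and both-suprabasal events
    are excluded from the dichotomy.
    """
    if not isinstance(events, pd.DataFrame):
        events = pd.DataFrame([vars(e) for e in events])
    rows = []
    for cat in CATEGORIES:
        if len(events):
            sub = events[(events["category"] == cat)]
            n_sym = int((sub["fate"] == "symmetric").sum())
            n_asym = int((sub["fate"] == "asymmetric").sum())
        else:
            n_sym = n_asym = 0
        n = n_sym + n_asym
        rows.append(
            {
                "category": cat,
                "symmetric": n_sym,
                "asymmetric": n_asym,
                "prop_symmetric": n_sym / n if n else np.nan,
                "prop_asymmetric": n_asym / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def angular_histogram(sample: AngleSample | np.ndarray, bin_width: float = 10.0):
    """Counts of division angles in [0, 90] per ``bin_width``-degree bin.

    Bins are [0, b), [b, 2b), ..., with the last bin closed at 90° so the
    counts conserve n.  Returns (counts, bin_edges).
    """
    angles = sample.angles_deg if isinstance(sample, AngleSample) else np.asarray(sample)
    if bin_width <= 0 or 90.0 % bin_width != 0:
        raise ValueError("bin width must evenly divide 90 degrees")
    edges = np.arange(0.0, 90.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    return counts, edges


def category_proportions(angles: np.ndarray) -> dict[str, float]:
    angles = np.asarray(angles, dtype=float)
    cats = np.array([classify_angle(t) for t in angles])
    n = len(angles)
    return {c: float((cats == c).sum()) / n if n else np.nan for c in CATEGORIES}


# ---------------------------------------------------------------------------
# track-table analysis


def tracks_from_dataframe(df: pd.DataFrame, frame_interval: float = 10.0) -> dict[str, NucleusTrack]:
    """Build NucleusTrack objects from a tidy tracks table.

    Expects columns cell_id, frame, x_um, y_um, z_um and optional
    mother_id; one row per nucleus per frame.
    """
    codes, uniques = pd.factorize(df["cell_id"].astype(str))
    frames = df["frame"].to_numpy(dtype=int)
    pos = np.column_stack(
        [df["x_um"].to_numpy(float), df["y_um"].to_numpy(float), df["z_um"].to_numpy(float)]
    )
    order = np.lexsort((frames, codes))
    codes, frames, pos = codes[order], frames[order], pos[order]
    starts = np.r_[0, np.flatnonzero(np.diff(codes)) + 1, len(codes)]
    mothers: dict[int, str | None] = {}
    if "mother_id" in df.columns:
        m = df["mother_id"].to_numpy(object)[order]
        for k in range(len(starts) - 1):
            v = m[starts[k]]
            mothers[k] = None if pd.isna(v) or v == "" else str(v)
    tracks: dict[str, NucleusTrack] = {}
    for k in range(len(starts) - 1):
        lo, hi = starts[k], starts[k + 1]
        cid = str(uniques[codes[lo]])
        tracks[cid] = NucleusTrack(
            cell_id=cid,
            frames=frames[lo:hi],
            positions=pos[lo:hi],
            mother_id=mothers.get(k),
            frame_interval=frame_interval,
        )
    return tracks


def estimate_basal_threshold(
    tracks: dict[str, NucleusTrack], nuclear_radius: float = 2.5
) -> float:
    """Default suprabasal criterion: 75th percentile of mother-population
    nuclear z plus one nuclear radius.

    Mothers (cells that divide, or all non-daughter cells when no lineage
    information exists) define the basal nuclear-z population.
    """
    zs = []
    daughters = {cid for cid, t in tracks.items() if t.mother_id is not None}
    mothers = {t.mother_id for t in tracks.values() if t.mother_id is not None}
    pool = mothers if mothers else (set(tracks) - daughters)
    for cid in pool:
        if cid in tracks:
            zs.append(tracks[cid].positions[:, 2])
    if not zs:
        raise ValueError("no mother tracks to estimate the basal threshold from")
    return float(np.percentile(np.concatenate(zs), 75) + nuclear_radius)


def analyze_tracks(
    df: pd.DataFrame,
    basal_threshold: float | None = None,
    window_min: float = 90.0,
    frame_interval: float = 10.0,
    label: str = "tracks",
) -> pd.DataFrame:
    """Full division analysis of a tracks table.

    Detects divisions from lineage (two tracks sharing a mother_id),
    measures each division angle at the first daughter-co-present frame,
    classifies it, and assigns positional fates against
    ``basal_threshold`` (estimated from the mother population when not
    given).  Returns one row per division.
    """
    tracks = tracks_from_dataframe(df, frame_interval=frame_interval)
    if basal_threshold is None:
        basal_threshold = estimate_basal_threshold(tracks)
    by_mother: dict[str, list[NucleusTrack]] = {}
    for t in tracks.values():
        if t.mother_id is not None:
            by_mother.setdefault(t.mother_id, []).append(t)
    rows = []
    for mother_id in sorted(by_mother):
        ds = sorted(by_mother[mother_id], key=lambda t: t.cell_id)
        if len(ds) != 2:
            continue
        da, db = ds
        mother = tracks.get(mother_id)
        frame = select_measurement_frame(mother, da, db)
        p_a, p_b = da.position_at(frame), db.position_at(frame)
        theta = division_angle(p_a, p_b)
        xy_axis = division_xy_axis(p_a, p_b)
        # fate window is anchored at the division (mother's last) frame
        div_frame = mother.last_frame if mother is not None else frame - 1
        fate, reason = assign_fate(
            da, db, div_frame, basal_threshold, window_min=window_min,
            frame_interval=frame_interval,
        )
        rows.append(
            {
                "label": label,
                "mother_id": mother_id,
                "daughter_a_id": da.cell_id,
                "daughter_b_id": db.cell_id,
                "division_frame": div_frame,
                "measurement_frame": frame,
                "angle_deg": theta,
                "category": classify_angle(theta),
                "xy_axis_deg": xy_axis,
                "fate": fate,
                "fate_reason": reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "mother_id", "daughter_a_id", "daughter_b_id",
            "division_frame", "measurement_frame", "angle_deg", "category",
            "xy_axis_deg", "fate", "fate_reason",
        ],
    )
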