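"""Simulation configuration for the synthetic basal-layer generator.

Defaults describe an E14.5-like wildtype basal layer: cells of ~116 μm²
cross-section (≈0.86 cells per 100 μm²), ~7.9 μm tall, imaged every
10 minutes, with roughly half of divisions planar and fates strongly
coupled to division orientation.  Values without a published measurement
(daughter separation, nuclear z levels and trajectories, track noise) are
plausible placeholders and are documented as such — the analysis modules
never depend on their particular values, only on the conventions shared
with the generator (z = 0 at the basement membrane, apical positive, the
basal/suprabasal threshold in μm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["SimulationConfig", "InvalidConfigError"]


class InvalidConfigError(ValueError):
    """Configuration violates an invariant (dimensions, weights, rates)."""


@dataclass
class SimulationConfig:
    # field geometry
    field_width: float = 150.0  # μm
    field_height: float = 150.0  # μm
    target_density: float = 0.86  # cells per 100 μm² (≈116 μm² mean area)
    lloyd_iterations: int = 2  # centroidal relaxation steps

    # cell geometry
    height_mean: float = 7.9  # μm, apical-basal
    height_sd: float = 1.5  # μm

    # division-angle law
    angle_mixture: tuple[float, float, float] = (0.51, 0.29, 0.20)  # planar/oblique/perp
    within_bin_law: str = "uniform"  # or "isotropic" (sine-weighted null)
    hertwig_mode: bool = False  # divide along the interphase 3D long axis
    hertwig_noise_sd: float = 10.0  # degrees, wrapped Gaussian on the axis

    # fate coupling: P(symmetric | category)
    fate_given_angle: tuple[float, float, float] = (0.94, 0.41, 0.11)

    # imaging / tracks
    frame_interval: float = 10.0  # minutes
    n_frames: int = 49  # ≈ 8 h movie
    daughter_separation: float = 6.0  # μm between telophase daughter centroids
    basal_nuclear_z: float = 5.0  # μm, mean basal nuclear centroid height
    basal_nuclear_z_sd: float = 0.5  # μm
    basal_threshold: float = 10.0  # μm; suprabasal when nuclear z exceeds this
    suprabasal_margin: float = 5.0  # μm above threshold for suprabasal daughters
    xy_noise_sd: float = 0.0  # μm, per-frame centroid jitter (idealised tracks)
    z_noise_sd: float = 0.0  # μm

    # divisions / proliferation
    n_divisions: int | None = None  # default: the mitotic cells
    mitotic_fraction: float = 0.025  # snapshot mitotic index

    # junctional polarity
    polarity_magnitude: float = 0.3  # m, dimensionless in [0, 1]
    polarity_axis: float = 0.0  # φ₀, degrees in [0, 180)
    polarity_axis_noise_sd: float = 10.0  # degrees, per-cell axis scatter
    intensity_baseline: float = 100.0  # arbitrary units
    intensity_noise_sd: float = 0.05  # relative (fraction of baseline)
    edge_sample_spacing: float = 1.0  # μm between boundary samples

    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.field_width <= 0 or self.field_height <= 0:
            raise InvalidConfigError("field dimensions must be positive")
        if self.target_density <= 0:
            raise InvalidConfigError("target density must be positive")
        w = np.asarray(self.angle_mixture, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise InvalidConfigError("angle_mixture must be 3 non-negative weights summing to 1")
        f = np.asarray(self.fate_given_angle, dtype=float)
        if f.shape != (3,) or np.any(f < 0) or np.any(f > 1):
            raise InvalidConfigError("fate probabilities must lie in [0, 1]")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be positive")
        if self.n_frames < 12:
            raise InvalidConfigError("n_frames too small to fit a fate window")
        if not 0.0 <= self.polarity_magnitude <= 1.0:
            raise InvalidConfigError("polarity_magnitude must lie in [0, 1]")
        if not 0.0 <= self.polarity_axis < 180.0:
            raise InvalidConfigError("polarity_axis must lie in [0, 180)")
        if self.within_bin_law not in ("uniform", "isotropic"):
            raise InvalidConfigError(f"unknown within-bin law {self.within_bin_law!r}")
        if self.height_mean <= 0 or self.height_sd < 0:
            raise InvalidConfigError("height law must have positive mean, non-negative sd")
        if self.daughter_separation <= 0:
            raise InvalidConfigError("daughter_separation must be positive")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["angle_mixture"] = list(self.angle_mixture)
        d["fate_given_angle"] = list(self.fate_given_angle)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("angle_mixture", "fate_given_angle"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "SimulationConfig":
        d = self.to_dict()
        d.update(kw)
        return SimulationConfig.from_dict(d)

    @property
    def field_area(self) -> float:
        return self.field_width * self.field_height

    @property
    def fate_window_frames(self) -> int:
        """Frames in the 1.5 h (90 min) fate-tracking window."""
        return int(np.ceil(90.0 / self.frame_interval))
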