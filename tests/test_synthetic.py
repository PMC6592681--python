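"""Synthetic basal-layer generator: contracts and ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from epistrat import InvalidConfigError, SimulationConfig
from epistrat.division import classify_angle
from epistrat.geometry import polygon_area
from epistrat.polarity import polarity_from_edge_table, tissue_polarity
from epistrat.synthetic import (
    emit_edge_intensities,
    emit_tracks,
    generate_field,
    render_label_mask,
    sample_division_angle,
    sample_divisions,
    simulate,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"field_width": 0.0},
            {"field_height": -5.0},
            {"target_density": 0.0},
            {"angle_mixture": (0.5, 0.5, 0.5)},
            {"angle_mixture": (-0.1, 0.6, 0.5)},
            {"fate_given_angle": (1.2, 0.4, 0.1)},
            {"frame_interval": 0.0},
            {"polarity_magnitude": 1.5},
            {"within_bin_law": "weird"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(**kw)

    def test_yaml_roundtrip(self, tmp_path, fast_config):
        path = tmp_path / "cfg.yaml"
        fast_config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == fast_config


class TestGenerateField:
    def test_cell_count_matches_target_density(self):
        # 215 cells per 1200 μm² convention as a config
        side = np.sqrt(1200.0)
        cfg = SimulationConfig(
            field_width=side, field_height=side, target_density=100 * 215 / 1200.0, seed=0
        )
        counts = [len(generate_field(cfg.replace(seed=s))[0].cells) for s in range(5)]
        assert all(abs(c - 215) <= 22 for c in counts)

    def test_polygons_tile_the_field(self, fast_config):
        fov, _ = generate_field(fast_config)
        total = sum(polygon_area(c.polygon) for c in fov.cells)
        assert total == pytest.approx(fov.area, rel=1e-6)
        for c in fov.cells:
            assert c.polygon[:, 0].min() >= -1e-9
            assert c.polygon[:, 0].max() <= fov.bounds[2] + 1e-9

    def test_determinism(self, fast_config):
        f1, t1 = generate_field(fast_config)
        f2, t2 = generate_field(fast_config)
        for c1, c2 in zip(f1.cells, f2.cells):
            assert np.array_equal(c1.polygon, c2.polygon)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_geometry_recovery_within_two_sem(self):
        cfg = SimulationConfig(field_width=200, field_height=200, height_mean=6.9, seed=21)
        fov, truth = generate_field(cfg)
        h = truth.cells["height_um"].to_numpy()
        sem = h.std(ddof=1) / np.sqrt(len(h))
        assert abs(h.mean() - 6.9) <= 2 * sem + 0.05  # slack for the >= 1 μm clip
        interior_area = np.array(
            [polygon_area(c.polygon) for c in fov.interior_cells()]
        )
        expected_area = 100.0 / cfg.target_density
        sem_a = interior_area.std(ddof=1) / np.sqrt(len(interior_area))
        assert abs(interior_area.mean() - expected_area) <= max(2 * sem_a, 0.1 * expected_area)

    def test_polygon_class_mode_is_six(self, fast_config):
        fov, truth = generate_field(fast_config)
        interior = {c.cell_id for c in fov.interior_cells()}
        counts = truth.cells[truth.cells.cell_id.isin(interior)]["neighbor_count"]
        assert counts.value_counts().idxmax() == 6

    def test_too_small_field_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_field(SimulationConfig(field_width=5, field_height=5))


class TestAngleSampling:
    def test_degenerate_mixture_stays_in_bin(self, rng):
        cfg = SimulationConfig(angle_mixture=(1.0, 0.0, 0.0))
        draws = [sample_division_angle(cfg, rng) for _ in range(500)]
        assert all(0.0 <= d <= 20.0 for d in draws)

    def test_hertwig_planar_axis_zero_noise(self, rng):
        cfg = SimulationConfig(hertwig_mode=True, hertwig_noise_sd=0.0)
        assert sample_division_angle(cfg, rng, np.array([1.0, 0.0, 0.0])) == 0.0
        assert sample_division_angle(cfg, rng, np.array([0.0, 0.0, 1.0])) == 90.0

    def test_hertwig_requires_axis(self, rng):
        cfg = SimulationConfig(hertwig_mode=True)
        with pytest.raises(ValueError):
            sample_division_angle(cfg, rng)

    def test_mixture_frequencies_binomial(self, rng):
        weights = (0.51, 0.29, 0.20)
        cfg = SimulationConfig(angle_mixture=weights)
        n = 10_000
        cats = [classify_angle(sample_division_angle(cfg, rng)) for _ in range(n)]
        for w, cat in zip(weights, ("planar", "oblique", "perpendicular")):
            freq = cats.count(cat) / n
            assert abs(freq - w) <= 3 * np.sqrt(w * (1 - w) / n)

    def test_isotropic_law_weights_high_angles(self, rng):
        # cos-elevation density puts less mass near 90° than uniform does
        cfg = SimulationConfig(
            angle_mixture=(0.0, 0.0, 1.0), within_bin_law="isotropic"
        )
        iso = np.array([sample_division_angle(cfg, rng) for _ in range(3000)])
        cfg_u = SimulationConfig(angle_mixture=(0.0, 0.0, 1.0))
        uni = np.array([sample_division_angle(cfg_u, rng) for _ in range(3000)])
        assert iso.mean() < uni.mean()
        assert np.all((iso > 70) & (iso <= 90))


class TestTracks:
    def _dataset(self, **kw):
        cfg = SimulationConfig(field_width=120, field_height=120, n_divisions=25, seed=3, **kw)
        ds = simulate(cfg, with_edges=False)
        return cfg, ds

    def test_mother_ends_daughters_begin(self):
        cfg, ds = self._dataset()
        for r in ds.divisions.itertuples(index=False):
            mother = ds.tracks[ds.tracks.cell_id == r.mother_id]
            da = ds.tracks[ds.tracks.cell_id == r.daughter_a_id]
            assert mother.frame.max() == r.division_frame
            assert da.frame.min() == r.division_frame + 1

    def test_daughter_separation_encodes_angle(self):
        cfg, ds = self._dataset()
        first = ds.tracks.sort_values("frame").groupby("cell_id").first().reset_index()
        for r in ds.divisions.itertuples(index=False):
            pa = first[first.cell_id == r.daughter_a_id][["x_um", "y_um", "z_um"]].to_numpy()[0]
            pb = first[first.cell_id == r.daughter_b_id][["x_um", "y_um", "z_um"]].to_numpy()[0]
            d = pa - pb
            assert np.linalg.norm(d) == pytest.approx(cfg.daughter_separation, rel=1e-9)
            theta = np.degrees(np.arcsin(abs(d[2]) / np.linalg.norm(d)))
            assert theta == pytest.approx(r.angle_deg, abs=1e-9)

    def test_fate_trajectories(self):
        cfg, ds = self._dataset()
        window = cfg.fate_window_frames
        for r in ds.divisions.itertuples(index=False):
            above = {}
            for did in (r.daughter_a_id, r.daughter_b_id):
                g = ds.tracks[
                    (ds.tracks.cell_id == did)
                    & (ds.tracks.frame > r.division_frame)
                    & (ds.tracks.frame <= r.division_frame + window)
                ].sort_values("frame")
                above[did] = (g.z_um > cfg.basal_threshold).to_numpy()
            n_sup = sum(a[-1] and a.sum() >= 2 for a in above.values())
            assert n_sup == (1 if r.fate == "asymmetric" else 0)

    def test_division_frame_out_of_window_rejected(self):
        cfg = SimulationConfig(field_width=120, field_height=120, seed=3)
        fov, truth = generate_field(cfg)
        bad = pd.DataFrame(
            [{
                "mother_id": fov.cells[0].cell_id, "daughter_a_id": "x_a",
                "daughter_b_id": "x_b", "division_frame": cfg.n_frames - 2,
                "angle_deg": 10.0, "category": "planar", "fate": "symmetric",
                "xy_axis_deg": 0.0,
            }]
        )
        with pytest.raises(ValueError):
            emit_tracks(fov, bad, cfg)

    def test_too_many_divisions_rejected(self):
        cfg = SimulationConfig(field_width=100, field_height=100, n_divisions=10_000)
        fov, truth = generate_field(cfg)
        with pytest.raises(InvalidConfigError):
            sample_divisions(fov, cfg, truth)

    def test_byte_identical_outputs_for_fixed_seed(self):
        cfg = SimulationConfig(field_width=100, field_height=100, n_divisions=10, seed=8)
        d1, d2 = simulate(cfg), simulate(cfg)
        assert d1.tracks.to_csv(index=False) == d2.tracks.to_csv(index=False)
        assert d1.edges.to_csv(index=False) == d2.edges.to_csv(index=False)
        assert d1.divisions.to_csv(index=False) == d2.divisions.to_csv(index=False)


class TestEdgeIntensities:
    def test_isotropic_when_magnitude_zero(self, fast_config):
        cfg = fast_config.replace(polarity_magnitude=0.0, intensity_noise_sd=0.0)
        fov, truth = generate_field(cfg)
        mag, _ = tissue_polarity(polarity_from_edge_table(emit_edge_intensities(fov, cfg, truth)))
        assert mag < 0.05

    def test_noise_free_axis_recovery(self):
        # three pooled fields, as rose plots are built from several images
        measures = []
        for seed in (2, 3, 4):
            cfg = SimulationConfig(
                polarity_magnitude=0.5, polarity_axis=30.0,
                polarity_axis_noise_sd=0.0, intensity_noise_sd=0.0, seed=seed,
            )
            fov, truth = generate_field(cfg)
            measures += polarity_from_edge_table(emit_edge_intensities(fov, cfg, truth))
        axes = np.array([m.axis_deg for m in measures])
        err = np.minimum(np.abs(axes - 30.0) % 180, 180 - np.abs(axes - 30.0) % 180)
        # irregular outlines couple cell-shape anisotropy into single-cell
        # estimates; the scatter is moderate and averages out at tissue level
        assert np.median(err) < 10.0
        mag, axis = tissue_polarity(measures)
        assert abs(axis - 30.0) < 2.0
        assert mag == pytest.approx(0.5, rel=0.05)

    def test_intensities_non_negative(self, fast_config):
        cfg = fast_config.replace(polarity_magnitude=1.0)
        fov, truth = generate_field(cfg)
        edges = emit_edge_intensities(fov, cfg, truth)
        assert (edges.intensity >= 0).all()


class TestLabelMask:
    def test_render_covers_field(self, fast_config):
        fov, _ = generate_field(fast_config)
        mask = render_label_mask(fov, um_per_px=1.0)
        assert mask.dtype == np.uint16
        assert mask.shape == (100, 100)
        assert (mask > 0).mean() > 0.95  # tessellation covers nearly all pixels
        assert mask.max() == len(fov.cells)
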