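"""Synthetic slide generator: determinism, planted truth, rendering."""

import numpy as np
import pytest
from scipy import stats

from budscan.core import SlideGeometry, circle_dice
from budscan.density import compute_density
from budscan.hotspot import select_hotspots
from budscan.stain import dab_mask, deconvolve
from budscan.synthetic import (
    ClusterSpec,
    SimulationConfig,
    SyntheticSlide,
    densest_disk_oracle,
    render_ihc,
    simulate_slide,
)
from conftest import brute_force_density


def _quiet_config(**kw):
    base = dict(
        width_mm=2.0, height_mm=2.0, background_rate=0.0, distractor_rate=0.0,
        teacher_fp_rate=0.0, n_manual_tb=0, n_manual_non_tb=0,
        clusters=(ClusterSpec(n_buds=12, sd_um=50.0, center_mm=(1.0, 1.0)),),
        grid_spacing_um=20.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateSlide:
    def test_single_cluster_all_points_planted(self):
        slide = simulate_slide(_quiet_config(seed=7))
        assert len(slide.true_buds) == 12
        assert slide.planted_count == 12

    def test_seeded_runs_are_identical(self):
        a = simulate_slide(SimulationConfig(seed=42, grid_spacing_um=20.0))
        b = simulate_slide(SimulationConfig(seed=42, grid_spacing_um=20.0))
        assert np.array_equal(a.true_buds, b.true_buds)
        assert np.array_equal(a.distractors, b.distractors)
        assert a.teacher_detections == b.teacher_detections
        assert a.manual_annotations == b.manual_annotations
        assert a.planted_hotspot == b.planted_hotspot

    def test_different_seeds_differ(self):
        a = simulate_slide(_quiet_config(seed=1))
        b = simulate_slide(_quiet_config(seed=2))
        assert not np.array_equal(a.true_buds, b.true_buds)

    def test_background_counts_follow_poisson(self):
        # total background over 60 sims of 2 / mm^2 * 25 mm^2 ~ Poisson(3000)
        cfg = SimulationConfig(
            width_mm=5.0, height_mm=5.0, background_rate=2.0, clusters=(),
            distractor_rate=0.0, teacher_fp_rate=0.0,
            n_manual_tb=0, n_manual_non_tb=0, grid_spacing_um=50.0,
        )
        total = sum(len(simulate_slide(cfg, seed=s).true_buds) for s in range(60))
        mu = 60 * 2.0 * 25.0
        lo, hi = stats.poisson.ppf([0.005, 0.995], mu)
        assert lo <= total <= hi

    def test_manual_annotations_are_sparse_labeled_subset(self):
        slide = simulate_slide(SimulationConfig(seed=5, grid_spacing_um=20.0))
        cfg = slide.config
        assert len(slide.manual_annotations) <= cfg.n_manual_tb + cfg.n_manual_non_tb
        buds = {tuple(p) for p in slide.true_buds}
        dis = {tuple(p) for p in slide.distractors}
        for d in slide.manual_annotations:
            assert (d.x, d.y) in (buds if d.label.value == "TB" else dis)

    def test_teacher_likelihoods_are_bimodal(self):
        slide = simulate_slide(SimulationConfig(seed=11, teacher_fp_rate=2.0,
                                                grid_spacing_um=20.0))
        n_true = len(slide.true_buds)
        true_l = [d.likelihood for d in slide.teacher_detections[:n_true]]
        false_l = [d.likelihood for d in slide.teacher_detections[n_true:]]
        assert np.mean(true_l) > 0.6 > np.mean(false_l)

    def test_degenerate_tissue_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(width_mm=0.0)


class TestDensestDiskOracle:
    def test_single_point(self):
        # every cell within one radius ties at count 1; row-major tie-break
        # picks the topmost, which still covers the point
        circle, count = densest_disk_oracle(np.array([[500.0, 500.0]]), 500.0, 8.0)
        assert count == 1
        assert np.hypot(circle.cx - 500.0, circle.cy - 500.0) <= 500.0

    def test_matches_brute_force_density_argmax(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 2000, size=(40, 2))
            g = SlideGeometry(2000.0, 2000.0, 16.0)
            circle, count = densest_disk_oracle(pts, 400.0, 16.0, geometry=g)
            grid = brute_force_density(pts, g, 400.0)
            assert count == grid.max()
            i, j = np.unravel_index(np.argmax(grid), grid.shape)
            assert (circle.cx, circle.cy) == g.pixel_center(i, j)

    def test_tie_breaks_row_major(self):
        # two identical clusters; the smaller row (then column) wins
        pts = np.array([[1500.0, 500.0], [500.0, 1500.0]])
        g = SlideGeometry(2000.0, 2000.0, 8.0)
        circle, count = densest_disk_oracle(pts, 100.0, 8.0, geometry=g)
        assert count == 1
        assert circle.cy < 1000.0  # the y = 500 point is found first

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            densest_disk_oracle(np.empty((0, 2)), 500.0, 8.0)


class TestPlantedHotspotRecovery:
    def test_pipeline_recovers_planted_hotspot(self):
        # 10 seeded default-config slides; full density + selection pipeline
        hits = 0
        for seed in range(10):
            slide = simulate_slide(SimulationConfig(seed=seed))
            cfg = slide.config
            g = SlideGeometry(cfg.width_mm * 1000, cfg.height_mm * 1000, cfg.grid_spacing_um)
            dets = [d for d in slide.teacher_detections][: len(slide.true_buds)]
            dmap = compute_density(dets, g, radius_um=cfg.radius_um)
            top = select_hotspots(dmap, k=1)[0]
            if circle_dice(top.circle, slide.planted_hotspot) >= 0.7:
                hits += 1
        assert hits == 10


class TestRenderIhc:
    def _small_slide(self, n_buds=4, n_dis=0, seed=0):
        from budscan.core import Circle

        cfg = _quiet_config(
            width_mm=0.5, height_mm=0.5, seed=seed,
            clusters=(ClusterSpec(n_buds=1, sd_um=10.0, center_mm=(0.25, 0.25)),),
        )
        # well-separated points on a grid, away from borders
        grid = [(80.0 + 110.0 * i, 80.0 + 110.0 * j) for i in range(4) for j in range(4)]
        buds = np.array(grid[:n_buds]).reshape(-1, 2)
        dis = np.array(grid[n_buds : n_buds + n_dis]).reshape(-1, 2)
        return SyntheticSlide(
            true_buds=buds if len(buds) else np.empty((0, 2)),
            distractors=dis if len(dis) else np.empty((0, 2)),
            manual_annotations=(), teacher_detections=(),
            planted_hotspot=Circle(250.0, 250.0, cfg.radius_um),
            planted_count=0, config=cfg,
        )

    def test_empty_slide_is_white(self):
        slide = self._small_slide(n_buds=0)
        tile = render_ihc(slide, noise_level=0.0)
        assert np.all(tile.pixels == 254)  # 255 minus the epsilon offset

    def test_mask_recovers_bud_count(self):
        slide = self._small_slide(n_buds=5)
        tile = render_ihc(slide, noise_level=1.0)
        conc = deconvolve(tile)
        mask = dab_mask(conc[..., 1], tile.spacing_um)
        assert len(mask.components) == 5

    def test_hematoxylin_distractors_invisible_to_dab(self):
        slide = self._small_slide(n_buds=0, n_dis=6)
        tile = render_ihc(slide, noise_level=1.0)
        conc = deconvolve(tile)
        mask = dab_mask(conc[..., 1], tile.spacing_um)
        assert len(mask.components) == 0

    def test_blob_radius_must_resolve(self):
        slide = self._small_slide(n_buds=1)
        with pytest.raises(ValueError):
            render_ihc(slide, spacing_um=4.0, blob_radius_um=6.0)
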