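"""Pseudo-label filtering, mask rejection and certainty-weighted merging."""

import numpy as np
import pytest

from budscan.core import Detection, Label, Source
from budscan.pseudolabel import (
    PseudoLabelConfig,
    filter_by_dab,
    filter_by_likelihood,
    merge_and_weight,
)
from budscan.stain import DabMask, dab_mask


def det(x, y, likelihood=None, label=Label.UNLABELED, source=Source.DETECTOR):
    return Detection(x, y, likelihood=likelihood, label=label, source=source)


def manual(x, y, label=Label.TB):
    return Detection(x, y, label=label, source=Source.MANUAL)


class TestLikelihoodFilter:
    def test_exactly_at_threshold_rejected(self):
        assert filter_by_likelihood([det(0, 0, 0.80)], 0.80) == []

    def test_above_threshold_retained(self):
        kept = filter_by_likelihood([det(0, 0, 0.95)], 0.80)
        assert len(kept) == 1

    def test_manual_bypasses_filter(self):
        m = manual(0, 0)
        assert filter_by_likelihood([m], 0.80) == [m]

    def test_missing_likelihood_rejected_for_detector_source(self):
        assert filter_by_likelihood([det(0, 0, None)], 0.80) == []

    def test_retained_count_monotone_in_threshold(self, rng):
        dets = [det(i, 0, float(l)) for i, l in enumerate(rng.uniform(0, 1, 100))]
        sizes = [len(filter_by_likelihood(dets, t)) for t in (0.2, 0.5, 0.8, 0.95)]
        assert sizes == sorted(sizes, reverse=True)


def _square_mask(lo_px=10, hi_px=20, size=40, spacing=1.0):
    grid = np.zeros((size, size), dtype=float)
    grid[lo_px:hi_px, lo_px:hi_px] = 1.0
    return dab_mask(grid, spacing_um=spacing, od_threshold=0.5,
                    min_area_um2=0.0, opening_radius_px=0)


class TestDabFilter:
    def test_on_component_retained(self):
        m = _square_mask()
        kept = filter_by_dab([det(15.0, 15.0, 0.9)], m)
        assert len(kept) == 1

    def test_background_rejected_at_zero_tolerance(self):
        m = _square_mask()
        assert filter_by_dab([det(35.0, 35.0, 0.9)], m, tolerance_um=0.0) == []

    def test_near_edge_within_tolerance_retained(self):
        # mask pixels cover columns 10..19; x = 23 is 3 um off the edge
        m = _square_mask()
        d = det(23.0, 15.0, 0.9)
        assert filter_by_dab([d], m, tolerance_um=5.0) == [d]
        assert filter_by_dab([d], m, tolerance_um=1.0) == []

    def test_outside_extent_rejected(self):
        m = _square_mask()
        assert filter_by_dab([det(-5.0, 2.0, 0.9)], m) == []

    def test_manual_bypasses_mask(self):
        m = _square_mask()
        mm = manual(35.0, 35.0)
        assert filter_by_dab([mm], m) == [mm]

    def test_retained_count_monotone_in_tolerance(self, rng):
        m = _square_mask()
        dets = [det(float(x), float(y), 0.9) for x, y in rng.uniform(0, 40, (80, 2))]
        sizes = [len(filter_by_dab(dets, m, tolerance_um=t)) for t in (0, 2, 5, 10)]
        assert sizes == sorted(sizes)


class TestMergeAndWeight:
    cfg = PseudoLabelConfig()

    def test_disjoint_sets_union(self):
        pseudo = [det(i * 100.0, 0, 0.9) for i in range(4)]
        man = [manual(i * 100.0, 500.0) for i in range(3)]
        manifest = merge_and_weight(pseudo, man, self.cfg)
        assert len(manifest.records) == 7
        assert manifest.n_manual == 3 and manifest.n_pseudo == 4

    def test_certainty_assignment(self):
        manifest = merge_and_weight([det(0, 0, 0.9)], [manual(500.0, 0)], self.cfg)
        by_source = {r.source: r for r in manifest.records}
        assert by_source[Source.MANUAL].certainty == 1.0
        assert by_source[Source.PSEUDO].certainty == 0.80

    def test_pseudo_on_manual_dropped(self):
        manifest = merge_and_weight([det(0, 0, 0.9)], [manual(0, 0)], self.cfg)
        assert manifest.n_pseudo == 0 and manifest.n_manual == 1

    def test_collision_counting(self, rng):
        # 20 pseudo, 5 manual, 2 of the pseudo colliding: 23 records
        man_pts = [(i * 500.0, 0.0) for i in range(5)]
        pseudo_pts = [(i * 500.0, 3000.0) for i in range(18)]
        pseudo_pts += [(0.0, 5.0), (500.0, 5.0)]  # within collision radius 15
        manifest = merge_and_weight(
            [det(x, y, 0.9) for x, y in pseudo_pts],
            [manual(x, y) for x, y in man_pts],
            self.cfg,
        )
        assert len(manifest.records) == 23
        assert sum(r.certainty == 1.0 for r in manifest.records) == 5

    def test_order_invariance(self, rng):
        pseudo = [det(float(x), float(y), 0.9) for x, y in rng.uniform(0, 1000, (30, 2))]
        man = [manual(float(x), float(y)) for x, y in rng.uniform(0, 1000, (5, 2))]
        a = merge_and_weight(pseudo, man, self.cfg)
        b = merge_and_weight(pseudo[::-1], man[::-1], self.cfg)
        assert a.records == b.records

    def test_patch_specs_follow_records(self):
        manifest = merge_and_weight([det(10.0, 20.0, 0.9)], [], self.cfg)
        (patch,) = manifest.patches
        assert patch.center_um == (10.0, 20.0)
        assert patch.side_px == 1024 and patch.spacing_um == 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PseudoLabelConfig(likelihood_threshold=1.0)
        with pytest.raises(ValueError):
            PseudoLabelConfig(pseudo_certainty=1.0, manual_certainty=0.8)


class TestEndToEnd:
    def test_perfect_teacher_recovers_planted_buds(self, rng):
        # planted buds score likelihood 1.0; noise scores < 0.8 everywhere
        planted = rng.uniform(100, 900, size=(25, 2))
        noise = rng.uniform(0, 1000, size=(40, 2))
        teacher = [det(x, y, 1.0) for x, y in planted]
        teacher += [det(x, y, float(l)) for (x, y), l in zip(noise, rng.uniform(0, 0.79, 40))]
        man = [manual(950.0, 950.0)]
        kept = filter_by_likelihood(teacher, 0.80)
        manifest = merge_and_weight(kept, man, PseudoLabelConfig())
        assert manifest.n_pseudo == 25
        assert manifest.n_manual == 1
        got = sorted((r.x, r.y) for r in manifest.records if r.source == Source.PSEUDO)
        assert got == sorted(map(tuple, planted))
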