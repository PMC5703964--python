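"""Segmentation and shape-metric geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import isletmorph as im
from isletmorph.quantify import (
    SegParams,
    SectionImage,
    feret_diameter,
    polygon_metrics,
    shape_metrics,
)
from isletmorph.synth import GeneratorConfig, IsletSpec, render_section


def _circle_polygon(radius, n=4096):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


def _disk_mask(radius_px, pad=4):
    n = 2 * (radius_px + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius_px + pad
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2


class TestPolygonMetrics:
    def test_circle_circularity_one(self):
        _, _, circ, feret = polygon_metrics(_circle_polygon(50.0))
        assert circ == pytest.approx(1.0, abs=0.02)
        assert feret == pytest.approx(100.0, rel=1e-3)

    def test_square_closed_form(self):
        s = 30.0
        sq = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float)
        area, perim, circ, feret = polygon_metrics(sq)
        assert area == pytest.approx(s * s)
        assert perim == pytest.approx(4 * s)
        assert circ == pytest.approx(math.pi / 4.0)
        assert feret == pytest.approx(s * math.sqrt(2.0))

    def test_ellipse_feret_is_major_axis(self):
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        poly = np.column_stack([100.0 * np.cos(t), 50.0 * np.sin(t)])
        assert polygon_metrics(poly)[3] == pytest.approx(200.0, rel=1e-3)

    @given(st.integers(min_value=0, max_value=200))
    def test_calipers_equal_exhaustive_maximum(self, seed):
        """Rotating calipers reproduces the brute-force pairwise maximum."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(4, 60), 2)) * rng.uniform(1, 100)
        brute = np.sqrt(
            ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        ).max()
        assert feret_diameter(pts) == pytest.approx(brute, rel=1e-9)


class TestMaskMetrics:
    def test_rasterized_circle(self):
        area, perim, circ, feret = shape_metrics(_disk_mask(50), 1.0)
        assert circ == pytest.approx(1.0, abs=0.02)
        assert area == pytest.approx(math.pi * 50**2, rel=0.02)
        assert feret == pytest.approx(100.0, rel=0.03)

    def test_single_pixel_defined(self):
        area, perim, circ, feret = shape_metrics(np.ones((1, 1), bool), 2.0)
        assert area == pytest.approx(4.0)
        assert 0 < circ <= 1.0

    def test_scale_equivariance(self):
        mask = _disk_mask(20)
        a1, p1, c1, f1 = shape_metrics(mask, 1.0)
        a2, p2, c2, f2 = shape_metrics(mask, 2.0)
        assert a2 == pytest.approx(4 * a1)
        assert p2 == pytest.approx(2 * p1)
        assert f2 == pytest.approx(2 * f1)
        assert c2 == pytest.approx(c1)

    def test_circularity_bounded_by_circle(self):
        rng = np.random.default_rng(3)
        blob = rng.random((40, 40)) > 0.55
        blob[15:25, 5:35] = True  # ensure one big component
        from scipy import ndimage as ndi

        lbl, _ = ndi.label(blob)
        sizes = ndi.sum_labels(blob, lbl, index=range(1, lbl.max() + 1))
        comp = lbl == (1 + int(np.argmax(sizes)))
        _, _, circ, _ = shape_metrics(comp, 1.0)
        assert circ <= 1.0
        assert circ < shape_metrics(_disk_mask(30), 1.0)[2] + 0.02

    def test_feret_at_least_effective_diameter(self):
        for mask in (_disk_mask(10), np.ones((3, 30), bool)):
            area, _, _, feret = shape_metrics(mask, 1.0)
            assert feret >= im.effective_diameter(area) * 0.99


def _spec(cx, cy, area, ar=1.0, beta=0.6, alpha=0.3, delta=0.1, block=1):
    return IsletSpec(
        block_index=block, center_x_um=cx, center_y_um=cy,
        true_area_um2=area, cell_count=area / 178.0,
        aspect_ratio=ar, orientation=0.0,
        beta_fraction=beta, alpha_fraction=alpha, delta_fraction=delta,
    )


class TestSegmentation:
    CFG = GeneratorConfig(section_size_px=(512, 512), seed=0)

    def test_blank_channels_give_no_records(self):
        img = render_section([], self.CFG, 1)
        assert im.segment_structures(img) == []
        assert np.count_nonzero(img.channels["beta"]) == 0

    def test_single_circular_islet_roundtrip(self):
        area = 16 * 178.0  # ~60 µm diameter
        img = render_section([_spec(256, 256, area)], self.CFG, 1)
        recs = im.segment_structures(img)
        assert len(recs) == 1
        assert recs[0].area_um2 == pytest.approx(area, rel=0.02)
        assert recs[0].beta_area_um2 / recs[0].hormone_area_um2 == pytest.approx(
            0.6, abs=0.01
        )

    def test_pure_beta_islet_has_empty_other_channels(self):
        img = render_section(
            [_spec(256, 256, 3000.0, beta=1.0, alpha=0.0, delta=0.0)], self.CFG, 1
        )
        assert np.count_nonzero(img.channels["alpha"]) == 0
        assert np.count_nonzero(img.channels["delta"]) == 0
        (rec,) = im.segment_structures(img)
        assert rec.beta_area_um2 == rec.hormone_area_um2

    def test_grouping_distance_merges_close_structures(self):
        """Structures nearer than twice the closing radius merge into one."""
        area = 1000.0
        r_um = math.sqrt(area / math.pi)
        params = SegParams(closing_radius_um=7.5)
        far = [_spec(200, 256, area), _spec(200 + 2 * r_um + 20, 256, area)]
        near = [_spec(200, 256, area), _spec(200 + 2 * r_um + 10, 256, area)]
        img_far = render_section(far, self.CFG, 1)
        img_near = render_section(near, self.CFG, 1)
        assert len(im.segment_structures(img_far, params)) == 2
        assert len(im.segment_structures(img_near, params)) == 1

    def test_hormone_area_closure(self, rendered_run):
        report, _ = rendered_run
        for r in report.islets:
            assert r.hormone_area_um2 <= r.area_um2 * (1 + 1e-9)

    def test_min_structure_area_filters_single_cells(self):
        img = render_section([_spec(256, 256, 120.0)], self.CFG, 1)
        assert im.segment_structures(img, SegParams(min_structure_area_um2=178.0)) == []

    def test_missing_channel_raises(self):
        img = SectionImage(
            channels={"beta": np.zeros((8, 8)), "tissue": np.ones((8, 8))},
            pixel_size_um=1.0,
        )
        with pytest.raises(KeyError):
            im.segment_structures(img)


class TestTissueArea:
    def test_full_and_half_coverage(self):
        full = np.full((40, 50), 255, dtype=np.uint8)
        img = SectionImage(
            channels={"tissue": full}, pixel_size_um=2.0
        )
        assert im.tissue_area(img) == pytest.approx(40 * 50 * 4.0)
        half = full.copy()
        half[:, 25:] = 0
        img2 = SectionImage(channels={"tissue": half}, pixel_size_um=2.0)
        assert im.tissue_area(img2) == pytest.approx(40 * 25 * 4.0)

    def test_matches_generator_tissue_mask(self, rendered_run):
        report, donor = rendered_run
        total = sum(b.tissue_area_um2 for b in report.blocks)
        assert total == pytest.approx(float(donor.block_tissue_areas_um2.sum()))
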