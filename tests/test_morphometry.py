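"""Morphometry: sub-pixel contour accuracy, cleft detection, classification."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from leukopan import geometry as G
from leukopan.morphometry import (
    MorphometryRecord,
    classify,
    detect_clefts,
    measure,
)
from leukopan.quantify import mann_whitney


def rasterize(shape: G.NucleusShape, scale: float = 0.1, area_um2: float = np.pi * 16):
    s = shape.scaled(area_um2)
    ext = np.abs(s.vertices).max() * 1.2
    n = int(2 * ext / scale) + 4
    mask = np.zeros((n, n), dtype=bool)
    rr, cc = draw_polygon(
        (s.vertices[:, 1] + ext) / scale, (s.vertices[:, 0] + ext) / scale, shape=mask.shape
    )
    mask[rr, cc] = True
    return mask, s


class TestContourAccuracy:
    def test_disk_nci_within_1pct(self):
        mask = np.zeros((100, 100), dtype=bool)
        rr, cc = draw_disk((50, 50), 30)
        mask[rr, cc] = True
        m = measure(mask, [mask], pixel_scale_um=1.0)
        assert m.nci == pytest.approx(2 * np.sqrt(np.pi), rel=0.01)

    def test_square_nci_within_1p5pct(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[20:100, 20:100] = True
        m = measure(mask, [mask], pixel_scale_um=1.0)
        assert m.nci == pytest.approx(4.0, rel=0.015)

    @pytest.mark.parametrize("r_px", [10, 20, 40])
    def test_perimeter_error_under_2pct(self, r_px):
        mask = np.zeros((2 * r_px + 20,) * 2, dtype=bool)
        rr, cc = draw_disk((r_px + 10, r_px + 10), r_px)
        mask[rr, cc] = True
        m = measure(mask, [mask], pixel_scale_um=1.0)
        assert m.nuclear_perimeter_um == pytest.approx(2 * np.pi * r_px, rel=0.02)

    def test_nucleus_larger_than_cell_rejected(self):
        big = np.ones((50, 50), dtype=bool)
        small = np.zeros((50, 50), dtype=bool)
        small[20:30, 20:30] = True
        with pytest.raises(ValueError):
            measure(small, [big], 1.0)


class TestDetectClefts:
    def test_circle_has_none(self):
        mask, _ = rasterize(G.ellipse_shape(1.0))
        m = measure(mask, [mask], 0.1)
        assert m.cleft_depths == []

    def test_eccentric_ellipse_has_none(self):
        """Convexity, not eccentricity, decides: no clefts on an ellipse."""
        mask, _ = rasterize(G.ellipse_shape(2.0))
        m = measure(mask, [mask], 0.1)
        assert all(d < 0.1 for d in m.cleft_depths)

    def test_four_lobe_depths_recovered(self):
        amp = G.lobed_amp_for_depth(0.6, k=4, sigma=0.25)
        mask, _ = rasterize(G.lobed_shape(4, amp, 0.25))
        m = measure(mask, [mask], 0.1)
        assert len(m.cleft_depths) == 4
        for d in m.cleft_depths:
            assert d == pytest.approx(0.6, abs=0.05)

    def test_kidney_single_shallow_indentation(self):
        amp = G.kidney_amp_for_depth(0.3, 0.3)
        mask, _ = rasterize(G.kidney_shape(amp, 0.3))
        m = measure(mask, [mask], 0.1)
        assert len(m.cleft_depths) <= 1
        assert all(d < 0.5 for d in m.cleft_depths)

    def test_self_intersecting_contour_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2.0], [0, 0.001]]) * 10
        with pytest.raises(ValueError):
            detect_clefts(bowtie)


def _rec(**kw):
    base = dict(
        cell_area_um2=np.pi * 25,
        equivalent_diameter_um=10.0,
        nuclear_area_um2=60.0,
        nuclear_perimeter_um=30.0,
        nc_ratio=4.0,
        granule_count=0,
        cleft_depths=[],
        nuclei_count=1,
        nci=3.6,
    )
    base.update(kw)
    return MorphometryRecord(**base)


class TestClassifyRules:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(equivalent_diameter_um=10, nc_ratio=4.0), "small_lymphocyte"),
            (dict(equivalent_diameter_um=14, nc_ratio=2.5), "large_lymphocyte"),
            (
                dict(equivalent_diameter_um=14, nc_ratio=2.5, granule_count=5),
                "granular_lymphocyte",
            ),
            (
                dict(equivalent_diameter_um=13, nc_ratio=2.5, granule_count=4,
                     cleft_depths=[0.6, 0.6, 0.6]),
                "granular_lobed_lymphocyte",
            ),
            (
                dict(equivalent_diameter_um=14, nc_ratio=2.6, cleft_depths=[0.55, 0.62]),
                "lobed_lymphocyte",
            ),
            (
                dict(equivalent_diameter_um=17, nc_ratio=1.1, cleft_depths=[0.3]),
                "monocyte",
            ),
            (dict(equivalent_diameter_um=17, nc_ratio=1.5), "reactive_lymphocyte"),
            (dict(equivalent_diameter_um=13, nc_ratio=2.0, nuclei_count=2),
             "binuclear_lymphocyte"),
            # the 12-13 um gap resolves by NC ratio
            (dict(equivalent_diameter_um=12.5, nc_ratio=3.5), "small_lymphocyte"),
            (dict(equivalent_diameter_um=12.5, nc_ratio=2.6), "large_lymphocyte"),
        ],
    )
    def test_rule_cascade(self, kw, expected):
        call = classify(_rec(**kw))
        assert call.label == expected
        assert call.rule_trace


class TestPopulationRecovery:
    def test_measured_nci_medians(self):
        """Lobed median ~4.4 on [4.2, 5]; non-lobed median ~3.75."""
        rng = np.random.default_rng(3)
        lob = []
        for t in G.sample_lobed_nci(rng, 24):
            amp = G.lobed_amp_for_nci(t, 2, 0.12)
            mask, _ = rasterize(G.lobed_shape(2, amp, 0.12, phase=rng.uniform(0, 6.28)))
            lob.append(measure(mask, [mask], 0.1).nci)
        non = []
        for t in G.sample_nonlobed_nci(rng, 40):
            q = G.ellipse_ratio_for_nci(t)
            mask, _ = rasterize(G.ellipse_shape(q, phase=rng.uniform(0, 6.28)))
            non.append(measure(mask, [mask], 0.1).nci)
        assert np.median(lob) == pytest.approx(4.4, abs=0.2)
        assert 4.1 <= min(lob) and max(lob) <= 5.1
        assert np.median(non) == pytest.approx(3.75, abs=0.15)

    def test_classification_accuracy_on_rendered_field(self, mixed_field, mixed_field_cells):
        gt = mixed_field.ground_truth
        df = mixed_field_cells
        tree = cKDTree(np.c_[gt.x_um, gt.y_um])
        _, idx = tree.query(df[["x_um", "y_um"]].to_numpy())
        truth = gt.morphotype.to_numpy()[idx]
        assert (df["morphotype"].to_numpy() == truth).mean() >= 0.95

    def test_measured_areas_match_generative_distribution(self, mixed_field,
                                                          mixed_field_cells):
        """Rank test cannot tell measured from generative cell areas."""
        gt = mixed_field.ground_truth
        df = mixed_field_cells
        rng = np.random.default_rng(0)
        for morph, n in (("small_lymphocyte", 70), ("monocyte", 40)):
            measured = df.loc[df.morphotype == morph, "cell_area_um2"].to_numpy()
            generative = gt.loc[gt.morphotype == morph, "cell_area_um2"].to_numpy()
            k = min(n, len(measured), len(generative))
            res = mann_whitney(
                rng.choice(measured, k, replace=False),
                rng.choice(generative, k, replace=False),
            )
            assert res.p > 0.01
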