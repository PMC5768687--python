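"""Landmark detection and the cross-microscope coordinate relation."""

import numpy as np
import pytest

import camikit as ck
from camikit.registration import MicroscopeFrame, register_contour, register_point
from camikit.targeting import CuttingContour


def brute_force_relation(p, src, tgt):
    """Independent coding of the printed transform, evaluated literally:
    (x2, y2)^T = (y1, x1)^T - (y_off1, x_off1)^T + (x_off2, y_off2)^T."""
    v = np.array([p[1], p[0]], dtype=float)
    v = v - np.array([src.y_off_um, src.x_off_um])
    v = v + np.array([tgt.x_off_um, tgt.y_off_um])
    return float(v[0]), float(v[1])


class TestDetectLandmark:
    PSZ = 0.65

    def test_planted_landmark_recovered(self):
        spec = ck.SlideSpec(rng_seed=3, noise_sd=0.0,
                            illumination_strength=0.0,
                            landmark_position_um=(120.0, 340.0),
                            landmark_rotation_deg=90)
        slide, gt = ck.generate_slide(spec)
        tmpl = ck.landmark_template(int(round(50.0 / self.PSZ)))
        det = ck.detect_landmark(slide.channels["nuclear"], tmpl, self.PSZ)
        assert det.accepted and det.peak > 0.99
        assert det.rotation_deg == 90
        assert det.x_um == pytest.approx(gt.landmark_position_um[0],
                                         abs=0.5 * self.PSZ)
        assert det.y_um == pytest.approx(gt.landmark_position_um[1],
                                         abs=0.5 * self.PSZ)

    def test_absent_landmark_rejected(self):
        rng = np.random.default_rng(0)
        image = rng.normal(100, 5, (256, 256))
        tmpl = ck.landmark_template(64)
        det = ck.detect_landmark(image, tmpl, self.PSZ)
        assert not det.accepted

    def test_translation_equivariance(self):
        spec = ck.SlideSpec(rng_seed=5, noise_sd=0.0, n_nuclei=0,
                            illumination_strength=0.0,
                            landmark_position_um=(200.0, 200.0))
        slide, _ = ck.generate_slide(spec)
        tmpl = ck.landmark_template(int(round(50.0 / self.PSZ)))
        img = slide.channels["nuclear"]
        d0 = ck.detect_landmark(img, tmpl, self.PSZ)
        shifted = np.roll(np.roll(img, 17, axis=0), -23, axis=1)
        d1 = ck.detect_landmark(shifted, tmpl, self.PSZ)
        assert d1.x_um - d0.x_um == pytest.approx(-23 * self.PSZ, abs=1e-6)
        assert d1.y_um - d0.y_um == pytest.approx(17 * self.PSZ, abs=1e-6)

    def test_template_must_be_smaller(self):
        with pytest.raises(ValueError, match="smaller"):
            ck.detect_landmark(np.zeros((32, 32)), np.zeros((64, 64)), 1.0)


class TestRegisterPoint:
    def test_pure_axis_swap_at_zero_offsets(self):
        f1 = MicroscopeFrame("s", 0.0, 0.0)
        f2 = MicroscopeFrame("t", 0.0, 0.0)
        q = register_point((5.0, 7.0), f1, f2)
        assert (q.x_um, q.y_um) == (7.0, 5.0)

    def test_landmark_maps_to_landmark(self):
        f1 = MicroscopeFrame("s", 11.5, -3.25)
        f2 = MicroscopeFrame("t", 200.0, 450.0)
        q = register_point((f1.x_off_um, f1.y_off_um), f1, f2)
        assert q.x_um == pytest.approx(f2.x_off_um, abs=1e-12)
        assert q.y_um == pytest.approx(f2.y_off_um, abs=1e-12)

    def test_matches_independent_oracle_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            src = MicroscopeFrame("s", *rng.uniform(-1e4, 1e4, 2))
            tgt = MicroscopeFrame("t", *rng.uniform(-1e4, 1e4, 2))
            p = tuple(rng.uniform(-1e4, 1e4, 2))
            q = register_point(p, src, tgt)
            ex, ey = brute_force_relation(p, src, tgt)
            assert abs(q.x_um - ex) <= 1e-12 * max(1.0, abs(ex))
            assert abs(q.y_um - ey) <= 1e-12 * max(1.0, abs(ey))

    def test_round_trip_identity(self):
        rng = np.random.default_rng(7)
        src = MicroscopeFrame("s", 12.0, 81.0)
        tgt = MicroscopeFrame("t", -40.0, 3.5)
        for _ in range(100):
            p = tuple(rng.uniform(-1e3, 1e3, 2))
            q = register_point(p, src, tgt)
            back = register_point((q.x_um, q.y_um), tgt, src)
            assert back.x_um == pytest.approx(p[0], abs=1e-9)
            assert back.y_um == pytest.approx(p[1], abs=1e-9)

    def test_orientation_disagreement_refused(self):
        f1 = MicroscopeFrame("s", 0.0, 0.0, rotation_deg=0)
        f2 = MicroscopeFrame("t", 0.0, 0.0, rotation_deg=90)
        with pytest.raises(ValueError, match="orientations disagree"):
            register_point((1.0, 2.0), f1, f2)

    def test_swap_axes_false_is_plain_translation(self):
        f1 = MicroscopeFrame("s", 10.0, 20.0)
        f2 = MicroscopeFrame("t", 110.0, 220.0)
        q = register_point((15.0, 27.0), f1, f2, swap_axes=False)
        assert (q.x_um, q.y_um) == (115.0, 227.0)


class TestRegisterContour:
    def _contour(self):
        theta = np.linspace(0, 2 * np.pi, 33)
        verts = np.stack([50 + 8 * np.cos(theta), 80 + 5 * np.sin(theta)],
                         axis=1)
        return CuttingContour(nucleus_label=1, slide_id="s0",
                              vertices_um=verts, ring_um=3.0)

    def test_isometry_preserves_area_exactly(self):
        from shapely.geometry import Polygon

        c = self._contour()
        src = MicroscopeFrame("s", 3.0, 4.0)
        tgt = MicroscopeFrame("t", 500.0, 700.0)
        r = register_contour(c, src, tgt)
        assert Polygon(r.vertices_um).area == pytest.approx(
            Polygon(c.vertices_um).area, abs=1e-9)
        assert r.frame_id == "t"

    def test_round_trip_and_vertex_order(self):
        c = self._contour()
        src = MicroscopeFrame("s", 3.0, 4.0)
        tgt = MicroscopeFrame("t", 500.0, 700.0)
        back = register_contour(register_contour(c, src, tgt), tgt, src)
        np.testing.assert_allclose(back.vertices_um, c.vertices_um, atol=1e-9)


def test_end_to_end_registration_on_paired_views(canonical_slide):
    """Detected frames on both views map planted centers within 1 px."""
    slide, gt = canonical_slide
    psz = slide.pixel_size_um
    target_view, truth = ck.synthetic.render_transposed_view(
        slide, gt, (250.0, 400.0))
    tmpl = ck.landmark_template(int(round(50.0 / psz)))
    det_s = ck.detect_landmark(slide.channels["nuclear"], tmpl, psz,
                               origin_offset_um=slide.origin_offset_um)
    det_t = ck.detect_landmark(target_view.channels["nuclear"], tmpl.T, psz,
                               origin_offset_um=target_view.origin_offset_um)
    assert det_s.accepted and det_t.accepted
    src = MicroscopeFrame("source", det_s.x_um, det_s.y_um)
    tgt = MicroscopeFrame("target", det_t.x_um, det_t.y_um)
    worst = 0.0
    for rec in gt.nuclei:
        p = slide.pixel_to_um(rec.cx, rec.cy)
        q = register_point(p, src, tgt)
        tx, ty = truth["nucleus_centers_um"][rec.nucleus_id]
        worst = max(worst, np.hypot(q.x_um - tx, q.y_um - ty))
    assert worst < psz  # within one pixel
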