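"""Elliptic Fourier transform, normalization and coefficient averaging."""

import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff

from seedmorph import (
    EFDCoefficients,
    SeedContour,
    average_contour,
    build_model,
    efd_transform,
    normalize_coeffs,
    reconstruct,
    sample_population,
)
from seedmorph.synthetic import population_contours

from conftest import circle_contour, ellipse_contour


def hausdorff(a: SeedContour, b: SeedContour) -> float:
    return max(directed_hausdorff(a.points, b.points)[0], directed_hausdorff(b.points, a.points)[0])


class TestTransform:
    def test_circle_is_single_harmonic(self):
        """A circle has uniform speed, so its arc-length expansion is exact at one harmonic."""
        e = efd_transform(circle_contour(r=1.0, n=720))
        assert np.allclose(e.harmonics[0], [1, 0, 0, 1], atol=1e-3)
        assert np.abs(e.harmonics[1:]).max() < 1e-3
        assert e.dc_term == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_ellipse_first_harmonic_structure(self):
        """Harmonic 1 carries the ellipse axes; the arc-length parameterization
        leaves only small odd-harmonic corrections."""
        e = efd_transform(ellipse_contour(2.0, 1.0))
        a1, b1, c1, d1 = e.harmonics[0]
        assert b1 == pytest.approx(0.0, abs=1e-6)
        assert c1 == pytest.approx(0.0, abs=1e-6)
        assert a1 / d1 == pytest.approx(2.0 / 1.0, rel=0.15)
        # even harmonics vanish by symmetry; all higher terms are small
        assert np.abs(e.harmonics[1]).max() < 1e-6
        assert np.abs(e.harmonics[1:]).max() < 0.1 * a1

    def test_dc_term_is_centroid(self):
        c = SeedContour(circle_contour().points + [5.0, -3.0])
        e = efd_transform(c)
        assert e.dc_term == pytest.approx((5.0, -3.0), abs=1e-3)

    def test_too_few_points_raises(self):
        tri = SeedContour(np.array([[0, 0], [1, 0], [0, 1]], float))
        with pytest.raises(ValueError, match="points"):
            efd_transform(tri, n_harmonics=8)

    def test_reconstruction_error_monotone_in_harmonics(self, templates):
        pops = [sample_population(templates[m], 10, 0.05, 0.03, rng_seed=s)
                for s, m in enumerate(("heben_like", "chenin_like"))]
        for pop in pops:
            for c in population_contours(pop):
                e = efd_transform(c, 8)
                ds = []
                for k in range(1, 9):
                    rec = reconstruct(EFDCoefficients(e.harmonics[:k], dc_term=e.dc_term), 720)
                    ds.append(hausdorff(rec, c))
                assert all(ds[i + 1] <= ds[i] + 1e-9 for i in range(7)), ds
                assert ds[7] < ds[1]  # 8 harmonics strictly better than 2


class TestNormalization:
    @pytest.mark.parametrize("angle,roll,scale", [(0.0, 0, 1.0), (0.7, 123, 1.0), (2.4, 50, 3.0), (-1.1, 200, 0.25)])
    def test_similarity_invariance(self, template_contours, angle, roll, scale):
        c = template_contours["heben_like"]
        ref = normalize_coeffs(efd_transform(c)).harmonics
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = SeedContour(np.roll(scale * (c.points @ rot.T) + [2.0, -7.0], roll, axis=0))
        got = normalize_coeffs(efd_transform(moved)).harmonics
        assert np.abs(got - ref).max() < 1e-6

    def test_idempotent(self, template_contours):
        e = normalize_coeffs(efd_transform(template_contours["chenin_like"]))
        again = normalize_coeffs(e)
        assert np.allclose(again.harmonics, e.harmonics)
        assert again.size_mm == e.size_mm

    def test_size_stored(self):
        e = normalize_coeffs(efd_transform(circle_contour(r=2.5, n=720)))
        assert e.size_mm == pytest.approx(2.5, rel=1e-3)
        assert e.normalized

    def test_degenerate_raises(self):
        e = EFDCoefficients(np.zeros((8, 4)))
        with pytest.raises(ValueError, match="first harmonic"):
            normalize_coeffs(e)


class TestAveraging:
    def test_average_of_identical_sets(self, templates):
        e = templates["heben_like"].efd()
        ac = average_contour([e, e, e], "x")
        assert np.allclose(ac.coeffs.harmonics, e.harmonics)
        assert ac.n_seeds == 3

    def test_midpoint_linearity_exact(self, templates):
        a = templates["heben_like"].efd()
        b = templates["chenin_like"].efd()
        ac = average_contour([a, b], "mid")
        assert np.array_equal(ac.coeffs.harmonics, (a.harmonics + b.harmonics) / 2.0)

    def test_mixed_normalization_rejected(self, templates):
        a = templates["heben_like"].efd()
        b = EFDCoefficients(a.harmonics.copy(), normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            average_contour([a, b], "bad")

    def test_zero_noise_ac_recovers_template(self, templates):
        """Pipeline identity: contour -> EFD -> normalize -> average = template."""
        t = templates["heben_like"]
        pop = sample_population(t, 5, 0.0, 0.0, rng_seed=3)
        coeffs = [normalize_coeffs(efd_transform(c)) for c in population_contours(pop)]
        ac = average_contour(coeffs, t.name)
        assert np.abs(ac.coeffs.harmonics - t.coeffs).max() < 5e-3
        assert ac.coeffs.size_mm == pytest.approx(t.size_mm, rel=0.01)

    def test_model_requires_two_acs(self, templates):
        ac = average_contour([templates["heben_like"].efd()], "one")
        with pytest.raises(ValueError):
            build_model([ac], "m")

    def test_model_is_midpoint_of_member_acs(self, templates):
        a = average_contour([templates["heben_like"].efd()], "a")
        b = average_contour([templates["chenin_like"].efd()], "b")
        m = build_model([a, b], "m")
        assert np.array_equal(m.coeffs.harmonics, (a.coeffs.harmonics + b.coeffs.harmonics) / 2.0)
        assert m.member_labels == ("a", "b")
        m_same = build_model([a, a], "same")
        assert np.allclose(m_same.coeffs.harmonics, a.coeffs.harmonics)


class TestReconstruct:
    def test_harmonic1_only_is_ellipse(self):
        e = EFDCoefficients(np.array([[2.0, 0.0, 0.0, 1.0]]))
        rec = reconstruct(e, 720)
        from seedmorph import measure

        m = measure(rec)
        assert m.aspect_ratio == pytest.approx(2.0, rel=0.01)
        assert m.solidity == 1000

    def test_circle_round_trip_area(self):
        c = circle_contour(r=1.0, n=720)
        rec = reconstruct(efd_transform(c), 360)
        assert rec.area() == pytest.approx(np.pi, rel=0.01)

    def test_negative_curvature_runs_at_most_three(self, template_contours):
        """The smooth 8-harmonic seed outlines have few non-convex stretches."""
        c = template_contours["heben_like"]
        p = c.points
        e_prev = p - np.roll(p, 1, axis=0)
        e_next = np.roll(p, -1, axis=0) - p
        cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
        neg = cross < -1e-12
        runs = int(np.sum(np.diff(np.concatenate([neg, neg[:1]]).astype(int)) == 1))
        assert runs <= 3
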