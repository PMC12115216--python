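"""J-index overlap, registration and population scoring."""

import numpy as np
import pytest

from seedmorph import (
    Pose,
    SeedContour,
    average_contour,
    jindex_population,
    normalize_coeffs,
    efd_transform,
    overlap_ratio,
    register,
    sample_population,
    validate_ac,
)
from seedmorph.contours import resample_contour
from seedmorph.jindex import overlap_ratio_raster
from seedmorph.synthetic import population_contours

from conftest import square_contour


def _square_at(x0: float, y0: float, side: float = 1.0) -> SeedContour:
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) * side + [x0, y0]
    return resample_contour(SeedContour(pts), 40)


class TestOverlapRatio:
    def test_identical_is_100(self, template_contours):
        c = template_contours["heben_like"]
        assert overlap_ratio(c, c) == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_is_0(self):
        assert overlap_ratio(_square_at(0, 0), _square_at(5, 5)) == 0.0

    def test_half_overlapping_unit_squares(self):
        # intersection 0.5, union 1.5 -> 100/3
        j = overlap_ratio(_square_at(0, 0), _square_at(0.5, 0))
        assert j == pytest.approx(100.0 / 3.0, abs=0.05)

    def test_symmetry(self, template_contours):
        a = template_contours["heben_like"]
        b = template_contours["chenin_like"]
        pose = Pose(dx=0.3, dy=-0.2, rotation=0.4, scale=1.1)
        posed_b = SeedContour(pose.apply(b.points, b.centroid()))
        assert overlap_ratio(a, b, pose) == pytest.approx(overlap_ratio(posed_b, a), abs=1e-9)

    def test_bounds(self, template_contours):
        rng = np.random.default_rng(0)
        a = template_contours["chenin_like"]
        for _ in range(10):
            pose = Pose(dx=rng.normal(), dy=rng.normal(), rotation=rng.uniform(-np.pi, np.pi),
                        scale=np.exp(rng.normal(0, 0.3)))
            j = overlap_ratio(a, a, pose)
            assert 0.0 <= j <= 100.0

    def test_degenerate_raises(self):
        flat = SeedContour(np.array([[0, 0], [1, 0], [2, 0], [1.0, 0]]))
        with pytest.raises(ValueError):
            overlap_ratio(flat, _square_at(0, 0))

    def test_raster_mode_agrees_with_exact(self, template_contours):
        a = template_contours["heben_like"]
        b = template_contours["chenin_like"]
        pose = register(a, b)
        je = overlap_ratio(a, b, pose)
        jr = overlap_ratio_raster(a, b, pose, px_per_mm=50.0)
        assert abs(je - jr) <= 0.5


class TestRegister:
    def test_recovers_rigid_copy(self, template_contours):
        c = template_contours["heben_like"]
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = SeedContour(c.points @ rot.T + [3.0, -1.5])
        pose = register(c, moved)
        assert overlap_ratio(c, moved, pose) >= 99.9

    def test_recovers_scaled_copy(self, template_contours):
        c = template_contours["chenin_like"]
        moved = SeedContour(2.0 * c.points + [1.0, 1.0])
        pose = register(c, moved)
        assert overlap_ratio(c, moved, pose) >= 99.9
        assert pose.scale == pytest.approx(0.5, rel=0.01)

    def test_never_below_centroid_aligned_initialization(self, template_contours):
        """Convex vs concave pairs: the registered pose scores at least as
        well as centroid alignment with area-equalizing scale."""
        from shapely.geometry import Polygon

        from conftest import circle_contour, ellipse_contour

        shapes = list(template_contours.values())
        pairs = [(circle_contour(r=3.0, n=240), shapes[0]),
                 (ellipse_contour(3.0, 2.0, n=240), shapes[1]),
                 (shapes[0], shapes[2])]
        for a, b in pairs:
            scale0 = float(np.sqrt(Polygon(a.points).area / Polygon(b.points).area))
            init = Pose(dx=float(a.centroid()[0] - b.centroid()[0]),
                        dy=float(a.centroid()[1] - b.centroid()[1]), scale=scale0)
            j_init = overlap_ratio(a, b, init)
            j_reg = overlap_ratio(a, b, register(a, b))
            assert j_reg >= j_init - 0.01

    def test_fixed_scale_mode(self, template_contours):
        c = template_contours["heben_like"]
        moved = SeedContour(1.5 * c.points)
        pose = register(c, moved, fixed_scale=True)
        assert pose.scale == 1.0
        assert overlap_ratio(c, moved, pose) < 99.0  # size mismatch cannot be absorbed


class TestPopulations:
    def test_population_of_model_copies(self, templates):
        t = templates["heben_like"]
        pop = sample_population(t, 4, 0.0, 0.0, rng_seed=0)
        contours = population_contours(pop)
        res = jindex_population(t.contour(360), contours)
        assert res.mean_j >= 99.9
        assert res.cv_j <= 0.1

    def test_empty_raises(self, template_contours):
        with pytest.raises(ValueError):
            jindex_population(template_contours["heben_like"], [])

    def test_validate_ac_zero_noise(self, templates):
        t = templates["chenin_like"]
        pop = sample_population(t, 4, 0.0, 0.0, rng_seed=1)
        contours = population_contours(pop)
        coeffs = [normalize_coeffs(efd_transform(c)) for c in contours]
        ac = average_contour(coeffs, "ac")
        res = validate_ac(ac, contours)
        assert all(j >= 99.0 for j in res.per_seed)

    def test_smooth_model_scores_higher_than_jagged_seed(self, template_contours):
        """High-frequency outline noise lowers J against a smooth model."""
        c = template_contours["heben_like"]
        rng = np.random.default_rng(5)
        radial = c.points - c.centroid()
        jag = SeedContour(c.centroid() + radial * (1.0 + 0.03 * rng.standard_normal((c.n_points, 1))))
        j_smooth = overlap_ratio(c, c, register(c, c))
        j_jagged = overlap_ratio(c, jag, register(c, jag))
        assert j_jagged < j_smooth

    def test_single_seed_identity_pose_is_optimal(self, templates):
        t = templates["heben_like"]
        c = t.contour(360)
        j_identity = overlap_ratio(c, c)
        rng = np.random.default_rng(2)
        for _ in range(5):
            perturbed = Pose(dx=rng.normal(0, 0.2), dy=rng.normal(0, 0.2),
                             rotation=rng.normal(0, 0.2), scale=float(np.exp(rng.normal(0, 0.1))))
            assert j_identity >= overlap_ratio(c, c, perturbed)


def test_image_average_vs_fourier_average_ac(templates):
    """The raster-mean route and the coefficient-mean route give Acs that
    score within one J point of each other against the same seeds."""
    from skimage import measure as skmeasure

    t = templates["heben_like"]
    pop = sample_population(t, 10, 0.05, 0.0, rng_seed=9)
    contours = population_contours(pop)
    coeffs = [normalize_coeffs(efd_transform(c)) for c in contours]
    fourier_ac = average_contour(coeffs, "fourier")

    # image-analysis route: average aligned binary masks, threshold at 0.5
    px = 40.0
    half = 6.0  # mm half-window
    n_px = int(2 * half * px)
    occupancy = np.zeros((n_px, n_px))
    from skimage.draw import polygon as fill_polygon

    for c in contours:
        pts = c.points - c.centroid()
        rows = (half - pts[:, 1]) * px
        cols = (pts[:, 0] + half) * px
        rr, cc = fill_polygon(rows, cols, occupancy.shape)
        mask = np.zeros_like(occupancy, dtype=bool)
        mask[rr, cc] = True
        occupancy += mask
    mean_mask = occupancy / len(contours)
    trace = max(skmeasure.find_contours(mean_mask, 0.5), key=len)
    x = trace[:, 1] / px - half
    y = half - trace[:, 0] / px
    image_ac = SeedContour(np.column_stack([x, y])).ensure_ccw()

    j_fourier = jindex_population(fourier_ac.reconstruction, contours).mean_j
    j_image = jindex_population(image_ac, contours).mean_j
    assert abs(j_fourier - j_image) <= 1.0
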