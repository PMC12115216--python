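"""Bezier curvature statistics on the lower seed profile.

The lower arc of the outline (leftmost to rightmost point, running under the
seed) is fitted with a degree-10 Bezier curve (least squares, chord-length
parameterization, endpoints interpolated) and the signed curvature

    kappa(t) = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2)      [mm^-1]

is evaluated on a dense grid over t in [0.2, 0.8] — the central stretch,
avoiding the unstable fit near the endpoints. Reported statistics: maximum,
minimum, mean and max/mean ratio. With the profile ordered left-to-right and
the seed body above, positive curvature means convex (bulging away from the
body); negative values mark non-convex regions such as the flanks of the
beak. A circle of radius r gives kappa = 1/r everywhere, so radius 1 mm
means curvature 1 mm^-1 and radius 0.1 mm means 10 mm^-1; a straight line
gives 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from seedmorph.contours import SeedContour

__all__ = ["CurvatureProfile", "BezierCurve", "extract_lower_profile", "fit_bezier", "curvature_stats",
           "DEFAULT_DEGREE", "DEFAULT_T_RANGE", "GRID_POINTS"]

DEFAULT_DEGREE = 10
DEFAULT_T_RANGE = (0.2, 0.8)
GRID_POINTS = 601


@dataclass
class CurvatureProfile:
    max_curv: float      # mm^-1
    min_curv: float      # mm^-1, negative inside non-convex regions
    mean_curv: float     # mm^-1
    max_to_mean_ratio: float
    t_range: tuple[float, float] = DEFAULT_T_RANGE
    degree: int = DEFAULT_DEGREE
    rms_residual: float = float("nan")


@dataclass
class BezierCurve:
    """Polynomial Bezier curve with analytic derivatives."""

    control_points: np.ndarray  # (degree+1, 2)
    rms_residual: float = 0.0

    @property
    def degree(self) -> int:
        return len(self.control_points) - 1

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return _bernstein(self.degree, np.asarray(t, float)) @ self.control_points

    def derivative(self) -> "BezierCurve":
        d = self.degree
        return BezierCurve(d * np.diff(self.control_points, axis=0))


def _bernstein(degree: int, t: np.ndarray) -> np.ndarray:
    i = np.arange(degree + 1)
    return comb(degree, i) * np.power.outer(t, i) * np.power.outer(1.0 - t, degree - i)


def extract_lower_profile(c: SeedContour) -> np.ndarray:
    """Open sub-path along the lower side, leftmost to rightmost point.

    The contour is assumed in standard orientation (major axis roughly
    horizontal, y up). Horizontal-extreme ties resolve to the lowest y.
    """
    pts = c.ensure_ccw().points
    n = len(pts)
    if n < 8:
        raise ValueError("contour too short for a lower profile")
    x, y = pts[:, 0], pts[:, 1]
    # ties on x resolved by lowest y
    i_left = int(np.lexsort((y, x))[0])
    i_right = int(np.lexsort((y, -x))[0])
    if i_left == i_right:
        raise ValueError("degenerate contour: left and right extremes coincide")

    def arc(i, j):
        idx = np.arange(i, j + 1) if j >= i else np.concatenate([np.arange(i, n), np.arange(0, j + 1)])
        return idx

    a1, a2 = arc(i_left, i_right), arc(i_right, i_left)
    # the lower arc is the one whose interior points sit lower on average
    m1 = y[a1[1:-1]].mean() if len(a1) > 2 else np.inf
    m2 = y[a2[1:-1]].mean() if len(a2) > 2 else np.inf
    lower = a1 if m1 <= m2 else a2[::-1]  # reorder so the path runs left -> right
    profile = pts[lower]
    if profile[0, 0] > profile[-1, 0]:
        profile = profile[::-1]
    return profile


def fit_bezier(points: np.ndarray, degree: int = DEFAULT_DEGREE) -> BezierCurve:
    """Least-squares Bezier fit with chord-length parameterization.

    Endpoints are interpolated exactly; interior control points solve the
    normal equations. RMS residual is stored on the returned curve.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}; lower the degree")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate profile (zero length)")
    t = np.concatenate([[0.0], np.cumsum(seg)]) / total
    basis = _bernstein(degree, t)  # (n, degree+1)
    # fix P0 and Pd at the endpoints, solve for the interior
    fixed = np.outer(basis[:, 0], pts[0]) + np.outer(basis[:, -1], pts[-1])
    interior, *_ = np.linalg.lstsq(basis[:, 1:-1], pts - fixed, rcond=None)
    ctrl = np.vstack([pts[0], interior, pts[-1]])
    curve = BezierCurve(ctrl)
    resid = np.hypot(*(curve(t) - pts).T)
    curve.rms_residual = float(np.sqrt(np.mean(resid**2)))
    return curve


def curvature_stats(curve: BezierCurve, t_range: tuple[float, float] = DEFAULT_T_RANGE, n_grid: int = GRID_POINTS) -> CurvatureProfile:
    """Signed-curvature statistics over a dense grid on ``t_range``."""
    t = np.linspace(t_range[0], t_range[1], n_grid)
    d1 = curve.derivative()
    d2 = d1.derivative()
    v = d1(t)
    a = d2(t)
    speed2 = v[:, 0] ** 2 + v[:, 1] ** 2
    if np.any(speed2 < 1e-20):
        raise ValueError("vanishing speed on the evaluation grid; curvature undefined")
    kappa = (v[:, 0] * a[:, 1] - v[:, 1] * a[:, 0]) / speed2**1.5
    mx, mn, mean = float(kappa.max()), float(kappa.min()), float(kappa.mean())
    ratio = mx / mean if mean != 0 else float("inf")
    return CurvatureProfile(max_curv=mx, min_curv=mn, mean_curv=mean, max_to_mean_ratio=ratio,
                            t_range=tuple(t_range), degree=curve.degree, rms_residual=curve.rms_residual)


def contour_curvature_profile(c: SeedContour, degree: int = DEFAULT_DEGREE,
                              t_range: tuple[float, float] = DEFAULT_T_RANGE) -> CurvatureProfile:
    """Convenience: lower profile -> Bezier fit -> curvature statistics."""
    return curvature_stats(fit_bezier(extract_lower_profile(c), degree), t_range)
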