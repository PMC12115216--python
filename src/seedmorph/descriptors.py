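"""The eight per-seed shape measurements (ImageJ conventions).

Area A and perimeter P come from the polygon itself; length L and width W
are the major/minor axes of the moment-equivalent ellipse rescaled so that
pi*L*W/4 equals the polygon area (ImageJ's fitted-ellipse convention, which
is what its aspect-ratio and roundness report). Derived quantities:

    circularity  C  = 4*pi*A / P**2
    aspect ratio AR = L / W
    roundness    R  = 4*A / (pi * L**2)
    solidity     S  = 1000 * A / area(convex hull), nearest integer

A Feret-diameter alternative for L/W is available for sensitivity checks
(``axis_mode="feret"``).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from shapely.geometry import Polygon

from seedmorph.contours import SeedContour

__all__ = ["ShapeMeasurements", "measure", "population_summary"]

_METRICS = ("area_mm2", "perimeter_mm", "length_mm", "width_mm", "circularity", "aspect_ratio", "roundness", "solidity")


@dataclass
class ShapeMeasurements:
    area_mm2: float
    perimeter_mm: float
    length_mm: float
    width_mm: float
    circularity: float
    aspect_ratio: float
    roundness: float
    solidity: int  # x1000 scale
    source_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "source_id"}


def _central_moments(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Area and 2x2 central second-moment matrix of a polygon (Green's theorem)."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    u, v = x - cx, y - cy
    un, vn = np.roll(u, -1), np.roll(v, -1)
    cr = u * vn - un * v
    ixx = np.sum(cr * (u * u + u * un + un * un)) / 12.0
    iyy = np.sum(cr * (v * v + v * vn + vn * vn)) / 12.0
    ixy = np.sum(cr * (u * vn + 2 * u * v + 2 * un * vn + un * v)) / 24.0
    m = np.array([[ixx, ixy], [ixy, iyy]]) / a  # normalized second moments
    return abs(a), m


def _ellipse_axes(points: np.ndarray, area: float) -> tuple[float, float]:
    """Major/minor axis lengths of the ImageJ-style fitted ellipse."""
    _, m = _central_moments(points)
    evals = np.linalg.eigvalsh(m)
    lam2, lam1 = max(evals[0], 1e-300), evals[1]
    ratio = np.sqrt(lam1 / lam2)
    # keep the moment axis ratio, rescale so the ellipse area matches A
    length = np.sqrt(4.0 * area * ratio / np.pi)
    width = length / ratio
    return float(length), float(width)


def _feret_axes(points: np.ndarray) -> tuple[float, float]:
    hull = np.asarray(Polygon(points).convex_hull.exterior.coords)[:-1]
    d = hull[:, None, :] - hull[None, :, :]
    dist = np.hypot(d[..., 0], d[..., 1])
    feret = float(dist.max())
    i, j = np.unravel_index(int(dist.argmax()), dist.shape)
    axis = hull[j] - hull[i]
    axis = axis / np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0]])
    proj = hull @ perp
    return feret, float(proj.max() - proj.min())


def measure(c: SeedContour, *, axis_mode: str = "ellipse") -> ShapeMeasurements:
    """Compute the eight measurements for one contour."""
    pts = c.ensure_ccw().points
    poly = Polygon(pts)
    area = poly.area
    if area <= 0:
        raise ValueError(f"degenerate polygon (zero area): {c.source_id!r}")
    perim = poly.length
    if axis_mode == "ellipse":
        length, width = _ellipse_axes(pts, area)
    elif axis_mode == "feret":
        length, width = _feret_axes(pts)
    else:
        raise ValueError("axis_mode must be 'ellipse' or 'feret'")
    hull_area = poly.convex_hull.area
    return ShapeMeasurements(
        area_mm2=float(area),
        perimeter_mm=float(perim),
        length_mm=length,
        width_mm=width,
        circularity=float(4.0 * np.pi * area / perim**2),
        aspect_ratio=length / width,
        roundness=float(4.0 * area / (np.pi * length**2)),
        solidity=int(round(1000.0 * area / hull_area)),
        source_id=c.source_id,
    )


def population_summary(measurements: list[ShapeMeasurements]) -> dict[str, dict[str, float]]:
    """Per-metric mean and CV (= 100*sd/mean, sample sd) over a seed population."""
    if not measurements:
        raise ValueError("population_summary needs at least one measurement")
    out: dict[str, dict[str, float]] = {}
    for name in _METRICS:
        vals = np.array([float(getattr(m, name)) for m in measurements])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[name] = {"mean": mean, "cv": 100.0 * sd / mean if mean != 0 else float("nan"), "n": len(vals)}
    return out
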