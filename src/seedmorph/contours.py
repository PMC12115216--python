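"""Calibrated closed seed outlines: image extraction, TPS I/O, resampling.

Coordinate convention: images are indexed (row, col) with the origin at the
top-left and rows increasing downward; every contour leaving this module is
in mathematical axes (x right, y up, mm units) and is oriented
counterclockwise. The flip happens exactly once, inside
:func:`extract_contours`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import measure as skmeasure

logger = logging.getLogger(__name__)

__all__ = ["SeedContour", "extract_contours", "read_tps", "write_tps", "resample_contour"]


@dataclass
class SeedContour:
    """One closed, ordered seed outline in mm coordinates.

    ``points`` stores the vertices without repeating the first point;
    closure is implicit.
    """

    points: np.ndarray  # (n, 2) float, mm
    source_id: str = ""
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(self.points) >= 2 and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
        if len(self.points) < 3:
            raise ValueError("a closed contour needs at least 3 distinct points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def closed(self) -> np.ndarray:
        """Vertices with the first point appended again (for plotting/shapely)."""
        return np.vstack([self.points, self.points[:1]])

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def area(self) -> float:
        return abs(self.signed_area())

    def perimeter(self) -> float:
        d = np.diff(self.closed(), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> np.ndarray:
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-300:
            return self.points.mean(axis=0)
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    def is_ccw(self) -> bool:
        return self.signed_area() > 0

    def ensure_ccw(self) -> "SeedContour":
        if self.is_ccw():
            return self
        return SeedContour(self.points[::-1].copy(), self.source_id, self.px_per_mm)

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.points).is_valid


def extract_contours(
    image: np.ndarray,
    px_per_mm: float,
    min_area_mm2: float = 0.0,
    *,
    exclude_border: bool = True,
) -> list[SeedContour]:
    """Extract one sub-pixel contour per connected foreground component.

    Non-binary input is thresholded at the midpoint of its range (logged).
    Components touching the image border are excluded (partial seeds bias
    every downstream shape statistic) and the exclusion is logged.
    Coordinates are scaled to mm and flipped to y-up; contours come back
    counterclockwise, largest-area first per the component labelling order.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    img = np.asarray(image)
    if img.dtype != bool:
        uniq = np.unique(img)
        if len(uniq) > 2:
            mid = (float(img.min()) + float(img.max())) / 2.0
            logger.info("non-binary input: thresholding at midpoint %.4g", mid)
            img = img > mid
        else:
            img = img > img.min()
    if not img.any():
        logger.warning("no foreground component in image")
        return []

    labels = skmeasure.label(img, connectivity=2)
    n_rows = img.shape[0]
    out: list[SeedContour] = []
    n_excluded = 0
    for region in skmeasure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        if exclude_border and (r0 == 0 or c0 == 0 or r1 == img.shape[0] or c1 == img.shape[1]):
            n_excluded += 1
            continue
        # pad by 1 so marching squares closes the contour
        mask = np.pad(region.image.astype(float), 1)
        traced = skmeasure.find_contours(mask, 0.5)
        if not traced:
            continue
        rc = max(traced, key=len)  # outer boundary is the longest trace
        rows = rc[:, 0] - 1 + r0
        cols = rc[:, 1] - 1 + c0
        x = cols / px_per_mm
        y = (n_rows - 1 - rows) / px_per_mm  # flip to y-up
        try:
            contour = SeedContour(np.column_stack([x, y]), source_id=f"seed_{region.label:03d}", px_per_mm=px_per_mm).ensure_ccw()
        except ValueError:
            continue
        if contour.area() >= min_area_mm2:
            out.append(contour)
    if n_excluded:
        logger.info("excluded %d border-touching component(s)", n_excluded)
    if not out:
        logger.warning("no component passed the min_area filter (%.3g mm^2)", min_area_mm2)
    return out


# --- TPS outline files -----------------------------------------------------

_TPS_KEY = re.compile(r"^(LM|OUTLINES|POINTS|CURVES|ID|IMAGE|SCALE)\s*=\s*(.*)$", re.IGNORECASE)


def read_tps(path: str | Path) -> list[SeedContour]:
    """Read outline records (``POINTS=``/``OUTLINES=`` or ``LM=`` blocks) from a TPS file."""
    path = Path(path)
    contours: list[SeedContour] = []
    pts: list[list[float]] = []
    n_expected = 0
    spec_id = ""
    scale: float | None = None
    spec_index = 0

    def flush() -> None:
        nonlocal pts, n_expected, spec_id, scale
        if n_expected or pts:
            if len(pts) != n_expected:
                raise ValueError(
                    f"malformed TPS record for specimen {spec_index}: expected {n_expected} points, found {len(pts)}"
                )
            arr = np.asarray(pts, dtype=float)
            if scale is not None:
                arr = arr * scale
            contours.append(SeedContour(arr, source_id=spec_id or f"specimen_{spec_index}"))
        pts, n_expected, spec_id, scale = [], 0, "", None

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _TPS_KEY.match(line)
        if m:
            key, value = m.group(1).upper(), m.group(2).strip()
            if key in ("LM", "POINTS"):
                if n_expected:
                    flush()
                    spec_index += 1
                n_expected = int(value)
            elif key == "ID":
                spec_id = value
            elif key == "IMAGE":
                spec_id = spec_id or value
            elif key == "SCALE":
                scale = float(value)
            # OUTLINES/CURVES counts are advisory; the point blocks carry the data
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed TPS coordinate line for specimen {spec_index}: {line!r}")
        pts.append([float(parts[0]), float(parts[1])])
    flush()
    return contours


def write_tps(contours: Sequence[SeedContour], path: str | Path) -> None:
    """Write contours as one TPS outline record per specimen."""
    path = Path(path)
    lines: list[str] = []
    for i, c in enumerate(contours):
        lines.append(f"LM={c.n_points}")
        for x, y in c.points:
            lines.append(f"{x:.6f} {y:.6f}")
        lines.append(f"ID={c.source_id or i}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def resample_contour(c: SeedContour, n_points: int = 360) -> SeedContour:
    """Resample a closed contour to ``n_points`` equally spaced by arc length."""
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    closed = c.closed()
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) contour")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return SeedContour(np.column_stack([x, y]), c.source_id, c.px_per_mm)
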