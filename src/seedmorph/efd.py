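"""Elliptic Fourier descriptors: transform, normalization, average contours, models.

A closed outline (x(t), y(t)) is expanded as a truncated elliptic Fourier
series (Kuhl & Giardina):

    x(t) = x0 + sum_n [ A_n cos(n t) + B_n sin(n t) ]
    y(t) = y0 + sum_n [ C_n cos(n t) + D_n sin(n t) ],   t in [0, 2*pi)

with one 2x2 coefficient block [[A, B], [C, D]] per harmonic. Eight harmonics
are used throughout (the 32 coefficients A1..A8, B1..B8, C1..C8, D1..D8).

Normalization standardizes start point and orientation via the first
harmonic (semi-major axis along +x, start point on it) and divides out the
scale, which is kept in ``size_mm`` so mm-scale reconstructions remain
available. Reflection is deliberately NOT normalized away: seeds are
photographed in a consistent lateral view. Because averaging normalized
coefficients is linear, the average contour (Ac) of a population and a
reference model (mean of two or more Acs) are both plain coefficient means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from seedmorph.contours import SeedContour

__all__ = [
    "EFDCoefficients",
    "AverageContour",
    "ShapeModel",
    "efd_transform",
    "normalize_coeffs",
    "average_contour",
    "build_model",
    "reconstruct",
    "N_HARMONICS",
]

N_HARMONICS = 8  # the study-wide harmonic count


@dataclass
class EFDCoefficients:
    """Elliptic Fourier coefficients of one closed curve.

    ``harmonics`` has shape (n_harmonics, 4) with columns (A, B, C, D).
    ``size_mm`` is the semi-major-axis length of the first-harmonic ellipse
    (the scale removed by normalization).
    """

    harmonics: np.ndarray
    dc_term: tuple[float, float] = (0.0, 0.0)
    size_mm: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        if self.harmonics.ndim != 2 or self.harmonics.shape[1] != 4:
            raise ValueError("harmonics must be an (n, 4) array of (A, B, C, D) rows")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def blocks(self) -> np.ndarray:
        """Coefficients as (n, 2, 2) matrices [[A, B], [C, D]]."""
        h = self.harmonics
        return np.stack([h[:, :2], h[:, 2:]], axis=1)

    def flat(self) -> np.ndarray:
        """Coefficients in A1..An, B1..Bn, C1..Cn, D1..Dn column order."""
        return self.harmonics.T.reshape(-1)


@dataclass
class AverageContour:
    """Mean shape of a seed population: arithmetic mean of normalized coefficients."""

    coeffs: EFDCoefficients
    n_seeds: int
    label: str
    reconstruction: SeedContour


@dataclass
class ShapeModel(AverageContour):
    """Reference model: coefficient mean of two or more average contours."""

    member_labels: tuple[str, ...] = ()


def efd_transform(c: SeedContour, n_harmonics: int = N_HARMONICS) -> EFDCoefficients:
    """Kuhl-Giardina elliptic Fourier coefficients of a closed polygon."""
    pts = c.ensure_ccw().points
    if len(pts) < 2 * n_harmonics + 1:
        raise ValueError(f"need at least {2 * n_harmonics + 1} points for {n_harmonics} harmonics")
    closed = np.vstack([pts, pts[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("degenerate contour")
    phi = 2.0 * np.pi * t / T  # (m+1,)

    n = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = const * (dcos @ dxdt)
    b = const * (dsin @ dxdt)
    cc = const * (dcos @ dydt)
    dd = const * (dsin @ dydt)

    # DC term (Kuhl & Giardina A0/C0): accumulated offsets at segment starts
    xi = np.concatenate([[0.0], np.cumsum(d[:, 0])[:-1]]) - (d[:, 0] / dt) * t[:-1]
    delta = np.concatenate([[0.0], np.cumsum(d[:, 1])[:-1]]) - (d[:, 1] / dt) * t[:-1]
    t2 = (t[1:] ** 2 - t[:-1] ** 2) / 2.0
    x0 = pts[0, 0] + float(np.sum((d[:, 0] / dt) * t2 + xi * dt)) / T
    y0 = pts[0, 1] + float(np.sum((d[:, 1] / dt) * t2 + delta * dt)) / T

    harm = np.column_stack([a, b, cc, dd])
    size = _semi_major(harm[0])
    return EFDCoefficients(harm, dc_term=(x0, y0), size_mm=size, normalized=False)


def _semi_major(h1: np.ndarray) -> float:
    m = np.array([[h1[0], h1[1]], [h1[2], h1[3]]])
    s = np.linalg.svd(m, compute_uv=False)
    return float(s[0])


def _phase_rotation(n: int, theta: float) -> np.ndarray:
    c, s = np.cos(n * theta), np.sin(n * theta)
    return np.array([[c, -s], [s, c]])


def _apply_normalization(blocks: np.ndarray, theta: float) -> np.ndarray:
    """Start-point shift by theta, then rotate so the harmonic-1 major axis lies on +x."""
    out = np.array([blk @ _phase_rotation(k + 1, theta) for k, blk in enumerate(blocks)])
    a1, c1 = out[0, 0, 0], out[0, 1, 0]
    psi = np.arctan2(c1, a1)
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    return np.einsum("ij,njk->nik", rot, out)


def normalize_coeffs(e: EFDCoefficients) -> EFDCoefficients:
    """Standardize start point, rotation and scale via the first harmonic.

    Idempotent; invariant to input rotation, translation, start point and
    scale. The residual half-turn ambiguity of the phase is resolved by
    choosing the candidate whose t=0 point has the larger x coordinate
    (for a beaked seed: start at the beak tip).
    """
    if e.normalized:
        return replace(e, harmonics=e.harmonics.copy())
    h1 = e.harmonics[0]
    a1, b1, c1, d1 = h1
    denom = a1**2 + c1**2 - b1**2 - d1**2
    num = 2.0 * (a1 * b1 + c1 * d1)
    if np.hypot(num, denom) < 1e-300:
        raise ValueError("degenerate first harmonic: cannot normalize")
    theta = 0.5 * np.arctan2(num, denom)
    blocks = e.blocks()
    cand = [_apply_normalization(blocks, theta), _apply_normalization(blocks, theta + np.pi)]
    # x(0) = sum of A_k; pick the larger (beak-end start); ties -> first
    xs = [float(np.sum(b[:, 0, 0])) for b in cand]
    best = cand[int(xs[1] > xs[0] + 1e-12)]
    scale = best[0, 0, 0]  # = semi-major length, > 0 by construction
    if scale <= 0:
        raise ValueError("degenerate first harmonic: zero scale")
    best = best / scale
    harm = np.column_stack([best[:, 0, 0], best[:, 0, 1], best[:, 1, 0], best[:, 1, 1]])
    return EFDCoefficients(harm, dc_term=(0.0, 0.0), size_mm=float(scale), normalized=True)


def reconstruct(e: EFDCoefficients, n_points: int = 360, *, at_scale: bool = False, source_id: str = "") -> SeedContour:
    """Evaluate the truncated Fourier series at uniform parameter values.

    ``at_scale=True`` multiplies normalized coefficients back by ``size_mm``
    so the contour is in mm.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, e.n_harmonics + 1)[:, None]
    cos_nt, sin_nt = np.cos(n * t), np.sin(n * t)
    h = e.harmonics
    x = h[:, 0] @ cos_nt + h[:, 1] @ sin_nt + e.dc_term[0]
    y = h[:, 2] @ cos_nt + h[:, 3] @ sin_nt + e.dc_term[1]
    pts = np.column_stack([x, y])
    if at_scale and e.normalized:
        pts = pts * e.size_mm
    return SeedContour(pts, source_id=source_id).ensure_ccw()


def _check_mergeable(coeff_list: list[EFDCoefficients]) -> None:
    if not coeff_list:
        raise ValueError("need at least one coefficient set")
    states = {e.normalized for e in coeff_list}
    if states != {True}:
        raise ValueError("all coefficient sets must be normalized before averaging")
    counts = {e.n_harmonics for e in coeff_list}
    if len(counts) != 1:
        raise ValueError(f"mixed harmonic counts: {sorted(counts)}")


def average_contour(coeff_list: list[EFDCoefficients], label: str, n_points: int = 360) -> AverageContour:
    """Average contour (Ac): element-wise mean of normalized coefficients."""
    _check_mergeable(coeff_list)
    harm = np.mean([e.harmonics for e in coeff_list], axis=0)
    size = float(np.mean([e.size_mm for e in coeff_list]))
    coeffs = EFDCoefficients(harm, dc_term=(0.0, 0.0), size_mm=size, normalized=True)
    return AverageContour(coeffs=coeffs, n_seeds=len(coeff_list), label=label,
                          reconstruction=reconstruct(coeffs, n_points, source_id=label))


def build_model(acs: list[AverageContour], name: str, n_points: int = 360) -> ShapeModel:
    """Reference model: coefficient mean across two or more average contours."""
    if len(acs) < 2:
        raise ValueError("a model requires at least 2 average contours")
    _check_mergeable([ac.coeffs for ac in acs])
    harm = np.mean([ac.coeffs.harmonics for ac in acs], axis=0)
    size = float(np.mean([ac.coeffs.size_mm for ac in acs]))
    coeffs = EFDCoefficients(harm, dc_term=(0.0, 0.0), size_mm=size, normalized=True)
    return ShapeModel(coeffs=coeffs, n_seeds=sum(ac.n_seeds for ac in acs), label=name,
                      reconstruction=reconstruct(coeffs, n_points, source_id=name),
                      member_labels=tuple(ac.label for ac in acs))
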