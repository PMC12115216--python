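"""Synthetic seed-contour populations with known morphotype parameters.

Three built-in templates stand in for the study's reference material:

* ``heben_like``    — triangular body, wide beak, high solidity
                      (target AR 1.62, solidity 975 x1000)
* ``chenin_like``   — straighter, narrower beak with deeper flank
                      concavities, lower solidity (AR 1.68, solidity 955)
* ``sylvestris_like`` — wild-type: rounder and more solid (AR 1.35,
                      solidity 985; low-AR class)

Template coefficients are frozen constants: each was obtained once by
fitting 8 normalized elliptic Fourier harmonics to a hand-designed pyriform
outline (ellipse body + Gaussian beak - flank dips) and tuning body
elongation and dip depth until the reconstruction measured the target
aspect ratio and solidity. ``scripts/tune_templates.py`` reproduces them.

Per-seed variation is multiplicative Gaussian noise on harmonics 2-8
(shape) plus a lognormal-free size factor on harmonic 1 (size), so size and
gross shape vary independently. Draws whose reconstruction self-intersects
are rejected and redrawn (at most 100 retries per seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from seedmorph.contours import SeedContour
from seedmorph.efd import EFDCoefficients, reconstruct

__all__ = ["MorphotypeTemplate", "SyntheticPopulation", "build_template", "sample_population",
           "rasterize_population", "population_contours", "MORPHOTYPES"]

MAX_RETRIES = 100

# frozen output of scripts/tune_templates.py (8 harmonics x [A, B, C, D])
_TEMPLATE_COEFFS: dict[str, np.ndarray] = {
    "heben_like": np.array([
        [+1.000000000000e+00, +0.000000000000e+00, +0.000000000000e+00, +6.931473092100e-01],
        [+2.461711075738e-02, +0.000000000000e+00, +0.000000000000e+00, -6.332216968908e-02],
        [+6.328281939772e-02, +0.000000000000e+00, +0.000000000000e+00, +5.035214750390e-02],
        [+1.447930294464e-02, +0.000000000000e+00, +0.000000000000e+00, +4.148378179778e-02],
        [+1.160175172374e-03, +0.000000000000e+00, +0.000000000000e+00, +1.460362821570e-02],
        [-2.301037543804e-03, +0.000000000000e+00, +0.000000000000e+00, -1.228268505234e-02],
        [+3.507176509043e-03, +0.000000000000e+00, +0.000000000000e+00, -8.092218629473e-03],
        [+3.643132487510e-03, +0.000000000000e+00, +0.000000000000e+00, +4.849134714190e-03],
    ]),
    "chenin_like": np.array([
        [+1.000000000000e+00, +0.000000000000e+00, +0.000000000000e+00, +6.396296941020e-01],
        [+2.297220025123e-02, +0.000000000000e+00, +0.000000000000e+00, -1.117706718749e-01],
        [+8.445859211603e-02, +0.000000000000e+00, +0.000000000000e+00, +1.600238288790e-02],
        [+3.721763485288e-02, +0.000000000000e+00, +0.000000000000e+00, +2.971980820593e-02],
        [+1.746205311238e-02, +0.000000000000e+00, +0.000000000000e+00, +3.346077872470e-02],
        [+7.905739496754e-04, +0.000000000000e+00, +0.000000000000e+00, +1.039440583718e-02],
        [+1.693692232478e-03, +0.000000000000e+00, +0.000000000000e+00, -3.940029302337e-03],
        [+6.251020671869e-03, +0.000000000000e+00, +0.000000000000e+00, -4.501481003698e-03],
    ]),
    "sylvestris_like": np.array([
        [+1.000000000000e+00, +0.000000000000e+00, +0.000000000000e+00, +8.070919214713e-01],
        [+4.325469150541e-02, +0.000000000000e+00, +0.000000000000e+00, -3.772195605949e-02],
        [+3.526355574828e-02, +0.000000000000e+00, +0.000000000000e+00, +4.347967186926e-02],
        [-4.571780234013e-03, +0.000000000000e+00, +0.000000000000e+00, +3.842428877863e-02],
        [+1.753335076044e-02, +0.000000000000e+00, +0.000000000000e+00, -2.193906340970e-02],
        [-1.254098927340e-02, +0.000000000000e+00, +0.000000000000e+00, -7.214007090474e-03],
        [+9.482637908234e-03, +0.000000000000e+00, +0.000000000000e+00, +1.992994624272e-02],
        [-1.386053587847e-03, +0.000000000000e+00, +0.000000000000e+00, -7.799644438986e-03],
    ]),
}

_TEMPLATE_META = {
    "heben_like": dict(nominal_length_mm=6.5, target_solidity=975, target_aspect_ratio=1.62),
    "chenin_like": dict(nominal_length_mm=6.8, target_solidity=955, target_aspect_ratio=1.68),
    "sylvestris_like": dict(nominal_length_mm=5.5, target_solidity=985, target_aspect_ratio=1.35),
}

MORPHOTYPES = tuple(_TEMPLATE_META)


@dataclass
class MorphotypeTemplate:
    name: str
    coeffs: np.ndarray  # (8, 4) normalized Fourier coefficients
    nominal_length_mm: float
    target_solidity: int
    target_aspect_ratio: float

    @property
    def size_mm(self) -> float:
        """Semi-major-axis scale used for mm reconstructions."""
        return self.nominal_length_mm / 2.0

    def efd(self) -> EFDCoefficients:
        return EFDCoefficients(self.coeffs.copy(), size_mm=self.size_mm, normalized=True)

    def contour(self, n_points: int = 360) -> SeedContour:
        return reconstruct(self.efd(), n_points, at_scale=True, source_id=self.name)


@dataclass
class SyntheticPopulation:
    template: MorphotypeTemplate
    seeds: list[np.ndarray]  # per-seed (8, 4) coefficient matrices
    true_label: str
    rng_seed: int


def build_template(morphotype: str) -> MorphotypeTemplate:
    """Return the fixed, versioned template for a known morphotype label."""
    if morphotype not in _TEMPLATE_COEFFS:
        raise ValueError(f"unknown morphotype {morphotype!r}; valid labels: {', '.join(MORPHOTYPES)}")
    meta = _TEMPLATE_META[morphotype]
    return MorphotypeTemplate(name=morphotype, coeffs=_TEMPLATE_COEFFS[morphotype].copy(), **meta)


def _is_simple(coeffs: np.ndarray) -> bool:
    rec = reconstruct(EFDCoefficients(coeffs, normalized=True), 200)
    return rec.is_simple()


def sample_population(template: MorphotypeTemplate, n: int, coeff_noise_cv: float = 0.05,
                      size_cv: float = 0.03, rng_seed: int = 0) -> SyntheticPopulation:
    """Draw ``n`` per-seed coefficient matrices around a template.

    Harmonics 2-8 get independent multiplicative zero-mean Gaussian noise
    (sd = coeff_noise_cv * |coefficient|); harmonic 1 is scaled by a size
    factor with CV ``size_cv``. Deterministic for a fixed ``rng_seed``;
    self-intersecting draws are redrawn (bounded retries).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if coeff_noise_cv < 0 or size_cv < 0:
        raise ValueError("noise CVs must be non-negative")
    rng = np.random.default_rng(rng_seed)
    seeds: list[np.ndarray] = []
    for _ in range(n):
        for attempt in range(MAX_RETRIES):
            coeffs = template.coeffs.copy()
            if coeff_noise_cv > 0:
                coeffs[1:] *= 1.0 + coeff_noise_cv * rng.standard_normal(coeffs[1:].shape)
            if size_cv > 0:
                coeffs[0] *= 1.0 + size_cv * rng.standard_normal()
            if coeff_noise_cv == 0 or _is_simple(coeffs):
                seeds.append(coeffs)
                break
        else:
            raise RuntimeError(
                f"no simple contour in {MAX_RETRIES} draws (coeff_noise_cv={coeff_noise_cv}); lower the noise"
            )
    return SyntheticPopulation(template=template, seeds=seeds, true_label=template.name, rng_seed=rng_seed)


def population_contours(pop: SyntheticPopulation, n_points: int = 360, *, at_scale: bool = True) -> list[SeedContour]:
    """Reconstruct every member as a (mm-scale) contour."""
    out = []
    for i, coeffs in enumerate(pop.seeds):
        e = EFDCoefficients(coeffs, size_mm=pop.template.size_mm, normalized=True)
        out.append(reconstruct(e, n_points, at_scale=at_scale, source_id=f"{pop.true_label}_{i:03d}"))
    return out


def rasterize_population(pop: SyntheticPopulation, px_per_mm: float = 20.0,
                         layout: tuple[int, int] | None = None, margin_mm: float = 1.5):
    """Render the population as a binary image of non-touching silhouettes.

    Returns ``(image, ground_truth)`` where ``ground_truth`` holds each
    seed's contour in the image's mm frame (y up, origin bottom-left).
    """
    from skimage.draw import polygon as fill_polygon

    contours = population_contours(pop)
    lengths = [np.ptp(c.points[:, 0]) for c in contours]
    if min(lengths) * px_per_mm < 100:
        raise ValueError("px_per_mm too low: each seed must span at least 100 px in length")
    n = len(contours)
    if layout is None:
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
    else:
        rows, cols = layout
        if rows * cols < n:
            raise ValueError(f"layout {layout} too small for {n} seeds")
    extents = np.array([c.points.max(axis=0) - c.points.min(axis=0) for c in contours])
    cell_mm = float(extents.max()) + 2.0 * margin_mm
    width_px = int(np.ceil(cols * cell_mm * px_per_mm)) + 1
    height_px = int(np.ceil(rows * cell_mm * px_per_mm)) + 1
    image = np.zeros((height_px, width_px), dtype=bool)
    truth: list[SeedContour] = []
    for i, c in enumerate(contours):
        r, k = divmod(i, cols)
        center = np.array([(k + 0.5) * cell_mm, (rows - r - 0.5) * cell_mm])
        pts = c.points - c.centroid() + center
        truth.append(SeedContour(pts, source_id=c.source_id, px_per_mm=px_per_mm))
        col_px = pts[:, 0] * px_per_mm
        row_px = (height_px - 1) - pts[:, 1] * px_per_mm
        rr, cc = fill_polygon(row_px, col_px, image.shape)
        image[rr, cc] = True
    return image, truth


def write_population(pop: SyntheticPopulation, out_dir: str | Path, px_per_mm: float = 20.0,
                     stem: str | None = None) -> dict[str, Path]:
    """Write the PNG mask, TPS outlines and a CSV manifest for a population."""
    import imageio.v3 as iio

    from seedmorph.contours import write_tps

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or pop.true_label
    image, truth = rasterize_population(pop, px_per_mm=px_per_mm)
    paths = {
        "image": out_dir / f"{stem}.png",
        "tps": out_dir / f"{stem}.tps",
        "manifest": out_dir / f"{stem}_manifest.csv",
    }
    iio.imwrite(paths["image"], (image * np.uint8(255)))
    write_tps(truth, paths["tps"])
    with open(paths["manifest"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["seed_id", "true_label", "rng_seed"])
        for c in truth:
            w.writerow([c.source_id, pop.true_label, pop.rng_seed])
    return paths
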