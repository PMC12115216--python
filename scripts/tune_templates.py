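"""Provenance script: derive the hard-coded morphotype template coefficients.

Each template starts from a hand-designed pyriform outline (ellipse body +
Gaussian beak bump - symmetric flank dips, in polar form), is transformed to
8 normalized elliptic Fourier harmonics, and the two free parameters (body
elongation ``a`` and flank-dip depth) are tuned until the measured aspect
ratio and solidity of the 8-harmonic reconstruction hit the morphotype
targets. Run from the repo root:

    python scripts/tune_templates.py

and paste the printed arrays into ``seedmorph.synthetic``. The committed
coefficients in the package are the frozen output of this script.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root

from seedmorph.contours import SeedContour
from seedmorph.descriptors import measure
from seedmorph.efd import efd_transform, normalize_coeffs, reconstruct, EFDCoefficients

# fixed morphology of each morphotype (beak geometry, dip placement);
# (a, dip_depth) are tuned to the (AR, S) targets below
MORPHOLOGY = {
    "heben_like": dict(beak_amp=0.55, beak_sigma=0.55, dip_angle=0.90, dip_sigma=0.35,
                       targets=(1.62, 975.0), x0=(1.15, 0.10)),
    "chenin_like": dict(beak_amp=0.80, beak_sigma=0.32, dip_angle=0.60, dip_sigma=0.30,
                        targets=(1.68, 955.0), x0=(1.25, 0.16)),
    "sylvestris_like": dict(beak_amp=0.28, beak_sigma=0.55, dip_angle=0.90, dip_sigma=0.30,
                            targets=(1.35, 985.0), x0=(1.15, 0.04)),
}


def base_outline(a: float, beak_amp: float, beak_sigma: float,
                 dip_depth: float, dip_angle: float, dip_sigma: float, n: int = 1024) -> SeedContour:
    th = np.linspace(-np.pi, np.pi, n, endpoint=False)
    b = 1.0
    r = a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
    r = r + beak_amp * np.exp(-((th / beak_sigma) ** 2))
    r = r - dip_depth * (np.exp(-(((th - dip_angle) / dip_sigma) ** 2))
                         + np.exp(-(((th + dip_angle) / dip_sigma) ** 2)))
    if np.any(r <= 0):
        raise ValueError("outline self-intersects (r <= 0)")
    return SeedContour(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def template_coeffs(a: float, dip_depth: float, morph: dict) -> np.ndarray:
    c = base_outline(a, morph["beak_amp"], morph["beak_sigma"], dip_depth,
                     morph["dip_angle"], morph["dip_sigma"])
    return normalize_coeffs(efd_transform(c, 8)).harmonics


def measured(harm: np.ndarray) -> tuple[float, float]:
    rec = reconstruct(EFDCoefficients(harm, normalized=True), 360)
    m = measure(rec)
    return m.aspect_ratio, float(m.solidity)


def tune(name: str) -> np.ndarray:
    morph = MORPHOLOGY[name]
    ar_t, s_t = morph["targets"]

    def resid(v):
        ar, s = measured(template_coeffs(v[0], v[1], morph))
        return [ar - ar_t, (s - s_t) / 100.0]

    sol = root(resid, morph["x0"], method="hybr", options={"xtol": 1e-10})
    if not sol.success:
        raise RuntimeError(f"{name}: tuning failed: {sol.message}")
    harm = template_coeffs(sol.x[0], sol.x[1], morph)
    ar, s = measured(harm)
    print(f"# {name}: a={sol.x[0]:.6f} dip={sol.x[1]:.6f}  AR={ar:.4f} S={s:.0f}")
    return harm


def main() -> None:
    np.set_printoptions(floatmode="unique")
    for name in MORPHOLOGY:
        harm = tune(name)
        rows = ",\n    ".join("[" + ", ".join(f"{v:+.12e}" for v in row) + "]" for row in harm)
        print(f'"{name}": np.array([\n    {rows}\n]),\n')


if __name__ == "__main__":
    main()
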