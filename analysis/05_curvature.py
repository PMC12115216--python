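"""Bezier curvature signature of each test seed's lower profile.

Seeds are first put in the standard orientation (normalized Fourier
reconstruction: major axis horizontal, beak to the right), then the lower
profile is fitted with a degree-10 Bezier curve and the signed curvature is
summarized over t in [0.2, 0.8]. Prints the per-morphotype means that
distinguish the two cultivated types: the straighter-beaked, low-solidity
type shows the stronger negative minimum and the larger max/mean ratio.

Writes ``results/curvature.csv``.
"""

import pandas as pd

from seedmorph.contours import read_tps
from seedmorph.curvature import contour_curvature_profile
from seedmorph.efd import efd_transform, normalize_coeffs, reconstruct

from common import RESULTS, TEST_POPULATIONS, tps_path


def main() -> None:
    rows = []
    for label in TEST_POPULATIONS:
        for c in read_tps(tps_path(label)):
            std = reconstruct(normalize_coeffs(efd_transform(c, 8)), 360, at_scale=True,
                              source_id=c.source_id)
            p = contour_curvature_profile(std)
            rows.append({"population": label, "seed_id": c.source_id, "max_curv": p.max_curv,
                         "min_curv": p.min_curv, "mean_curv": p.mean_curv,
                         "max_to_mean_ratio": p.max_to_mean_ratio, "degree": p.degree,
                         "rms_residual": p.rms_residual})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "curvature.csv", index=False, float_format="%.6f")
    print(df.groupby("population")[["max_curv", "min_curv", "mean_curv", "max_to_mean_ratio"]]
            .mean().round(3).to_string())
    print(f"\n{len(df)} seeds -> {RESULTS / 'curvature.csv'}")


if __name__ == "__main__":
    main()
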