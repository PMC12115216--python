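"""Score the test populations against both models and classify.

Each test seed is registered against each model (rotation sweep + local
refinement) and scored with the J-index; the population value is the mean
over its seeds. Populations are then split by aspect ratio, ranked by
descending solidity, and assigned to the four J-index groups.

Writes ``results/jindex.csv`` (per seed) and ``results/groups.csv``.
"""

import numpy as np
import pandas as pd

from seedmorph.classify import assign_group, order_by_solidity, split_by_aspect_ratio
from seedmorph.contours import read_tps, SeedContour
from seedmorph.efd import EFDCoefficients, reconstruct
from seedmorph.jindex import jindex_population

from common import COEFF_NAMES, RESULTS, TEST_POPULATIONS, tps_path


def model_contours() -> dict[str, SeedContour]:
    models = pd.read_csv(RESULTS / "models.csv")
    out = {}
    for _, row in models.iterrows():
        coeffs = EFDCoefficients(row[COEFF_NAMES].to_numpy(float).reshape(4, 8).T,
                                 size_mm=float(row["size_mm"]), normalized=True)
        out[row["model"]] = reconstruct(coeffs, 360, at_scale=True, source_id=row["model"])
    return out


def main() -> None:
    models = model_contours()
    meas = pd.read_csv(RESULTS / "measurements.csv").set_index("population")

    j_rows, mean_j = [], {}
    for label in TEST_POPULATIONS:
        seeds = read_tps(tps_path(label))
        mean_j[label] = {}
        for mname, mcontour in models.items():
            res = jindex_population(mcontour, seeds, population_label=label)
            mean_j[label][mname] = res.mean_j
            for sid, j, pose in zip(res.seed_ids, res.per_seed, res.poses):
                j_rows.append({"population": label, "model": mname, "seed_id": sid, "J": j,
                               "dx": pose.dx, "dy": pose.dy,
                               "theta_deg": float(np.rad2deg(pose.rotation)), "scale": pose.scale})
    pd.DataFrame(j_rows).to_csv(RESULTS / "jindex.csv", index=False, float_format="%.4f")

    pop_ar = {lab: float(meas.loc[lab, "aspect_ratio"].mean()) for lab in TEST_POPULATIONS}
    pop_s = {lab: float(meas.loc[lab, "solidity"].mean()) for lab in TEST_POPULATIONS}
    ar_class = split_by_aspect_ratio(pop_ar)
    ranks = order_by_solidity({lab: (ar_class[lab], pop_s[lab]) for lab in TEST_POPULATIONS})

    rows = []
    print(f"{'population':16s} {'J_heben':>8s} {'J_chenin':>9s} {'AR':>6s} {'S':>6s} group rank")
    for label in TEST_POPULATIONS:
        jh, jc = mean_j[label]["heben"], mean_j[label]["chenin"]
        group = assign_group(jh, jc)
        rows.append({"population": label, "J_heben": jh, "J_chenin": jc, "AR": pop_ar[label],
                     "S": pop_s[label], "ar_class": ar_class[label], "rank": ranks[label], "group": group})
        print(f"{label:16s} {jh:8.2f} {jc:9.2f} {pop_ar[label]:6.2f} {pop_s[label]:6.1f} {group:>5s} {ranks[label]:4d}")
    pd.DataFrame(rows).sort_values("rank").to_csv(RESULTS / "groups.csv", index=False, float_format="%.4f")


if __name__ == "__main__":
    main()
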