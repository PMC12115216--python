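"""Average contours (Acs) and the two reference models.

Per population: 8-harmonic normalized Fourier coefficients per seed, their
arithmetic mean (the Ac). The two models are coefficient means of their
member Acs. The Heben-type Ac is validated the way the study validates Acs:
J-index of the Ac against the very seeds it was derived from.

Writes ``results/coefficients.csv`` (per seed), ``results/acs.csv`` and
``results/models.csv`` (one coefficient row each), and
``results/ac_validation.csv``.
"""

import pandas as pd

from seedmorph.contours import read_tps
from seedmorph.efd import average_contour, build_model, efd_transform, normalize_coeffs
from seedmorph.jindex import validate_ac

from common import COEFF_NAMES, MODELS, POPULATIONS, RESULTS, tps_path


def main() -> None:
    coeff_rows, acs = [], {}
    contours_by_pop = {}
    for label in sorted(POPULATIONS):
        contours = read_tps(tps_path(label))
        contours_by_pop[label] = contours
        coeffs = [normalize_coeffs(efd_transform(c, 8)) for c in contours]
        acs[label] = average_contour(coeffs, label)
        for c, contour in zip(coeffs, contours):
            coeff_rows.append({"population": label, "seed_id": contour.source_id,
                               "size_mm": c.size_mm, **dict(zip(COEFF_NAMES, c.flat()))})
    pd.DataFrame(coeff_rows).to_csv(RESULTS / "coefficients.csv", index=False, float_format="%.10f")

    ac_rows = [{"population": lab, "n_seeds": ac.n_seeds, "size_mm": ac.coeffs.size_mm,
                **dict(zip(COEFF_NAMES, ac.coeffs.flat()))} for lab, ac in acs.items()]
    pd.DataFrame(ac_rows).to_csv(RESULTS / "acs.csv", index=False, float_format="%.10f")

    model_rows = []
    for name, members in MODELS.items():
        model = build_model([acs[m] for m in members], name)
        model_rows.append({"model": name, "members": "|".join(members),
                           "size_mm": model.coeffs.size_mm, **dict(zip(COEFF_NAMES, model.coeffs.flat()))})
        print(f"model {name!r} = mean of Acs {members}")
    pd.DataFrame(model_rows).to_csv(RESULTS / "models.csv", index=False, float_format="%.10f")

    # Ac validation: J of each reference Ac against its own seeds
    val_rows = []
    for label in ("heben_2024", "gewurztraminer"):
        res = validate_ac(acs[label], contours_by_pop[label])
        val_rows.append({"population": label, "mean_J": res.mean_j, "cv_J": res.cv_j})
        print(f"Ac validation {label:14s}: mean J = {res.mean_j:.1f} (CV {res.cv_j:.1f})")
    pd.DataFrame(val_rows).to_csv(RESULTS / "ac_validation.csv", index=False, float_format="%.4f")


if __name__ == "__main__":
    main()
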