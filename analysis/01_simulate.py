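"""Generate the synthetic seed populations for the whole analysis.

Writes, per population: TPS outlines (the canonical downstream input), a
binary PNG of the rasterized silhouettes, and a CSV manifest. Populations
follow the study design in ``common.py``; per-seed child seeds derive from
one root RNG seed.
"""

import numpy as np

from seedmorph.synthetic import build_template, sample_population, write_population
from seedmorph.contours import write_tps
from seedmorph.synthetic import population_contours

from common import POPULATIONS, RNG_SEED, SYNTH, tps_path


def main() -> None:
    SYNTH.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(RNG_SEED)
    labels = sorted(POPULATIONS)
    child = {lab: int(s) for lab, s in zip(labels, root.integers(0, 2**31 - 1, size=len(labels)))}
    for label in labels:
        morphotype, n = POPULATIONS[label]
        pop = sample_population(build_template(morphotype), n, coeff_noise_cv=0.05,
                                size_cv=0.03, rng_seed=child[label])
        contours = population_contours(pop)
        for i, c in enumerate(contours):
            c.source_id = f"{label}_{i:03d}"
        write_tps(contours, tps_path(label))
        write_population(pop, SYNTH, px_per_mm=20.0, stem=label)
        print(f"{label:16s} {morphotype:16s} n={n:3d} rng_child={child[label]}")
    print(f"\nwrote TPS/PNG/manifest for {len(labels)} populations under {SYNTH}")


if __name__ == "__main__":
    main()
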