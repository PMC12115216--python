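"""Measure every seed: the eight shape descriptors, per population.

Reads the TPS outlines from step 01, writes ``results/measurements.csv``
(one row per seed) and prints the per-population mean (CV%) of aspect ratio
and solidity — the two descriptors that drive the preliminary ordering.
"""

import pandas as pd

from seedmorph.contours import read_tps
from seedmorph.descriptors import measure, population_summary

from common import POPULATIONS, RESULTS, tps_path


def main() -> None:
    rows = []
    print(f"{'population':16s} {'AR mean (CV%)':>16s} {'S mean (CV%)':>16s}")
    for label in sorted(POPULATIONS):
        ms = [measure(c) for c in read_tps(tps_path(label))]
        for m in ms:
            rows.append({"population": label, "seed_id": m.source_id, **m.as_dict()})
        s = population_summary(ms)
        print(f"{label:16s} {s['aspect_ratio']['mean']:8.3f} ({s['aspect_ratio']['cv']:4.1f}) "
              f"{s['solidity']['mean']:9.1f} ({s['solidity']['cv']:4.1f})")
    out = RESULTS / "measurements.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6f")
    print(f"\n{len(rows)} seeds -> {out}")


if __name__ == "__main__":
    main()
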