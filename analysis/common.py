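"""Shared configuration for the numbered analysis scripts.

The analysis runs on synthetic populations that mirror the study design:
two reference populations per model (the Heben-type model averages two
harvests of the same morphotype, the Chenin-type model two related
cultivars) plus one 25-seed test population per morphotype. Everything is
generated from RNG_SEED, so the whole analysis is reproducible end to end.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
SYNTH = RESULTS / "synthetic"

RNG_SEED = 20240

POPULATIONS = {
    "heben_2020": ("heben_like", 30),
    "heben_2024": ("heben_like", 20),
    "chenin": ("chenin_like", 20),
    "gewurztraminer": ("chenin_like", 20),
    "heben_test": ("heben_like", 25),
    "chenin_test": ("chenin_like", 25),
    "sylvestris_test": ("sylvestris_like", 25),
}
MODELS = {"heben": ["heben_2020", "heben_2024"], "chenin": ["chenin", "gewurztraminer"]}
TEST_POPULATIONS = ["heben_test", "chenin_test", "sylvestris_test"]

COEFF_NAMES = [f"{c}{k}" for c in "ABCD" for k in range(1, 9)]


def tps_path(label: str) -> Path:
    return SYNTH / f"{label}.tps"
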