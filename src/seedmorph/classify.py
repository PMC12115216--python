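"""Cultivar ordering (aspect-ratio split + descending solidity) and the
four-group J-index classification.

Groups, using J against the two reference models (Heben-type, Chenin-type):

    G1  : J < 90 with both models (wild-type / non-vinifera signature)
    G2  : J(Heben) > 94
    G3  : J(Chenin) > 94
    G4a : remainder, J(Heben) >= J(Chenin)
    G4b : remainder, J(Chenin) > J(Heben)

Boundary semantics: both "lower than 90" and "higher than 94" are strict, so
values in [90, 94] with neither model above 94 fall to Group 4. If both J
values exceed 94 the larger one wins (G2 on ties) — recorded in output
metadata since no observed case fixes this rule.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GroupAssignment", "split_by_aspect_ratio", "order_by_solidity", "assign_group",
           "J_LOW", "J_HIGH", "AR_BOUNDARY"]

J_LOW = 90.0    # below this with both models -> Group 1
J_HIGH = 94.0   # above this with a model -> that model's group
AR_BOUNDARY = 1.575  # rounds to the 1.58-2.40 high-AR band at 2 decimals


@dataclass
class GroupAssignment:
    label: str  # G1 | G2 | G3 | G4a | G4b
    j_heben: float
    j_chenin: float
    rank: int | None = None
    ar_class: str | None = None  # "high" | "low"


def split_by_aspect_ratio(cultivar_ars: dict[str, float], boundary: float = AR_BOUNDARY) -> dict[str, str]:
    """Classify each cultivar as high- or low-aspect-ratio.

    AR is rounded to 2 decimals first, matching how the reported band
    endpoints (1.57 vs 1.58) separate the classes.
    """
    out = {}
    for name, ar in cultivar_ars.items():
        out[name] = "high" if round(ar, 2) >= boundary else "low"
    return out


def order_by_solidity(cultivars: dict[str, tuple[str, float]]) -> dict[str, int]:
    """Rank cultivars: the high-AR block first, each block by descending solidity.

    ``cultivars`` maps name -> (ar_class, solidity). Ties break
    alphabetically by name so the ordering is deterministic.
    """
    def block(ar_class: str) -> list[str]:
        members = [n for n, (cls, _) in cultivars.items() if cls == ar_class]
        return sorted(members, key=lambda n: (-cultivars[n][1], n))

    ordered = block("high") + block("low")
    return {name: i + 1 for i, name in enumerate(ordered)}


def assign_group(j_heben: float, j_chenin: float, *, j_low: float = J_LOW, j_high: float = J_HIGH) -> str:
    """Four-group label from the two J-index values (precedence G1, G2, G3, G4)."""
    for j in (j_heben, j_chenin):
        if not 0.0 <= j <= 100.0:
            raise ValueError(f"J-index out of range [0, 100]: {j}")
    if j_heben < j_low and j_chenin < j_low:
        return "G1"
    if j_heben > j_high and j_chenin > j_high:
        return "G2" if j_heben >= j_chenin else "G3"
    if j_heben > j_high:
        return "G2"
    if j_chenin > j_high:
        return "G3"
    return "G4a" if j_heben >= j_chenin else "G4b"


def classify(j_heben: float, j_chenin: float, *, ar: float | None = None, **kw) -> GroupAssignment:
    label = assign_group(j_heben, j_chenin, **kw)
    ar_class = None if ar is None else split_by_aspect_ratio({"_": ar})["_"]
    return GroupAssignment(label=label, j_heben=j_heben, j_chenin=j_chenin, ar_class=ar_class)
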