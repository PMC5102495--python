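"""IMGT unique numbering of the heavy-chain variable domain.

The variable domain is numbered 1-128 with fixed region boundaries
(FR1H 1-26, CDR1H 27-38, FR2H 39-55, CDR2H 56-65, FR3H 66-104,
CDR3H 105-117, FR4H 118-128).  Not every position is occupied in every
species: in cattle no amino acid is assigned to positions 10, 31-34,
60-62 and 73, so CDR1H covers 8 of its 12 positions and CDR2H 7 of 10.

CDR3H loops longer than the 13 base positions 105-117 receive extended
labels 111.1..111.x and 112.y..112.1 inserted at the loop apex; loops
shorter than 13 drop positions from the middle outward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
__all__ = [
    "PositionLabel",
    "RegionScheme",
    "REGIONS",
    "cattle_scheme",
    "extend_cdr3_labels",
    "cdr3_group",
]

REGIONS = ("FR1H", "CDR1H", "FR2H", "CDR2H", "FR3H", "CDR3H", "FR4H")

#: conserved anchor residues of the V domain: position -> one-letter amino acid
ANCHORS = {23: "C", 41: "W", 89: "L", 104: "C"}


@dataclass(frozen=True)
class PositionLabel:
    """One IMGT position, possibly an extended CDR3H label (e.g. 111.2)."""

    base: int
    sub: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.base <= 128:
            raise ValueError(f"IMGT position {self.base} outside 1-128")
        if self.sub is not None and self.base not in (111, 112):
            raise ValueError("extended labels exist only at 111.x / 112.y")
        if self.sub is not None and self.sub < 1:
            raise ValueError("sub-position must be a positive integer")

    def sort_key(self) -> tuple[int, int, int]:
        # 111 < 111.1 < ... < 111.x < 112.y < ... < 112.1 < 112
        if self.sub is None:
            return (self.base, 0, 0)
        if self.base == 111:
            return (111, 1, self.sub)
        return (111, 2, -self.sub)

    def __lt__(self, other: "PositionLabel") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return str(self.base) if self.sub is None else f"{self.base}.{self.sub}"

    @classmethod
    def parse(cls, text: str) -> "PositionLabel":
        if "." in text:
            base, sub = text.split(".", 1)
            return cls(int(base), int(sub))
        return cls(int(text))


@dataclass(frozen=True)
class RegionScheme:
    """Region boundaries plus the species' unoccupied positions."""

    region_bounds: dict[str, tuple[int, int]]
    missing_positions: frozenset[int]
    species_label: str = "unnamed"

    def __post_init__(self) -> None:
        spans = [self.region_bounds[r] for r in REGIONS]
        if spans[0][0] != 1 or spans[-1][1] != 128:
            raise ValueError("region bounds must cover 1-128")
        for (_, hi), (lo2, _) in zip(spans, spans[1:]):
            if lo2 != hi + 1:
                raise ValueError("region bounds must be contiguous")
        for p in self.missing_positions:
            if self.region_of(p) in ("CDR3H", "FR4H"):
                raise ValueError("missing positions may not fall in CDR3H/FR4H")

    def region_of(self, label: PositionLabel | int) -> str:
        base = label.base if isinstance(label, PositionLabel) else int(label)
        for name in REGIONS:
            lo, hi = self.region_bounds[name]
            if lo <= base <= hi:
                return name
        raise ValueError(f"position {base} outside 1-128")

    def occupied_positions(self, region: str) -> list[int]:
        """Ascending occupied (non-missing) base positions of a region."""
        lo, hi = self.region_bounds[region]
        return [p for p in range(lo, hi + 1) if p not in self.missing_positions]

    def v_positions(self) -> list[int]:
        """Occupied positions of the V segment proper (1..104, FR1H-FR3H)."""
        out: list[int] = []
        for region in ("FR1H", "CDR1H", "FR2H", "CDR2H", "FR3H"):
            out.extend(self.occupied_positions(region))
        return out

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "species_label": self.species_label,
                "region_bounds": {k: list(v) for k, v in self.region_bounds.items()},
                "missing_positions": sorted(self.missing_positions),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RegionScheme":
        obj = json.loads(text)
        return cls(
            region_bounds={k: tuple(v) for k, v in obj["region_bounds"].items()},
            missing_positions=frozenset(obj["missing_positions"]),
            species_label=obj.get("species_label", "unnamed"),
        )


def cattle_scheme() -> RegionScheme:
    """The bundled cattle scheme (positions 10, 31-34, 60-62, 73 unoccupied)."""
    text = resources.files("bovig.data").joinpath("cattle_scheme.json").read_text()
    return RegionScheme.from_json(text)


def extend_cdr3_labels(length: int) -> list[PositionLabel]:
    """Position labels for a CDR3H of ``length`` amino acids.

    Lengths up to 13 use a subset of 105-117 filled from both ends inward
    (the 3'-side position is dropped last); longer loops insert extended
    labels at the apex, the odd extra position going to the 112.* side.
    """
    if length < 1:
        raise ValueError("CDR3H length must be >= 1")
    if length <= 13:
        n_left = length // 2
        n_right = length - n_left
        left = [PositionLabel(p) for p in range(105, 105 + n_left)]
        right = [PositionLabel(p) for p in range(118 - n_right, 118)]
        return left + right
    extras = length - 13
    n111 = extras // 2
    n112 = extras - n111
    labels = [PositionLabel(p) for p in range(105, 112)]
    labels += [PositionLabel(111, s) for s in range(1, n111 + 1)]
    labels += [PositionLabel(112, s) for s in range(n112, 0, -1)]
    labels += [PositionLabel(p) for p in range(112, 118)]
    return labels


def cdr3_group(length: int) -> int:
    """Length class: 1 (<=10 aa), 2 (11-47 aa) or 3 (>=48 aa)."""
    if length < 1:
        raise ValueError("CDR3H length must be >= 1")
    if length <= 10:
        return 1
    if length <= 47:
        return 2
    return 3
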