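"""Compound registry for aliphatic glucosinolates.

The seven seed chemotypes of *Arabidopsis thaliana* are defined over nine
canonical short-chain (C3/C4) aliphatic glucosinolates.  Side-chain class
determines which enzyme product a compound reports on:

* ``MT`` (methylthio) -- core-pathway product, upstream of *GS-AOP*;
* ``MSO`` (methylsulfinyl) -- accumulates when both AOP enzymes are inactive;
* ``alkenyl`` -- AOP2 product (Allyl, 3-Butenyl);
* ``hydroxyalkyl`` -- AOP3 product (3OHP, 4OHB);
* ``OH-alkenyl`` -- GS-OH product (2-OH-3-Butenyl).

Chain length (3 or 4 carbons) reports on the *GS-Elong* (MAM) locus:
MAM2 produces C3, MAM1 produces C4 glucosinolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SIDE_CLASSES = ("MT", "MSO", "hydroxyalkyl", "alkenyl", "OH-alkenyl", "other")

#: (chain_length, side_class) for the nine canonical short-chain aliphatics.
CANONICAL_SHORT_CHAIN: dict[str, tuple[int, str]] = {
    "3MT": (3, "MT"),
    "3MSO": (3, "MSO"),
    "3OHP": (3, "hydroxyalkyl"),
    "Allyl": (3, "alkenyl"),
    "4MT": (4, "MT"),
    "4MSO": (4, "MSO"),
    "4OHB": (4, "hydroxyalkyl"),
    "3-Butenyl": (4, "alkenyl"),
    "2-OH-3-Butenyl": (4, "OH-alkenyl"),
}

C3_COMPOUNDS = tuple(c for c, (n, _) in CANONICAL_SHORT_CHAIN.items() if n == 3)
C4_COMPOUNDS = tuple(c for c, (n, _) in CANONICAL_SHORT_CHAIN.items() if n == 4)

ALKENYL_COMPOUNDS = ("Allyl", "2-OH-3-Butenyl", "3-Butenyl")
ALKYL_COMPOUNDS = ("3OHP", "4OHB")
MSO_COMPOUNDS = ("3MSO", "4MSO")


@dataclass(frozen=True)
class CompoundInfo:
    name: str
    chain_length: int
    side_class: str
    is_short_chain_aliphatic: bool

    def __post_init__(self) -> None:
        if self.side_class not in SIDE_CLASSES:
            raise ValueError(
                f"unknown side class {self.side_class!r} for {self.name!r}"
            )


@dataclass
class CompoundRegistry:
    """Lookup table mapping compound names to chain length and side class."""

    compounds: dict[str, CompoundInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_SHORT_CHAIN if c not in self.compounds]
        if missing:
            raise ValueError(
                "registry is missing canonical short-chain compounds: "
                + ", ".join(missing)
            )
        for name, (length, side) in CANONICAL_SHORT_CHAIN.items():
            info = self.compounds[name]
            if (info.chain_length, info.side_class) != (length, side) or (
                not info.is_short_chain_aliphatic
            ):
                raise ValueError(
                    f"canonical compound {name!r} misclassified: "
                    f"expected C{length} {side} short-chain aliphatic"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.compounds

    def __getitem__(self, name: str) -> CompoundInfo:
        return self.compounds[name]

    @property
    def names(self) -> list[str]:
        return list(self.compounds)

    @property
    def short_chain(self) -> list[str]:
        return [
            c for c, info in self.compounds.items() if info.is_short_chain_aliphatic
        ]

    def add(self, info: CompoundInfo) -> None:
        self.compounds[info.name] = info

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound": info.name,
                    "chain_length": info.chain_length,
                    "side_class": info.side_class,
                    "is_short_chain_aliphatic": info.is_short_chain_aliphatic,
                }
                for info in self.compounds.values()
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CompoundRegistry":
        required = {"compound", "chain_length", "side_class", "is_short_chain_aliphatic"}
        if not required.issubset(frame.columns):
            raise ValueError(f"registry table needs columns {sorted(required)}")
        compounds = {}
        for row in frame.itertuples(index=False):
            compounds[row.compound] = CompoundInfo(
                name=row.compound,
                chain_length=int(row.chain_length),
                side_class=row.side_class,
                is_short_chain_aliphatic=bool(row.is_short_chain_aliphatic),
            )
        return cls(compounds)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CompoundRegistry":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


#: Filler compounds used to pad simulated profiles to the 23 compounds a
#: seed HPLC-DAD run typically detects: long-chain aliphatic, indolic and
#: benzenic glucosinolates that play no role in short-chain chemotyping.
DEFAULT_FILLER_COMPOUNDS: dict[str, tuple[int, str]] = {
    "5MSO": (5, "other"),
    "6MSO": (6, "other"),
    "7MSO": (7, "other"),
    "8MSO": (8, "other"),
    "6MT": (6, "other"),
    "7MT": (7, "other"),
    "8MT": (8, "other"),
    "I3M": (0, "other"),
    "4OH-I3M": (0, "other"),
    "4MO-I3M": (0, "other"),
    "1MO-I3M": (0, "other"),
    "2-Phenylethyl": (0, "other"),
    "3-Benzoyloxypropyl": (3, "other"),
    "4-Benzoyloxybutyl": (4, "other"),
}


def default_registry(include_fillers: bool = False) -> CompoundRegistry:
    """Registry of the nine canonical compounds, optionally padded to 23."""
    compounds = {
        name: CompoundInfo(name, length, side, True)
        for name, (length, side) in CANONICAL_SHORT_CHAIN.items()
    }
    if include_fillers:
        for name, (length, side) in DEFAULT_FILLER_COMPOUNDS.items():
            compounds[name] = CompoundInfo(name, length, side, False)
    return CompoundRegistry(compounds)


def as_profile(amounts: Mapping[str, float] | pd.Series) -> dict[str, float]:
    """Normalize a per-compound amount mapping to a plain dict of floats."""
    if isinstance(amounts, pd.Series):
        amounts = amounts.to_dict()
    return {str(k): float(v) for k, v in amounts.items()}


def total(profile: Mapping[str, float], compounds: Iterable[str]) -> float:
    """Sum of ``profile`` over ``compounds``; absent compounds count as zero."""
    return float(sum(profile.get(c, 0.0) for c in compounds))
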