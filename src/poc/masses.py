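"""Molecular-formula masses and adduct m/z for conjugate characterization.

Monoisotopic masses use the most-abundant-isotope masses and average masses
the standard atomic weights, both pinned below from the NIST Atomic Weights
and Isotopic Compositions compilation (CODATA-adjusted, AME2020 values,
https://physics.nist.gov/Comp).  Ion species masses account for the electron
(proton = 1.007276 Da).

The printed "calc." values for the two catalytic peptides are monoisotopic
sums; see the methods note for the conjugate-mass caveat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "FormulaParseError",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "adduct_mz",
    "parse_adduct",
    "PROTON_MASS",
]

# Da; most abundant isotope (NIST AME2020)
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Li": 7.01600455,
    "F": 18.99840322,
    "Cl": 34.96885268,
}

# Da; standard atomic weights (IUPAC 2021)
AVERAGE = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
    "S": 32.06,
    "Na": 22.98976928,
    "K": 39.0983,
    "Li": 6.94,
    "F": 18.998403163,
    "Cl": 35.45,
}

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = 1.007276          # Da (H minus electron)

# cation masses (neutral atom minus one electron), Da
ION_SPECIES = {
    "H": PROTON_MASS,
    "Na": MONOISOTOPIC["Na"] - ELECTRON_MASS,
    "K": MONOISOTOPIC["K"] - ELECTRON_MASS,
    "Li": MONOISOTOPIC["Li"] - ELECTRON_MASS,
}


class FormulaParseError(ValueError):
    """Text does not match the element-count grammar."""


@dataclass(frozen=True)
class MolecularFormula:
    element_counts: tuple[tuple[str, int], ...]

    def __post_init__(self):
        for el, n in self.element_counts:
            if el not in MONOISOTOPIC:
                raise FormulaParseError(f"element {el!r} not in the pinned mass table")
            if n < 0:
                raise FormulaParseError(f"negative count for {el}")

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        return cls(tuple(sorted(counts.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for el, n in other.element_counts:
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula.from_counts(merged)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical
        counts = self.as_dict()
        parts = []
        for el in ["C", "H"] + sorted(set(counts) - {"C", "H"}):
            if counts.get(el):
                n = counts[el]
                parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse e.g. ``C52H99N21O11``.

    Underscores and brackets from typeset notation ("[C_52_H_99_...]") are
    tolerated and stripped.  Unknown element symbols are rejected.
    """
    clean = re.sub(r"[\[\]_\s]", "", text)
    if not clean:
        raise FormulaParseError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(clean):
        m = _TOKEN.match(clean, pos)
        if not m or m.group(1) not in MONOISOTOPIC:
            raise FormulaParseError(f"cannot parse formula {text!r} at {clean[pos:]!r}")
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return MolecularFormula.from_counts(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Σ count × most-abundant-isotope mass (Da)."""
    return sum(n * MONOISOTOPIC[el] for el, n in f.element_counts)


def average_mass(f: MolecularFormula) -> float:
    """Σ count × standard atomic weight (Da)."""
    return sum(n * AVERAGE[el] for el, n in f.element_counts)


@dataclass(frozen=True)
class AdductSpec:
    """Charged adduct, e.g. [M+2H]²⁺ = AdductSpec((("H", 2),), charge=2)."""

    added_species: tuple[tuple[str, int], ...]
    charge: int

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        for sp, n in self.added_species:
            if sp not in ION_SPECIES:
                raise ValueError(f"unknown ion species {sp!r}")
            if n < 1:
                raise ValueError(f"species count must be positive ({sp})")


def parse_adduct(text: str, charge: int | None = None) -> AdductSpec:
    """Parse adduct notation like ``M+2H``, ``M+H+Na`` or ``[M+K]+``.

    If ``charge`` is omitted it defaults to the total count of added
    cations.
    """
    clean = text.strip().strip("[]").replace(" ", "")
    parts = clean.split("+")
    if parts[0].upper() != "M":
        raise ValueError(f"adduct must start with M: {text!r}")
    counts: dict[str, int] = {}
    for p in parts[1:]:
        if not p:
            continue
        m = re.fullmatch(r"(\d*)([A-Z][a-z]?)", p)
        if not m or m.group(2) not in ION_SPECIES:
            raise ValueError(f"cannot parse adduct component {p!r}")
        n = int(m.group(1)) if m.group(1) else 1
        counts[m.group(2)] = counts.get(m.group(2), 0) + n
    if not counts:
        raise ValueError(f"adduct {text!r} adds no species")
    total = sum(counts.values())
    return AdductSpec(tuple(sorted(counts.items())), charge if charge is not None else total)


def adduct_mz(mass: float, adduct: AdductSpec) -> float:
    """m/z of the adduct ion: (M + Σ added cation masses) / charge."""
    added = sum(n * ION_SPECIES[sp] for sp, n in adduct.added_species)
    return (mass + added) / adduct.charge
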