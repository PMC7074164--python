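"""Molecular formulas and exact-mass arithmetic.

All high-resolution mass reasoning in the package runs through this module:
Hill-notation parsing, monoisotopic masses from the packaged IUPAC isotope
table, ion m/z under either electron-mass convention, and ppm errors.

Two m/z conventions coexist in the metabolomics literature and both are
exposed here.  The physically correct m/z of a +z cation subtracts z electron
masses from the atomic sum (``MassConvention.ELECTRON_CORRECTED``); many
published "calcd." values are plain atomic-mass sums
(``MassConvention.ATOMIC_SUM``).  The pipeline default is electron-corrected;
nothing in this module guesses which one an external number used.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ELECTRON_MASS",
    "Element",
    "Formula",
    "FormulaError",
    "MassConvention",
    "element_table",
    "ion_mz",
    "monoisotopic_mass",
    "parse_formula",
    "ppm_error",
]

#: CODATA electron mass in Da.
ELECTRON_MASS = 0.000548579909


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


@dataclass(frozen=True)
class Element:
    """One element: stable isotopes as (mass Da, natural abundance) pairs.

    Isotopes are sorted by mass; the monoisotopic mass is the lightest
    isotope's, which for every element used here is also the most abundant.
    """

    symbol: str
    isotopes: Tuple[Tuple[float, float], ...]

    @property
    def monoisotopic_mass(self) -> float:
        return self.isotopes[0][0]


def _load_elements() -> Dict[str, Element]:
    raw: Dict[str, list] = {}
    path = resources.files("ahlscreen.data").joinpath("elements.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        for rec in csv.DictReader(rows):
            raw.setdefault(rec["symbol"], []).append(
                (float(rec["mass"]), float(rec["abundance"]))
            )
    return {
        sym: Element(sym, tuple(sorted(iso)))  # sort by mass ascending
        for sym, iso in raw.items()
    }


_ELEMENTS: Dict[str, Element] = _load_elements()


def element_table() -> Mapping[str, Element]:
    """The packaged element/isotope table (symbol -> :class:`Element`)."""
    return _ELEMENTS


class MassConvention(Enum):
    """How ion m/z relates to the atomic mass sum of the ion's formula."""

    #: subtract one electron mass per positive charge (physically correct)
    ELECTRON_CORRECTED = "electron_corrected"
    #: plain atomic-mass sum, no electron correction
    ATOMIC_SUM = "atomic_sum"


@dataclass(frozen=True)
class Formula:
    """An elemental composition: element symbol -> non-negative count.

    Instances are immutable and hashable; addition merges counts element-wise,
    so fragment bookkeeping (e.g. lactone + acylium = precursor ion) is plain
    arithmetic on formulas.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for sym, n in self.counts.items():
            if sym not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {sym} must be a non-negative int, got {n!r}")
            if n:
                clean[sym] = n
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self.counts == other.counts

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Hill notation: C, then H, then other elements alphabetically."""
        order = [s for s in ("C", "H") if s in self.counts]
        order += sorted(s for s in self.counts if s not in ("C", "H"))
        return "".join(f"{s}{self.counts[s] if self.counts[s] > 1 else ''}" for s in order)

    def __str__(self) -> str:
        return self.hill()


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string such as ``"C9H13BrNO"``.

    Implicit counts are 1; trailing charge tokens (``+``) are ignored so the
    cation formulas printed in the literature parse directly.
    """
    body = text.strip().rstrip("+")
    if not body:
        raise FormulaError("empty formula string")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN.match(body, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol: {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Monoisotopic (lightest-isotope) mass of a formula in Da."""
    return sum(n * _ELEMENTS[sym].monoisotopic_mass for sym, n in f.counts.items())


def ion_mz(
    f: Formula,
    z: int = 1,
    convention: MassConvention = MassConvention.ELECTRON_CORRECTED,
) -> float:
    """m/z of a +z cation whose atoms are exactly ``f``.

    Under ``ELECTRON_CORRECTED`` the z missing electrons are subtracted;
    under ``ATOMIC_SUM`` the value is the plain monoisotopic sum divided by z.
    """
    if not isinstance(z, int) or z < 1:
        raise ValueError(f"charge must be a positive integer, got {z!r}")
    mass = monoisotopic_mass(f)
    if convention is MassConvention.ELECTRON_CORRECTED:
        mass -= z * ELECTRON_MASS
    return mass / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical!r}")
    return 1e6 * (observed - theoretical) / theoretical
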