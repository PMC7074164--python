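"""The AHL congener space: naming, formulas, fragments, candidate grids.

An N-acyl homoserine lactone (AHL) is the homoserine-lactone head amide-linked
to a fatty acyl chain of n carbons, optionally carrying one chain C=C
unsaturation (u=1, the ":1" suffix) and one of three C3 oxidation states:
plain (Cn-AHL), 3-oxo (OCn-AHL) or 3-hydroxy (OHCn-AHL).  Collision-induced
spectra of every AHL share the deacylated lactone product ion C4H8NO2+ at
m/z 102.0550, with a complementary acylium fragment that reports chain length
and oxidation state; those two fragments plus the [M+H]+ exact mass are the
screen's evidence.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .formula import Formula, MassConvention, ion_mz, ppm_error

__all__ = [
    "AHLSpec",
    "Candidate",
    "StandardEntry",
    "SUBSTITUTIONS",
    "STANDARD_NAMES",
    "acyl_fragment_mz",
    "default_standards",
    "fragment_formulas",
    "generate_candidate_space",
    "ion_formula",
    "lactone_fragment_mz",
    "LACTONE_FRAGMENT",
    "load_standards",
    "match_candidates",
    "neutral_formula",
    "precursor_mz",
]

SUBSTITUTIONS: Tuple[str, ...] = ("plain", "3-oxo", "3-hydroxy")

_PREFIX = {"plain": "", "3-oxo": "O", "3-hydroxy": "OH"}
_PREFIX_INV = {v: k for k, v in _PREFIX.items()}
_NAME_RE = re.compile(r"^(OH|O)?C(\d+)(:1)?-AHL$")

#: Deacylated homoserine lactone cation, the diagnostic product ion.
LACTONE_FRAGMENT = Formula({"C": 4, "H": 8, "N": 1, "O": 2})


@dataclass(frozen=True, order=True)
class AHLSpec:
    """One AHL congener: chain length, unsaturation count, C3 substitution.

    The oxo/hydroxy position is a class label only — the source data never
    assigns a locant.
    """

    n: int
    u: int = 0
    subst: str = "plain"

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"acyl chain needs >=4 carbons, got n={self.n}")
        if self.u not in (0, 1):
            raise ValueError(f"unsaturation count must be 0 or 1, got {self.u}")
        if self.subst not in SUBSTITUTIONS:
            raise ValueError(f"unknown substitution class {self.subst!r}")

    @property
    def name(self) -> str:
        return f"{_PREFIX[self.subst]}C{self.n}{':1' if self.u else ''}-AHL"

    @classmethod
    def from_name(cls, name: str) -> "AHLSpec":
        m = _NAME_RE.match(name.strip())
        if m is None:
            raise ValueError(f"not a valid AHL name: {name!r}")
        prefix = m.group(1) or ""
        return cls(n=int(m.group(2)), u=1 if m.group(3) else 0, subst=_PREFIX_INV[prefix])

    @property
    def oxygenated(self) -> bool:
        return self.subst != "plain"


def neutral_formula(s: AHLSpec) -> Formula:
    """Neutral molecular formula of the congener.

    plain      C(n+4) H(2n+5-2u) N O3
    3-oxo      C(n+4) H(2n+3-2u) N O4
    3-hydroxy  C(n+4) H(2n+5-2u) N O4
    """
    h = {"plain": 2 * s.n + 5, "3-oxo": 2 * s.n + 3, "3-hydroxy": 2 * s.n + 5}[s.subst] - 2 * s.u
    o = 3 if s.subst == "plain" else 4
    return Formula({"C": s.n + 4, "H": h, "N": 1, "O": o})


def ion_formula(s: AHLSpec) -> Formula:
    """Atoms of the [M+H]+ pseudomolecular cation."""
    return neutral_formula(s) + Formula({"H": 1})


def precursor_mz(s: AHLSpec, convention: MassConvention = MassConvention.ELECTRON_CORRECTED) -> float:
    """[M+H]+ m/z of the congener (charge +1)."""
    return ion_mz(ion_formula(s), 1, convention)


def fragment_formulas(s: AHLSpec) -> Dict[str, Formula]:
    """The two diagnostic fragments of the [M+H]+ ion.

    The lactone cation is C4H8NO2+ for every congener; the acylium carries the
    chain: CnH(2n-1-2u)O+ (plain), CnH(2n-3-2u)O2+ (3-oxo),
    CnH(2n-1-2u)O2+ (3-hydroxy).  Each fragment cation pairs with a neutral
    loss, so lactone + acylium atoms equal the [M+H]+ ion's atoms plus one H.
    """
    h = {"plain": 2 * s.n - 1, "3-oxo": 2 * s.n - 3, "3-hydroxy": 2 * s.n - 1}[s.subst] - 2 * s.u
    o = 1 if s.subst == "plain" else 2
    return {"lactone": LACTONE_FRAGMENT, "acyl": Formula({"C": s.n, "H": h, "O": o})}


def lactone_fragment_mz(convention: MassConvention = MassConvention.ELECTRON_CORRECTED) -> float:
    return ion_mz(LACTONE_FRAGMENT, 1, convention)


def acyl_fragment_mz(s: AHLSpec, convention: MassConvention = MassConvention.ELECTRON_CORRECTED) -> float:
    return ion_mz(fragment_formulas(s)["acyl"], 1, convention)


@dataclass(frozen=True)
class Candidate:
    """A grid entry: congener, its theoretical [M+H]+ m/z, isomer group id.

    Candidates sharing an ion formula (e.g. OCn and OHCn:1) share a group id;
    exact mass alone cannot tell them apart.
    """

    spec: AHLSpec
    mz: float
    isomer_group: int


def generate_candidate_space(
    n_min: int = 4,
    n_max: int = 20,
    allow_unsat: bool = True,
    substitutions: Sequence[str] = SUBSTITUTIONS,
) -> List[Candidate]:
    """Enumerate the AHL search grid, sorted by [M+H]+ m/z.

    Cardinality is (n_max-n_min+1) x |substitutions| x (2 if allow_unsat).
    """
    if n_min < 4:
        raise ValueError(f"n_min must be >= 4, got {n_min}")
    if n_min > n_max:
        raise ValueError(f"n_min={n_min} > n_max={n_max}")
    specs = [
        AHLSpec(n, u, subst)
        for n in range(n_min, n_max + 1)
        for subst in substitutions
        for u in ((0, 1) if allow_unsat else (0,))
    ]
    specs.sort(key=lambda s: (precursor_mz(s), s.name))
    groups: Dict[str, int] = {}
    out: List[Candidate] = []
    for s in specs:
        key = ion_formula(s).hill()
        gid = groups.setdefault(key, len(groups))
        out.append(Candidate(s, precursor_mz(s), gid))
    return out


def match_candidates(grid: Sequence[Candidate], mz: float, tol_ppm: float) -> List[Candidate]:
    """Grid entries whose theoretical m/z lies within tol_ppm of ``mz``."""
    return [c for c in grid if abs(ppm_error(mz, c.mz)) <= tol_ppm]


# --- synthetic-standards reference table -----------------------------------

#: The 21 commercially available AHL standards run alongside the samples.
STANDARD_NAMES: Tuple[str, ...] = (
    "C4-AHL", "C6-AHL", "OC6-AHL", "C8-AHL", "OC8-AHL", "OHC8-AHL",
    "C10-AHL", "OC10-AHL", "OHC10-AHL", "C12-AHL", "OC12-AHL", "OHC12-AHL",
    "C14-AHL", "OC14-AHL", "OHC14-AHL", "C16-AHL", "OC16-AHL", "OHC16-AHL",
    "C18-AHL", "OC18-AHL", "OHC18-AHL",
)


@dataclass(frozen=True)
class StandardEntry:
    """Reference data for one synthetic AHL standard."""

    spec: AHLSpec
    reference_rt_min: float
    #: optional reference MS/MS peak list [(m/z, relative intensity), ...]
    reference_msms: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.reference_rt_min <= 0:
            raise ValueError("reference RT must be positive")


def load_standards(path: "Path | str") -> List[StandardEntry]:
    """Read a standards table CSV (name, chain_length, unsat, subst, reference_rt_min)."""
    entries: List[StandardEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        for rec in csv.DictReader(rows):
            spec = AHLSpec(int(rec["chain_length"]), int(rec["unsat"]), rec["subst"])
            if "name" in rec and rec["name"] and spec.name != rec["name"]:
                raise ValueError(f"standards row name {rec['name']!r} does not match fields -> {spec.name}")
            entries.append(StandardEntry(spec, float(rec["reference_rt_min"])))
    return entries


def default_standards() -> List[StandardEntry]:
    """The packaged reference table for the 21 synthetic standards.

    Reference RTs come from the published study tables where the congener was
    reported there; the remaining rows are SYNTHETIC values predicted by the
    package's retention-time model (flagged in the CSV), not measured data.
    """
    path = resources.files("ahlscreen.data").joinpath("standards_reference_rt.csv")
    with resources.as_file(path) as p:
        return load_standards(p)
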