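"""Published AHL screening tables for *Sarcotragus spinosulus*.

These are the printed identification tables from the sponge study the package
emulates: experimental [M+H]+ values, retention times (min) and per-sample
presence marks for the crude extracts (specimens 454-460), the microbial
cell fractions (SCS-B..F) and the chromatographic fractions (S1-S6).
They serve two roles: ground truth for the synthetic-run fixtures, and the
anchor set for the retention-time model.

Presence marks: ``"x"`` = detected, ``"L"`` = detected in low amount.

The OC12-AHL row of the cell-fraction table prints m/z 298.0009, ~670 ppm away
from any C16 AHL ion (theory ~298.2013); it is carried here verbatim but
flagged ``suspect_mz`` and excluded from fixtures and numeric assertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

__all__ = ["TableRow", "TABLES", "SAMPLES", "rt_anchors", "presence"]


@dataclass(frozen=True)
class TableRow:
    name: str
    mz_exp: float          # printed experimental [M+H]+
    rt_min: float          # printed retention time, minutes
    marks: Mapping[str, str]   # sample label -> "x" | "L"
    fraction_only: bool = False    # bold in the cell-fraction table
    suspect_mz: bool = False


SAMPLES: Dict[int, Tuple[str, ...]] = {
    1: ("454", "455", "456", "457", "460"),
    2: ("SCS-B", "SCS-C", "SCS-D", "SCS-E", "SCS-F"),
    3: ("S1", "S2", "S3", "S4", "S5", "S6"),
}

TABLES: Dict[int, Tuple[TableRow, ...]] = {
    # Crude extracts of the five sponge specimens.
    1: (
        TableRow("OHC6:1-AHL", 214.1073, 1.73, {"455": "x"}),
        TableRow("C6-AHL", 200.1280, 11.86, {"457": "x"}),
        TableRow("C8-AHL", 228.1593, 15.39, {"454": "x"}),
        TableRow("C10:1-AHL", 254.1749, 15.89, {"455": "x", "457": "x", "460": "x"}),
        TableRow("OC10-AHL", 270.1697, 17.46, {"457": "x"}),
        TableRow("C12-AHL", 284.2217, 24.18, {"460": "x"}),
        TableRow("C14-AHL", 312.2527, 27.63, {"460": "x"}),
        TableRow("OHC14-AHL", 328.2479, 23.58, {"457": "x"}),
        TableRow("OHC16-AHL", 356.2794, 25.18, {"457": "x"}),
        TableRow("OHC18-AHL", 384.3102, 30.25, {"460": "x"}),
        TableRow("OC16-AHL", 354.2635, 25.22, {"457": "x"}),
    ),
    # Microbial-enriched cell fractions; bold rows were fraction-only finds.
    2: (
        TableRow("C10:1-AHL", 254.1749, 15.89, {"SCS-B": "x", "SCS-C": "x", "SCS-D": "x"}, fraction_only=True),
        TableRow("C6-AHL", 200.1280, 11.86, {"SCS-C": "x"}, fraction_only=True),
        TableRow("C8:1-AHL", 226.1437, 11.16, {"SCS-B": "x", "SCS-C": "x"}),
        TableRow("C8-AHL", 228.1593, 15.39, {"SCS-C": "x"}, fraction_only=True),
        TableRow("OC14-AHL", 326.2320, 24.96, {"SCS-B": "x", "SCS-C": "x"}),
        TableRow("OHC10-AHL", 272.1853, 16.17, {"SCS-C": "x"}),
        TableRow("OHC12-AHL", 300.2168, 20.08, {"SCS-C": "x"}),
        TableRow("OHC14:1-AHL", 326.2321, 23.86, {"SCS-E": "x"}, fraction_only=True),
        TableRow("OHC14-AHL", 328.2479, 23.58, {"SCS-C": "x"}),
        TableRow("OHC16-AHL", 356.2794, 25.18, {"SCS-D": "x"}, fraction_only=True),
        TableRow("OHC18-AHL", 384.3102, 30.25, {"SCS-D": "x"}, fraction_only=True),
        TableRow("OHC6:1-AHL", 214.1073, 1.73, {"SCS-C": "x"}, fraction_only=True),
        TableRow("OHC8-AHL", 244.1544, 10.46, {"SCS-C": "x", "SCS-F": "x"}),
        TableRow("OC12-AHL", 298.0009, 21.44, {"SCS-C": "x"}, suspect_mz=True),
    ),
    # Chromatographically enriched fractions of the combined extracts.
    3: (
        TableRow("OC10-AHL", 270.1697, 17.44, {"S6": "x"}),
        TableRow("OHC14:1-AHL", 326.2321, 23.86, {"S6": "x"}),
        TableRow("C16-AHL", 340.2845, 30.71, {"S1": "L", "S2": "x", "S3": "L", "S4": "L", "S5": "L"}),
        TableRow("OC16-AHL", 354.2635, 25.22, {"S1": "L", "S2": "x", "S3": "x", "S4": "L", "S5": "L"}),
        TableRow("C18-AHL", 368.3148, 33.88, {"S1": "L", "S2": "x", "S3": "x", "S4": "L", "S5": "L"}),
        TableRow("OC18-AHL", 382.2946, 31.26, {"S1": "L", "S2": "x", "S3": "x", "S4": "L", "S5": "L"}),
        TableRow("OHC18-AHL", 384.3103, 29.95, {"S1": "L", "S2": "x", "S3": "x", "S4": "L", "S5": "L"}),
        TableRow("C18:1-AHL", 366.2998, 31.45, {"S1": "L", "S2": "x", "S3": "x", "S4": "L", "S5": "L"}),
        TableRow("C19-AHL", 382.3312, 32.83, {"S1": "L", "S2": "x", "S3": "x", "S4": "L", "S5": "L"}),
        TableRow("OC19-AHL", 396.3104, 30.20, {"S1": "L", "S2": "x", "S3": "x", "S4": "L", "S5": "L"}),
    ),
}

#: Printed within-series RT pairs that the source tables themselves invert
#: relative to homologous-series elution order (longer chain printed earlier).
PRINTED_RT_INVERSIONS = (("C18-AHL", "C19-AHL"), ("OC18-AHL", "OC19-AHL"))


def rt_anchors(exclude_n19: bool = True) -> Dict[str, float]:
    """Congener name -> printed RT (median across tables).

    The two n=19 congeners print RTs that invert homologous-series order
    against their C18 counterparts; by default they are excluded so a monotone
    RT model can be anchored on self-consistent data.  The suspect OC12 row is
    always excluded.
    """
    seen: Dict[str, list] = {}
    for rows in TABLES.values():
        for row in rows:
            if row.suspect_mz:
                continue
            if exclude_n19 and row.name in ("C19-AHL", "OC19-AHL"):
                continue
            seen.setdefault(row.name, []).append(row.rt_min)
    import statistics

    return {name: statistics.median(v) for name, v in seen.items()}


#: Census claimed by the study's summary: counts of distinct AHLs identified.
REPORTED_CENSUS = {"saturated": 18, "unsaturated": 6}


def congener_census(include_suspect: bool = True) -> Dict[str, int]:
    """Distinct saturated/unsaturated congeners across all three tables.

    The union of the tables yields a different saturated/unsaturated split
    than the study's summary census (``REPORTED_CENSUS``) under the ":1"
    naming; callers should print both rather than reconcile them.
    """
    names = {
        row.name
        for rows in TABLES.values()
        for row in rows
        if include_suspect or not row.suspect_mz
    }
    unsat = sum(1 for n in names if ":1" in n)
    return {"saturated": len(names) - unsat, "unsaturated": unsat}


def presence(which: int, include_suspect: bool = False) -> Dict[str, Dict[str, str]]:
    """Presence matrix of one table: congener name -> {sample: mark}."""
    out: Dict[str, Dict[str, str]] = {}
    for row in TABLES[which]:
        if row.suspect_mz and not include_suspect:
            continue
        out[row.name] = dict(row.marks)
    return out
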