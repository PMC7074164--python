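"""End-to-end screening: diagnostic-fragment gating, AHL annotation,
isomer resolution, bromine flagging and report compilation.

The screen follows the targeted dereplication logic of the sponge study:

1. every MS2 scan containing the deacylated-lactone product ion
   (C4H8NO2+, m/z 102.0550) within ppm tolerance nominates its precursor;
2. the precursor is matched against the theoretical AHL grid at ppm tolerance;
   presence of the congener's acylium fragment upgrades confidence, and a
   retention-time match against a synthetic standard upgrades it further;
3. exact-mass isomer groups (e.g. OCn vs OHCn:1) are ranked by retention-time
   plausibility rather than silently broken;
4. separately, MS1 envelopes with an M+2 companion at ~+1.998 Da are scored
   for bromine count and handed to an exhaustive CHNOBr composition search.

Confidence tiers: A = diagnostic + acylium + standard RT; B = diagnostic +
acylium; C = diagnostic only.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formula import (
    ELECTRON_MASS,
    Formula,
    MassConvention,
    element_table,
    ion_mz,
    ppm_error,
)
from .isotopes import IsotopePattern, halogen_count
from .library import (
    AHLSpec,
    Candidate,
    StandardEntry,
    acyl_fragment_mz,
    default_standards,
    generate_candidate_space,
    lactone_fragment_mz,
    match_candidates,
)
from .spectra import Run, Spectrum

__all__ = [
    "AHLAnnotation",
    "BrominatedCandidate",
    "ScreenConfig",
    "ScreenReport",
    "compile_report",
    "composition_search",
    "resolve_isomers",
    "screen_ahls",
    "screen_brominated",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable screen parameters (all m/z tolerances in ppm)."""

    tol_ppm: float = 5.0                 # precursor and fragment match window
    standard_rt_window: float = 0.2      # min; RT agreement with a standard
    isotope_spacing: float = 1.99795     # Da; Br M -> M+2 step
    isotope_spacing_tol: float = 0.010   # Da; companion search half-window
    min_ms1_intensity: float = 1e4       # floor for bromine-envelope seeds
    # CHNOBr composition-search bounds (natural-product plausibility window)
    max_c: int = 30
    max_h: int = 50
    max_n: int = 4
    max_o: int = 6
    max_br: int = 2
    rdbe_range: Tuple[float, float] = (0.0, 15.0)

    @classmethod
    def from_toml(cls, path: "Path | str") -> "ScreenConfig":
        doc = tomllib.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        params = {k: v for k, v in doc.get("screen", doc).items() if k in known}
        if "rdbe_range" in params:
            params["rdbe_range"] = tuple(params["rdbe_range"])
        return cls(**params)


@dataclass
class AHLAnnotation:
    """One annotated MS2 precursor event.

    ``spec`` is the resolved congener, or ``None`` for an unknown (diagnostic
    fragment present, no grid match).  ``alternatives`` keeps any exact-mass
    isomers that could not be excluded — ties are retained, never broken
    silently.
    """

    spec: Optional[AHLSpec]
    observed_mz: float
    rt: float
    ppm: Optional[float]
    diagnostic_fragment: bool = True
    acyl_fragment: bool = False
    standard_rt_match: bool = False
    rt_consistent: bool = True
    tier: str = "C"
    alternatives: Tuple[AHLSpec, ...] = ()
    intensity: float = 0.0

    @property
    def name(self) -> str:
        return self.spec.name if self.spec is not None else "unknown"


@dataclass
class BrominatedCandidate:
    """An MS1 envelope flagged as mono- or di-brominated."""

    mz_observed: Tuple[float, ...]       # (M, M+2[, M+4])
    rt: float
    br_count: int
    confidence: float
    ratios: Tuple[float, ...]            # (M+2/M[, M+4/M])
    formulas: Tuple[Tuple[str, float], ...]   # (Hill formula, ppm error)
    intensity: float = 0.0


def _standard_rts(standards: Sequence[StandardEntry]) -> Dict[str, float]:
    return {e.spec.name: e.reference_rt_min for e in standards}


def screen_ahls(
    run: Run,
    grid: Optional[Sequence[Candidate]] = None,
    standards: Optional[Sequence[StandardEntry]] = None,
    cfg: ScreenConfig = ScreenConfig(),
) -> List[AHLAnnotation]:
    """Annotate every diagnostic-fragment-positive MS2 precursor in a run.

    Precursors with no grid match within tolerance are reported as unknowns
    (``spec=None``), not dropped.  Exact-mass isomer groups are resolved with
    :func:`resolve_isomers` using the run's unambiguous annotations as
    context; unresolved ties stay in ``alternatives``.
    """
    if grid is None:
        grid = generate_candidate_space()
    if not grid:
        raise ValueError("candidate grid is empty")
    if standards is None:
        standards = default_standards()
    std_rt = _standard_rts(standards)
    diag = lactone_fragment_mz()

    annotations: List[AHLAnnotation] = []
    for s in run.ms2():
        diag_hit = s.matched_intensity(diag, cfg.tol_ppm)
        if diag_hit <= 0:
            continue
        cands = match_candidates(grid, s.precursor_mz, cfg.tol_ppm)
        if not cands:
            annotations.append(
                AHLAnnotation(None, s.precursor_mz, s.rt_min, None, tier="unknown",
                              intensity=diag_hit)
            )
            continue
        with_acyl = [
            c for c in cands if s.matched_intensity(acyl_fragment_mz(c.spec), cfg.tol_ppm) > 0
        ]
        acyl_flag = bool(with_acyl)
        pool = with_acyl if acyl_flag else cands
        # minimal-|ppm| choice is only allowed inside the fragment-agreeing
        # pool; exact-mass isomers (identical theoretical m/z) remain tied
        best = min(pool, key=lambda c: abs(ppm_error(s.precursor_mz, c.mz)))
        tied = [c.spec for c in pool if c.isomer_group == best.isomer_group]
        spec = tied[0] if len(tied) == 1 else None
        annotations.append(
            AHLAnnotation(
                spec=spec,
                observed_mz=s.precursor_mz,
                rt=s.rt_min,
                ppm=ppm_error(s.precursor_mz, best.mz),
                acyl_fragment=acyl_flag,
                alternatives=tuple(tied) if len(tied) > 1 else (),
                intensity=diag_hit,
            )
        )

    # resolve isomer ties against unambiguous annotations; iterate so that a
    # congener resolved in one pass can serve as series context in the next
    for _ in range(5):
        context = [a for a in annotations if a.spec is not None]
        changed = False
        for i, a in enumerate(annotations):
            if a.spec is None and a.alternatives:
                ranked = resolve_isomers(a, context, standards=standards, cfg=cfg)
                top_score = ranked[0][1]
                top = [spec for spec, score in ranked if score == top_score]
                if len(top) == 1:
                    annotations[i] = replace(a, spec=top[0], alternatives=tuple(s for s, _ in ranked[1:]))
                    changed = True
                else:
                    annotations[i] = replace(a, alternatives=tuple(s for s, _ in ranked))
        if not changed:
            break

    # evidence flags and confidence tiers
    resolved = [a for a in annotations if a.spec is not None]
    for i, a in enumerate(annotations):
        if a.spec is None:
            continue
        std = std_rt.get(a.spec.name)
        std_match = std is not None and abs(a.rt - std) <= cfg.standard_rt_window
        consistent = _series_consistent(a.spec, a.rt, [(b.spec, b.rt) for b in resolved if b is not a])
        tier = "A" if (a.acyl_fragment and std_match) else ("B" if a.acyl_fragment else "C")
        annotations[i] = replace(a, standard_rt_match=std_match, rt_consistent=consistent, tier=tier)
    return annotations


def _series_consistent(spec: AHLSpec, rt: float, context: Sequence[Tuple[AHLSpec, float]]) -> bool:
    """Is (spec, rt) consistent with homologous-series elution order?

    Within a (substitution, unsaturation) series, RT must increase with chain
    length relative to every context member.
    """
    for other, other_rt in context:
        if other.subst == spec.subst and other.u == spec.u and other.n != spec.n:
            if (spec.n - other.n) * (rt - other_rt) < 0:
                return False
    return True


def resolve_isomers(
    a: AHLAnnotation,
    series_context: Sequence[AHLAnnotation],
    standards: Optional[Sequence[StandardEntry]] = None,
    cfg: ScreenConfig = ScreenConfig(),
) -> List[Tuple[AHLSpec, float]]:
    """Rank the exact-mass isomer candidates of one annotation.

    Scoring combines retention-time and dereplication plausibility:

    * a candidate whose synthetic standard elutes at the observed RT gains
      strong support (+2); a candidate whose standard RT is known and clearly
      different is penalized (-2);
    * each independently annotated member of the candidate's homologous
      series (same substitution and unsaturation, other chain length) lends
      support (+0.75) — a congener extending an established series is a more
      plausible assignment than one founding a new series;
    * an elution-order violation against such a member costs -1 (within a
      series RT must increase with chain length);
    * at equal chain length a 3-oxo/3-hydroxy congener must elute before its
      plain counterpart, and an unsaturated one before its saturated one
      (-1 per violation).

    Context annotations are aggregated per congener (median RT), so repeated
    MS2 sightings do not multiply the evidence.  Candidates are returned
    best-first with their scores; equal scores mean the ambiguity stands.
    """
    cands = list(a.alternatives) if a.alternatives else ([a.spec] if a.spec else [])
    if len(cands) < 2:
        return [(c, 0.0) for c in cands]
    if standards is None:
        standards = default_standards()
    std_rt = _standard_rts(standards)
    by_name: Dict[str, List[float]] = {}
    specs_by_name: Dict[str, AHLSpec] = {}
    for b in series_context:
        if b.spec is not None:
            by_name.setdefault(b.spec.name, []).append(b.rt)
            specs_by_name[b.spec.name] = b.spec
    ctx = [(specs_by_name[n], float(np.median(rts))) for n, rts in by_name.items()]

    scored: List[Tuple[AHLSpec, float]] = []
    for c in cands:
        score = 0.0
        std = std_rt.get(c.name)
        if std is not None:
            if abs(a.rt - std) <= cfg.standard_rt_window:
                score += 2.0
            else:
                score -= 2.0
        for other, other_rt in ctx:
            if other == c:
                continue
            if other.subst == c.subst and other.u == c.u and other.n != c.n:
                score += 0.75
                if (c.n - other.n) * (a.rt - other_rt) < 0:
                    score -= 1.0
            elif other.n == c.n and other.u == c.u and (other.subst == "plain") != (c.subst == "plain"):
                oxy_first = other_rt > a.rt if c.subst != "plain" else a.rt > other_rt
                if not oxy_first:
                    score -= 1.0
            elif other.n == c.n and other.subst == c.subst and other.u != c.u:
                unsat_first = other_rt > a.rt if c.u == 1 else a.rt > other_rt
                if not unsat_first:
                    score -= 1.0
        scored.append((c, score))
    scored.sort(key=lambda t: (-t[1], t[0].name))
    return scored


# --- brominated-metabolite path -------------------------------------------

def composition_search(
    target_mz: float,
    br: int,
    tol_ppm: float = 5.0,
    cfg: ScreenConfig = ScreenConfig(),
) -> List[Tuple[Formula, float]]:
    """Exhaustive CHNOBr compositions for a +1 cation at ``target_mz``.

    Element bounds and the ring-and-double-bond-equivalent window come from
    ``cfg``; the bromine count is fixed by the isotope classifier.  Results
    are sorted by |ppm error|.
    """
    masses = {s: element_table()[s].monoisotopic_mass for s in ("C", "H", "N", "O", "Br")}
    target_mass = target_mz + ELECTRON_MASS  # atoms of the cation
    out: List[Tuple[Formula, float]] = []
    for c in range(1, cfg.max_c + 1):
        for n in range(cfg.max_n + 1):
            for o in range(cfg.max_o + 1):
                rem = target_mass - c * masses["C"] - n * masses["N"] - o * masses["O"] - br * masses["Br"]
                h = round(rem / masses["H"])
                if h < 0 or h > cfg.max_h:
                    continue
                rdbe = c - (h + br) / 2 + n / 2 + 1
                if not cfg.rdbe_range[0] <= rdbe <= cfg.rdbe_range[1]:
                    continue
                counts = {"C": c, "H": h, "N": n, "O": o, "Br": br}
                f = Formula({k: v for k, v in counts.items() if v})
                err = ppm_error(target_mz, ion_mz(f, 1))
                if abs(err) <= tol_ppm:
                    out.append((f, err))
    out.sort(key=lambda t: abs(t[1]))
    return out


def screen_brominated(run: Run, cfg: ScreenConfig = ScreenConfig()) -> List[BrominatedCandidate]:
    """Flag MS1 envelopes whose M+2 companions indicate 1 or 2 bromines.

    Every sufficiently intense MS1 peak with a companion at +1.998 +- tol Da is
    scored with the isotope classifier on its measured (M, M+2, M+4) local
    envelope; candidates surviving classification get formula suggestions from
    the composition search.  Repeated sightings of the same envelope across
    scans are merged at the apex.
    """
    if not run.ms1():
        return []
    raw: List[BrominatedCandidate] = []
    for s in run.ms1():
        for i in range(s.mz.size):
            if s.intensity[i] < cfg.min_ms1_intensity:
                continue
            mz0, i0 = float(s.mz[i]), float(s.intensity[i])
            i2 = _window_intensity(s, mz0 + cfg.isotope_spacing, cfg.isotope_spacing_tol)
            if i2 <= 0:
                continue
            i4 = _window_intensity(s, mz0 + 2 * cfg.isotope_spacing, cfg.isotope_spacing_tol)
            pattern = IsotopePattern(
                intensities={0: 1.0, 2: i2 / i0, **({4: i4 / i0} if i4 > 0 else {})},
                mz={0: mz0, 2: mz0 + cfg.isotope_spacing,
                    **({4: mz0 + 2 * cfg.isotope_spacing} if i4 > 0 else {})},
            )
            count, conf = halogen_count(pattern)
            if count == 0:
                continue
            observed = (mz0, mz0 + cfg.isotope_spacing) + ((mz0 + 2 * cfg.isotope_spacing,) if count == 2 else ())
            ratios = (i2 / i0,) + ((i4 / i0,) if count == 2 else ())
            raw.append(BrominatedCandidate(observed, s.rt_min, count, conf, ratios, (), intensity=i0))

    merged: List[BrominatedCandidate] = []
    for cand in sorted(raw, key=lambda c: -c.intensity):
        dup = next(
            (m for m in merged
             if abs(ppm_error(cand.mz_observed[0], m.mz_observed[0])) < 2 * cfg.tol_ppm
             and abs(cand.rt - m.rt) < 0.5),
            None,
        )
        if dup is None:
            merged.append(cand)
    # drop 13C satellites: a weaker candidate one carbon-isotope step above a
    # stronger one is the M+1 of that envelope, not an independent metabolite
    merged = [
        c for c in merged
        if not any(
            m.intensity > c.intensity
            and abs((c.mz_observed[0] - m.mz_observed[0]) - _C13_STEP) < 0.02
            and abs(c.rt - m.rt) < 0.5
            for m in merged
        )
    ]
    for i, cand in enumerate(merged):
        formulas = composition_search(cand.mz_observed[0], cand.br_count, cfg.tol_ppm, cfg)
        merged[i] = replace(cand, formulas=tuple((f.hill(), round(e, 3)) for f, e in formulas))
    merged.sort(key=lambda c: c.rt)
    return merged


#: m(13C) - m(12C), the spacing of carbon isotope satellites.
_C13_STEP = 1.00336


def _window_intensity(s: Spectrum, center: float, half_window_da: float) -> float:
    lo = np.searchsorted(s.mz, center - half_window_da, side="left")
    hi = np.searchsorted(s.mz, center + half_window_da, side="right")
    return float(s.intensity[lo:hi].sum())


# --- reporting -------------------------------------------------------------

@dataclass
class ScreenReport:
    """Per-sample annotations condensed into a presence matrix.

    ``matrix`` is congener x sample (bool); ``table`` mirrors the published
    layout (AHLs, median M+H, median Rt, one mark column per sample).
    """

    samples: Tuple[str, ...]
    annotations: Dict[str, List[AHLAnnotation]]
    matrix: pd.DataFrame
    table: pd.DataFrame
    saturated: int
    unsaturated: int
    unknowns: Dict[str, int]

    def audit(self) -> bool:
        """Every present cell must trace to >=1 stored annotation."""
        for name in self.matrix.index:
            for sample in self.matrix.columns:
                if self.matrix.at[name, sample]:
                    backing = [a for a in self.annotations.get(sample, []) if a.name == name]
                    if not backing:
                        raise AssertionError(f"presence cell ({name}, {sample}) has no annotation")
        return True

    def to_tsv(self, path: "Path | str") -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compile_report(
    annotations: Mapping[str, Sequence[AHLAnnotation]],
    samples: Optional[Sequence[str]] = None,
) -> ScreenReport:
    """Build the presence matrix from per-sample annotation lists.

    Rows are the union of resolved congeners sorted by m/z, one row per
    congener with median observed m/z and RT; unknowns are counted per sample
    but excluded from the matrix.  Sample labels must be unique.
    """
    if samples is None:
        samples = list(annotations)
    if len(set(samples)) != len(samples):
        raise ValueError("sample labels must be unique")

    by_name: Dict[str, List[Tuple[str, AHLAnnotation]]] = {}
    unknowns = {s: 0 for s in samples}
    for sample in samples:
        for a in annotations.get(sample, []):
            if a.spec is None:
                unknowns[sample] += 1
            else:
                by_name.setdefault(a.spec.name, []).append((sample, a))

    names = sorted(by_name, key=lambda n: np.median([a.observed_mz for _, a in by_name[n]]))
    matrix = pd.DataFrame(False, index=names, columns=list(samples), dtype=bool)
    rows = []
    for name in names:
        events = by_name[name]
        for sample, _ in events:
            matrix.at[name, sample] = True
        row = {
            "AHLs": name,
            "M+H (exp)": round(float(np.median([a.observed_mz for _, a in events])), 4),
            "Rt": round(float(np.median([a.rt for _, a in events])), 2),
        }
        for sample in samples:
            row[sample] = "x" if matrix.at[name, sample] else ""
        rows.append(row)
    table = pd.DataFrame(rows, columns=["AHLs", "M+H (exp)", "Rt", *samples])
    specs = [AHLSpec.from_name(n) for n in names]
    return ScreenReport(
        samples=tuple(samples),
        annotations={s: list(annotations.get(s, [])) for s in samples},
        matrix=matrix,
        table=table,
        saturated=sum(1 for s in specs if s.u == 0),
        unsaturated=sum(1 for s in specs if s.u == 1),
        unknowns=unknowns,
    )
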