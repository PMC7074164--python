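"""Ground-truthed synthetic LC-MS/MS runs.

The study's raw Orbitrap runs were never deposited, so every pipeline stage
is exercised against synthetic runs that emulate them: planted AHLs with
isotope envelopes eluting as Gaussian peaks, MS2 scans near each apex carrying
the diagnostic lactone fragment and the acylium, mono-/di-brominated MS1
envelopes, Gaussian ppm mass jitter, uniform chemical noise and decoy
precursors.  A :class:`GroundTruthManifest` records exactly what was planted,
so recovery is checkable peak by peak.

The retention-time model maps a hydrophobicity index
``h = n - a*u - b(substitution)`` to minutes through a monotone
piecewise-linear fit anchored on the published (congener, Rt) pairs — the
reversed-phase elution logic the study argues from: longer chains elute later,
unsaturation and C3 oxygenation elute earlier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.isotonic import IsotonicRegression

from . import study_tables
from .formula import Formula, MassConvention, ion_mz, ppm_error
from .isotopes import simulate_pattern
from .library import (
    AHLSpec,
    acyl_fragment_mz,
    ion_formula,
    lactone_fragment_mz,
    precursor_mz,
)
from .spectra import Run, Spectrum, write_run

__all__ = [
    "Decoy",
    "GroundTruthManifest",
    "PlantedAHL",
    "PlantedCompound",
    "RTModel",
    "TableFixture",
    "rt_model",
    "simulate_run",
    "table_fixture",
]


# --- retention-time model --------------------------------------------------

@dataclass
class RTModel:
    """Monotone piecewise-linear retention-time predictor.

    ``a`` discounts the hydrophobicity index by one unsaturation; ``b_oxo`` /
    ``b_oh`` discount the 3-oxo / 3-hydroxy head oxygenation, all in
    chain-carbon equivalents.  ``eps`` adds a strictly positive slope so
    predictions increase strictly with chain length even across anchor ties.
    """

    h_knots: np.ndarray
    rt_knots: np.ndarray
    a: float = 1.5
    b_oxo: float = 1.7
    b_oh: float = 2.6
    eps: float = 1e-3

    def hydrophobicity(self, s: AHLSpec) -> float:
        b = {"plain": 0.0, "3-oxo": self.b_oxo, "3-hydroxy": self.b_oh}[s.subst]
        return s.n - self.a * s.u - b

    def predict_h(self, h: float) -> float:
        x, y = self.h_knots, self.rt_knots
        if h <= x[0]:
            slope = self._edge_slope(head=True)
            base = y[0] + slope * (h - x[0])
        elif h >= x[-1]:
            slope = self._edge_slope(head=False)
            base = y[-1] + slope * (h - x[-1])
        else:
            base = float(np.interp(h, x, y))
        return base + self.eps * h

    def _edge_slope(self, head: bool) -> float:
        x, y = self.h_knots, self.rt_knots
        overall = (y[-1] - y[0]) / (x[-1] - x[0])
        idx = np.nonzero(np.diff(y) > 0)[0]
        if idx.size == 0:
            return max(overall, 0.0)
        i = idx[0] if head else idx[-1]
        return float((y[i + 1] - y[i]) / (x[i + 1] - x[i]))

    def predict(self, s: AHLSpec) -> float:
        return self.predict_h(self.hydrophobicity(s))


def rt_model(
    anchors: Optional[Mapping[str, float]] = None,
    a: float = 1.5,
    b_oxo: float = 1.7,
    b_oh: float = 2.6,
) -> RTModel:
    """Fit the RT model through (congener name -> Rt minutes) anchors.

    Defaults to the published table anchors (suspect and series-inverting rows
    excluded).  Isotonic regression enforces monotonicity in the
    hydrophobicity index; at least two anchors are required.
    """
    if anchors is None:
        anchors = study_tables.rt_anchors()
    if len(anchors) < 2:
        raise ValueError(f"need >=2 RT anchors, got {len(anchors)}")
    model = RTModel(np.empty(0), np.empty(0), a=a, b_oxo=b_oxo, b_oh=b_oh)
    pairs = sorted(
        (model.hydrophobicity(AHLSpec.from_name(name)), rt) for name, rt in anchors.items()
    )
    h = np.array([p[0] for p in pairs])
    rt = np.array([p[1] for p in pairs])
    iso = IsotonicRegression(increasing=True).fit(h, rt)
    model.h_knots = h
    model.rt_knots = iso.predict(h)
    return model


# --- simulation plan types -------------------------------------------------

@dataclass(frozen=True)
class PlantedAHL:
    """One AHL to plant: congener, elution apex, abundance, optional m/z override.

    ``mz`` overrides the theoretical [M+H]+ (e.g. to plant a published
    experimental value); ``None`` uses electron-corrected theory.
    """

    spec: AHLSpec
    rt: float
    abundance: float = 1e6
    mz: Optional[float] = None

    @property
    def true_mz(self) -> float:
        return self.mz if self.mz is not None else precursor_mz(self.spec)


@dataclass(frozen=True)
class PlantedCompound:
    """A non-AHL cation to plant in MS1 only (e.g. a brominated metabolite)."""

    name: str
    ion: Formula
    rt: float
    abundance: float = 1e6

    @property
    def true_mz(self) -> float:
        return ion_mz(self.ion, 1, MassConvention.ELECTRON_CORRECTED)


@dataclass(frozen=True)
class Decoy:
    """A decoy precursor: triggers MS2 but must never be annotated.

    Either it lacks the diagnostic lactone fragment (``diagnostic=False``) or
    its m/z sits far (>20 ppm) off the AHL grid.
    """

    mz: float
    rt: float
    abundance: float = 2e5
    diagnostic: bool = False


@dataclass
class GroundTruthManifest:
    """What was planted: fully determines the emitted run given the seed."""

    seed: str
    planted: List[Dict] = field(default_factory=list)
    decoys: List[Dict] = field(default_factory=list)
    params: Dict = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def planted_ahl_names(self) -> List[str]:
        return [p["name"] for p in self.planted if p["kind"] == "ahl"]

    def to_json(self, path: "Path | str") -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: "Path | str") -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


# --- run synthesis ---------------------------------------------------------

def _jitter(rng: np.random.Generator, mz: float, ppm: float) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm) * 1e-6) if ppm > 0 else mz


#: m/z exclusion half-window (ppm) around the diagnostic fragment for noise.
_DIAG_GUARD_PPM = 50.0


def _noise_mz(rng: np.random.Generator, n: int, mz_range: Tuple[float, float]) -> np.ndarray:
    """Uniform noise m/z values avoiding the diagnostic-fragment window."""
    diag = lactone_fragment_mz()
    guard = diag * _DIAG_GUARD_PPM * 1e-6
    vals = rng.uniform(*mz_range, size=n)
    bad = np.abs(vals - diag) < guard
    while bad.any():
        vals[bad] = rng.uniform(*mz_range, size=int(bad.sum()))
        bad = np.abs(vals - diag) < guard
    return vals


def simulate_run(
    ahls: Sequence[PlantedAHL] = (),
    compounds: Sequence[PlantedCompound] = (),
    decoys: Sequence[Decoy] = (),
    *,
    seed: Union[int, np.random.SeedSequence],
    ppm_jitter: float = 0.0,
    rt_range: Tuple[float, float] = (0.5, 35.0),
    ms1_interval: float = 0.1,
    peak_sigma: float = 0.1,
    n_ms2: int = 3,
    noise_peaks: int = 15,
    noise_intensity: float = 2e3,
    mz_range: Tuple[float, float] = (100.0, 600.0),
    out_mzml: Optional["Path | str"] = None,
) -> Tuple[Run, GroundTruthManifest]:
    """Synthesize one centroided LC-MS/MS run plus its ground-truth manifest.

    MS1 scans run every ``ms1_interval`` min across ``rt_range``; each planted
    species contributes its isotope envelope under a Gaussian elution profile
    (sigma ``peak_sigma`` min).  Each planted AHL and each decoy triggers
    ``n_ms2`` MS2 scans straddling its apex; planted AHL MS2 scans contain the
    diagnostic lactone fragment, the acylium and a residual precursor peak.
    All m/z values carry independent Gaussian jitter of ``ppm_jitter`` ppm.
    The same seed reproduces the run exactly.
    """
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be >= 0")
    rng = np.random.default_rng(seed)

    species: List[Tuple[str, str, float, float, Formula]] = []  # kind,name,mz,rt,ion formula
    manifest = GroundTruthManifest(seed=repr(seed))
    for p in ahls:
        frags = {
            "diagnostic": lactone_fragment_mz(),
            "acyl": acyl_fragment_mz(p.spec),
        }
        species.append(("ahl", p.spec.name, p.true_mz, p.rt, ion_formula(p.spec)))
        manifest.planted.append(
            dict(kind="ahl", name=p.spec.name, mz=p.true_mz, rt=p.rt,
                 abundance=p.abundance, fragments=frags)
        )
    for c in compounds:
        species.append(("compound", c.name, c.true_mz, c.rt, c.ion))
        manifest.planted.append(
            dict(kind="compound", name=c.name, formula=c.ion.hill(), mz=c.true_mz,
                 rt=c.rt, abundance=c.abundance, fragments={})
        )
    for d in decoys:
        manifest.decoys.append(asdict(d))
    manifest.params = dict(
        ppm_jitter=ppm_jitter, rt_range=list(rt_range), ms1_interval=ms1_interval,
        peak_sigma=peak_sigma, n_ms2=n_ms2, noise_peaks=noise_peaks,
        noise_intensity=noise_intensity, mz_range=list(mz_range),
    )
    for i, (k1, n1, mz1, rt1, _) in enumerate(species):
        for k2, n2, mz2, rt2, _ in species[i + 1 :]:
            if abs(ppm_error(mz1, mz2)) < 5 and abs(rt1 - rt2) < 2 * peak_sigma:
                manifest.warnings.append(f"overlap: {n1} and {n2} share m/z and RT")

    abundances = {p["name"]: p["abundance"] for p in manifest.planted}
    patterns = {name: simulate_pattern(f, z=1) for _, name, _, _, f in species}
    # shift each envelope so its monoisotopic peak sits at the planted m/z
    env: Dict[str, List[Tuple[float, float]]] = {}
    for kind, name, mz0, _, f in species:
        pat = patterns[name]
        env[name] = [(mz0 + (pat.mz[off] - pat.mz[0]), inten) for off, inten in pat.intensities.items()]

    spectra: List[Tuple[float, int, Spectrum]] = []
    times = np.arange(rt_range[0], rt_range[1] + 1e-9, ms1_interval)
    for t in times:
        mzs: List[float] = []
        ints: List[float] = []
        for kind, name, mz0, rt0, _ in species:
            amp = abundances[name] * np.exp(-0.5 * ((t - rt0) / peak_sigma) ** 2)
            if amp < abundances[name] * 1e-3:
                continue
            for mz_i, rel in env[name]:
                mzs.append(_jitter(rng, mz_i, ppm_jitter))
                ints.append(amp * rel)
        for d in decoys:
            amp = d.abundance * np.exp(-0.5 * ((t - d.rt) / peak_sigma) ** 2)
            if amp >= d.abundance * 1e-3:
                mzs.append(_jitter(rng, d.mz, ppm_jitter))
                ints.append(amp)
        noise_mz = _noise_mz(rng, noise_peaks, mz_range)
        mzs.extend(noise_mz.tolist())
        ints.extend(rng.exponential(noise_intensity, size=noise_peaks).tolist())
        spectra.append((float(t), 1, Spectrum(1, float(t), np.array(mzs), np.array(ints))))

    diag = lactone_fragment_mz()
    offsets = (np.arange(n_ms2) - (n_ms2 - 1) / 2) * ms1_interval
    for p in ahls:
        acyl = acyl_fragment_mz(p.spec)
        for off in offsets:
            t = float(np.clip(p.rt + off, *rt_range))
            scale = p.abundance * float(rng.lognormal(0.0, 0.2))
            frag_mz = [_jitter(rng, diag, ppm_jitter), _jitter(rng, acyl, ppm_jitter),
                       _jitter(rng, p.true_mz, ppm_jitter)]
            frag_int = [scale, 0.8 * scale, 0.3 * scale]
            nm = _noise_mz(rng, 3, mz_range)
            frag_mz.extend(nm.tolist())
            frag_int.extend(rng.exponential(noise_intensity, size=3).tolist())
            prec = _jitter(rng, p.true_mz, ppm_jitter)
            spectra.append((t, 2, Spectrum(2, t, np.array(frag_mz), np.array(frag_int), precursor_mz=prec)))
    for d in decoys:
        for off in offsets:
            t = float(np.clip(d.rt + off, *rt_range))
            scale = d.abundance * float(rng.lognormal(0.0, 0.2))
            frag_mz = _noise_mz(rng, 5, mz_range).tolist()
            frag_int = rng.exponential(0.3 * scale, size=5).tolist()
            if d.diagnostic:
                frag_mz.append(_jitter(rng, diag, ppm_jitter))
                frag_int.append(scale)
            prec = _jitter(rng, d.mz, ppm_jitter)
            spectra.append((t, 2, Spectrum(2, t, np.array(frag_mz), np.array(frag_int), precursor_mz=prec)))

    spectra.sort(key=lambda x: (x[0], x[1]))
    run = Run(spectra=[s for _, _, s in spectra],
              metadata={"polarity": "positive",
                        "gradient": "10% ACN 3 min, 10-90% ACN over 30 min, 90% ACN 3 min"})
    if out_mzml is not None:
        write_run(out_mzml, run)
    return run, manifest


# --- published-table fixtures ---------------------------------------------

#: Abundance assigned to an "x" (detected) and an "L" (low amount) mark.
_MARK_ABUNDANCE = {"x": 1.0e6, "L": 2.0e5}

#: Fixed decoys added to every fixture sample: one lacking the diagnostic
#: fragment, one with it but sitting far off the AHL m/z grid.
_FIXTURE_DECOYS = (
    Decoy(mz=250.2000, rt=18.0, diagnostic=False),
    Decoy(mz=333.3333, rt=26.0, diagnostic=True),
)


@dataclass
class TableFixture:
    """A published identification table recast as per-sample simulation plans."""

    which: int
    samples: Tuple[str, ...]
    plans: Dict[str, List[PlantedAHL]]
    expected_presence: Dict[str, Dict[str, str]]
    excluded: Tuple[str, ...] = ()

    def simulate_all(
        self, *, seed: int, ppm_jitter: float = 0.0, decoys: Sequence[Decoy] = _FIXTURE_DECOYS, **kwargs
    ) -> Dict[str, Tuple[Run, GroundTruthManifest]]:
        """Simulate one run per sample (independent substreams of ``seed``)."""
        root = np.random.SeedSequence(seed)
        children = root.spawn(len(self.samples))
        return {
            sample: simulate_run(self.plans[sample], decoys=decoys, seed=child,
                                 ppm_jitter=ppm_jitter, **kwargs)
            for sample, child in zip(self.samples, children)
        }


def table_fixture(which: int) -> TableFixture:
    """Recast published Table 1, 2 or 3 as a ground-truthed simulation plan.

    Planted m/z and RT are the table's printed experimental values; the
    suspect OC12 row of the cell-fraction table is excluded and recorded in
    ``excluded``.
    """
    if which not in study_tables.TABLES:
        raise ValueError(f"no such table: {which!r}")
    samples = study_tables.SAMPLES[which]
    plans: Dict[str, List[PlantedAHL]] = {s: [] for s in samples}
    expected: Dict[str, Dict[str, str]] = {}
    excluded: List[str] = []
    for row in study_tables.TABLES[which]:
        if row.suspect_mz:
            excluded.append(row.name)
            continue
        spec = AHLSpec.from_name(row.name)
        expected[row.name] = dict(row.marks)
        for sample, mark in row.marks.items():
            plans[sample].append(
                PlantedAHL(spec, rt=row.rt_min, abundance=_MARK_ABUNDANCE[mark], mz=row.mz_exp)
            )
    return TableFixture(which, samples, plans, expected, tuple(excluded))
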