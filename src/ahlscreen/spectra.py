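"""Centroided LC-MS/MS runs: mzML and JSON I/O, chromatograms, peak picking.

The mzML 1.1.0 reader and writer here are self-contained (stdlib XML,
base64-encoded 64-bit float arrays, optional zlib): the reader streams
spectra with ``iterparse``, understands minute- and second-unit scan times
and 32/64-bit and zlib-compressed binary arrays, and a write/read cycle is
bit-equivalent on peak values.  Only centroided data are supported — profile
spectra are rejected loudly, because every downstream operation is peak-list
arithmetic.  An equivalent JSON run format is provided for small text
fixtures.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formula import ppm_error

__all__ = [
    "ChromPeak",
    "Run",
    "Spectrum",
    "UnsupportedDataError",
    "pick_peaks",
    "product_ion_chromatogram",
    "read_run",
    "write_run",
]


class UnsupportedDataError(ValueError):
    """Raised for mzML dialects the package does not handle (e.g. profile mode)."""


@dataclass
class Spectrum:
    """One centroided scan: sorted peak list plus acquisition metadata."""

    ms_level: int
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")

    def matched_intensity(self, target_mz: float, tol_ppm: float) -> float:
        """Summed intensity of peaks within ``tol_ppm`` of ``target_mz``."""
        if self.mz.size == 0:
            return 0.0
        half = target_mz * tol_ppm * 1e-6
        lo = np.searchsorted(self.mz, target_mz - half, side="left")
        hi = np.searchsorted(self.mz, target_mz + half, side="right")
        return float(self.intensity[lo:hi].sum())


@dataclass
class Run:
    """An acquisition: RT-ordered spectra plus free-form metadata."""

    spectra: List[Spectrum] = field(default_factory=list)
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt_min for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be ordered by non-decreasing retention time")

    def ms1(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class ChromPeak:
    """A picked chromatographic peak."""

    rt_apex: float
    apex_intensity: float
    rt_left: float
    rt_right: float
    area: float

    def __post_init__(self) -> None:
        if not self.rt_left <= self.rt_apex <= self.rt_right:
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be >= 0")


# --- reading ---------------------------------------------------------------

_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda: ET.Element) -> Tuple[Optional[str], np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind accession, values)."""
    kind = None
    dtype = "<f8"
    compressed = False
    text = ""
    for child in bda.iter():
        t = _local(child.tag)
        if t == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MZ_ARRAY or acc == _ACC_INT_ARRAY:
                kind = acc
            elif acc == _ACC_FLOAT32:
                dtype = "<f4"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif t == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem: ET.Element, source: str) -> Spectrum:
    sid = elem.get("id", "?")
    level: Optional[int] = None
    rt_min: Optional[float] = None
    precursor: Optional[float] = None
    mz = inten = None
    for child in elem.iter():
        t = _local(child.tag)
        if t == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_PROFILE:
                raise UnsupportedDataError(
                    f"{source} scan {sid!r}: profile-mode spectra are not supported; centroid first"
                )
            if acc == _ACC_MS_LEVEL:
                level = int(child.get("value"))
            elif acc == _ACC_SCAN_START:
                val = float(child.get("value"))
                unit = (child.get("unitName") or "minute").lower()
                rt_min = val / 60.0 if "second" in unit else val
            elif acc == _ACC_SELECTED_MZ:
                precursor = float(child.get("value"))
        elif t == "binaryDataArray":
            kind, values = _decode_binary(child)
            if kind == _ACC_MZ_ARRAY:
                mz = values
            elif kind == _ACC_INT_ARRAY:
                inten = values
    if level is None:
        raise UnsupportedDataError(f"{source} scan {sid!r}: no ms level cvParam")
    if level == 2 and precursor is None:
        raise UnsupportedDataError(f"{source}: MS2 scan {sid!r} has no selected precursor ion")
    if mz is None or inten is None:
        raise UnsupportedDataError(f"{source} scan {sid!r}: missing m/z or intensity array")
    return Spectrum(ms_level=level, rt_min=float(rt_min or 0.0), mz=mz,
                    intensity=inten, precursor_mz=precursor)


def read_run(path: "Path | str") -> Run:
    """Read a centroided run from mzML or the package's JSON run format."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path)
    spectra: List[Spectrum] = []
    try:
        for event, elem in ET.iterparse(str(path), events=("end",)):
            if _local(elem.tag) == "spectrum":
                spectra.append(_parse_spectrum(elem, path.name))
                elem.clear()
    except ET.ParseError as exc:
        raise UnsupportedDataError(f"{path.name}: malformed XML ({exc})") from exc
    return Run(spectra=spectra)


def _read_json(path: Path) -> Run:
    doc = json.loads(path.read_text())
    spectra = [
        Spectrum(
            ms_level=s["ms_level"],
            rt_min=s["rt_min"],
            mz=np.array(s["mz"], dtype=float),
            intensity=np.array(s["intensity"], dtype=float),
            precursor_mz=s.get("precursor_mz"),
        )
        for s in doc["spectra"]
    ]
    return Run(spectra=spectra, metadata=dict(doc.get("metadata", {})))


# --- writing ---------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **unit) -> ET.Element:
    el = ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value)
    for k, v in unit.items():
        el.set(k, v)
    return el


def _binary(parent: ET.Element, values: np.ndarray, accession: str, name: str, unit: dict) -> None:
    raw = struct.pack(f"<{values.size}d", *map(float, values))
    b64 = base64.b64encode(raw).decode("ascii")
    arr = ET.SubElement(parent, "binaryDataArray", encodedLength=str(len(b64)))
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    _cv(arr, accession, name, **unit)
    ET.SubElement(arr, "binary").text = b64


def write_run(path: "Path | str", run: Run) -> None:
    """Write a run as centroided mzML 1.1.0 (or JSON if path ends in .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        _write_json(path, run)
        return

    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
                  URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    ET.SubElement(cvlist, "cv", id="UO", fullName="Unit Ontology",
                  URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft = ET.SubElement(root, "softwareList", count="1")
    ET.SubElement(soft, "software", id="ahlscreen", version="0.1.0")
    icl = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ic = ET.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dpl, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="ahlscreen")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = ET.SubElement(root, "run", id=run.metadata.get("run_id", "run1"),
                           defaultInstrumentConfigurationRef="IC1")
    slist = ET.SubElement(run_el, "spectrumList", count=str(len(run.spectra)),
                          defaultDataProcessingRef="DP1")
    for i, s in enumerate(run.spectra):
        sp = ET.SubElement(slist, "spectrum", index=str(i), id=f"scan={i + 1}",
                           defaultArrayLength=str(s.mz.size))
        _cv(sp, "MS:1000511", "ms level", str(s.ms_level))
        if s.ms_level == 1:
            _cv(sp, "MS:1000579", "MS1 spectrum")
        else:
            _cv(sp, "MS:1000580", "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        _cv(sp, "MS:1000130", "positive scan")
        scl = ET.SubElement(sp, "scanList", count="1")
        _cv(scl, "MS:1000795", "no combination")
        scan = ET.SubElement(scl, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(s.rt_min)),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if s.ms_level == 2:
            plist = ET.SubElement(sp, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            silist = ET.SubElement(prec, "selectedIonList", count="1")
            si = ET.SubElement(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000044", "dissociation method")
        bdal = ET.SubElement(sp, "binaryDataArrayList", count="2")
        _binary(bdal, s.mz, "MS:1000514", "m/z array",
                dict(unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z"))
        _binary(bdal, s.intensity, "MS:1000515", "intensity array",
                dict(unitCvRef="MS", unitAccession="MS:1000131", unitName="number of detector counts"))

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _write_json(path: Path, run: Run) -> None:
    doc = {
        "metadata": run.metadata,
        "spectra": [
            {
                "ms_level": s.ms_level,
                "rt_min": s.rt_min,
                "mz": s.mz.tolist(),
                "intensity": s.intensity.tolist(),
                **({"precursor_mz": s.precursor_mz} if s.precursor_mz is not None else {}),
            }
            for s in run.spectra
        ],
    }
    path.write_text(json.dumps(doc, indent=1))


# --- chromatograms ---------------------------------------------------------

def product_ion_chromatogram(
    run: Run, target_mz: float, tol_ppm: float = 5.0
) -> List[Tuple[float, float, float]]:
    """Trace a product ion across MS2 scans.

    Returns RT-ordered ``(rt_min, summed matched intensity, precursor m/z)``
    for every MS2 spectrum containing >=1 fragment within ``tol_ppm`` of
    ``target_mz``.  A run without MS2 scans yields an empty list.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out = []
    for s in run.ms2():
        hit = s.matched_intensity(target_mz, tol_ppm)
        if hit > 0:
            out.append((s.rt_min, hit, s.precursor_mz))
    return out


def extracted_ion_chromatogram(
    run: Run, target_mz: float, tol_ppm: float = 5.0
) -> List[Tuple[float, float]]:
    """MS1 intensity-vs-RT trace for a narrow m/z window (EIC)."""
    return [(s.rt_min, s.matched_intensity(target_mz, tol_ppm)) for s in run.ms1()]


def pick_peaks(
    trace: Sequence[Tuple[float, float]],
    min_snr: float = 5.0,
    min_points: int = 3,
) -> List[ChromPeak]:
    """Pick chromatographic peaks from an RT-ordered (rt, intensity) trace.

    The baseline is the trace median and the noise scale is 1.4826 x MAD
    (robust to sparse peaks); local maxima exceeding baseline + ``min_snr`` x
    noise that are at least ``min_points`` samples wide are returned
    RT-ordered.  Peak bounds extend to the first sample at or below the noise
    floor (or a local minimum); area is trapezoidal.
    """
    if not trace:
        return []
    rt = np.asarray([p[0] for p in trace], dtype=float)
    inten = np.asarray([p[1] for p in trace], dtype=float)
    if np.any(np.diff(rt) < 0):
        raise ValueError("trace must be RT-ordered")
    baseline = float(np.median(inten))
    scale = 1.4826 * float(np.median(np.abs(inten - baseline)))
    noise = baseline + scale
    threshold = max(baseline + min_snr * scale, np.finfo(float).tiny)

    peaks: List[ChromPeak] = []
    n = inten.size
    for i in range(n):
        left_ok = i == 0 or inten[i] > inten[i - 1]
        right_ok = i == n - 1 or inten[i] >= inten[i + 1]
        if not (left_ok and right_ok and inten[i] >= threshold):
            continue
        lo = i
        while lo > 0 and inten[lo - 1] < inten[lo] and inten[lo - 1] > noise:
            lo -= 1
        hi = i
        while hi < n - 1 and inten[hi + 1] < inten[hi] and inten[hi + 1] > noise:
            hi += 1
        if hi - lo + 1 < min_points:
            continue
        area = float(np.trapezoid(inten[lo : hi + 1], rt[lo : hi + 1]))
        peaks.append(ChromPeak(float(rt[i]), float(inten[i]), float(rt[lo]), float(rt[hi]), area))
    return peaks
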