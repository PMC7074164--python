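"""Run I/O round trips, chromatogram extraction and peak picking."""

import subprocess

import numpy as np
import pytest

from ahlscreen.spectra import (
    ChromPeak,
    Run,
    Spectrum,
    UnsupportedDataError,
    pick_peaks,
    product_ion_chromatogram,
    read_run,
    write_run,
)


def _toy_run() -> Run:
    return Run(
        spectra=[
            Spectrum(1, 0.50, np.array([100.0, 200.128668, 200.5]), np.array([5.0, 1000.0, 2.0])),
            Spectrum(2, 0.55, np.array([102.054955, 141.5]), np.array([800.0, 10.0]),
                     precursor_mz=200.128119),
            Spectrum(1, 0.60, np.array([150.0]), np.array([7.0])),
        ],
        metadata={"polarity": "positive"},
    )


def _runs_equal(a: Run, b: Run) -> bool:
    if len(a) != len(b):
        return False
    return all(
        x.ms_level == y.ms_level
        and x.rt_min == y.rt_min
        and x.precursor_mz == y.precursor_mz
        and np.array_equal(x.mz, y.mz)
        and np.array_equal(x.intensity, y.intensity)
        for x, y in zip(a.spectra, b.spectra)
    )


@pytest.mark.parametrize("suffix", [".mzML", ".json"])
def test_write_read_roundtrip_bit_equivalent(tmp_path, suffix):
    run = _toy_run()
    path = tmp_path / f"toy{suffix}"
    write_run(path, run)
    back = read_run(path)
    assert _runs_equal(run, back)
    # idempotence: write(read(x)) re-read == read(x)
    path2 = tmp_path / f"again{suffix}"
    write_run(path2, back)
    assert _runs_equal(back, read_run(path2))


def test_mzml_readable_by_bioconductor_mzr(tmp_path):
    """Independent oracle: mzR (Bioconductor) parses the emitted mzML."""
    run = _toy_run()
    path = tmp_path / "toy.mzML"
    write_run(path, run)
    script = (
        'suppressMessages(library(mzR)); f <- openMSfile("%s"); h <- header(f); '
        'p <- peaks(f, 1); cat(nrow(h), h$msLevel[2], sprintf("%%.4f", h$retentionTime[1]), '
        'sprintf("%%.6f", p[2, 1]), sprintf("%%.1f", p[2, 2]))' % path
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    nspec, level2, rt_sec, mz, inten = out.stdout.split()
    assert int(nspec) == 3
    assert int(level2) == 2
    assert float(rt_sec) == pytest.approx(0.50 * 60, abs=1e-3)
    assert float(mz) == pytest.approx(200.128668, abs=1e-6)
    assert float(inten) == 1000.0


def test_malformed_xml_raises(tmp_path):
    bad = tmp_path / "bad.mzML"
    bad.write_text("<mzML><spectrum></mzML>")
    with pytest.raises(UnsupportedDataError, match="malformed"):
        read_run(bad)


def test_profile_mode_rejected(tmp_path):
    path = tmp_path / "toy.mzML"
    write_run(path, _toy_run())
    text = path.read_text().replace(
        'accession="MS:1000127" name="centroid spectrum"',
        'accession="MS:1000128" name="profile spectrum"',
    )
    prof = tmp_path / "profile.mzML"
    prof.write_text(text)
    with pytest.raises(UnsupportedDataError, match="profile"):
        read_run(prof)


def test_ms2_without_precursor_rejected(tmp_path):
    path = tmp_path / "toy.mzML"
    write_run(path, _toy_run())
    text = path.read_text().replace('accession="MS:1000744" name="selected ion m/z"',
                                    'accession="MS:1000000" name="stripped"')
    bad = tmp_path / "noprec.mzML"
    bad.write_text(text)
    with pytest.raises(UnsupportedDataError, match="scan=2"):
        read_run(bad)


def test_spectrum_validation():
    with pytest.raises(ValueError):
        Spectrum(2, 1.0, np.array([100.0]), np.array([1.0]))  # MS2 needs precursor
    with pytest.raises(ValueError):
        Spectrum(1, -1.0, np.array([100.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        Spectrum(1, 1.0, np.array([100.0]), np.array([-1.0]))
    # unsorted peak lists are sorted on construction
    s = Spectrum(1, 1.0, np.array([200.0, 100.0]), np.array([1.0, 2.0]))
    assert list(s.mz) == [100.0, 200.0]
    assert list(s.intensity) == [2.0, 1.0]


def test_run_requires_rt_order():
    spectra = [
        Spectrum(1, 2.0, np.array([100.0]), np.array([1.0])),
        Spectrum(1, 1.0, np.array([100.0]), np.array([1.0])),
    ]
    with pytest.raises(ValueError):
        Run(spectra=spectra)


class TestProductIonChromatogram:
    DIAG = 102.054955

    def test_planted_fragment_found_with_precursor(self):
        run = _toy_run()
        trace = product_ion_chromatogram(run, self.DIAG, tol_ppm=5)
        assert len(trace) == 1
        rt, intensity, precursor = trace[0]
        assert rt == 0.55
        assert intensity == 800.0
        assert precursor == pytest.approx(200.128119)

    def test_target_off_by_50ppm_excluded(self):
        run = _toy_run()
        off = self.DIAG * (1 + 50e-6)
        assert product_ion_chromatogram(run, off, tol_ppm=5) == []

    def test_coeluting_scans_keep_distinct_precursors(self):
        run = Run(
            spectra=[
                Spectrum(2, 1.0, np.array([self.DIAG]), np.array([10.0]), precursor_mz=200.1281),
                Spectrum(2, 1.0, np.array([self.DIAG]), np.array([20.0]), precursor_mz=254.1751),
            ]
        )
        trace = product_ion_chromatogram(run, self.DIAG, tol_ppm=5)
        assert [t[2] for t in trace] == [200.1281, 254.1751]

    def test_no_ms2_yields_empty(self):
        run = Run(spectra=[Spectrum(1, 1.0, np.array([100.0]), np.array([1.0]))])
        assert product_ion_chromatogram(run, self.DIAG) == []

    def test_intensity_conservation(self):
        # summed matched intensity equals the sum over individually matched peaks
        mzs = np.array([self.DIAG * (1 - 2e-6), self.DIAG * (1 + 2e-6), 300.0])
        run = Run(spectra=[Spectrum(2, 1.0, mzs, np.array([5.0, 7.0, 100.0]), precursor_mz=400.0)])
        trace = product_ion_chromatogram(run, self.DIAG, tol_ppm=5)
        assert trace[0][1] == pytest.approx(12.0)

    def test_tolerance_monotonicity(self):
        run = _toy_run()
        narrow = product_ion_chromatogram(run, self.DIAG, tol_ppm=1)
        wide = product_ion_chromatogram(run, self.DIAG, tol_ppm=50)
        assert len(wide) >= len(narrow)


class TestPickPeaks:
    @staticmethod
    def _gaussian_trace(rng, centers, height=1000.0, noise=5.0):
        rt = np.arange(0.0, 20.0, 0.05)
        inten = rng.normal(noise, 1.0, size=rt.size).clip(min=0)
        for c in centers:
            inten = inten + height * np.exp(-0.5 * ((rt - c) / 0.1) ** 2)
        return list(zip(rt, inten))

    def test_single_gaussian_apex_recovered(self):
        rng = np.random.default_rng(0)
        peaks = pick_peaks(self._gaussian_trace(rng, [12.0]), min_snr=5, min_points=3)
        assert len(peaks) == 1
        assert peaks[0].rt_apex == pytest.approx(12.0, abs=0.05)
        assert peaks[0].rt_left <= peaks[0].rt_apex <= peaks[0].rt_right
        assert peaks[0].area > 0

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(1)
        rt = np.arange(0.0, 20.0, 0.05)
        trace = list(zip(rt, rng.normal(5.0, 1.0, size=rt.size).clip(min=0)))
        assert pick_peaks(trace, min_snr=5, min_points=3) == []

    def test_two_resolved_peaks_in_order(self):
        rng = np.random.default_rng(2)
        peaks = pick_peaks(self._gaussian_trace(rng, [5.0, 14.0]), min_snr=5, min_points=3)
        assert len(peaks) == 2
        assert peaks[0].rt_apex < peaks[1].rt_apex

    def test_empty_trace(self):
        assert pick_peaks([]) == []


def test_chrompeak_validation():
    with pytest.raises(ValueError):
        ChromPeak(1.0, 10.0, 2.0, 3.0, 1.0)  # apex outside bounds
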