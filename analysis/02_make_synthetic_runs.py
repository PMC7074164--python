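#!/usr/bin/env python
"""Emit ground-truthed synthetic mzML runs emulating the three published tables.

One centroided mzML file plus a JSON ground-truth manifest per sample, with
the published experimental m/z and Rt as planted truth and two decoy
precursors per run.  These files are the inputs for 03_screen_ahls.py and
demonstrate that the whole loop runs on standard formats, not in-memory
shortcuts.
"""

from pathlib import Path

from ahlscreen.spectra import write_run
from ahlscreen.synthetic import table_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20260925


def generate(outdir: Path = OUT, seed: int = SEED, ppm_jitter: float = 0.0) -> dict:
    """Write per-sample runs for tables 1-3; returns {table: {sample: path}}."""
    paths: dict = {}
    for which in (1, 2, 3):
        fx = table_fixture(which)
        tdir = outdir / f"table{which}"
        tdir.mkdir(parents=True, exist_ok=True)
        paths[which] = {}
        for sample, (run, manifest) in fx.simulate_all(seed=seed + which, ppm_jitter=ppm_jitter).items():
            stem = sample.replace(":", "_")
            mzml = tdir / f"{stem}.mzML"
            write_run(mzml, run)
            manifest.to_json(tdir / f"{stem}.manifest.json")
            paths[which][sample] = mzml
            print(f"table {which} sample {sample}: {len(run)} spectra, "
                  f"{len(manifest.planted)} planted AHLs, {len(manifest.decoys)} decoys -> {mzml.name}")
    return paths


if __name__ == "__main__":
    generate()
    print(f"\nSynthetic study runs written under {OUT}")
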