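# Methods

This note documents the models, parameter choices and known limitations of
the screen, in the order the data flow through it.

## Exact-mass arithmetic and the two m/z conventions

All masses derive from a packaged IUPAC/CODATA isotope table
(`src/ahlscreen/data/elements.csv`, ≥ 7 decimals for H, C, N, O, Br;
electron mass 0.000549 Da).  The monoisotopic mass of an element is its
lightest stable isotope's, which for every element used here is also the
most abundant.

Two conventions for the m/z of a +1 cation coexist in the metabolomics
literature, and published values for this chemistry mix them: product-ion
and precursor m/z values are *electron-corrected* (atomic sum minus one
electron mass — physically correct for a cation), while "calcd." reference
values for the brominated metabolites are *plain atomic sums*.  The package
exposes both (`MassConvention`), defaults to electron-corrected for
everything it computes itself, and never guesses which convention an
external number used.  The gap is a constant 0.000549 Da at z = 1 — about
2.7 ppm at m/z 200 and therefore material at screening tolerances.

A note on fragment bookkeeping: the diagnostic lactone cation C₄H₈NO₂⁺ and
the acylium are *each* even-electron cations paired with a neutral loss, so
their summed atoms equal the [M+H]⁺ ion's atoms **plus one hydrogen**
(C₄H₈NO₂ + C₁₉H₃₇O = C₂₃H₄₅NO₃ = C₂₃H₄₄NO₃⁺ + H).  The tests assert this
chemically correct closure.

## AHL congener space

The default candidate grid covers n ∈ [4, 20], u ∈ {0, 1} and all three C3
substitution classes — 102 congeners — which brackets everything reported
from sponges (C6 through C19, odd chains included) with one carbon of
headroom on either side.  The 3-oxo/3-hydroxy position is a class label, not
a locant: the underlying data never assign one.  Congeners sharing an ion
formula (OCn and OHCn:1, for every n) are linked into isomer groups; exact
mass alone can never separate them, and neither can the acylium, whose
formula coincides too.

## Isotope envelopes and bromine counting

Envelopes are simulated by per-element abundance convolution on the nominal
(integer) mass-offset grid, propagating intensity-weighted exact masses per
offset bin.  Nominal-offset aggregation (rather than fine structure) is the
right resolution for M/M+2/M+4 reasoning; the oracle tests show the
convolution equals exhaustive isotopologue enumeration to 1e-9.  The default
prune threshold of 1e-4 (relative to the monoisotopic peak) keeps ≤ 2-Br
patterns exact to four significant figures.

The bromine classifier reads the (M+2/M, M+4/M) ratio pair against the
theoretical centers (0.973, 0) for one Br and (1.946, 0.946) for two, with
generous windows — Br = 1 if M+2/M ∈ [0.7, 1.3] and M+4/M < 0.2; Br = 2 if
M+2/M ∈ [1.6, 2.4] and M+4/M ∈ [0.6, 1.3] — so realistic intensity noise
does not flip the call.  Confidence is 1/(1 + distance to the matched
center).  In the MS1 screen, a candidate one ¹³C step (+1.00336 Da) above a
stronger candidate is discarded as the M+1 satellite of that envelope.
Chlorine and sulfur counting would be straightforward extensions but are out
of scope.

Formula suggestions come from an exhaustive CHNOBr composition search with
natural-product bounds C ≤ 30, H ≤ 50, N ≤ 4, O ≤ 6, Br ≤ 2 and
ring-and-double-bond equivalents in [0, 15] (computed on the cation, so
half-integer values are legitimate), at the same ppm tolerance as the rest
of the screen.

## Spectra I/O

Only centroided data are supported; profile-mode mzML is rejected with an
explicit error because every downstream operation is peak-list arithmetic.
The mzML 1.1.0 reader and writer are self-contained (streaming ElementTree;
base64 64-bit float arrays, no compression on write; 32-bit and
zlib-compressed arrays understood on read; scan times in minutes or
seconds).  A write/read cycle is bit-equivalent on peak values, and
Bioconductor's mzR independently parses the emitted files (one test runs
that cross-check through Rscript).  A JSON run format with the same schema
serves as a human-readable fixture format.

Matching windows are ppm-based everywhere (default 5 ppm), matching the
4-decimal printed masses of Orbitrap-class data; retention times are decimal
minutes.  Chromatographic peak picking uses baseline = trace median and
noise = 1.4826 × MAD, robust to sparse peaks; a peak is a local maximum
above baseline + 5 × noise at least 3 samples wide, with trapezoidal area.

## The screen

Gate: an MS2 scan nominates its precursor iff it contains a fragment within
tolerance of the diagnostic 102.0550.  Precursors with no grid match are
reported as unknowns, never dropped.  Among grid matches, the acylium
fragment narrows the pool, and the minimal-|ppm| candidate is chosen only
when fragment evidence agrees; exact-mass isomer groups survive as explicit
ambiguity sets.

Isomer resolution ranks the tied candidates by evidence:

* standard retention-time agreement within ±0.2 min (+2) or clear
  disagreement (−2) — the ±0.2 min window reflects sub-minute
  reproducibility of a short reversed-phase gradient and is configurable;
* +0.75 per independently annotated member of the candidate's homologous
  series — extending an established series is a more plausible dereplication
  call than founding a new one;
* −1 per elution-order violation (RT must increase with chain length within
  a series; 3-oxo/3-hydroxy before plain, unsaturated before saturated at
  equal chain length).

Context is aggregated per congener (median RT), so repeated MS2 sightings do
not multiply evidence; resolution iterates to a fixpoint so congeners
resolved in one pass provide series context in the next.  Ties are retained
as ambiguous.  Confidence tiers: A = diagnostic + acylium + standard RT
match, B = diagnostic + acylium, C = diagnostic only — mirroring the use of
standards where they exist and mass/fragment-only reasoning for the novel
long-chain congeners.

The shipped standards table covers the 21 commercial AHL standards.  Where a
standard's congener has a published retention time, the table carries that
value (standards run on the same LC as the samples); the remaining rows are
model predictions, flagged `source=model` in the CSV, and are synthetic
rather than measured data.

## Retention-time model

Predicted RT is a monotone piecewise-linear function (isotonic fit through
the published anchors, plus an ε = 10⁻³ · h slope to make the map strictly
increasing) of a hydrophobicity index h = n − 1.5 u − b, with b = 0 (plain),
1.7 (3-oxo) or 2.6 (3-hydroxy) chain-carbon equivalents.  The coefficients
were set from the published within-pair gaps (C18/C18:1 ≈ 2.4 min at
≈ 1.6 min/CH₂; C19/OC19 ≈ 2.6 min; C14/OHC14 ≈ 4 min) and are model
defaults, not fitted per run.  Out-of-range h extrapolates with the edge
slope of the monotone fit.

Two published retention times — C19-AHL (32.83 min) and OC19-AHL
(30.20 min) — print *earlier* than their C18 counterparts (33.88 and
31.26 min), inverting homologous-series order.  A monotone model cannot
reproduce those two pairs and no attempt is made to: the n = 19 anchors are
excluded from the fit, the two pairs are recorded as
`PRINTED_RT_INVERSIONS`, and the ordering tests cover every other printed
within-series pair.  Likewise OHC14:1 prints 0.28 min *after* OHC14,
contradicting the unsaturation rule, which is why isomer resolution leans on
standard-RT mismatch evidence rather than the unsaturation rule alone.

## Synthetic data: what it emulates and what it does not

`simulate_run` emits MS1 scans on a fixed cycle (default 0.1 min over
0.5–35 min, the span of the published 36-min gradient) with each planted
species contributing its full isotope envelope under a Gaussian elution
profile (σ = 0.1 min, the simplest shape satisfying the peak picker while
still stressing co-elution), log-normal MS2 intensity scatter, independent
Gaussian ppm jitter on every peak, uniform chemical noise, and decoys that
either lack the diagnostic fragment or sit > 20 ppm off-grid.  Noise m/z
values deliberately avoid a ±50 ppm guard band around 102.0550 so that a
decoy failing the gate fails it by construction, not by luck.  All
randomness flows from one explicit seed; identical seeds give identical
files.

The table fixtures plant each published congener at its printed experimental
m/z and Rt, with "low amount" marks mapped to 5× lower abundance (absolute
abundances are unreported in the source, so fixture abundances are
arbitrary).  The OC12-AHL row of the cell-fraction table prints m/z
298.0009 — ~670 ppm from any C16 AHL ion and irreconcilable with the
congener's formula — and is treated as a typographical error: carried in the
stored tables with a `suspect_mz` flag, excluded from fixtures.

Passing the closed loop on these fixtures shows the screen's logic is sound
at the study's printed masses, retention times and mass accuracy.  It does
not show robustness to what the generator omits: real matrix complexity,
co-eluting isobars closer than 5 ppm, retention drift between runs,
saturation or resolution-dependent peak shapes.

## Problem sizes

Defaults were chosen so every check runs in seconds: table fixtures are
5–6 runs of ~350 spectra each; robustness sweeps use 20 seeds × 24 planted
congeners; isotope-oracle comparisons stay below ~30 atoms where exhaustive
enumeration is exact and fast.

## Saturated/unsaturated census

The study's summary census counts eighteen saturated plus six unsaturated
AHLs; the union of the three published tables yields 19 saturated and 5
unsaturated distinct congeners (24 in total, suspect OC12 row included)
under the ":1" naming.  `study_tables.congener_census()` computes the table
union, `REPORTED_CENSUS` carries the summary claim, and the analysis driver
prints both side by side rather than reconciling them.
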