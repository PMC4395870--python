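# Methods

## FRET index pipeline

The sensitized-emission scheme acquires three registered images per
z-frame: donor emission under donor excitation (`ID`), acceptor emission
under direct acceptor excitation (`IA`), and acceptor emission under
donor excitation (`IF`, the raw FRET channel). Processing order is fixed
as: bin once → subtract background → correct bleed-through → compute the
index → 3×3 median filter → intensity threshold.

* **Binning.** One pass of block averaging (default 2×2, configurable)
  raises SNR. Trailing rows/columns that do not fill a block are
  cropped. Since binning averages `b²` independent pixels, the variance
  model applied downstream uses an effective gain `g/b²`.
* **Background.** A scalar per channel, either user-supplied or
  estimated as the mean of the darkest 5% of pixels. Negative
  post-subtraction values are retained, never clipped; the validity mask
  handles them.
* **Bleed-through.** `cF = IF − δ·ID − α·IA` with measured fractions α
  (acceptor) and δ (donor). The correction is linear, so with zero noise
  it is exactly invertible — a property the round-trip tests exploit.
* **Index.** `F = cF·Q_D·φ / (qD + cF·Q_D·φ)` with `φ = φ_D/φ_A` and
  `qD` the background-subtracted donor channel. The acceptor quantum
  yield is folded into `φ_A` rather than carried as a separate constant:
  the forward model in the synthetic module adopts the same convention,
  which makes the printed formula the generator's exact inverse and
  gives the round-trip identity without an extra calibration parameter.
  Pixels with `qD ≤ 0` or a non-positive denominator are invalid (NaN),
  not propagated.
* **Median filter.** 3×3 window, reflect padding at borders. NaN
  (invalid) entries are excluded from each window so an isolated invalid
  pixel does not poison its neighbourhood; an all-NaN window stays NaN.
* **Uncertainty.** First-order propagation of `Var(I) = g·I` (shot
  noise, gain `g` counts/photon, default 1) through both equations using
  the analytic partials with respect to the three raw channels.
  Backgrounds contribute variance (they are detected photons). σF falls
  as intensities rise at fixed F — halving when all channels quadruple —
  and matches a Poisson Monte-Carlo resampling oracle within a few
  percent at realistic budgets.
* **Threshold.** A pixel is analysable when *every* raw channel exceeds
  its `background + k·√(g·background)` (default k = 2). An intramolecular
  sensor is bright in all three channels wherever it is present, and the
  three-channel coincidence suppresses isolated shot-noise false
  positives that a single-channel rule admits at the percent level —
  enough, we found, to bias the mean of a large ROI through the
  occasional sensor-free pixel carrying a meaningless index value. The
  rule still selects the sensor-rich cell cortex and excludes cytoplasm
  and exterior.

The numbers α, δ, Q_D and φ_D/φ_A are instrument calibrations; the
defaults (0.3, 0.15, 0.85, 1.2) are documented placeholders in the
physically typical range, and real use requires the measured values.

## ROI statistics

Each embryo contributes a small SDR box (sensory depression region — the
pharynx attachment site) and the rest of the embryo footprint (non-SDR).
Comparing the two regions *within* one image cancels expression level,
bleaching and acquisition differences, since every pixel shares the same
history. Valid-pixel means are taken per frame, frames with an empty ROI
are dropped with a warning, and the unweighted mean over the retained
3–5 frames is the per-embryo experimental value.

Tests: two-tailed paired t on per-embryo SDR−non-SDR differences;
classical pooled-variance two-sample t between groups (Welch behind a
flag, for use when the equal-variance check fails); Jarque–Bera
normality (`n/6·(S² + K²/4)` against χ²₂); Levene centred at the group
means (the original formulation, since that is the named test, not the
median-centred Brown–Forsythe variant); Mann–Whitney U with mid-rank
ties, exact enumeration up to n = 20 per group and the tie-corrected
normal approximation beyond. Degenerate inputs (zero-variance
differences) return the exact limiting p-value with a warning rather
than NaN. The expression-independence check reports Pearson r between
valid-pixel F and raw acceptor counts; for intramolecular transfer it
should be near zero, and a concentration-dependent (intermolecular)
component drives it up — both behaviours are covered by tests.

## Synthetic embryo scenes

The default scene is an 80×120 ellipse with a 3-px cortical band where
the sensor concentrates (membrane-bound spectrin), plus a box on the
anterior cortex with elevated force standing in for the sensory
depression. Force maps to efficiency through a linear entropic spring in
series with the Förster relation, `E = 1/(1 + ((r0 + f/κ)/R0)⁶)`;
defaults r0 = 6 nm, R0 = 5.4 nm (zero-force E ≈ 0.35, in the range
reported for flagelliform-linker modules), κ = 1 pN/nm, base force
0.5 pN and SDR force 2 pN (E ≈ 0.25 vs ≈ 0.09). Control constructs are
force-insensitive: the terminal fusion reads E₀ everywhere, and the
short-rigid-linker / long-separator controls read fixed high (0.60) and
low (0.12) efficiencies — no measured values exist for these, so they
are configuration, not truth.

Channels are generated per cortical pixel with excitation budget S:
`qD = S·(1−E)·Q_D·φ_D`, `cF = S·E·φ_A`, `IA_signal = S`
(FRET-independent), mixed as `IF = cF + δ·qD + α·IA_signal`, plus a
constant background (default 100 counts) in every channel, then
(optionally) Poisson noise. φ_A is the unit of collection (φ_D = φ).
Sensor expression varies across the cortex as a static mean-preserving
log-normal field (CV 0.3, drawn once per scene seed): real embryos
express the sensor unevenly, and without expression variance the
independence check would only measure the bleed-through-induced
shot-noise anticorrelation. The default photon budget is S = 2000
excitations/pixel/frame, which puts per-pixel σF near 0.02 — comparable
to a well-exposed confocal acquisition.

What the generator does **not** emulate: PSF blur, chromatic
registration error, photobleaching, autofluorescence, z-dependent
attenuation, or sensor in the cytoplasm. Passing tests therefore
demonstrate the correctness of the arithmetic, the calibration of the
statistics under shot noise, and the exact invertibility of the linear
mixing — not robustness to optical artefacts absent from the model.

Power/size studies use a 48×72 scene, 10 embryos × 3 frames per cohort
and 10³ cohorts per condition (400 in the acceptance script), sizes
chosen to keep full runs in the minutes range while leaving Monte-Carlo
error on a rejection rate near ±0.01. The efficiency contrast is imposed
by inverting the spring/Förster relation for target efficiencies
(non-SDR 0.30, SDR 0.30 − ΔE).

## Tiling-array classification

Region means are arithmetic means of probe intensities (probe tables
enter pre-normalised; array-level normalisation is upstream and out of
scope). Fold is mutant/wild-type; calls use strict inequality at the
threshold (default 1.5), with down-calls symmetric on the log scale
(fold < 1/1.5). Intron-down is deliberately not a category — a loss of
unspliced signal has no splicing interpretation in this design — such
regions are "none". Regions with non-positive wild-type means are
excluded with a recorded reason. A gene joins every category for which
it has ≥1 called region; multi-category genes are counted in each and
listed separately, and the region-count conservation (called + uncalled
= total) is asserted in tests.

Enrichment: per-category AS proportions are compared pairwise by
chi-square on the 2×2 table with continuity correction, falling back to
Fisher's exact test when any expected cell is below 5 (logged), and
against the fixed ~25% genome-wide AS background by a two-sided exact
binomial test.

The scenario generator plants effects in a configurable fraction of
genes (default 15%) with kinds intron-up / exon-up / exon-down / mixed
(weights 0.15/0.35/0.40/0.10, roughly matching the relative sizes of
the observed categories), effect fold 3, log-normal probe noise
(SD 0.1), 4 probes per region, and an elevated AS-annotation rate (0.6
vs the 0.25 background) for genes whose effect touches splicing, so the
enrichment machinery has signal to detect. Genes alternate exon/intron
regions and always start and end with an exon (odd region counts,
default 3–9).

## Interfaces

Stacks are multi-page TIFFs, z-major/channel-minor, channel order
ID, IA, IF recorded in the image description together with per-channel
backgrounds; maps are 32-bit float TIFFs; all tables are TSV with header
rows and `# key: value` provenance comments carrying the resolved config
hash and seed. Configs are flat `key = value` text; unknown keys are
rejected. The `fretsplice` command exposes `simulate-fret`,
`fret-index`, `roi-stats`, `simulate-array`, `classify-regions` and
`report`; exit codes are 0 (ok), 1 (usage error), 2 (data error).

## Known limitations

* The round-trip identity holds for the unsmoothed, unbinned index:
  block averaging and the median filter mix pixels of different true
  efficiency at region boundaries, so exactness is only claimed (and
  tested) with `bin_factor=1` and the filter off; the binned pipeline is
  exact wherever true efficiency is block-constant.
* Real calibration constants (α, δ, Q_D, φ_D/φ_A) must be measured on
  the instrument; results scale with them.
* No automatic SDR detection: on real images the box is user-supplied;
  on synthetic scenes it comes from ground truth.
* The classifier is fold-only; no variance filter or probe-level test is
  applied, and upstream array normalisation is assumed done.
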