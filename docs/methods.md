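# Methods

This note records the models behind `ptrscreen`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-
engineer from the code.

## Detector model and dead-time correction

The detector is modelled as non-paralyzable: within one extraction, at
most one ion can be registered per flight-time bin, and a registered
count blanks the following `d` bins of that extraction (`d` =
`dead_time_bins`, default 2; instrument vendors do not publish this
figure, so it is configuration, not a claim). For bin *i* with expected
arrival count λᵢ over the acquisition and N_ext extractions, registered
counts are

    A(i) ~ Binomial(N_avail(i), 1 − e^(−λᵢ/N_ext)),
    N_avail(i) = N_ext − Σ_{j=i−d}^{i−1} A(j),

N_avail being the number of extractions still live at bin *i*. Inverting
the expectation gives the correction implemented in
`tof.correct_dead_time`:

    A′(i) = −N_ext · ln(1 − A(i)/N_avail(i)).

The multiplier is N_ext (not N_avail): blanked extractions lose their
arrivals entirely, so the per-extraction rate recovered from the live
pool must be scaled back to the full pool. With this form the correction
is exact in expectation under the simulator's censoring model — the
Monte-Carlo tests verify recovery within 1 % at rates where raw counts
are >20 % low. At `d = 0` it reduces to the familiar pile-up inversion
−N_ext·ln(1 − A/N_ext). Corrected counts are left real-valued;
saturation (A ≥ N_avail) is an error naming the bin, because no finite
rate reproduces it.

The simulator draws censored counts by an exact monotone coupling:
uncensored counts C(i) ~ Binomial(N_ext, p) first (one stream,
independent of `d`), then A(i) | C(i) ~ Hypergeometric(live, blanked,
C(i)) sequentially. This yields the Binomial(N_avail, p) marginal above
while guaranteeing A(i) ≤ C(i) pointwise for the same seed — dead time
only ever removes counts.

## Mass axis and calibration

The first-order ToF law t = a·√(m/z) + t₀ is used throughout (a
third-order term would only matter over much wider mass ranges than
15–300 Th). Internal calibration (`tof.calibrate`) locates each
reference ion as the dominant maximum within ±0.3 Th of its theoretical
m/z on the instrument's nominal axis, takes a sub-bin centroid
(log-parabola over the contiguous half-maximum region — exact for a
Gaussian and well-conditioned at any peak width in bins; an
intensity-weighted mean is the sparse-data fallback), and fits (a, t₀)
by linear least squares in √(m/z). Reported `achieved_accuracy` is the
maximum leave-one-out m/z residual, i.e. an estimate of the error on
peaks *not* used in the fit; with the default three references spanning
21–137 Th and realistic 30-s count levels it sits well below 1 mTh.
Each 30-s spectrum is calibrated independently; drift-in-time
recalibration across a run is out of scope.

## Peak shapes and extraction

"Modified Gaussian" is implemented as a Gaussian core plus a co-centered
broader Gaussian wing component,

    f(m) = H·[(1−w)·e^(−z²/2) + w·e^(−z²/(2κ²))],  z = (m−c)/σ,

the minimal two-extra-parameter shape capturing ToF tailing; the
functional form is isolated behind `peaks.modified_gaussian` so an
exponentially-modified Gaussian could be swapped in. Its area,
H√(2π)σ((1−w)+wκ), is analytic, and all fitting happens in count
*density* (counts/Th) so areas are invariant (±1 %, tested) to the bin
grid. Peaks within 4σ are fitted jointly; bounds are w ∈ [0, 0.5],
κ ∈ [1.2, 8], σ within [0.3, 3]× the resolution expectation, and each
segment carries one free constant offset (baseline subtraction leaves a
small positive residual; the offset may fit slightly negative because
the subtraction is itself noisy). Non-convergence after two restarts
falls back to a flagged trapezoidal area within ±2σ; zero-amplitude
peaks are dropped.

Baseline removal is a moving 10th-percentile estimate computed blockwise
(window 501 bins) and interpolated — O(n), robust to peaks occupying a
small fraction of any window — with subtraction clipped at zero.
Detection runs on a Gaussian-smoothed trace (σ = 1.5 bins, a matched
filter near the expected width) and applies **two** local-SNR conditions
at the same threshold (default 3): the smoothed excess over the local
median must exceed threshold × (MAD·1.4826) of the smoothed trace, and
the raw counts near the maximum must exceed the local raw median by
threshold × √(median+1). The second, Poisson-aware gate exists because
smoothed low-count Poisson noise keeps a heavy upper tail: over ~10⁵
bins, pure MAD thresholding at 5σ still fires on noise in roughly half
of baseline-only spectra, while the combined criterion yields zero
detections in ≥95 % of them (tested). Near-duplicate maxima closer than
half the resolution width merge, keeping the higher (ties: lower m/z).

A statistical note on overlap: for two peaks 1.5σ apart at peak height
~10⁴ counts, the joint decomposition has an information limit of roughly
7–20 % per-replicate spread on the individual areas (verified with an
independent curve-fit oracle, both unweighted and Poisson-weighted). The
fitter is unbiased at that separation (tested to <5 % mean error), but
no fitter can pin single-replicate areas to a few percent there. Truly
isobaric ions (e.g. different monoterpenes at the same nominal formula)
are indistinguishable by construction and out of scope.

## Quantification

`quant.concentration_ppbv` applies first-order proton-transfer kinetics:
[R] = I_R/(I_{H₃O⁺}·k·t), mixing ratio = [R]/N × 10⁹ ppbv with
N = p/(k_B·T). Defaults: k = 2×10⁻⁹ cm³ s⁻¹ with a per-ion override
table (rate coefficients are compound-specific), reaction time 100 µs,
drift length 9.3 cm. The drift length and reaction time are instrument
geometry that the operating conditions (550 V, 2.3 mbar, 110 °C) do not
determine uniquely; the defaults are typical for this instrument class
and put E/N at ≈136 Td, which the tests check only against the coarse
[130, 150] Td window. The primary-ion signal is read from the H₃¹⁸O⁺
isotopologue at 21.0221 Th and multiplied by the ¹⁶O/¹⁸O abundance
factor (default 487) — the direct 19.0178 Th peak saturates ion-counting
detectors and is therefore neither quantified nor simulated by default
(a direct-H₃O⁺ mode exists and is tested for consistency with the
isotopologue convention). Peaks below the detection threshold enter the
emission table as exact zeros with a below-LOD flag; fresh-weight
normalization is exact division, and rows with missing weight are kept
in the ppbv table but excluded from the normalized one.

## Simulator: what it emulates, what it does not

Emulated: kinetic signal generation (inverse of the quantification),
resolution-limited Gaussian peaks mapped through the ToF law, Poisson
baseline, extraction statistics, exact dead-time censoring, and the
screening design — 116 lines packed into blocks of 32 with one Col-0
reference per block (4 blocks → 120 vials), randomized measurement
order, per-vial fresh weights (normal, 25 ± 5 mg, floored at 5 mg),
log-normal emissions with median 5 ppbv·mgFW⁻¹ and σ_log = 0.5106
(population skewness ≈ 1.8), Col-0 background emission 0.14 ppbv·mgFW⁻¹,
and transgene expression generated for the top 29 emitters with noise
calibrated so the expected emission–expression R² is 0.28 (realized
per-run values scatter widely at n = 29; the calibration is verified on
the mean over seeds to ±0.05).

Not emulated: ion optics and peak-shape asymmetry (simulated peaks are
pure Gaussians, so wing parameters are exercised by the fitter tests,
not the simulator), humidity-dependent primary-ion chemistry and water
clusters, transmission curves (default 1), fragmentation chemistry
(fragment ions must be specified directly as sources), chromatographic
or temporal drift, and vial-to-instrument flow dynamics. Consequently,
passing the end-to-end tests demonstrates the *processing chain* is
correct and unbiased under its stated model; it does not certify
accuracy against matrix effects or shape mismatch on a real instrument.

A practical note on tails: sample skewness/kurtosis near 1.8/2.6
together with several lines above 80 ppbv·mgFW⁻¹ (as real screens show)
would require a far heavier-tailed distribution (σ_log ≈ 1.9) than the
skewness-1.8 default used here; the generator exposes both parameters so
either regime can be simulated.

## Screening statistics

Welch's one-way statistic and Welch–Satterthwaite degrees of freedom are
implemented in closed form (and cross-checked against an independent
implementation in the tests); its type-I error is verified at
0.05 ± 0.01 under the null. Bonferroni uses the number of compounds
tested as the family (one adjusted significance per compound row, as in
the published table layout), configurable. The compact letter display
uses insert-and-absorb with column duplication on partial conflicts, on
pairwise Welch t-tests at unadjusted α = 0.05, with genotypes processed
in ascending mean order so 'a' always marks the lowest-mean group (the
wild-type reference in practice); sharing a letter is exactly equivalent
to pairwise p ≥ α (property-tested). Distribution summaries report
median, moment skewness g₁ = m₃/m₂^1.5 and excess kurtosis
g₂ = m₄/m₂² − 3 *without* small-sample correction — the convention is
printed in the output because other software defaults to Fisher-
corrected estimators — plus Shapiro–Wilk via the standard Royston
algorithm. The regression band is a case-resampling bootstrap (residual
resampling optional), percentile 2.5/97.5 on an even 50-point x-grid,
clipped to contain the point fit; N = 1999 replicates reproduce a
10×-larger bootstrap to well under 1 % of the response range, and
coverage of the true line at the study's n = 29, R² = 0.28 conditions is
≥90 % of grid points (tested over 60 seeds). Line ranking is descending
with ties broken by line ID. The per-block Col-0 reference is carried in
the metadata and reported raw; no block-drift normalization is applied
by default because the published design does not state that arithmetic.

## Problem sizes and determinism

All tests and the acceptance script re-simulate their inputs at run
time. Monte-Carlo sizes are chosen to make the suite complete in about
two minutes on one core while keeping decision margins: 25–60 seeds for
recovery/coverage loops, 4000 replicates for the type-I-error check, 40
seeds for the overlap-bias check; the full blind screening test runs the
complete 116-line design once with targeted peak extraction (only the
primary, one calibrant and the isoprene window fitted). Every random
draw flows from an explicit seed through `numpy.random.default_rng`;
identical seeds give bit-identical spectra, tables and reports (the CLI
determinism test compares output files byte-for-byte).

## Known limitations

* Element alphabet for annotation defaults to C/H/O/N (+¹⁸O token);
  exhaustive enumeration is exponential in the number of elements, so
  wide alphabets need tight bounds.
* `achieved_accuracy` needs ≥3 references; with exactly two the fit is
  exact and accuracy is reported as 0 rather than estimated.
* The XLSX emissions reader guesses common column layouts and otherwise
  requires an explicit column map; it does not parse merged-cell or
  multi-sheet supplements.
* Fitted `height` is reported in count-density per extraction divided
  out to counts/extraction via the analytic area; for strongly winged
  peaks height and area are not redundant.
* Throughput (vials/hour) is logged, never asserted: it is hardware-
  dependent.
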