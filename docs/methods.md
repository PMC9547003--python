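# Methods

This note records the models, estimators, numerical choices and
limitations behind `kymotrap`, in the order data flows through the
package.

## The emulated experiment

A dual-trap optical tweezers instrument with confocal line scanning: a
15 kbp DNA tether with a central four-way junction is held between two
4.5 µm beads. Three kinds of records are produced and analysed:

1. **Force-extension cycles** at constant pulling rate (defaults
   0.2 µm/s, 60 Hz) from ~0.5 to 50 pN and back.
2. **Kymographs**: repeated 1D confocal scans along the DNA axis
   (default 10 Hz line rate, 100 nm pixels, Gaussian scan PSF of
   σ = 150 nm), showing labelled enzymes as bright spots and the beads
   as saturated bands at the edges.
3. **Force-clamp traces** in which bilateral junction cleavage severs
   the tether and the measured force drops to zero.

## Synthetic-data generator

Every estimator is validated by parameter recovery on synthetic data
with known ground truth. All generators are pure functions of
(parameters, seed); identical seeds give bit-identical output.

- **Brownian tracks.** Pure 1D diffusion: independent normal increments
  of variance 2·D·Δt, reflecting boundaries at the tether ends. No
  drift; hopping/slipping jumps are not simulated by default.
- **Kymographs.** Per scan line, each emitter contributes a Gaussian
  profile (peak amplitude `peak_counts`, width `psf_sigma`) on a uniform
  `background`; counts are Poisson-sampled. Bead bands are rendered as
  saturated pixels within one bead radius of each bead centre, with the
  tether spanning exactly the region between the two inner bead
  surfaces. Dimeric emitters bleach in `bleach_step_count` equal
  downward steps (default 2) at exponential times.
- **Force-extension cycles.** The force is swept on a uniform grid;
  extension follows the eWLC with contour length Lc below a rupture
  force drawn from N(mean, sd²) and Lc + ΔLc above it; the relax curve
  switches back below the drawn refold force (redrawn jointly until
  refold < unfold). Gaussian noise of SD `noise_sd` is added to the
  measured force; timestamps follow from extension change divided by
  the pulling rate, so the commanded pulling rate is honoured on
  average. Rupture is force-triggered, not kinetic: no loading-rate
  dependence is modelled, because only the force distributions are
  needed downstream.
- **Dwell times** are exponential with rate k(F) = k₀·exp(−F·Δx‡/kBT);
  **force clamps** are a noisy plateau at the setpoint with a step to
  zero at the programmed cleavage time.

What the generator does *not* emulate — and therefore what passing
recovery tests cannot certify about real data: bead Brownian noise and
trap compliance, scan-line motion blur within a line, spatially
structured background, spectral crosstalk, drift, and kinetic
(loading-rate-dependent) rupture.

## Force spectroscopy

**Model.** Odijk high-force eWLC,
x(F) = Lc·[1 − ½√(kBT/(F·Lp)) + F/S], valid across the 3–18 pN fit
window and above; kBT is fixed at 4.114 pN·nm (298 K). The inverse
(force from extension) uses bracketed Brent root finding; the closed
form is monotone in F so the root is unique.

**Compliance weighting.** Measurement noise lives on the force channel.
Its footprint in extension space is σ_F·dx/dF, which varies by an order
of magnitude across the fit window (the tether is soft at low force).
All eWLC fits therefore minimise residuals divided by the local
compliance dx/dF — i.e. residuals in force units — which restores
homoscedasticity and markedly tightens the contour-length estimate.
Standard errors come from the Jacobian at the optimum scaled by the
residual variance.

**Finding the transition: segmented profile fit.** Rupture forces
scatter; when one falls inside the baseline fit window, a baseline
fitted to the whole window is dragged toward the unfolded branch and
can hide the very jump it is meant to expose. The transition is
therefore located by a segmented (changepoint) fit: one eWLC below an
unknown split, the same chain with Lc + ΔLc above it, Lp and S shared
across branches. At fixed (Lp, S) the extension is linear in the
per-branch contour length, so the weighted least-squares profile over
every candidate split is computed from prefix sums in O(n); (Lp, Lc, S,
ΔLc) are then refitted jointly at the best split and the scan repeated
(3 rounds). Because both branches share Lp and S, errors in those
parameters cancel in ΔLc — the key property that keeps the estimate
unbiased wherever the rupture falls (measured on simulated ensembles:
ΔLc bias −0.1 ± 0.4 nm, rupture-force bias < 0.1 pN).

An event is accepted when the SSE-reduction statistic ("gain") exceeds
100 and ΔLc > max(1 nm, 3·SE). The threshold was calibrated on
simulated rupture-free curves at 0.2 pN force noise, whose gain
distribution has a 99.9th percentile near 60 (1000 curves, maximum 78);
true events in the same conditions never fell below ~130. The measured
false-positive rate is < 0.1%; detection-threshold and persistence
parameters remain configurable.

**Rupture force.** With the split known, the folded baseline is
refitted by plain least squares on forces below the rupture, and the
rupture index is the first sample whose compliance-scaled residual
exceeds 3× the robust residual SD (median absolute deviation over the
baseline window) sustained for ≥ 5 samples; the rupture force is the
measured force at that sample.

**ΔLc.** Two estimators are available. The default is the segmented
estimate above. The classical two-stage recipe — refit Lc over a
post-rupture force window (default 23–29 pN) with Lp and S held at the
baseline values — is retained as `delta_lc_method="two-stage"` and by
`measure_delta_lc`. The two-stage difference is leveraged by any error
in S when the post window sits far above the baseline window (δ(ΔLc) ≈
Lc·ΔF·δS/S², several nm for a typical single-curve S uncertainty), so
it is only advisable when rupture forces sit just below a nearby post
window; the segmented estimator is immune by construction.

**Refolding.** On the relax curve, each sample is classified by which
shared-parameter branch model (folded vs unfolded contour length) lies
closer in extension; the refold force is the force at the start of the
first sustained (≥ 5-sample) folded-classified run, scanning from high
to low force. Hysteresis (refold < unfold) is asserted, never assumed.

**Unfolding free energy.** The area under the transition — the
trapezoidal integral of force over extension between the last
folded-branch sample and the first unfolded-branch sample — converted
by 1 pN·nm = 0.1439 kcal/mol. With a force-triggered generator the
transition is a two-sample extension jump at nearly constant force, so
the area is ≈ F_rupture·Δx. This area estimate is method-sensitive
(its value depends on how the transition region is delimited) and the
system is out of equilibrium, so it bounds rather than equals the
folding free energy; the integration bounds used here are the event's
transition indices.

## Kymograph tracking

**Beads and coordinates.** Bead centres are centroids of the two
outermost bands above 80% of the saturation level in the time-averaged
profile. Pixels are 0-based with a pixel's position at its centre.
Genomic interpolation is linear between the *inner bead surfaces*
(centre ± radius) by default — 0 kbp at the left surface,
`tether_length_kbp` at the right — with a `mode="centers"` variant.
The map ignores force-dependent extension per base pair (at 5 pN a
base pair occupies ~0.31 nm rather than 0.34); positions in kbp are
therefore proportional, not absolute, at the few-percent level.

**Localization.** Three consecutive scan lines are summed (moving
window, stride 1) and a Gaussian-plus-constant is least-squares fitted
over ±5 px around the detection. Fits are rejected when the width falls
outside 0.5–5 px or the amplitude is below 2× the background noise SD.
Two consequences of the 3-line window are worth knowing. First,
consecutive localizations share two of three lines, so their errors are
correlated and the frame-to-frame RMS displacement of a static spot
underestimates the raw single-window precision. Second, a moving
emitter is blurred: the window average deviates from the instantaneous
position with variance (2/9)·2DΔt (≈ 30 nm at D = 0.02 µm²/s, 10 Hz),
which dominates the tracking error for mobile enzymes, and the boxcar
correlation subtracts ~(2/3)·2DΔt from the MSD intercept, which can
drive the fitted offset negative. Neither effect biases the MSD *slope*
over lag indices ≥ 3, which is why the diffusion estimate is taken
there.

**Linking.** Greedy nearest-neighbour assignment under a per-frame
displacement gate of 1 µm (scaled by the gap length), gaps of up to 3
frames bridged by flagged linear interpolation, trajectories shorter
than 1 s discarded. Gate, gap tolerance and minimum duration are
configuration keys; the defaults permit the large per-frame excursions
of a fast-diffusing dimer without inviting identity swaps between
well-separated spots.

**Diffusive/static segmentation.** A rolling 51-frame window yields a
local diffusion coefficient per point from an OLS line through
MSD(lags 1–8) — the intercept absorbs localization noise, so a static
spot with 30 nm noise is not mistaken for a mobile one. Frames with
local D below 0.001 µm²/s (the static detection limit) are labelled
static; segments shorter than 1 s are merged into their neighbours.
The window/lag defaults were chosen so that both mislabelling rates
(static-with-noise called diffusive, Brownian at 0.02 µm²/s called
static) are below 1% in simulation; a trajectory shorter than the
window receives a single global label.

**Photobleaching steps.** Penalized binary segmentation on the
amplitude series (penalty 3·σ²·log n, σ estimated robustly from first
differences); downward level changes of at least half a
single-fluorophore amplitude (by default half the median detected
downward step) count as bleaching steps. Two steps identify a dimer.

**Downsampling** sums kymograph lines (photon counts conserved over
retained lines) or block-averages force traces, rescaling the timing
metadata.

## Diffusion analysis

The time-averaged MSD uses every overlapping pair at each lag,
MSD(n) = Σ (X_{i+n} − X_i)²/(N − n), n = 1…N−1; frames bridged over
detection gaps are excluded pairwise. The estimator is tested for exact
agreement with an O(N²) brute-force oracle.

**Factor-of-2 convention.** For 1D Brownian motion MSD(τ) = 2Dτ + b,
so the diffusion coefficient is *half* the fitted slope. This package
defines D = slope/2 throughout — the single most consequential
convention in the analysis chain, chosen so that the generator
(variance 2DΔt per step) and the estimator agree and parameter-recovery
tests are meaningful. The offset b estimates localization accuracy
(b ≈ 2σ² for uncorrelated noise).

The fit is an OLS line over lag indices 3–10 inclusive (0.3–1 s at
10 Hz): shorter lags are noise-dominated, longer lags bend from
confinement by the finite tether. Quality-control flags mark
trajectories longer than 10 s and slope standard errors below
0.001 µm²/s (the SE threshold is interpreted in µm²/s on the slope;
the unit is a configuration key). Conversion to bp²/s uses a helical
rise of 0.34 nm/bp: D_bp = D_µm²·10⁶/0.34², so 0.021 µm²/s ↔
0.18·10⁶ bp²/s. Note that with this rise 0.001 µm²/s converts to
0.0087·10⁶ bp²/s; the package always uses the exact conversion.

Localization precision is the RMS frame-to-frame displacement of a
static (junction-bound) trajectory — σ√2 for i.i.d. errors of SD σ.
Survey speed is the summed absolute displacement of the
Savitzky–Golay-smoothed trajectory (defaults: 1 s window, order 2)
divided by the total time, in kbp/s. Group comparisons use Welch's
two-sided t-test and report medians ± SEM per group.

## Cleavage kinetics

Cleavage is the first sample of a force-clamp trace below 1 pN
sustained for ≥ 0.2 s; brief feedback-loop artifacts above the
threshold are thereby ignored. Dwell time runs from junction docking to
cleavage, or to the end of the recording (right-censored) when
photobleaching or the recording end intervenes.

The default rate estimator is the censoring-aware maximum likelihood
for an exponential law: k = n_uncensored / Σ(all observation times),
SE = k/√n_uncensored. Censored dwells contribute observation time
without counting as events; ignoring them biases the rate upward
(asserted directionally in the tests). A histogram mode (least-squares
fit of A·e^{−kt} to 2 s bins) replicates the classical figure-style
analysis. A single-exponential model suffices because the second of
the two sequential strand cleavages is much faster than the first,
making the first cleavage rate-limiting.

The Bell-Evans fit is weighted least squares of ln k on clamp force:
slope = −Δx‡/kBT, intercept = ln k₀, with weights (k/SE_k)² (the
delta-method variance of ln k) and the parameter covariance taken from
the weighted normal equations without residual rescaling — i.e. the
quoted errors propagate the stated per-force rate uncertainties. The
negative exponent encodes that tension slightly hinders cleavage.

## Pipeline, formats, provenance

Kymographs travel as multi-page TIFF plus a JSON sidecar (line time,
pixel size, channels, saturation level, generator ground truth), or as
an HDF5 container with `/kymo/{green,red}`, `/kymo/line_time_s`,
`/kymo/pixel_size_nm` and `/force/{t,F}`. Curves, trajectories and
dwell samples are CSV with named columns. `RunConfig` validates nested
configuration against the defaults (unknown keys rejected) and stamps
every output with its sha256 hash and the seed; `run_pipeline` executes
simulate → track → segment → MSD → kinetics and writes a manifest with
per-stage timings. Identical config + seed give byte-identical
results.json.

## Problem sizes in the acceptance script

The recovery studies use: one noisy stretch curve (~350 samples) for
the contour length; ensembles of 36/35/13 stretch-relax cycles for
ΔLc, unfolding and refolding forces, with per-quantity population SDs
set to SEM·√n so that the ensemble scatter matches the reported
standard errors; 2000 dwells for the cleavage rate; five forces × 200
dwells for the Bell-Evans parameters; and 50 static 60 s trajectories
at 10 Hz with 30 nm noise for the static detection limit. These sizes
put each recovered mean within its quoted uncertainty while keeping
the whole script in the seconds range on one core. Ensemble means are
summarised by a Gaussian fit to the recovered distribution (for a
normal sample the fitted mean equals the sample mean).

## Known limitations

- The Odijk eWLC is a high-force form; fits below ~2 pN would need the
  full interpolation formula.
- The segmented transition finder assumes a single unfolding event per
  stretch; multi-step unfolding would require a multi-changepoint
  extension.
- Genomic coordinates are linear in scan position and uncorrected for
  force-dependent rise.
- No drift correction, no multi-emitter overlap deconvolution, no
  2D scan analysis; crossing trajectories are linked greedily and
  should be excluded from MSD analysis (as the QC flags encourage).
- The area-based free energy depends on how the transition region is
  delimited and is reported as-is, not as an equilibrium ΔG.
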