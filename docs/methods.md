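# Methods

This note documents the models implemented in `fccskit`, the default
parameter values and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions that a
user extending the package should know about.

## Correlation estimator

Both the brute-force reference (`correlate_direct`) and the production
multi-tau correlator (`correlate_multitau`) use the normalised
fluctuation estimator

    G(k) = <a(t) b(t+k)> / (<a>_seg <b>_seg) − 1

in which the two means are taken over the truncated, overlapping
segments at each lag. Per-lag segment means (rather than one global
mean) remove the linear-trend bias that slow drifts introduce into the
standard estimator. Lag 0 is never part of a curve: for photon counting
it is dominated by shot noise, and fits refer to the smallest positive
lag.

The multi-tau grid consists of the first `2m` lags at native bin
resolution (`m = points_per_octave`, default 8 — the conventional
hardware-correlator value) followed, per octave, by lags `m+1..2m` in
units of a bin width that doubles each octave by *averaging* adjacent
bins. Averaging (not summing) leaves the normalised estimator unchanged
in expectation, and the native-resolution lags are numerically identical
to the brute-force estimator (this is property-tested to 1e-9).

Per-lag uncertainties (`estimate_curve_noise`) come from splitting the
trace into `n_segments` equal blocks (default 10), correlating each
block on the full-trace lag grid, and reporting the standard deviation
over blocks divided by √n_segments — the standard error of the
full-trace estimate, used as the weight in curve fitting.

## Diffusion models and fitting

The observation volume is the usual 3-D Gaussian,
`W(r) = exp(−2(x²+y²)/w_xy² − 2z²/w_z²)`, for which

    G(τ) = (1/N)(1 + τ/τ_D)^−1 (1 + τ/(κ²τ_D))^−1/2,
    V_eff = π^{3/2} w_xy² w_z,   τ_D = w_xy²/(4D),   N = C·N_A·V_eff.

No triplet term is included by default: the fitted lag range starts at
the first correlator lag (≥100 µs at the default binning), above
typical triplet times, and the tagged proteins of interest are slow. A
two-component variant (fraction-weighted decays, shared κ) is available
for mixed populations.

Fits are weighted nonlinear least squares (lmfit/`least_squares`) with:

* κ **fixed** at the calibrated value during sample fits. Refitting κ
  against sample curves inflates the N–τ_D covariance; calibration
  (`calibrate_volume`) fits κ freely against a dye of known D and then
  pins it.
* a **free baseline offset** `g_inf`. Measured curves do not decay
  exactly to zero (instrumental drift in experiments; in closed-volume
  simulations the exact −1/N_box depletion term, see below), and an
  offset keeps N and τ_D unbiased. On noiseless model curves the offset
  converges to 0 and parameters are recovered to machine precision.
* initial guesses from the curve itself (N₀ = 1/G(first lag), τ_D₀ =
  half-amplitude lag), positivity bounds, and up to three restarts from
  perturbed initials; persistent failure is reported as
  `converged=False` with parameters withheld, never interpolated. A
  non-positive first-lag amplitude raises an explicit no-fit signal.

Physical conversions: `D = w_xy²/(4τ_D)` (µm²/s), `C = N/(N_A V_eff)`,
Stokes–Einstein `R_h = k_B T/(6πηD)`. The effective intracellular
viscosity is sample-dependent and is therefore an explicit input with
no asserted default.

## Dual-colour amplitudes and K_D

With free green, free red and a doubly labelled complex at
concentrations `C_g, C_r, C_c` (molar) and `s = N_A·V_eff`:

    G_g(0) = 1/(s(C_g+C_c)),  G_r(0) = 1/(s(C_r+C_c)),
    G_x(0) = C_c/(s(C_g+C_c)(C_r+C_c)).

These assume equal molecular brightness within each channel and no
spectral cross-talk (the instrument configuration this emulates uses
well-separated 505–540 nm / 580–625 nm detection windows); a cross-talk
correction hook is deliberately out of scope for v1. Inversion gives
absolute concentrations and `K_D = C_g·C_r/C_c`; a zero complex
concentration reports the `+inf` sentinel ("no detectable
interaction"). Noise can make the inferred free concentrations
negative; they are **reported, not clipped**, so aggregate bias stays
visible, and K_D is withheld (NaN with a diagnostic) in that case.

The cross-correlation quotient `q` is defined here as the larger of the
two bound fractions `G_x(0)/G_r(0)` and `G_x(0)/G_g(0)` — i.e.
normalised by the limiting autocorrelation. Conventions differ between
instruments and labs; the definition is isolated in
`cross_correlation_quotient` so an alternative can be swapped in.

The forward equilibrium solver uses the numerically stable root
`C_c = 2AB/((A+B+K) + sqrt((A+B+K)² − 4AB))`, with `K→0` handled as the
infinite-affinity limit `min(A, B)`.

## Brownian/Poisson photon-trace generator

Each species contributes `round(C·N_A·V_box)` point emitters placed
uniformly in a periodic cuboid with half-widths
`box_multiplier × (w_xy, w_xy, w_z)`. Per timestep every molecule takes
an isotropic Gaussian step of per-axis sd `sqrt(2DΔt)`; the photon rate
is `brightness × W(r)` summed over molecules, integrated over each bin
by the midpoint rule over sub-steps, and bin counts are Poisson. A
bound complex is simply a species bright in both channels, so
cross-correlation arises physically from co-diffusion. All randomness
(initial positions, displacements, shot noise) flows from one seed
through a single generator stream; the number of timesteps consumed per
kernel call is fixed, so a given seed is bit-reproducible.

Finite-box physics worth knowing:

* The measured amplitude carries an exact depletion term:
  `G(0) = 1/N_eff − 1/N_box` (particle number is conserved in the box).
  At the default `box_multiplier = 3` this is a ~2.5% effect, absorbed
  by the fitted offset.
* Beyond lags of roughly `box_multiplier²·τ_D`, periodic images add
  spurious correlation. Pipelines therefore fit lags up to `9·τ_D` of
  the slowest species by default. The model-agreement test uses a 5×
  box where images are negligible across the tested band.
* `box_multiplier ≥ 3` is enforced; 3 keeps edge artefacts below
  correlator noise while bounding the molecule count (cost scales with
  the cube of the multiplier).

Default operating point of the composite experiments
(`fccskit.pipelines`), chosen to emulate the live-cell system the
package targets: V_eff ≈ 0.22 fL (w_xy = 0.2 µm, κ = 5), both binding
partners at 100 nM total; the large ligase complex and anything bound
to it diffuse at 6.44 µm²/s (the measured value for the tagged complex
in cells), the smaller free green-labelled substrate at 15 µm²/s
(typical for a ~90 kDa fluorescent fusion in cytoplasm); molecular
brightness 10 kHz/molecule (a bright FP under confocal illumination);
20 s acquisitions binned at 100 µs with timestep = bin width (the
per-step displacement, ≤0.08 µm, is well below w_xy). Twenty seeds per
condition give median-K_D estimates reproducible to a few percent;
single measurements scatter by ~10–30%, comparable to the cell-to-cell
scatter of real in-cell FCCS.

What the generator does **not** emulate: triplet blinking and other
photophysics, detector afterpulsing and dead time, spectral cross-talk,
membrane/anomalous diffusion, cellular autofluorescence background, and
spatial heterogeneity within a measurement. Passing recovery tests
therefore demonstrate correctness of the estimator chain under the
stated model, not robustness to every artefact of real hardware.

## Degradation traces and kinetics pipeline

The generator's trace model is

    I(t) = baseline · bleach(t) · d(t) + ε_t,

with linear-in-frame bleaching `1 − bleach_rate·(t − first)` (matching
the straight-line correction used downstream; exponential bleaching is
available as an option), `d(t) = 1` up to and including the onset frame
and first-order decay `exp(−decay_rate·(t − onset))` after it, and
i.i.d. Gaussian noise. The true post-onset curve shape in cells is not
established; exponential is the simplest monotone choice and a logistic
("sigmoidal") alternative is exposed as a parameter rather than
asserted. Defaults (30 s frames, bleach 0.2%/frame, decay 0.1/frame,
noise sd 0.02 of the plateau, onset at anaphase) reproduce the look of
measured normalised trajectories.

Analysis conventions (anaphase = frame 0, "N frames prior" = −N):

* **Normalisation**: background-subtracted division by the value at an
  explicit reference frame (−20 by default; −25 and −10 are used by
  some acquisition protocols, so the reference is always a parameter).
* **Bleach correction**: either division by a matched normalised
  control trace (translation + degradation blocked, so its decay is
  bleaching only), or division by a straight line fitted to frames
  −30..−25 (inclusive, 6 frames) and extrapolated.
* **Smoothing**: trailing four-point moving average, labelled at the
  window's last frame. Trailing alignment preserves causality of the
  onset label; only frames with full support are retained.
* **Onset**: sliding five-point least-squares slopes over the smoothed
  trace; onset is the first frame of the first window with slope
  *strictly* below −0.05 (a tie at exactly the threshold does not
  trigger), and the initial speed is that window's slope. Absence of
  any qualifying window is a valid result (`None`), not an error.
* **Maximum speed**: the backward first difference of the smoothed
  trace is minimised (ties to the earliest frame); a least-squares line
  through the five smoothed values centred there (clamped at the trace
  ends) gives the maximum degradation speed. Whether the derivative
  minimum should be located on smoothed or raw data is ambiguous in
  common practice; smoothed is the default, raw is available via
  `derivative_on="raw"`.
* Slopes are in normalised intensity **per frame**, deliberately not
  rescaled by the frame interval: the same threshold is conventionally
  applied across 30 s and 1 min acquisitions. The interval is carried
  in metadata for users who want physical rates.

On noiseless synthetic traces the detector is exact against
hand-computed window slopes; at 2% noise the onset is recovered within
±2 frames in ≥90% of runs. The detector has a small systematic: it can
fire one frame before the true onset (the window spanning the kink
already exceeds the threshold), which is inside the documented ±2
tolerance.

Line profiles sample at unit spacing along the centrosome–centrosome
axis, averaging bilinear interpolations at `thickness_px` perpendicular
offsets (spacing 1 px, centred: −4.5..+4.5 for the default thickness
10). Min–max scaling to [0, 1] is applied after background subtraction
and is undefined (an error) for constant profiles. Compartment
quantification (`compartment_means`) takes a caller-supplied binary
mask; automatic segmentation is out of scope.

## File formats, configuration, reproducibility

All data files are plain text: CSVs with `#`-prefixed `key: value`
metadata lines (trace kind, bin width, frame interval, seed) above the
header row, and schema-versioned JSON results with a provenance block
(tool version, config hash, input-file hashes, seed, timestamp).
Infinite K_D serialises as the string `"inf"`; an absent onset as JSON
`null`. Floats are written with `repr` and parsed with pandas'
round-trip parser, so write→read is exact. The run configuration is a
flat TOML file validated against each module's preconditions at load
time; unknown keys are errors so a misspelled threshold cannot silently
revert to a default.

## Problem sizes used in validation

The test suite and the reproduction script size their simulations as
follows, as the package's own validation protocol: oracle-equivalence
on 100 random traces of 2×10⁴ bins; noiseless round trips over 100–200
random parameter draws; diffusion recovery over 20 seeds of 10-s
single-species traces at 100 nM; K_D recovery over 20 seeds of 20-s
dual-colour pairs per compartment; onset/ordering statistics over 100
seeded repeats. Medians over seeds are compared at 15% (D) and 25%
(K_D) while the observed errors are typically a few percent.

## Known limitations

* The amplitude relations ignore cross-talk and brightness
  heterogeneity; K_D values from real two-colour data with leaky
  filters will be biased unless corrected upstream.
* Autocorrelation fits use the one-component model by default; for a
  strongly bimodal mixture (e.g. ~4× different diffusion times at
  comparable fractions) the fitted τ_D is an effective value, though
  the amplitude — all that K_D estimation uses — remains accurate to a
  few percent.
* The Brownian generator is not a full photon Monte Carlo (no pulsed
  excitation, no detector physics); its Poisson bin counts are exact
  only at the bin, not photon-arrival, level.
* `detect_onset` assumes a monotone post-onset decline; oscillating
  traces can trigger on noise excursions if the threshold is loosened.
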