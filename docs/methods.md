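# Methods

This note documents the models and procedures implemented in `ecogdac`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Distance-averaged correlation (DAC)

Recordings are band-pass filtered (six zero-phase FIR bands of roughly 0.6
octave: 6–9, 10–15, 20–30, 35–50, 70–110, 130–200 Hz, chosen to avoid
60 Hz), segmented into non-overlapping 2 s windows within artifact-free
regions, and Pearson-correlated for every unordered channel pair per
window.  Pooling all pair × window values and averaging within groups of
equidistant pairs gives the DAC curve; uncertainty is a normal-approximation
95% CI on the pooled mean (a percentile bootstrap is available).  Pairs with
a zero-variance channel are undefined and dropped, not zero-filled, because
zero-filling biases the mean toward zero.

Artifact exclusion follows three threshold rules with fixed margins: a
sample is marked when the recorded reference strays more than 35 µV from
zero, any channel leaves ±4 mV, or the highest-band signal exceeds 20× that
band's RMS; marked samples drag 750 ms before and 1.25 s after into the
exclusion, and surviving clean segments shorter than 6 s are excluded too.
Two rules the thresholds leave open were resolved as follows: the reference
rule applies to the *raw* reference trace, and the 20× RMS rule is
per-channel with the RMS taken over the full recording (global RMS is
stable and simple; a per-segment RMS would make the rule self-referential).
Windows are left-aligned within each clean segment and partial trailing
windows are discarded.

Filters are windowed-sinc FIR designs whose tap count sets the transition
width to 20% of the lower band edge, applied forward-backward.  Zero-phase
filtering matters here: the quantity under study is instantaneous
inter-channel correlation, and any phase distortion would contaminate it.
Downsampling applies an anti-alias low-pass at 0.45× the target rate.

## Gaussian spatial-component forward model

Component weights are circular 2D Gaussians of the channel–component
distance, `W[i,j] = A_j exp(-d²/2σ_j²)`.  With unit-variance uncorrelated
components the covariance is `Σ = WWᵀ`; a product-of-Gaussians identity
factors each entry into `F_ij · exp(-d_ij²/(2(√2σ)²))`, where `F_ij`
depends only on the component density around the pair's midpoint.  When
many equally sized components cover an area comfortably larger than the
grid, `F` is constant and the correlation is exactly Gaussian in distance
with standard deviation `√2 σ`.  The package reproduces this limit to
within 2–3% (dense equal-amplitude ensemble, center margins of several σ).

The standard random ensemble mimics measured component spectra: 150
components on a 10 × 15 unit-pitch grid, centers uniform over the grid
extent plus σ/5 margin per side, amplitudes uniform on [0.5, 1.5], sorted
descending, scaled by `e^(−0.1k)` (k = 1, 2, …).  Two consequences of that
amplitude decay are worth stating plainly, because they are properties of
the model itself:

* The decay leaves only ≈10 effective components (`(Σa²)²/Σa⁴`), so `F` is
  far from constant.  The mean fitted DAC width under this ensemble is
  ≈1.62 σ, not √2 σ ≈ 1.41 σ — distant pairs sit nearer the grid edge than
  their midpoints, inflating their correlations.  The √2 law is recovered
  exactly as the ensemble is made dense and equal-amplitude; the package
  tests assert both behaviors rather than pretending the decaying ensemble
  obeys the limit law.
* A spatially uniform reference (covariance ρ added everywhere) raises a
  pair's correlation iff `Σ_ij + ρ` is below the harmonic mean of the two
  channel variances (+ρ).  With homogeneous variances that is every pair
  with r < 1; under strong amplitude decay, near-unity correlations between
  channels of very unequal variance can *decrease*.  Monotonicity is
  therefore asserted in the homogeneous regime, the same regime in which
  the DAC-level claims (noise lowers the intercept, reference raises the
  large-distance asymptote) are made — those DAC-level claims themselves
  hold under the decaying ensemble and are asserted there.

Noise and reference enter the model on the covariance scale:
`Σ' = Σ + ε δ_ij + ρ` with ε the per-channel noise *variance* and ρ the
squared reference weight; the synthetic generator's `noise_sd` and
`reference_amplitude` correspond to `√ε` and `√ρ`.

DAC curves are fit with `a·exp(−d²/2s²) + c` by bounded least squares with
amplitude and offset free: the free offset absorbs a reference-induced
asymptote and the free amplitude a noise-induced intercept drop.  Degenerate
flat curves return R² = 0; non-convergence is flagged with NaN rather than
raising.

## Synthetic recordings

The generator produces `data = Z Wᵀ + noise`, with one unit-variance
band-limited time course per source and Gaussian spatial weights, plus
optional white channel noise and a constant-weight common reference.  The
default temporal waveform is a bursty narrowband oscillation: a sinusoidal
carrier at a random frequency in the central 70% of the source band,
multiplied by a rectified low-passed-noise envelope (cutoff min(4 Hz,
bandwidth/3)) and standardized.  This choice is deliberate: band-passed
Gaussian noise has the same second-order structure but is a Gaussian
process, and mixtures of Gaussian sources are not identifiable by any ICA
contrast — source-recovery validation would be impossible by construction.
Bursty narrowband activity is also the more realistic emulation of cortical
oscillations.  The Gaussian-noise waveform remains available
(`waveform="bandpass_noise"`) for covariance-level tests and as an explicit
unidentifiable control.

The reference study configuration (`five_source_study_spec`) places five
sources of equal width (default 1.5 pitches) at four quadrant positions and
the grid center of a 7 × 8, 0.4 mm-pitch grid, amplitudes 1.0–0.8 µV in
steps of 0.05, all in the 20–30 Hz band, with 0.05 µV channel noise
(per-channel SNR far above 10) over 20 s at 500 S/s.  Twenty seconds is
used for source-recovery validation rather than a single 2 s window because
the envelope timescale (≈4 Hz) leaves too few independent envelope states
in 2 s for any ICA contrast to resolve five overlapping maps reliably; the
pipeline itself decomposes 2 s windows exactly as it would real data.

What the generator does **not** emulate: 1/f broadband spectra (sources are
per-band by construction), non-Gaussian spatial profiles, nonstationary
mixing within a window, spatially correlated noise, and volume-conductor
physics beyond the Gaussian-profile abstraction.  Passing tests therefore
show the *analysis chain* is correct and self-consistent, not that real
cortex satisfies the model.

## Decomposition and attribution

Windows are mean-removed, reduced to `n_keep` principal dimensions
(default: the smallest count capturing ≥95% of variance, capped at 20 for
grids up to 32 channels and 30 otherwise), whitened, and rotated by
extended infomax ICA.  The estimated unmixing is symmetrically
decorrelated — projected to the nearest orthogonal rotation in whitened
space — so the whitening identity `WWᵀ = reduced-rank sample covariance`
holds to machine precision rather than approximately; FastICA (cube
contrast) and plain PCA are selectable alternatives, and ICA failure falls
back to PCA with a warning.  Component sign is ambiguous, so each column is
canonicalized with its largest-magnitude weight positive (the spatial fits
require A > 0); components are ordered by descending weight power.

Per-component attribution uses the reduced correlation
`rᶜ_ij = w_ic w_jc / √(Σ_ii Σ_jj)` (full-covariance denominator), whose
distance averages sum exactly to the full DAC.  The drop a component
explains subtracts its zero-distance value (the mean diagonal share); the
summary percentage averages the component's share of the total drop over
distances, excluding distances where the total drop is below 1e-9 in
magnitude (division guard).  The zero-distance point itself is excluded
from the average, since its drop is identically zero.

## Weight-map fits

Each component map is fit to `A·exp(−((x−B)²+(y−C)²)/2D²)+E` by bounded
trust-region least squares in grid-pitch units: A positive, center within
40 pitches of the grid, D between 1 pitch (below which the grid cannot
resolve a width) and 400 pitches (an upper cap the original formulation
leaves open; it prevents numerical escape while still letting flat
gradients resolve to very wide off-grid Gaussians).  Five starts are tried
(four interior quarter points plus the |w|-weighted center of mass) and the
best SSE kept; R² = 1 − SSE/SST with SST about the mean weight, and a
constant map is flagged degenerate with R² = 0.  Maps are fit raw, not
normalized — A absorbs scale.  Note the fitted width of a *weight map*
estimates the component's σ itself; the √2 factor applies to DAC curves,
not weight maps.

Width summaries use the median over fits with R² > 0.7 (the width of a
poorly fit map is not meaningful, and the width distribution is
right-skewed) with a 5,000-resample percentile bootstrap 95% CI, seeded.

After CAR (`C = I − J/N`) every weight column is recentred to zero mean, so
a peaked component's fitted offset E becomes strictly negative — a
diagnostic the pipeline reproduces on synthetic data.

## Reproducibility and problem sizes

All randomness flows from one master seed expanded per stage and window via
`SeedSequence`; reruns with identical manifests are byte-identical.  The
test-suite simulations are sized for a single CPU: forward-model ensembles
use 200 iterations (matching the standard study design), dense-limit checks
use up to 20,000 components on the 10 × 15 grid, and recovery studies use
one 20 s, 56-channel recording per configuration.

## Known limitations

* No EDF writer (reading is supported through MNE); HDF5 and CSV are the
  native formats.
* Coherence (frequency-resolved similarity) is out of scope; the package
  measures time-domain correlation per band.
* The artifact detector is a fixed-threshold rule set, not an adaptive
  classifier.
* ICA on 2 s windows of a single narrow band is inherently limited by the
  few effective samples; component maps vary between adjacent windows, as
  expected for short-window decompositions.
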