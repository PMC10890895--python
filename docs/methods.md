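# Methods

## Measurement model

A measurement is a spectral-temporal TCSPC histogram: counts `y[p, m]` over
`P` spectral channels and `M` uniform time bins, plus an instrument response
function (IRF) `h[p, m]` on the same grid.  The observed decay in a channel
is modelled as the fluorescence impulse response convolved with the IRF plus
a constant bias,

    s[p, m] = (f[p] ∗ h[p])[m] + b[p],    f[p, m] = γ[p] · exp(−t_m / τ[p]),

with discrete causal convolution on the bin grid, output truncated to `M`
bins, decays evaluated at bin centers `t_m = (m + ½)·dt`, and the IRF
normalised to unit sum per channel before fitting.  The bias absorbs dark
counts and fibre background.  With a unit-sum IRF the convolution conserves
the per-channel photon expectation up to the truncated tail (for the slowest
5 ns preset component the loss is below 0.1% of the channel total).

All estimators minimise unweighted sums of squared residuals, matching the
measurement model above rather than a Poisson likelihood; a weighted variant
is deliberately out of scope.

## Single-channel / band estimation (AFL)

`fit_single_decay` estimates `(γ, τ, b)` for one decay by variable
projection: for fixed `τ` the model is linear in `(γ, b)`, which are solved
by linear least squares, so the search runs over `τ` alone.  The profiled
1-D loss is scanned on a 64-point log grid over the box `τ ∈ [dt, 50·dt·M]`,
augmented with three starting points at 0.5×/1×/2× a log-linear fit to the
post-peak tail; the four best candidates are refined by bounded scalar
minimisation (tolerance 1e-10 on `τ`).  This reliably matches a 0.001 ns
brute-force grid search in achieved loss (asserted in the tests at 1e-6).

Exact consequences of the linear profiling, used as test invariants: scaling
the counts by `c` scales `γ` and `b` by `c` and leaves `τ` unchanged;
rescaling `dt` rescales `τ` proportionally.

`fit_afl` aggregates the 160 channels into wide bands — by default the two
40 nm bands 557.13–597.42 nm and 597.93–638.22 nm, kept exactly as printed
with the one-channel gap between them — sums the per-channel IRF over the
same member channels, re-normalises, and fits each band.  A channel belongs
to a band iff `lower ≤ λ ≤ upper`.

`apparent_lifetime_two_component` fits a single exponential (no IRF, no
bias) to a two-component decay `γ_a e^{−t/τ_a} + γ_b e^{−t/τ_b}` on a given
time grid.  It is an analysis oracle, not a data mode: the result lies
strictly between the component lifetimes, nearer the more abundant one, and
is monotone in the abundance ratio — the mechanism that makes the SFL of a
mixture wavelength-dependent.

## Joint spectral estimation (MuFLE)

`fit_mufle` couples all channels through cubic B-splines: `γ(ω)` and `τ(ω)`
are clamped-basis expansions with 3 equidistant internal knots (placed at
the quartile points of the wavelength span), giving 7 basis functions each;
the basis forms a partition of unity at every channel.  The loss is the
global `J₂` above with one free bias per channel.

The optimisation is separable.  For a fixed lifetime curve, profiling the
biases reduces each channel to mean-centered vectors, and the 7 emission
coefficients solve a 7×7 normal system assembled channel-wise (a ridge of
1e-12 guards singular geometry).  The outer search over the 7 lifetime
coefficients uses Nelder–Mead (adaptive simplex, up to 4000 evaluations,
relative loss tolerance 1e-10), seeded by a vectorised 80-point per-channel
lifetime scan projected onto the basis by least squares.  Lifetime curves
dipping below 0.05·dt anywhere are rejected by penalty during the search.

Positivity is not constrained during optimisation (the loss is defined
without constraints); instead the result is validated post-fit and returned
with `valid=False` plus diagnostics when `τ(ω) ≤ 0` at any channel or
`γ(ω) < 0` over more than 5% of channels.

`fit_per_channel` applies `fit_single_decay` independently per channel — the
uncoupled comparator.  Because the spline restricts the per-channel family,
the joint optimum's `J₂` is never below the sum of per-channel optima
(a nesting inequality asserted in the tests), while on noisy
constant-lifetime data the joint SFL has strictly lower cross-channel
variance.

## Preprocessing and quality control

Repeated acquisitions of a location are summed element-wise before any
analysis (exact photon conservation).  A summed histogram passes QC iff its
*peak intensity* — the maximum single (channel, bin) count — is at least the
threshold (default 300).  "Peak" is read as the 2-D maximum, the simplest
interpretation; the boundary is inclusive, so a peak of exactly 300 passes.
The wavelength grid is always taken from the data file and never recomputed:
160 evenly spaced centers over 557.13–638.22 nm imply ≈0.51 nm spacing, and
the module treats spacing as data rather than enforcing a nominal value.

Files use a long-format CSV dialect
(`channel_index,wavelength_nm,bin_index,time_ns,counts`) with a key-value
sidecar for label/group metadata; floats are written as `%.17g` and read
with round-trip precision so write→read is bit-identical.

## Synthetic data

The simulator emulates the study geometry: `P = 160` channels over
557.13–638.22 nm, `M = 490` bins of 0.05 ns, an exponential IRF with a
0.378 ns decay constant shared across channels, and Poisson counting noise
applied cell-wise to the clean expectation.  Each fluorophore has a fixed
lifetime and a monotonically declining emission tail — exponential
`A·exp(−(ω−ω_min)/s)` or hyperbolic `A/(1+(ω−ω_min)/s)` — because the
analysed window sits on the long-wavelength tail of the real fluorophores'
emission under 485 nm excitation.

The three-fluorophore preset uses lifetimes 5, 2 and 0.8 ns.  Amplitudes
and tail scales (2000/60 nm exponential, 1500/80 nm hyperbolic, 3500/18 nm
exponential respectively) are this package's own construction, chosen once
so that the relative abundances cross over inside the window: the short-
lived component declines fastest, so its share falls across the window
while the 5 ns share peaks mid-window, producing an interior SFL extremum
rather than a flat or monotone curve, with clean peak counts of a few
thousand photons (comfortably above the QC threshold).  Background defaults
to zero; the bias term is exercised through a config option.

Cohorts mirror the paired-tissue sampling design: each sample contributes
3–6 locations per arm, each acquired in triplicate.  The abnormal arm
multiplies each fluorophore's amplitude at each location by an independent
factor `1 + shift·u`, `u ~ Uniform(−1, 1)` — heterogeneous abundance
changes with no systematic direction, which alters SFL *shape* more than
mean magnitude — and can additionally offset every lifetime by a constant
(a directional *magnitude* change).  With `shift = 0` and no lifetime
offset the arms are statistically identical.  All randomness derives from
one master seed through counter-indexed `SeedSequence` children, so cohorts
are reproducible histogram by histogram.

What the simulator does **not** emulate: photon-by-photon arrival streams,
detector pile-up, wavelength-dependent IRFs, autofluorescence background
drift, or the spatial/biological heterogeneity of real tissue.  Passing
tests therefore demonstrate correctness of the estimators and statistics
under the stated noise model, not clinical performance.

## Group statistics

**Magnitude.**  `channelwise_ttest` runs a two-sided two-sample Student
t-test per channel between pooled groups (Welch behind a flag), reporting
raw p-values — no multiplicity correction by default, with a correction
available to callers via standard libraries.  Zero-variance channels report
NaN rather than fabricated significance.  `paired_channel_ttest` pairs the
two mean curves at their channels; a constant difference is degenerate and
reported as `p = 1` (zero difference) or `p = 0` (non-zero shift) with a
flag.

**Shape.**  `procrustes_disparity` embeds each curve as `P` points
(channel index scaled to [0, 1], z-scored lifetime) and applies the
standard Procrustes standardisation (zero centroid, unit Frobenius norm,
optimal rotation); the disparity is the residual sum of squares.  The
z-scoring of the lifetime coordinate is a deliberate design choice: a
uniform scale-plus-offset of the lifetime values alone is an *anisotropic*
transform of the raw (channel, lifetime) point set, which
rotation-plus-uniform-scale Procrustes would not remove; z-scoring first
makes the disparity exactly invariant to affine changes of lifetime
magnitude, i.e. a pure shape comparison.  Constant curves are degenerate
and rejected.  The pairwise matrix is symmetric with zero diagonal; group
medians are taken over unordered within-group pairs.

**Power.**  `required_sample_size` searches integers for the smallest
per-group `n` whose exact noncentral-t power (two-sided, equal-variance,
`df = 2n−2`, noncentrality `δ/(σ√(2/n))`) reaches the target.  For a 50 ps
difference, 200 ps spread, α = 0.05 and power 0.8 this gives 253 per group;
the normal-approximation mode gives 252, a documented one-sample
discrepancy at this power boundary.

## Pipeline

`run_pipeline` chains simulate/ingest → replicate summing → QC → MuFLE +
AFL per location → group statistics, from a single declarative YAML
configuration in which every analysis constant (QC threshold, band edges,
window, spline settings) is a default, never hard-coded.  The QC log
accounts for every input (analyzed + excluded = inputs, with reasons); the
run log records per-fit convergence flags and loss values.  All CSVs are
written with a fixed float format, so identical seed and configuration
reproduce every output byte for byte, and reruns are idempotent.

## Problem sizes in tests and the acceptance script

Noiseless recovery, mixture-shape and optimizer-equivalence checks run at
the full 160×490 geometry.  Monte-Carlo and cohort-level checks use reduced
geometries chosen as this package's own test sizes — 32×200 for the 50
variance-comparison histograms, 24×150 for cohort statistics and pipeline
checks, 200 draws for single-channel recovery, 1000 replicates for t-test
calibration — large enough for the asserted tolerances (Monte-Carlo mean
lifetime within 2%, type-I error within 3 standard errors of 5%).

## Known limitations

* Single-exponential-per-channel model only; no multi-exponential unmixing
  (which would require knowing the number of fluorophores a priori).
* Unweighted least squares is mildly inefficient at very low counts
  relative to a Poisson likelihood.
* No sub-bin IRF/decay time-shift parameter is fitted; IRF and data are
  assumed aligned on the same grid.
* Nelder–Mead over 7 coefficients finds the separable problem's optimum
  reliably from the per-channel seed but, like any local method, carries no
  global guarantee for pathological mixtures.
* Procrustes disparity values depend on the embedding convention (channel
  coordinate in [0, 1], z-scored lifetime); comparisons are meaningful
  within this convention, and group-level conclusions are directional.
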