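# sfl — spectral fluorescence lifetime analysis

Tissue autofluorescence carries diagnostic information: naturally occurring
fluorophores (FAD, riboflavin, elastin, ...) each have a characteristic
emission spectrum and fluorescence lifetime, and disease can change their
relative abundance.  Fibre-based time-resolved fluorescence spectrometers
operated in time-correlated single-photon counting (TCSPC) mode record this
as a spectral-temporal histogram `y[p, m]`: photon counts over hundreds of
narrow spectral channels `p` and sub-nanosecond arrival-time bins `m`.

This package analyses such histograms.  It targets the geometry of an
extensively-parallel TRFS measurement — 160 channels spanning
557.13–638.22 nm, 490 bins of 0.05 ns, an exponential instrument response
with a 0.378 ns decay constant — and provides, as a Python library with a
thin `sfl` command-line wrapper:

* **Simulation** of clean and Poisson-noised histograms for known
  fluorophore mixtures, including paired "normal"/"abnormal" cohorts with
  replicate acquisitions and ground truth attached.
* **AFL** (aggregated fluorescence lifetime): channels summed into two
  40 nm bands, one single-exponential lifetime per band — the conventional
  low-spectral-resolution analysis.  The decay model per band is
  `s[m] = (f ∗ h)[m] + b`, `f[m] = γ exp(−t_m/τ)`, with `h` the unit-sum
  instrument response and `(γ, τ, b)` estimated by least squares
  `J₁ = Σ_m (y[m] − s[m])²`.
* **MuFLE / SFL** (multichannel fluorescence lifetime estimation): the
  emission spectrum `γ(ω) = Σᵢ aᵢᵞ Bᵢ(ω)` and lifetime curve
  `τ(ω) = Σᵢ aᵢᵗ Bᵢ(ω)` are cubic B-spline expansions (3 equidistant
  internal knots, 7 basis functions) fitted jointly over all channels by
  minimising `J₂ = Σ_p Σ_m (y[p,m] − s[p,m])²` with a free bias per
  channel.  The fitted `τ(ω)` is the *spectral fluorescence lifetime* (SFL):
  constant for a single fluorophore, wavelength-dependent for mixtures,
  tracking the locally most abundant component.
* **Group statistics**: channel-wise and paired t-tests for SFL magnitude,
  Procrustes shape disparity (magnitude-free) with within-group medians and
  pairwise matrices, and the noncentral-t sample-size computation for a
  two-sample lifetime comparison.
* A **pipeline** (`sfl run`) chaining replicate summing, peak-count quality
  control, both fits, and the group comparison into one seeded,
  byte-reproducible report.

## Worked example

Fit the SFL of a noisy simulated three-fluorophore mixture (lifetimes 0.8,
2 and 5 ns, overlapping declining emission tails) and compare with
independent per-channel fits:

```sh
python examples/03_spectral_lifetime.py
```

```
SFL range: 2.239 - 3.120 ns (components: 0.8, 2, 5 ns)
SFL extremum at channel 113 (614.8 nm): the wavelength where the slow component's relative abundance peaks
cross-channel spread, joint fit:      0.2486 ns
cross-channel spread, per-channel fit: 0.2493 ns
median |joint - per-channel| difference: 0.0117 ns
```

Every channel's apparent lifetime lies between the fastest (0.8 ns) and
slowest (5 ns) component, and the curve peaks where the 5 ns component's
relative abundance is largest — the SFL shape encodes the mixture
composition even though no component's lifetime varies with wavelength.

The cohort example adds the group comparison:

```sh
python examples/04_cohort_statistics.py
```

```
channels with raw p < 0.05: 0 of 24 (abundance shifts move shape more than mean magnitude)
median shape disparity, normal arm:   0.0007
median shape disparity, abnormal arm: 0.0098
higher abnormal-arm disparity = more within-group shape variability
detecting a 50 ps mean difference against a 200 ps spread would need 253 samples per group (alpha 0.05, power 0.8)
```

Heterogeneous abundance perturbations in the abnormal arm barely move the
per-channel mean lifetime but multiply the within-group *shape* variability
— the pattern the shape disparity is designed to expose.

The remaining examples cover simulation (`01`), band aggregation (`02`) and
the end-to-end pipeline (`05`).  The equivalent shell commands are
`sfl simulate`, `sfl qc`, `sfl aggregate`, `sfl fit-afl`, `sfl fit-mufle`,
`sfl power` and `sfl run --config pipeline.yaml`.

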