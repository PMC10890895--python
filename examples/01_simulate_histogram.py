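"""Simulate a spectral-temporal photon histogram of a fluorophore mixture.

Builds the three-fluorophore mixture (lifetimes 0.8, 2 and 5 ns, each with a
monotonically declining emission tail over 557-638 nm), convolves it with the
exponential 0.378 ns instrument response, adds Poisson counting noise, and
prints the geometry and photon budget of the resulting measurement.
"""

import numpy as np

from sfl import (
    SimulationConfig,
    add_poisson_noise,
    clean_histogram,
    emission_profile,
    three_fluor_preset,
)

config = SimulationConfig(seed=1)
specs = three_fluor_preset()
clean = clean_histogram(specs, config)
noisy = add_poisson_noise(clean, seed=config.seed)

print(f"geometry: {noisy.n_channels} channels x {noisy.n_bins} bins "
      f"of {noisy.dt_ns:.2f} ns "
      f"({noisy.wavelengths_nm[0]:.2f}-{noisy.wavelengths_nm[-1]:.2f} nm)")
print(f"peak (channel, bin) count: {noisy.peak_count:.0f} photons")
print(f"total photons: {noisy.total_counts:.3g}")

# Where each fluorophore dominates: the mixture's apparent lifetime follows
# the locally most abundant component.
w = config.wavelengths_nm
shares = np.array([emission_profile(s, w) for s in specs])
shares /= shares.sum(axis=0)
for spec, share in zip(specs, shares):
    peak_ch = int(np.argmax(share))
    print(f"tau={spec.lifetime_ns:.1f} ns component: largest relative "
          f"abundance {share.max():.2f} at {w[peak_ch]:.1f} nm")
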