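"""Aggregated fluorescence lifetime (AFL): the low-resolution view.

Sums the 160 narrow spectral channels into the two standard 40 nm bands
(557.13-597.42 nm and 597.93-638.22 nm) and fits one single-exponential
lifetime per band — the analysis a conventional few-channel instrument would
deliver.  On a mixture the two bands return different lifetimes because the
fluorophores' relative abundances differ between the bands, but all spectral
detail inside each band is lost.
"""

from sfl import (
    SimulationConfig,
    add_poisson_noise,
    clean_histogram,
    exponential_irf,
    fit_afl,
    three_fluor_preset,
)

config = SimulationConfig(seed=7)
irf = exponential_irf(config)
noisy = add_poisson_noise(clean_histogram(three_fluor_preset(), config),
                          seed=config.seed)

for band, fit in fit_afl(noisy, irf).items():
    print(f"band {band}: tau = {fit.tau_ns:.3f} ns, "
          f"intensity = {fit.gamma:.0f}, bias = {fit.bias:.2f} "
          f"(converged={fit.converged})")
print("Both lifetimes sit between the fastest (0.8 ns) and slowest (5 ns)")
print("component: each band reports an abundance-weighted compromise.")
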