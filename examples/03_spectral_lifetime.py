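"""Spectral fluorescence lifetime (SFL) via the joint spline fit (MuFLE).

Fits the emission spectrum gamma(w) and lifetime curve tau(w) of a noisy
three-fluorophore measurement jointly across all 160 channels, each curve a
7-function cubic B-spline.  Compares against independent per-channel fits:
the joint fit tracks the same curve with far less channel-to-channel noise.
"""

import numpy as np

from sfl import (
    SimulationConfig,
    add_poisson_noise,
    clean_histogram,
    exponential_irf,
    fit_mufle,
    fit_per_channel,
    three_fluor_preset,
)

config = SimulationConfig(seed=3)
irf = exponential_irf(config)
noisy = add_poisson_noise(clean_histogram(three_fluor_preset(), config),
                          seed=config.seed)

fit = fit_mufle(noisy, irf)
per_channel = np.array([f.tau_ns for f in fit_per_channel(noisy, irf)])

w = noisy.wavelengths_nm
print(f"SFL range: {fit.sfl_ns.min():.3f} - {fit.sfl_ns.max():.3f} ns "
      f"(components: 0.8, 2, 5 ns)")
peak = int(np.argmax(fit.sfl_ns))
print(f"SFL extremum at channel {peak} ({w[peak]:.1f} nm): the wavelength "
      "where the slow component's relative abundance peaks")
print(f"cross-channel spread, joint fit:      {np.std(fit.sfl_ns):.4f} ns")
print(f"cross-channel spread, per-channel fit: {np.std(per_channel):.4f} ns")
print(f"median |joint - per-channel| difference: "
      f"{np.median(np.abs(fit.sfl_ns - per_channel)):.4f} ns")
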