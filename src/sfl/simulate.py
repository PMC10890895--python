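"""Synthetic spectral-temporal TCSPC data for known fluorophore mixtures.

The generator emulates the measurement geometry of a fibre-based
extensively-parallel TRFS instrument operated in photon-counting mode:
160 spectral channels spanning 557.13-638.22 nm, 490 time bins of 0.05 ns,
an exponential instrument response with a 0.378 ns decay constant, and
Poisson counting noise.  Each simulated fluorophore has a fixed lifetime
and a monotonically declining emission tail (the analysis window sits on
the long-wavelength tail of the real fluorophores' emission), so mixtures
produce a wavelength-dependent apparent lifetime even though every
component lifetime is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .histograms import InstrumentResponse, SpectralTemporalHistogram

__all__ = [
    "FluorophoreSpec",
    "SimulationConfig",
    "CohortSpec",
    "CohortMember",
    "emission_profile",
    "exponential_irf",
    "convolve_causal",
    "clean_histogram",
    "add_poisson_noise",
    "generate_cohort",
    "three_fluor_preset",
    "single_fluor_preset",
]


@dataclass(frozen=True)
class FluorophoreSpec:
    """One simulated fluorophore: an emission tail plus a fixed lifetime.

    ``amplitude`` is the photon scale at the short-wavelength edge of the
    window (where the tail is highest); ``shape_param`` is the wavelength
    scale (nm) over which the tail declines; the lifetime is constant
    across wavelength.
    """

    profile_kind: Literal["exponential_tail", "hyperbolic_tail"]
    amplitude: float
    shape_param: float
    lifetime_ns: float

    def __post_init__(self) -> None:
        if self.profile_kind not in ("exponential_tail", "hyperbolic_tail"):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape_param <= 0:
            raise ValueError("shape_param must be > 0")
        if self.lifetime_ns <= 0:
            raise ValueError("lifetime_ns must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument geometry and acquisition settings for simulation."""

    n_channels: int = 160
    n_bins: int = 490
    dt_ns: float = 0.05
    wavelength_min_nm: float = 557.13
    wavelength_max_nm: float = 638.22
    irf_lifetime_ns: float = 0.378
    background_per_bin: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_bins < 1:
            raise ValueError("n_channels and n_bins must be >= 1")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be > 0")
        if self.wavelength_min_nm >= self.wavelength_max_nm:
            raise ValueError("wavelength range must be non-empty")
        if self.irf_lifetime_ns <= 0:
            raise ValueError("irf_lifetime_ns must be > 0")
        if self.background_per_bin < 0:
            raise ValueError("background_per_bin must be >= 0")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        """Evenly spaced channel centers across the window (inclusive ends)."""
        return np.linspace(
            self.wavelength_min_nm, self.wavelength_max_nm, self.n_channels
        )

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.dt_ns


@dataclass(frozen=True)
class CohortSpec:
    """Paired normal/abnormal cohort layout.

    Each sample contributes 3-6 measured locations per arm; each location is
    acquired in triplicate.  In the abnormal arm each fluorophore's amplitude
    at each location is multiplied by an independent factor
    ``1 + abundance_shift * u`` with ``u ~ Uniform(-1, 1)``, modelling
    heterogeneous changes in relative fluorophore abundance; an optional
    ``lifetime_shift_ns`` additionally offsets every abnormal-arm lifetime.
    """

    n_samples: int
    locations_per_sample: int = 3
    replicates_per_location: int = 3
    abundance_shift: float = 0.0
    lifetime_shift_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 3 <= self.locations_per_sample <= 6:
            raise ValueError("locations_per_sample must be within 3-6")
        if self.replicates_per_location < 1:
            raise ValueError("replicates_per_location must be >= 1")
        if not 0 <= self.abundance_shift <= 1:
            raise ValueError("abundance_shift must be within [0, 1]")


def emission_profile(spec: FluorophoreSpec, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Evaluate a fluorophore's emission tail at the given wavelengths.

    ``exponential_tail``: A * exp(-(w - w_min) / s);
    ``hyperbolic_tail``:  A / (1 + (w - w_min) / s).
    Both are monotonically non-increasing across the window, replicating the
    tail end of real emission spectra under 485 nm excitation.
    """
    w = np.asarray(wavelengths_nm, dtype=float)
    x = (w - w.min()) / spec.shape_param
    if spec.profile_kind == "exponential_tail":
        return spec.amplitude * np.exp(-x)
    return spec.amplitude / (1.0 + x)


def exponential_irf(config: SimulationConfig) -> InstrumentResponse:
    """Single-channel exponential instrument response, normalized to unit sum."""
    t = config.bin_centers_ns
    resp = np.exp(-t / config.irf_lifetime_ns)
    return InstrumentResponse(
        response=resp[None, :], bin_centers_ns=t, normalized=False
    ).normalize()


def convolve_causal(signal: np.ndarray, irf: np.ndarray) -> np.ndarray:
    """Discrete causal convolution on the bin grid, truncated to M bins.

    Both arguments are (P, M) or (M,); the IRF is applied row-wise.  With a
    unit-sum IRF the column-sum (photon expectation) is conserved up to the
    truncated tail beyond the last bin.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    irf = np.atleast_2d(np.asarray(irf, dtype=float))
    if irf.shape[0] == 1 and signal.shape[0] > 1:
        irf = np.broadcast_to(irf, signal.shape)
    m = signal.shape[1]
    full = fftconvolve(signal, irf, mode="full", axes=1)
    out = np.maximum(full[:, :m], 0.0)  # clip FFT round-off below zero
    return out


def clean_histogram(
    specs: Sequence[FluorophoreSpec],
    config: SimulationConfig = SimulationConfig(),
    irf: InstrumentResponse | None = None,
) -> SpectralTemporalHistogram:
    """Noise-free expected histogram of a fluorophore mixture.

    The per-channel signal is the sum over fluorophores of
    ``gamma_f[p] * exp(-t_m / tau_f)``, convolved causally with the (unit-sum)
    instrument response, plus any constant background per bin.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one fluorophore spec")
    if irf is None:
        irf = exponential_irf(config)
    elif not irf.normalized:
        irf = irf.normalize()
    w = config.wavelengths_nm
    t = config.bin_centers_ns
    decay = np.zeros((config.n_channels, config.n_bins))
    for spec in specs:
        gamma = emission_profile(spec, w)
        decay += gamma[:, None] * np.exp(-t / spec.lifetime_ns)[None, :]
    conv = convolve_causal(decay, irf.response)
    return SpectralTemporalHistogram(
        counts=conv + config.background_per_bin,
        wavelengths_nm=w,
        bin_centers_ns=t,
        label="clean",
        group="simulated",
    )


def add_poisson_noise(
    clean: SpectralTemporalHistogram, seed: int
) -> SpectralTemporalHistogram:
    """Perturb each (channel, bin) intensity with Poisson counting noise.

    Each count is drawn Poisson with mean equal to the clean value, so cells
    with zero expected signal stay exactly zero.  Reproducible under a fixed
    seed.
    """
    if np.any(clean.counts < 0):
        raise ValueError("clean intensities must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(clean.counts).astype(float)
    return replace(clean, counts=noisy)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def single_fluor_preset(
    lifetime_ns: float = 2.0, amplitude: float = 3000.0
) -> list[FluorophoreSpec]:
    """One fluorophore with an exponential emission tail — the constant-SFL case."""
    return [
        FluorophoreSpec(
            profile_kind="exponential_tail",
            amplitude=amplitude,
            shape_param=40.0,
            lifetime_ns=lifetime_ns,
        )
    ]


def three_fluor_preset() -> list[FluorophoreSpec]:
    """Three-fluorophore mixture with lifetimes 5, 2 and 0.8 ns.

    The component lifetimes match the simulation narrative; tail shapes and
    amplitudes are chosen so the relative abundances cross over inside the
    557-638 nm window: the short-lived (0.8 ns) component declines fastest,
    so its share of the signal drops across the window while the 5 ns and
    2 ns shares grow, producing an interior extremum in the apparent
    spectral fluorescence lifetime rather than a flat curve.
    """
    return [
        FluorophoreSpec("exponential_tail", amplitude=2000.0, shape_param=60.0,
                        lifetime_ns=5.0),
        FluorophoreSpec("hyperbolic_tail", amplitude=1500.0, shape_param=80.0,
                        lifetime_ns=2.0),
        FluorophoreSpec("exponential_tail", amplitude=3500.0, shape_param=18.0,
                        lifetime_ns=0.8),
    ]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortMember:
    """One measured location: replicate histograms plus the generating truth."""

    sample_id: int
    location_id: int
    arm: Literal["normal", "abnormal"]
    replicates: list[SpectralTemporalHistogram]
    specs: list[FluorophoreSpec]
    true_gamma: np.ndarray  # (n_fluorophores, P) emission at channel centers
    true_tau_ns: np.ndarray  # (n_fluorophores,)

    @property
    def summed(self) -> SpectralTemporalHistogram:
        from .histograms import sum_replicates

        return sum_replicates(self.replicates)


def _child_seed(master: int, counter: int) -> int:
    """Deterministic per-histogram seed: counter-indexed child of the master."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    cohort: CohortSpec,
    base_specs: Sequence[FluorophoreSpec],
    config: SimulationConfig = SimulationConfig(),
) -> list[CohortMember]:
    """Generate a paired normal/abnormal cohort of replicate histograms.

    For every sample the normal arm measures the base mixture and the
    abnormal arm a perturbed mixture (see :class:`CohortSpec`).  Ground
    truth — the per-channel emission of each fluorophore and its lifetime —
    is stored alongside every location.  All randomness (abundance factors,
    Poisson noise) derives from ``config.seed`` through a counter scheme, so
    the cohort is reproducible histogram-by-histogram.
    """
    base_specs = list(base_specs)
    irf = exponential_irf(config)
    w = config.wavelengths_nm
    members: list[CohortMember] = []
    counter = 0
    shift_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xABC,))
    )
    for sample in range(cohort.n_samples):
        for arm in ("normal", "abnormal"):
            for loc in range(cohort.locations_per_sample):
                if arm == "normal":
                    specs = base_specs
                else:
                    u = shift_rng.uniform(-1.0, 1.0, size=len(base_specs))
                    specs = [
                        replace(
                            s,
                            amplitude=s.amplitude
                            * (1.0 + cohort.abundance_shift * ui),
                            lifetime_ns=max(
                                s.lifetime_ns + cohort.lifetime_shift_ns, 1e-3
                            ),
                        )
                        for s, ui in zip(base_specs, u)
                    ]
                clean = clean_histogram(specs, config, irf=irf)
                reps = []
                for rep in range(cohort.replicates_per_location):
                    noisy = add_poisson_noise(clean, _child_seed(config.seed, counter))
                    counter += 1
                    noisy = replace(
                        noisy,
                        label=f"s{sample:02d}_{arm}_loc{loc}_rep{rep}",
                        group=arm,
                    )
                    reps.append(noisy)
                members.append(
                    CohortMember(
                        sample_id=sample,
                        location_id=loc,
                        arm=arm,
                        replicates=reps,
                        specs=specs,
                        true_gamma=np.array(
                            [emission_profile(s, w) for s in specs]
                        ),
                        true_tau_ns=np.array([s.lifetime_ns for s in specs]),
                    )
                )
    return members
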