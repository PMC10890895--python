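"""Synthetic histogram generation: profiles, convolution, noise, cohorts."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from sfl.decay import fit_single_decay
from sfl.histograms import InstrumentResponse
from sfl.simulate import (
    CohortSpec,
    FluorophoreSpec,
    SimulationConfig,
    add_poisson_noise,
    clean_histogram,
    convolve_causal,
    emission_profile,
    exponential_irf,
    generate_cohort,
    single_fluor_preset,
    three_fluor_preset,
)

spec_strategy = st.builds(
    FluorophoreSpec,
    profile_kind=st.sampled_from(["exponential_tail", "hyperbolic_tail"]),
    amplitude=st.floats(1.0, 1e4),
    shape_param=st.floats(5.0, 200.0),
    lifetime_ns=st.floats(0.3, 8.0),
)


class TestEmissionProfile:
    def test_exponential_tail_at_window_edge(self):
        spec = FluorophoreSpec("exponential_tail", 1200.0, 30.0, 2.0)
        w = np.linspace(557.13, 638.22, 160)
        gamma = emission_profile(spec, w)
        assert gamma[0] == pytest.approx(1200.0)

    def test_hyperbolic_half_amplitude_at_shape_param(self):
        spec = FluorophoreSpec("hyperbolic_tail", 800.0, 25.0, 2.0)
        w = np.array([557.13, 557.13 + 25.0, 600.0])
        gamma = emission_profile(spec, w)
        assert gamma[1] == pytest.approx(400.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(spec=spec_strategy)
    def test_tail_is_monotone_nonincreasing(self, spec):
        w = np.linspace(557.13, 638.22, 160)
        gamma = emission_profile(spec, w)
        assert np.all(np.diff(gamma) <= 1e-12)
        assert np.all(gamma >= 0)


class TestCleanHistogram:
    def test_delta_irf_is_convolution_identity(self, small_config):
        delta = np.zeros(small_config.n_bins)
        delta[0] = 1.0
        irf = InstrumentResponse(
            response=delta[None, :],
            bin_centers_ns=small_config.bin_centers_ns,
            normalized=True,
        )
        spec = single_fluor_preset(2.0)[0]
        h = clean_histogram([spec], small_config, irf=irf)
        gamma = emission_profile(spec, small_config.wavelengths_nm)
        expected = gamma[:, None] * np.exp(
            -small_config.bin_centers_ns / 2.0
        )[None, :]
        np.testing.assert_allclose(h.counts, expected, rtol=1e-10)

    def test_linearity_over_fluorophores(self, small_config):
        specs = three_fluor_preset()
        total = clean_histogram(specs, small_config)
        parts = [clean_histogram([s], small_config) for s in specs]
        np.testing.assert_allclose(
            total.counts, np.sum([p.counts for p in parts], axis=0), rtol=1e-9
        )

    def test_default_geometry(self):
        h = clean_histogram(single_fluor_preset(), SimulationConfig())
        assert h.counts.shape == (160, 490)
        assert h.dt_ns == pytest.approx(0.05)
        assert h.wavelengths_nm[0] == pytest.approx(557.13)
        assert h.wavelengths_nm[-1] == pytest.approx(638.22)

    def test_unit_sum_irf_conserves_photon_expectation(self, full_config):
        """Convolution with a unit-sum IRF conserves per-channel totals up to
        the truncated tail (< 0.1%)."""
        irf = exponential_irf(full_config)
        spec = three_fluor_preset()[0]  # slowest decay: worst-case truncation
        gamma = emission_profile(spec, full_config.wavelengths_nm)
        decay = gamma[:, None] * np.exp(
            -full_config.bin_centers_ns / spec.lifetime_ns
        )[None, :]
        conv = convolve_causal(decay, irf.response)
        before = decay.sum(axis=1)
        after = conv.sum(axis=1)
        np.testing.assert_allclose(after, before, rtol=1e-3)

    def test_background_adds_constant(self, small_config):
        cfg = replace(small_config, background_per_bin=7.5)
        h0 = clean_histogram(single_fluor_preset(), small_config)
        h1 = clean_histogram(single_fluor_preset(), cfg)
        np.testing.assert_allclose(h1.counts - h0.counts, 7.5, rtol=1e-9)


class TestPoissonNoise:
    def test_zero_mean_stays_zero(self, toy_histogram):
        h = toy_histogram.with_counts(np.zeros_like(toy_histogram.counts))
        noisy = add_poisson_noise(h, seed=4)
        assert noisy.total_counts == 0

    def test_deterministic_under_seed(self, small_config):
        clean = clean_histogram(single_fluor_preset(), small_config)
        a = add_poisson_noise(clean, seed=99)
        b = add_poisson_noise(clean, seed=99)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_counts_are_nonnegative_integers(self, small_config):
        clean = clean_histogram(three_fluor_preset(), small_config)
        noisy = add_poisson_noise(clean, seed=2)
        assert np.all(noisy.counts >= 0)
        np.testing.assert_array_equal(noisy.counts, np.round(noisy.counts))

    def test_monte_carlo_mean(self, toy_histogram):
        """Mean over many seeded draws of a cell with mean 100 is within 3 SE."""
        h = toy_histogram.with_counts(
            np.full_like(toy_histogram.counts, 100.0)
        )
        n = 10_000
        draws = np.array(
            [add_poisson_noise(h, seed=s).counts[0, 0] for s in range(n)]
        )
        se = np.sqrt(100.0 / n)
        assert abs(draws.mean() - 100.0) < 3 * se


class TestMixtureLifetimeBounds:
    def test_apparent_lifetime_within_component_range(self, small_config):
        """At every channel the apparent single-exponential lifetime of the
        mixture lies between the fastest and slowest component lifetimes."""
        specs = three_fluor_preset()
        irf = exponential_irf(small_config)
        clean = clean_histogram(specs, small_config)
        taus = [s.lifetime_ns for s in specs]
        for p in range(0, small_config.n_channels, 6):
            fit = fit_single_decay(
                clean.counts[p], irf.response[0], small_config.dt_ns
            )
            assert min(taus) <= fit.tau_ns <= max(taus)


class TestCohort:
    def test_location_count_arithmetic(self, small_config):
        cohort = CohortSpec(n_samples=2, locations_per_sample=4)
        members = generate_cohort(cohort, single_fluor_preset(), small_config)
        assert len(members) == 2 * 2 * 4  # samples x arms x locations
        per_arm = sum(1 for m in members if m.arm == "normal")
        assert per_arm == 8
        assert all(len(m.replicates) == 3 for m in members)

    def test_fourteen_sample_bounds(self):
        """14 samples at 3-6 locations give 42-84 locations per arm."""
        for k in (3, 6):
            cohort = CohortSpec(n_samples=14, locations_per_sample=k)
            n_locs = cohort.n_samples * cohort.locations_per_sample
            assert 42 <= n_locs <= 84

    def test_null_cohort_arms_share_truth(self, small_config):
        cohort = CohortSpec(n_samples=2, abundance_shift=0.0)
        members = generate_cohort(cohort, three_fluor_preset(), small_config)
        base_tau = np.array([s.lifetime_ns for s in three_fluor_preset()])
        for m in members:
            np.testing.assert_array_equal(m.true_tau_ns, base_tau)
            np.testing.assert_allclose(
                m.true_gamma,
                members[0].true_gamma,
                rtol=1e-12,
            )

    def test_reproducible_histogram_by_histogram(self, small_config):
        cohort = CohortSpec(n_samples=1, abundance_shift=0.2)
        a = generate_cohort(cohort, three_fluor_preset(), small_config)
        b = generate_cohort(cohort, three_fluor_preset(), small_config)
        for ma, mb in zip(a, b):
            for ra, rb in zip(ma.replicates, mb.replicates):
                np.testing.assert_array_equal(ra.counts, rb.counts)

    def test_lifetime_shift_lowers_apparent_lifetime_everywhere(self, small_config):
        """Lowering every component lifetime lowers the clean-signal apparent
        lifetime at every channel (per-channel fit oracle on clean signals)."""
        irf = exponential_irf(small_config)
        shift = -0.5
        base = three_fluor_preset()
        shifted = [replace(s, lifetime_ns=s.lifetime_ns + shift) for s in base]
        h_base = clean_histogram(base, small_config)
        h_shift = clean_histogram(shifted, small_config)
        for p in range(0, small_config.n_channels, 8):
            tau_base = fit_single_decay(
                h_base.counts[p], irf.response[0], small_config.dt_ns
            ).tau_ns
            tau_shift = fit_single_decay(
                h_shift.counts[p], irf.response[0], small_config.dt_ns
            ).tau_ns
            assert tau_shift < tau_base

    def test_invalid_cohort_specs_rejected(self):
        with pytest.raises(ValueError, match="3-6"):
            CohortSpec(n_samples=2, locations_per_sample=7)
        with pytest.raises(ValueError, match="abundance_shift"):
            CohortSpec(n_samples=2, abundance_shift=1.5)
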