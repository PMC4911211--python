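"""Odds-ratio / module-disease-propensity mapping and distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modincidence import (
    LocusRecord,
    OrDistribution,
    RafDistribution,
    correct_or_distribution,
    gwas_detection_power,
    make_power_model,
    mdp_density,
    mdp_from_or,
    or_from_mdp,
)
from modincidence.genetics import mdp_density_binned

PHI = 0.63


class TestOrMdpMapping:
    def test_null_allele_fixed_point(self):
        for p in (0.05, 0.3, 0.8):
            assert or_from_mdp(PHI, p, PHI) == pytest.approx(1.0, rel=1e-14)
            assert mdp_from_or(1.0, p, PHI) == pytest.approx(PHI, rel=1e-14)

    def test_rare_allele_limits(self):
        # p -> 0: OR -> F/Phi and F -> OR*Phi
        assert or_from_mdp(0.5, 1e-9, PHI) == pytest.approx(0.5 / PHI, rel=1e-6)
        assert mdp_from_or(1.2, 1e-9, PHI) == pytest.approx(1.2 * PHI, rel=1e-6)

    def test_strictly_increasing_in_mdp(self):
        F = np.linspace(0.05, 0.8, 50)
        v = or_from_mdp(F, 0.3, PHI)
        assert np.all(np.diff(v) > 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        F=st.floats(0.01, 0.99),
        p=st.floats(0.01, 0.99),
    )
    def test_round_trip_identity(self, F, p):
        if PHI - (1 - (1 - p) ** 2) * F <= 1e-6:
            return  # outside the joint domain
        v = or_from_mdp(F, p, PHI)
        assert mdp_from_or(v, p, PHI) == pytest.approx(F, abs=1e-12)

    def test_round_trip_on_random_triples(self):
        rng = np.random.default_rng(0)
        F = rng.uniform(0.01, 0.95, 1000)
        p = rng.uniform(0.01, 0.99, 1000)
        ok = PHI - (1 - (1 - p) ** 2) * F > 1e-6
        v = or_from_mdp(F[ok], p[ok], PHI)
        back = mdp_from_or(v, p[ok], PHI)
        assert np.max(np.abs(back - F[ok])) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            or_from_mdp(0.99, 0.9, PHI)  # denominator nonpositive
        with pytest.raises(ValueError):
            mdp_from_or(50.0, 0.01, PHI)  # implied F > 1
        with pytest.raises(ValueError):
            or_from_mdp(0.5, 1.2, PHI)

    def test_cohort_simulation_oracle(self):
        """One-locus cohort: carriers' affected module has propensity F,
        non-carriers' the complementary value that preserves the
        population mean; the 2x2-table odds ratio must match the
        closed-form mapping within Monte-Carlo error."""
        F, p, N = 0.75, 0.3, 12
        q = 1 - (1 - p) ** 2  # carrier fraction
        F_nc = (PHI - q * F) / (1 - q)
        rng = np.random.default_rng(123)
        n = 3 * 10**6
        carrier = rng.random(n) < q
        # affected module permissive draw, remaining N-1 at the mean
        first = rng.random(n) < np.where(carrier, F, F_nc)
        rest = rng.random((n, N - 1)) < PHI
        disease = first & rest.all(axis=1)
        a = np.sum(disease & carrier)
        b = np.sum(~disease & carrier)
        c = np.sum(disease & ~carrier)
        d = np.sum(~disease & ~carrier)
        log_or_mc = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        want = np.log(or_from_mdp(F, p, PHI))
        assert abs(log_or_mc - want) < 3 * se


class TestMdpDensity:
    def test_point_mass_at_unit_or_concentrates_at_phi(self):
        nu = OrDistribution.point_mass(1.0, width=1e-4)
        rho = RafDistribution.beta(2, 2)
        grid = np.linspace(0.55, 0.70, 151)
        g = mdp_density(nu, rho, PHI, grid)
        mass = g.density / g.density.sum()
        cell = grid[np.argmax(g.density)]
        assert abs(cell - PHI) <= (grid[1] - grid[0])
        assert mass.max() > 0.5

    def test_quadrature_matches_monte_carlo_change_of_variables(self):
        nu = OrDistribution.lognormal(1.1, 0.15, lower=1.02)
        rho = RafDistribution.beta(2, 2)
        edges = np.linspace(PHI * 1.005, 0.95, 41)
        g = mdp_density_binned(nu, rho, PHI, edges)
        rng = np.random.default_rng(2)
        n = 10**6
        ors = nu.rvs(n, rng)
        ps = rho.rvs(n, rng)
        # direct change of variables; draws mapping outside (0, 1) fall
        # outside the histogram range and are dropped by both routes
        F = ors * PHI / ((1 - ps) ** 2 + ors * (2 * ps - ps**2))
        hist, _ = np.histogram(F, bins=edges)
        mc = hist / n / np.diff(edges)
        assert np.max(np.abs(mc - g)) / g.max() < 0.02

    def test_density_integrates_to_one(self):
        """With an OR support bounded away from 1 and mapped inside (0,1)
        the implied density is proper."""
        nu = OrDistribution.from_histogram(
            np.geomspace(1.05, 1.5, 21), np.exp(-np.linspace(0, 3, 20))
        )
        rho = RafDistribution.beta(2, 2)
        edges = np.concatenate([
            PHI + np.geomspace(1e-4, 0.02, 25),  # resolve the near-Phi spike
            np.linspace(PHI + 0.025, 0.97, 60),
        ])
        g = mdp_density_binned(nu, rho, PHI, edges, n_sub=7)
        total = float(np.sum(g * np.diff(edges)))
        # small mass sits between Phi and the first edge
        assert total == pytest.approx(1.0, abs=5e-3)

    def test_concentrates_near_phi(self):
        nu = OrDistribution.lognormal(1.1, 0.15, lower=1.02)
        rho = RafDistribution.beta(2, 2)
        grid = np.linspace(0.64, 0.95, 101)
        g = mdp_density(nu, rho, PHI, grid)
        # unimodal and peaked just above Phi
        peak = grid[np.argmax(g.density)]
        assert peak < 0.72
        assert g.density[grid > 0.85].max() < 0.05 * g.density.max()

    def test_unreachable_support_gives_zero_density(self):
        # reachable ORs at x start at x/phi; a support entirely below that
        # contributes nothing, and below phi a support above 1 contributes
        # nothing either
        nu = OrDistribution.from_histogram([1.05, 1.2], [1.0])
        rho = RafDistribution.beta(2, 2)
        g = mdp_density(nu, rho, 0.63, np.array([0.4, 0.62, 0.70, 0.9]))
        assert g.density[0] == 0.0  # below phi
        assert g.density[1] == 0.0  # below phi
        assert g.density[2] > 0.0   # 0.70/0.63 = 1.11 inside the support
        assert g.density[3] == 0.0  # 0.9/0.63 = 1.43 > or_hi: unreachable


class TestPowerCorrection:
    def test_unit_power_is_identity(self):
        raw = OrDistribution.from_histogram([1.0, 1.2, 1.4, 1.6], [0.2, 0.5, 0.3])
        out = correct_or_distribution(raw, lambda v: np.ones_like(np.asarray(v, float)))
        np.testing.assert_allclose(out.weights, raw.weights)

    def test_two_bins_half_and_full_power(self):
        raw = OrDistribution.from_histogram([1.0, 1.1, 1.2], [0.5, 0.5])
        out = correct_or_distribution(
            raw, lambda v: np.where(np.asarray(v) < 1.1, 0.5, 1.0)
        )
        np.testing.assert_allclose(out.weights, [2 / 3, 1 / 3])

    def test_power_increases_with_or_and_raf_sample_size(self):
        assert gwas_detection_power(1.3, 0.3) > gwas_detection_power(1.1, 0.3)
        assert gwas_detection_power(1.2, 0.3, n_cases=50_000) > gwas_detection_power(
            1.2, 0.3, n_cases=5_000
        )

    def test_zero_power_bin_rejected(self):
        raw = OrDistribution.from_histogram([1.0001, 1.001, 1.5], [0.5, 0.5])
        with pytest.raises(ValueError):
            correct_or_distribution(
                raw, lambda v: np.where(np.asarray(v) > 1.1, 1.0, 0.0)
            )

    def test_thinning_round_trip_recovers_truth(self):
        """Sample loci from a known OR distribution, discard each with
        probability 1-power, correct the survivor histogram: the original
        bin masses must be recovered within sampling error."""
        edges = np.geomspace(1.05, 1.6, 11)
        true_w = np.exp(-np.linspace(0.2, 2.2, 10))
        truth = OrDistribution.from_histogram(edges, true_w)
        power = make_power_model(raf=0.3, n_cases=15_000, n_controls=20_000,
                                 alpha=1e-4)
        rng = np.random.default_rng(5)
        n = 10**4
        ors = truth.rvs(n, rng)
        centers = np.sqrt(edges[:-1] * edges[1:])
        # thin with the per-bin power the correction divides by, so the
        # estimator is exactly unbiased and only sampling error remains
        bin_idx = np.clip(np.searchsorted(edges, ors, side="right") - 1, 0, 9)
        keep = rng.random(n) < power(centers)[bin_idx]
        hist, _ = np.histogram(ors[keep], bins=edges)
        corrected = correct_or_distribution(
            OrDistribution.from_histogram(edges, hist), power
        )
        # per-bin multinomial standard error propagated through 1/power
        pw = power(centers)
        se_raw = np.sqrt(np.maximum(hist, 1)) / pw
        se = 3 * se_raw / (hist / pw).sum()
        np.testing.assert_array_less(np.abs(corrected.weights - truth.weights), se + 1e-3)


class TestRecordsAndValidation:
    def test_locus_record_validation(self):
        with pytest.raises(ValueError):
            LocusRecord("x", raf=1.2, or_value=1.1)
        with pytest.raises(ValueError):
            LocusRecord("x", raf=0.3, or_value=-1.0)
        with pytest.raises(ValueError):
            LocusRecord("x", raf=0.3, or_value=1.1, mdp=1.5)

    def test_histogram_distribution_validation(self):
        with pytest.raises(ValueError):
            OrDistribution.from_histogram([1.0, 0.9], [1.0])
        with pytest.raises(ValueError):
            OrDistribution.from_histogram([1.0, 1.1, 1.2], [0.0, 0.0])
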