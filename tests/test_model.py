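"""Free energy, variational residuals, torsion elimination, excluded volume."""

import numpy as np
import pytest

from frenetfold.geometry import FrenetAngles, coords_from_angles
from frenetfold.model import (
    ModelSpec,
    SolitonSegment,
    eliminate_torsion,
    excluded_volume_ok,
    free_energy,
    number_operator,
    variational_residuals,
)

from conftest import random_chain_angles


def brute_force_energy(theta, phi, spec):
    """Independent term-by-term evaluation of the free energy (test oracle)."""
    p = spec.per_site_params()
    e = 0.0
    M = len(theta)
    for i in range(M):
        if i + 1 < M:  # kinetic pair -2θ_{i+1}θ_i + 2θ_i²
            e += -2.0 * theta[i + 1] * theta[i] + 2.0 * theta[i] ** 2
        e += p["lambda_"][i] * (theta[i] ** 2 - p["m"][i] ** 2) ** 2
        if i >= 1:  # torsion defined from the second site on
            e += 0.5 * p["d"][i] * theta[i] ** 2 * phi[i] ** 2
            e += -p["b"][i] * theta[i] ** 2 * phi[i] - p["a"][i] * phi[i]
            e += 0.5 * p["c"][i] * phi[i] ** 2
    return e


class TestFreeEnergy:
    def test_uniform_well_bottom_with_bare_dnls_is_zero(self):
        seg = SolitonSegment(1, 5, lambda_=3.7, m=1.1, a=0, b=0, c=0, d=0)
        spec = ModelSpec(segments=(seg,), n_sites=7)
        angles = FrenetAngles(theta=np.full(5, 1.1), phi=np.zeros(5))
        eb = free_energy(angles, spec, check_excluded_volume=False)
        assert eb.total == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_summed_oracle_on_stated_example(self):
        seg = SolitonSegment(1, 3, lambda_=1, m=1, a=0.1, b=0.2, c=1, d=0.5)
        spec = ModelSpec(segments=(seg,), n_sites=5)
        theta = np.array([0.5, 1.0, 0.5])
        phi = np.array([0.0, 0.2, 0.0])
        eb = free_energy(FrenetAngles(theta=theta, phi=phi), spec, check_excluded_volume=False)
        assert eb.total == pytest.approx(brute_force_energy(theta, phi, spec), abs=1e-12)

    def test_matches_oracle_on_random_multisegment_configs(self, small_model):
        rng = np.random.default_rng(21)
        for _ in range(25):
            theta = rng.uniform(-2, 2, 12)
            phi = rng.uniform(-3, 3, 12)
            eb = free_energy(FrenetAngles(theta=theta, phi=phi), small_model, check_excluded_volume=False)
            assert eb.total == pytest.approx(brute_force_energy(theta, phi, small_model), rel=1e-12)

    def test_hardcore_violation_yields_infinite_sentinel(self):
        # hairpin: two strands brought within 3.0 Å
        theta = np.concatenate([np.full(8, 0.05), [np.pi - 0.05, np.pi - 0.05], np.full(8, 0.05)])
        phi = np.zeros(18)
        spec = ModelSpec(segments=(SolitonSegment(1, 18),), n_sites=20)
        trace = coords_from_angles(FrenetAngles(theta=theta, phi=phi))
        assert not excluded_volume_ok(trace, 3.8)
        eb = free_energy(FrenetAngles(theta=theta, phi=phi), spec)
        assert np.isinf(eb.total)
        assert not eb.excluded_volume_ok
        assert np.isfinite(eb.theta_sector)

    def test_energy_is_extensive_in_chain_length(self):
        """Uniform chains: the energy grows by a fixed per-site amount."""
        def uniform_energy(n):
            seg = SolitonSegment(1, n - 2, lambda_=1.5, m=1.2, a=0.3, b=0.4, c=1.0, d=0.2)
            spec = ModelSpec(segments=(seg,), n_sites=n)
            angles = FrenetAngles(theta=np.full(n - 2, 0.9), phi=np.full(n - 2, 0.7))
            return free_energy(angles, spec, check_excluded_volume=False).total

        e20, e30, e40 = uniform_energy(20), uniform_energy(30), uniform_energy(40)
        assert e30 - e20 == pytest.approx(e40 - e30, rel=1e-12)

    def test_grand_canonical_energy_decreases_with_mu(self, small_model):
        rng = np.random.default_rng(22)
        angles = random_chain_angles(rng, 12)
        eb = free_energy(angles, small_model, check_excluded_volume=False)
        n_val = eb.number_operator_value
        assert n_val > 0
        grand = [eb.total - mu * n_val for mu in (0.0, 0.02, 0.05)]
        assert grand[0] > grand[1] > grand[2]

    def test_length_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            free_energy(FrenetAngles(theta=np.ones(5), phi=np.zeros(5)), small_model)


class TestVariationalResiduals:
    def test_constant_solution_has_zero_residuals(self):
        lam, m, a, b, c, d = 2.0, 1.3, 0.2, 0.4, 1.0, 0.5
        seg = SolitonSegment(1, 10, lambda_=lam, m=m, a=a, b=b, c=c, d=d)
        spec = ModelSpec(segments=(seg,), n_sites=12)
        phi_star = (b * m**2 + a) / (d * m**2 + c)
        # uniform θ = m is stationary for the lattice part; residuals keep the
        # torsion back-reaction, so pick m consistent with it: here simply
        # verify r_φ vanishes and r_θ equals the analytic back-reaction
        angles = FrenetAngles(theta=np.full(10, m), phi=np.full(10, phi_star))
        r_theta, r_phi = variational_residuals(angles, spec)
        assert np.nanmax(np.abs(r_phi)) < 1e-12
        expected = (d * phi_star**2 - 2 * b * phi_star) * m
        assert np.allclose(r_theta[1:-1], expected, atol=1e-12)

    def test_residuals_match_numerical_gradient(self, small_model):
        rng = np.random.default_rng(23)
        h = 1e-6
        for _ in range(10):
            theta = rng.uniform(-2, 2, 12)
            phi = rng.uniform(-3, 3, 12)
            r_theta, r_phi = variational_residuals(FrenetAngles(theta=theta, phi=phi), small_model)

            def energy(th, ph):
                return free_energy(
                    FrenetAngles(theta=th, phi=ph), small_model, check_excluded_volume=False
                ).total

            for i in range(1, 11):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h
                tm[i] -= h
                assert r_theta[i] == pytest.approx((energy(tp, phi) - energy(tm, phi)) / (2 * h), abs=1e-5)
                pp, pm = phi.copy(), phi.copy()
                pp[i] += h
                pm[i] -= h
                assert r_phi[i] == pytest.approx((energy(theta, pp) - energy(theta, pm)) / (2 * h), abs=1e-5)

    def test_end_sites_reported_undefined(self, small_model):
        rng = np.random.default_rng(24)
        r_theta, r_phi = variational_residuals(random_chain_angles(rng, 12), small_model)
        assert np.isnan(r_theta[0]) and np.isnan(r_theta[-1])
        assert np.isnan(r_phi[0])


class TestEliminateTorsion:
    def test_zero_theta_gives_a_over_c(self):
        seg = SolitonSegment(1, 3, a=0.7, b=2.0, c=2.0, d=1.0)
        assert eliminate_torsion(np.zeros(3), seg) == pytest.approx([0.35, 0.35, 0.35])

    def test_b_d_zero_is_theta_independent(self):
        seg = SolitonSegment(1, 3, a=0.6, b=0.0, c=1.5, d=0.0)
        out = eliminate_torsion(np.array([0.1, 1.0, 2.5]), seg)
        assert np.allclose(out, 0.4)

    def test_substitution_zeroes_phi_residual(self, small_model):
        rng = np.random.default_rng(25)
        theta = rng.uniform(-2.5, 2.5, 12)
        p = small_model.per_site_params()
        phi = eliminate_torsion(theta, {k: p[k] for k in ("a", "b", "c", "d")})
        _, r_phi = variational_residuals(FrenetAngles(theta=theta, phi=phi), small_model)
        assert np.nanmax(np.abs(r_phi)) < 1e-13

    def test_elimination_is_torsion_sector_minimum(self):
        seg = SolitonSegment(1, 1, a=0.3, b=0.8, c=1.2, d=0.4)
        theta = np.array([1.4])
        phi_star = float(eliminate_torsion(theta, seg)[0])

        def torsion_energy(phi):
            t2 = theta[0] ** 2
            return 0.5 * seg.d * t2 * phi**2 - seg.b * t2 * phi - seg.a * phi + 0.5 * seg.c * phi**2

        for dphi in (-0.5, -0.01, 0.01, 0.5):
            assert torsion_energy(phi_star + dphi) > torsion_energy(phi_star)

    def test_nonpositive_denominator_rejected(self):
        seg = SolitonSegment(1, 3, c=-1.0, d=0.0)
        with pytest.raises(ValueError):
            eliminate_torsion(np.zeros(3), seg)


class TestNumberOperator:
    def test_zero_field_gives_zero(self):
        angles = FrenetAngles(theta=np.zeros(10), phi=np.zeros(10))
        assert number_operator(angles, (3, 5, 7)) == 0.0

    def test_helical_histidines_sum_arithmetic(self):
        angles = FrenetAngles(theta=np.full(20, 1.55), phi=np.zeros(20))
        assert number_operator(angles, range(1, 13)) == pytest.approx(12 * 1.55**2)

    def test_empty_site_set(self):
        angles = FrenetAngles(theta=np.ones(10), phi=np.zeros(10))
        assert number_operator(angles, ()) == 0.0

    def test_out_of_range_site_raises(self):
        angles = FrenetAngles(theta=np.ones(10), phi=np.zeros(10))
        with pytest.raises(IndexError):
            number_operator(angles, (11,))


class TestExcludedVolume:
    def test_ideal_helix_is_self_avoiding(self, ideal_helix):
        assert excluded_volume_ok(ideal_helix, 3.8)

    def test_two_residue_chain_vacuously_ok(self):
        from frenetfold.geometry import CalphaTrace

        trace = CalphaTrace(positions=np.array([[0, 0, 0], [1, 0, 0]], float))
        assert excluded_volume_ok(trace, 3.8)


class TestModelSpecValidation:
    def test_segments_must_tile_defined_sites(self):
        with pytest.raises(ValueError):
            ModelSpec(segments=(SolitonSegment(1, 4), SolitonSegment(6, 8)), n_sites=10)
        with pytest.raises(ValueError):
            ModelSpec(segments=(SolitonSegment(2, 8),), n_sites=10)

    def test_titratable_sites_must_be_defined(self):
        with pytest.raises(ValueError):
            ModelSpec(segments=(SolitonSegment(1, 8),), n_sites=10, titratable_sites=(9,))

    def test_yaml_roundtrip(self, small_model):
        assert ModelSpec.from_yaml(small_model.to_yaml()) == small_model

    def test_yaml_rejects_unknown_format(self):
        with pytest.raises(ValueError, match="format"):
            ModelSpec.from_yaml("format: something-else/9\nsegments: []\n")
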