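"""Glauber sampler: acceptance rule, balance, trajectories, averages."""

import numpy as np
import pytest

from frenetfold.ensemble import (
    SamplerState,
    ScheduleSpec,
    ensemble_average,
    glauber_probability,
    mc_sweep,
    run_trajectory,
)
from frenetfold.geometry import FrenetAngles, angles_from_coords
from frenetfold.io_fixtures import make_ideal_helix
from frenetfold.model import ModelSpec, SolitonSegment, free_energy
from frenetfold.decoy_fit import rmsd_superposed
from frenetfold.geometry import coords_from_angles


class TestGlauberProbability:
    def test_symmetric_point(self):
        assert glauber_probability(0.0, 3.7) == 0.5

    def test_zero_temperature_limits(self):
        assert glauber_probability(1.0, 1e6) == pytest.approx(0.0, abs=1e-12)
        assert glauber_probability(-1.0, 1e6) == pytest.approx(1.0, abs=1e-12)

    def test_infinite_cost_always_rejected(self):
        assert glauber_probability(np.inf, 1.0) == 0.0
        assert glauber_probability(np.inf, 0.0) == 0.0

    def test_detailed_balance_identity(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            delta = rng.uniform(-5, 5)
            beta = rng.uniform(0, 10)
            ratio = glauber_probability(delta, beta) / glauber_probability(-delta, beta)
            assert ratio == pytest.approx(np.exp(-beta * delta), rel=1e-10)

    def test_beta_zero_accepts_half(self):
        rng = np.random.default_rng(42)
        assert np.allclose(glauber_probability(rng.uniform(-9, 9, 50), 0.0), 0.5)


def _helix_state(n=30, mu=0.0, titratable=()):
    trace = make_ideal_helix(n)
    angles = angles_from_coords(trace)
    spec = ModelSpec(
        segments=(SolitonSegment(1, n - 2, lambda_=1.0, m=1.55, a=-0.3, b=0.5),),
        n_sites=n,
        titratable_sites=titratable,
    )
    return SamplerState.from_angles(angles, spec, mu=mu), spec


class TestSweep:
    def test_energy_cache_and_hard_core_invariant(self):
        state, spec = _helix_state()
        rng = np.random.default_rng(43)
        for beta in (0.5, 2.0, 20.0):
            for _ in range(5):
                state, _ = mc_sweep(state, spec, beta, rng, debug=True)  # raises on drift

    def test_beta_zero_acceptance_near_half(self):
        # short chain, narrow proposals: hard-core rejections are rare, so
        # the Glauber factor alone sets the rate
        state, spec = _helix_state(n=8)
        rng = np.random.default_rng(44)
        fracs = [
            mc_sweep(state, spec, 0.0, rng, sigma_theta=0.05, sigma_phi=0.05)[1]
            for _ in range(300)
        ]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.03)

    def test_low_temperature_keeps_native_profile(self, two_kink_decoy):
        trace, angles, spec = two_kink_decoy
        state = SamplerState.from_angles(angles, spec, mu=0.0)
        rng = np.random.default_rng(45)
        acc = 0.0
        for _ in range(100):
            state, frac = mc_sweep(state, spec, 1e6, rng)
            acc += frac
        assert acc / 100 < 0.02  # essentially no uphill acceptance
        assert rmsd_superposed(state.trace, trace) < 0.1

    def test_chemical_potential_enters_acceptance(self):
        state0, spec0 = _helix_state(n=20, mu=0.0, titratable=(5, 10, 15))
        state1, _ = _helix_state(n=20, mu=0.5, titratable=(5, 10, 15))
        spec = spec0
        r0, r1 = np.random.default_rng(46), np.random.default_rng(46)
        for _ in range(30):
            state0, _ = mc_sweep(state0, spec, 5.0, r0)
            state1, _ = mc_sweep(state1, spec, 5.0, r1)
        # positive μ rewards large θ² at the titratable sites
        assert not np.array_equal(state0.theta, state1.theta)

    def test_cached_energy_matches_free_energy_after_sweeps(self):
        state, spec = _helix_state(n=25)
        rng = np.random.default_rng(47)
        for _ in range(50):
            state, _ = mc_sweep(state, spec, 2.0, rng)
        eb = free_energy(state.angles, spec)
        assert eb.excluded_volume_ok
        assert state.f_total == pytest.approx(eb.total, abs=1e-7)


class TestTrajectories:
    def test_identical_seeds_are_bit_identical(self, two_kink_decoy):
        trace, angles, spec = two_kink_decoy
        sched = ScheduleSpec.geometric(50.0, 1.0, 4, sweeps_per_rung=60,
                                       hold_sweeps_at_extremes=60, seed=9)
        rec1 = run_trajectory(SamplerState.from_angles(angles, spec), spec, sched)
        rec2 = run_trajectory(SamplerState.from_angles(angles, spec), spec, sched)
        assert rec1.table.equals(rec2.table)
        assert np.array_equal(rec1.final_angles.theta, rec2.final_angles.theta)

    def test_heating_expands_and_disorders(self, two_kink_decoy):
        trace, angles, spec = two_kink_decoy
        sched = ScheduleSpec.geometric(100.0, 0.5, 8, sweeps_per_rung=300,
                                       hold_sweeps_at_extremes=300, seed=10)
        rec = run_trajectory(SamplerState.from_angles(angles, spec), spec, sched)
        tab = rec.table
        assert tab["rg_mean"].iloc[-1] > tab["rg_mean"].iloc[0]
        assert tab["qalpha_mean"].iloc[-1] < tab["qalpha_mean"].iloc[0]

    def test_cycle_schedule_walks_ladder_both_ways(self):
        sched = ScheduleSpec(beta_ladder=(10.0, 5.0, 2.0), direction="cycle",
                             sweeps_per_rung=10, hold_sweeps_at_extremes=20)
        rungs = sched.rungs()
        betas = [b for b, _ in rungs]
        assert betas == [10.0, 5.0, 2.0, 5.0, 10.0]
        assert rungs[2][1] == 20 and rungs[-1][1] == 20  # holds at both extremes

    def test_ladder_direction_validated(self):
        with pytest.raises(ValueError):
            ScheduleSpec(beta_ladder=(1.0, 2.0), direction="heat")
        with pytest.raises(ValueError):
            ScheduleSpec(beta_ladder=(2.0, 1.0), direction="cool")
        with pytest.raises(ValueError):
            ScheduleSpec(beta_ladder=(1.0,), direction="sideways")

    def test_per_segment_torsion_series_recorded(self, two_kink_decoy):
        trace, angles, spec = two_kink_decoy
        sched = ScheduleSpec.geometric(50.0, 10.0, 2, sweeps_per_rung=40,
                                       hold_sweeps_at_extremes=0, seed=11)
        rec = run_trajectory(
            SamplerState.from_angles(angles, spec), spec, sched,
            segments_for_phi={"h1": (3, 18)},
        )
        assert "phi_h1_mean" in rec.table.columns
        assert rec.table["phi_h1_mean"].iloc[0] == pytest.approx(0.9, abs=0.2)


class TestEnsembleAverage:
    def test_constant_series(self):
        mean, stderr, tau = ensemble_average(np.full(100, 3.25), burn_in=0.0)
        assert mean == 3.25 and stderr == 0.0

    def test_iid_gaussian_stderr(self):
        rng = np.random.default_rng(48)
        x = rng.normal(2.0, 1.0, 4000)
        mean, stderr, tau = ensemble_average(x, burn_in=0.0)
        assert mean == pytest.approx(2.0, abs=0.1)
        assert stderr == pytest.approx(1.0 / np.sqrt(4000), rel=0.35)

    def test_autocorrelated_series_inflates_stderr(self):
        rng = np.random.default_rng(49)
        n, rho = 4000, 0.95
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.normal()
        mean, stderr, tau = ensemble_average(x, burn_in=0.0)
        naive = np.std(x, ddof=1) / np.sqrt(n)
        assert stderr > 2 * naive
        assert tau > 4

    def test_burn_in_discards_prefix(self):
        x = np.concatenate([np.full(50, 100.0), np.full(50, 1.0)])
        mean, _, _ = ensemble_average(x, burn_in=0.5)
        assert mean == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average(np.array([1.0]), burn_in=0.5)


class TestDiscreteToyChainBalance:
    """Glauber long-run frequencies vs exact Boltzmann on a tiny state space."""

    def test_marginal_matches_enumeration(self):
        # 2 interior sites, 3×3 (θ, φ) grid each -> 81 joint states, exactly
        # enumerable; the acceptance suite runs the larger 3-site 5×5 version
        from frenetfold.geometry import FrenetAngles

        thetas = np.linspace(1.2, 1.9, 3)
        phis = np.linspace(0.5, 1.3, 3)
        n = 4
        spec = ModelSpec(segments=(SolitonSegment(1, 2, lambda_=1.0, m=1.55, a=-0.3, b=0.5),),
                         n_sites=n)
        beta = 1.5
        states = [(i1, j1, i2, j2) for i1 in range(3) for j1 in range(3)
                  for i2 in range(3) for j2 in range(3)]
        energies = {}
        for s in states:
            th = np.array([thetas[s[0]], thetas[s[2]]])
            ph = np.array([phis[s[1]], phis[s[3]]])
            eb = free_energy(FrenetAngles(theta=th, phi=ph), spec)
            energies[s] = eb.total
        finite = {s: e for s, e in energies.items() if np.isfinite(e)}
        e0 = min(finite.values())
        weights = {s: np.exp(-beta * (e - e0)) for s, e in finite.items()}
        z = sum(weights.values())
        exact_marginal = np.zeros((3, 3))
        for s, w in weights.items():
            exact_marginal[s[0], s[1]] += w / z

        rng = np.random.default_rng(50)
        state = (1, 1, 1, 1)
        counts = np.zeros((3, 3))
        n_steps = 120_000
        samples = np.empty(n_steps, dtype=int)
        for t in range(n_steps):
            site = rng.integers(2)
            cand = list(state)
            cand[2 * site] = rng.integers(3)
            cand[2 * site + 1] = rng.integers(3)
            cand = tuple(cand)
            delta = energies[cand] - energies[state]
            if rng.random() < glauber_probability(delta, beta):
                state = cand
            counts[state[0], state[1]] += 1
            samples[t] = state[0] * 3 + state[1]
        freq = counts / n_steps
        # batch-means standard error per bin
        nb = 40
        batch = samples[: nb * (n_steps // nb)].reshape(nb, -1)
        for i in range(3):
            for j in range(3):
                ind = (batch == i * 3 + j).mean(axis=1)
                se = ind.std(ddof=1) / np.sqrt(nb)
                assert abs(freq[i, j] - exact_marginal[i, j]) < 3 * se + 1e-3
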