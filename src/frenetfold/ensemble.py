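"""Grand-canonical Glauber Monte Carlo over backbone (θ, φ) angles.

States are weighted by exp(-β(F - μN)) with F the multi-soliton free
energy and N = Σ θ² over the titratable sites.  Single-site symmetric
Gaussian proposals are accepted with the Glauber probability

    P(Δ) = e^{-βΔ} / (1 + e^{-βΔ}),        Δ = Δ(F - μN),

which satisfies detailed balance and models pure relaxation dynamics.
Hard-core excluded-volume violations have Δ = +∞ and are rejected.

Unfolding/folding trajectories walk a β ladder adiabatically (many sweeps
per rung, long holds at the extremes for full thermalisation) while
recording post-burn-in observable averages per rung.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import CalphaTrace, FrenetAngles
from .model import EnergyBreakdown, ModelSpec, free_energy
from .observables import HelixCriterion, helical_content, radius_of_gyration, segment_torsion_average

__all__ = [
    "ScheduleSpec",
    "SamplerState",
    "TrajectoryRecord",
    "glauber_probability",
    "mc_sweep",
    "run_trajectory",
    "ensemble_average",
]


def glauber_probability(delta, beta):
    """Glauber acceptance e^{-βΔ}/(1+e^{-βΔ}); Δ = +∞ maps to 0."""
    delta = np.asarray(delta, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        x = beta * delta
        p = np.where(
            np.isposinf(delta), 0.0, 1.0 / (1.0 + np.exp(np.clip(x, -700, 700)))
        )
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class ScheduleSpec:
    """Adiabatic β ladder for heating/cooling trajectories.

    ``beta_ladder`` is listed cold→hot (decreasing β) for ``direction``
    'heat', hot→cold for 'cool'; 'cycle' walks the heat ladder, holds at
    the hot extreme, then walks it back.
    """

    beta_ladder: tuple
    sweeps_per_rung: int = 200
    hold_sweeps_at_extremes: int = 400
    proposal_sigma_theta: float = 0.1
    proposal_sigma_phi: float = 0.3
    seed: int = 0
    direction: str = "heat"

    def __post_init__(self):
        ladder = tuple(float(b) for b in self.beta_ladder)
        object.__setattr__(self, "beta_ladder", ladder)
        if len(ladder) < 1:
            raise ValueError("empty beta ladder")
        diffs = np.diff(ladder)
        if self.direction == "heat" and not np.all(diffs < 0):
            raise ValueError("heating ladder must have strictly decreasing β")
        if self.direction == "cool" and not np.all(diffs > 0):
            raise ValueError("cooling ladder must have strictly increasing β")
        if self.direction == "cycle" and not np.all(diffs < 0):
            raise ValueError("cycle ladder is given cold→hot (strictly decreasing β)")
        if self.direction not in ("heat", "cool", "cycle"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.proposal_sigma_theta <= 0 or self.proposal_sigma_phi <= 0:
            raise ValueError("proposal widths must be positive")

    @classmethod
    def geometric(
        cls,
        beta_cold: float,
        beta_hot: float,
        n_rungs: int,
        direction: str = "heat",
        **kwargs,
    ) -> "ScheduleSpec":
        """Geometrically spaced ladder between β_cold and β_hot."""
        ladder = np.geomspace(beta_cold, beta_hot, n_rungs)
        if direction == "cool":
            ladder = ladder[np.argsort(ladder)]
        return cls(beta_ladder=tuple(ladder), direction=direction, **kwargs)

    def rungs(self):
        """(β, extra_hold_sweeps) in simulation order."""
        ladder = list(self.beta_ladder)
        if self.direction in ("heat", "cool"):
            out = [(b, 0) for b in ladder]
            out[-1] = (ladder[-1], self.hold_sweeps_at_extremes)
            return out
        out = [(b, 0) for b in ladder]
        out[-1] = (ladder[-1], self.hold_sweeps_at_extremes)
        out += [(b, 0) for b in reversed(ladder[:-1])]
        out[-1] = (ladder[0], self.hold_sweeps_at_extremes)
        return out


@dataclass
class SamplerState:
    """Mutable sampler state with cached coordinates, frames and energy."""

    theta: np.ndarray
    phi: np.ndarray
    mu: float
    spec: ModelSpec
    pos: np.ndarray = field(repr=False, default=None)
    frames: np.ndarray = field(repr=False, default=None)
    f_total: float = np.nan  # free energy F (finite part)
    n_value: float = np.nan  # Σ_his θ²

    @classmethod
    def from_angles(cls, angles: FrenetAngles, spec: ModelSpec, mu: float = 0.0) -> "SamplerState":
        st = cls(theta=np.array(angles.theta, dtype=float), phi=np.array(angles.phi, dtype=float), mu=float(mu), spec=spec)
        st.resync()
        eb = free_energy(st.angles, spec)
        if not eb.excluded_volume_ok:
            raise ValueError("initial state violates excluded volume")
        return st

    @property
    def angles(self) -> FrenetAngles:
        return FrenetAngles(
            theta=self.theta.copy(), phi=self.phi.copy(), bond_length=self.spec.bond_length
        )

    @property
    def trace(self) -> CalphaTrace:
        return CalphaTrace(positions=self.pos.copy())

    @property
    def grand_energy(self) -> float:
        """F - μN of the cached state."""
        return self.f_total - self.mu * self.n_value

    def resync(self) -> None:
        """Recompute coordinates, frames and cached energies from angles."""
        M = len(self.theta)
        if self.pos is None:
            self.pos = np.empty((M + 2, 3))
            self.frames = np.empty((M + 1, 3, 3))
        _kernels.propagate(self.theta, self.phi, self.spec.bond_length, self.pos, self.frames)
        eb = free_energy(self.angles, self.spec, check_excluded_volume=False)
        self.f_total = eb.total
        self.n_value = eb.number_operator_value

    def energy_breakdown(self) -> EnergyBreakdown:
        return free_energy(self.angles, self.spec)


def mc_sweep(
    state: SamplerState,
    spec: ModelSpec,
    beta: float,
    rng: np.random.Generator,
    *,
    sigma_theta: float = 0.1,
    sigma_phi: float = 0.3,
    debug: bool = False,
) -> tuple[SamplerState, float]:
    """One sweep of single-site Glauber updates in random site order.

    Mutates ``state`` in place (and returns it) for speed; the cached
    energy is updated incrementally.  With ``debug=True`` the cache is
    cross-checked against a full recomputation after the sweep.
    """
    M = len(state.theta)
    p = spec.per_site_params()
    order = rng.permutation(M).astype(np.int64)
    normals = rng.standard_normal((M, 2))
    uniforms = rng.random(M)
    moved = np.empty((M + 2, 3))
    n_acc, dF, dN = _kernels.sweep(
        state.theta,
        state.phi,
        state.pos,
        state.frames,
        p["lambda_"],
        p["m"],
        p["a"],
        p["b"],
        p["c"],
        p["d"],
        spec.titratable_mask(),
        state.mu,
        float(beta),
        spec.bond_length,
        spec.excluded_radius,
        float(sigma_theta),
        float(sigma_phi),
        order,
        normals,
        uniforms,
        moved,
    )
    state.f_total += dF
    state.n_value += dN
    if debug:
        eb = free_energy(state.angles, spec)
        if not eb.excluded_volume_ok:
            raise AssertionError("excluded volume violated by an accepted state")
        if abs(eb.total - state.f_total) > 1e-8 * max(1.0, abs(eb.total)):
            raise AssertionError(
                f"energy cache drift: cached {state.f_total}, exact {eb.total}"
            )
        state.f_total = eb.total
        state.n_value = eb.number_operator_value
    return state, n_acc / M


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-rung observable averages of one heating/cooling trajectory."""

    table: pd.DataFrame
    schedule: ScheduleSpec
    mu: float
    seed: int
    final_angles: FrenetAngles


def run_trajectory(
    start: SamplerState,
    spec: ModelSpec,
    schedule: ScheduleSpec,
    observables: Sequence[str] = ("rg", "qalpha"),
    *,
    segments_for_phi: dict | None = None,
    burn_in: float = 0.5,
    sample_every: int = 1,
    debug: bool = False,
) -> TrajectoryRecord:
    """Walk the β ladder, recording post-burn-in means per rung.

    Fully reproducible from ``schedule.seed``; the sampler state is
    resynchronised (frames re-orthonormalised, energy recomputed) at every
    rung so numerical drift cannot accumulate.
    """
    rng = np.random.default_rng(schedule.seed)
    state = start
    criterion = HelixCriterion()
    rows = []
    for rung_index, (beta, extra_hold) in enumerate(schedule.rungs()):
        state.resync()
        n_sweeps = schedule.sweeps_per_rung + extra_hold
        n_burn = int(burn_in * n_sweeps)
        series = {name: [] for name in observables}
        seg_series = {name: [] for name in (segments_for_phi or {})}
        acc = 0.0
        for s in range(n_sweeps):
            state, frac = mc_sweep(
                state,
                spec,
                beta,
                rng,
                sigma_theta=schedule.proposal_sigma_theta,
                sigma_phi=schedule.proposal_sigma_phi,
                debug=debug,
            )
            acc += frac
            if s >= n_burn and (s - n_burn) % sample_every == 0:
                if "rg" in series:
                    series["rg"].append(_rg_from_positions(state.pos))
                if "qalpha" in series:
                    series["qalpha"].append(
                        helical_content(state.angles, criterion)
                    )
                if "energy" in series:
                    series["energy"].append(state.grand_energy)
                for name, (lo, hi) in (segments_for_phi or {}).items():
                    seg_series[name].append(
                        segment_torsion_average(state.angles, {name: (lo, hi)})[name][0]
                    )
        row = {
            "rung": rung_index,
            "beta": beta,
            "T": 1.0 / beta,
            "mu": state.mu,
            "acceptance": acc / n_sweeps,
            "n_sweeps": n_sweeps,
        }
        for name, vals in series.items():
            mean, stderr, tau = ensemble_average(np.asarray(vals), burn_in=0.0)
            row[f"{name}_mean"] = mean
            row[f"{name}_stderr"] = stderr
        for name, vals in seg_series.items():
            row[f"phi_{name}_mean"] = _circular_mean(np.asarray(vals))
        rows.append(row)
    return TrajectoryRecord(
        table=pd.DataFrame(rows),
        schedule=schedule,
        mu=state.mu,
        seed=schedule.seed,
        final_angles=state.angles,
    )


def _rg_from_positions(pos: np.ndarray) -> float:
    centred = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def _circular_mean(x: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * x))))


def ensemble_average(samples, burn_in: float = 0.5, n_batches: int = 20):
    """Mean, batch-means standard error and autocorrelation-time estimate.

    The standard error uses batch means (``n_batches`` batches) so it is
    inflated by the integrated autocorrelation time τ relative to the
    naive σ/√n; τ is estimated as the ratio of the two variances.
    """
    x = np.asarray(samples, dtype=float)
    n0 = int(len(x) * burn_in)
    x = x[n0:]
    n = len(x)
    if n < 2:
        raise ValueError("series too short after burn-in")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        return mean, 0.0, 1.0
    nb = min(n_batches, n)
    batch_size = n // nb
    batches = x[: nb * batch_size].reshape(nb, batch_size).mean(axis=1)
    bvar = float(np.var(batches, ddof=1)) if nb > 1 else var
    stderr = float(np.sqrt(bvar / nb))
    tau = max(1.0, bvar * batch_size / var)
    return mean, stderr, tau
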