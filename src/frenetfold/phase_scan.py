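"""(T, μ) phase-diagram orchestration, transition detection, T calibration.

A phase grid is built from independent heating trajectories: at each μ the
sampler walks the temperature ladder from the native state, and the
post-burn-in observable means per rung fill one grid column; pooling over
trajectories gives per-cell means and standard errors of ⟨Rg⟩ and ⟨Qα⟩.

Transition lines are located on one-dimensional cuts: slope-change points
(breaks in d⟨Rg⟩/dμ) as outliers of the second finite difference, and
discontinuous (jump-like) transitions as outliers of the first difference
over both the propagated sampling noise and an absolute floor.  Region
labels follow the molten-globule scheme N / F / I_b / I_a / U with the
termination of the I_a–I_b jump line reported as the tricritical-point
estimate.

Simulation temperature is related to Celsius by an affine map in
log T_sim fixed by matching the midpoint and 10–90% width of the
simulated melting curve ⟨Qα⟩(T_sim) to a reference helicity-vs-°C curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import SamplerState, ScheduleSpec, run_trajectory
from .geometry import FrenetAngles
from .model import ModelSpec

__all__ = [
    "PhaseGrid",
    "Breakpoint",
    "TemperatureCalibration",
    "scan_grid",
    "detect_breakpoints",
    "calibrate_temperature",
    "classify_regions",
    "write_grid",
    "read_grid",
]

REGION_ORDER = ("N", "F", "I_b", "I_a")  # along increasing μ at low T; U overlays


@dataclass
class PhaseGrid:
    """Ensemble averages on a (T, μ) lattice with uncertainties."""

    t_values: np.ndarray  # simulation temperature, shape (nT,)
    mu_values: np.ndarray  # shape (nM,)
    rg_mean: np.ndarray  # (nT, nM)
    rg_stderr: np.ndarray
    qalpha_mean: np.ndarray
    qalpha_stderr: np.ndarray
    n_traj: np.ndarray  # (nT, nM) int
    mask: np.ndarray  # (nT, nM) bool, True = valid cell
    labels: np.ndarray | None = None  # (nT, nM) of str, optional
    t_celsius: np.ndarray | None = None
    tricritical_t: float | None = None
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        nT, nM = len(self.t_values), len(self.mu_values)
        for name in ("rg_mean", "rg_stderr", "qalpha_mean", "qalpha_stderr", "n_traj", "mask"):
            arr = getattr(self, name)
            if np.asarray(arr).shape != (nT, nM):
                raise ValueError(f"{name} must have shape ({nT}, {nM})")

    def is_complete(self) -> bool:
        return bool(np.all(self.mask))


def scan_grid(
    spec: ModelSpec,
    T_list,
    mu_list,
    schedule: ScheduleSpec,
    n_traj: int = 4,
    seed: int = 0,
    *,
    start_angles: FrenetAngles | None = None,
) -> PhaseGrid:
    """Fill a (T, μ) grid from independent heating trajectories.

    ``schedule`` supplies the per-rung sweep counts and proposal widths;
    its β ladder is replaced by the one implied by ``T_list`` (ascending
    T).  ``start_angles`` is the native multi-soliton profile the
    trajectories heat up from (typically a fit result).  Deterministic
    for fixed ``seed``; trajectories that fail leave their column masked
    with the failure recorded in the manifest.
    """
    if start_angles is None:
        raise ValueError("scan_grid needs the native start_angles (e.g. a fit result)")
    T = np.sort(np.asarray(list(T_list), dtype=float))
    mus = np.asarray(list(mu_list), dtype=float)
    if len(T) == 0 or len(mus) == 0:
        raise ValueError("empty T or μ list")
    ladder = tuple(1.0 / T)  # decreasing β = heating
    nT, nM = len(T), len(mus)
    shape = (nT, nM)
    rg_sum = np.zeros(shape)
    rg_sq = np.zeros(shape)
    q_sum = np.zeros(shape)
    q_sq = np.zeros(shape)
    rg_within = np.zeros(shape)
    q_within = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    failures = []
    child_seeds = np.random.SeedSequence(seed).generate_state(nM * n_traj) % (2**31)
    for im, mu in enumerate(mus):
        for it_traj in range(n_traj):
            traj_seed = int(child_seeds[im * n_traj + it_traj])
            sched = ScheduleSpec(
                beta_ladder=ladder,
                sweeps_per_rung=schedule.sweeps_per_rung,
                hold_sweeps_at_extremes=schedule.hold_sweeps_at_extremes,
                proposal_sigma_theta=schedule.proposal_sigma_theta,
                proposal_sigma_phi=schedule.proposal_sigma_phi,
                seed=traj_seed,
                direction="heat",
            )
            try:
                state = SamplerState.from_angles(start_angles, spec, mu=mu)
                rec = run_trajectory(state, spec, sched)
            except Exception as exc:  # failed cells are masked, not fatal
                failures.append({"mu": float(mu), "traj": it_traj, "error": str(exc)})
                continue
            tab = rec.table.iloc[:nT]  # hold rows share the last rung index
            rg = tab["rg_mean"].to_numpy()
            q = tab["qalpha_mean"].to_numpy()
            rg_sum[:, im] += rg
            rg_sq[:, im] += rg**2
            q_sum[:, im] += q
            q_sq[:, im] += q**2
            rg_within[:, im] += tab["rg_stderr"].to_numpy() ** 2
            q_within[:, im] += tab["qalpha_stderr"].to_numpy() ** 2
            counts[:, im] += 1
    mask = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rg_mean = np.where(mask, rg_sum / np.maximum(counts, 1), np.nan)
        q_mean = np.where(mask, q_sum / np.maximum(counts, 1), np.nan)
        # across-trajectory spread; fall back to pooled within-trajectory
        # stderr when only one trajectory ran
        rg_var = rg_sq / np.maximum(counts, 1) - rg_mean**2
        q_var = q_sq / np.maximum(counts, 1) - q_mean**2
        rg_err = np.where(
            counts > 1,
            np.sqrt(np.maximum(rg_var, 0.0) / np.maximum(counts - 1, 1)),
            np.sqrt(rg_within) / np.maximum(counts, 1),
        )
        q_err = np.where(
            counts > 1,
            np.sqrt(np.maximum(q_var, 0.0) / np.maximum(counts - 1, 1)),
            np.sqrt(q_within) / np.maximum(counts, 1),
        )
    return PhaseGrid(
        t_values=T,
        mu_values=mus,
        rg_mean=rg_mean,
        rg_stderr=rg_err,
        qalpha_mean=q_mean,
        qalpha_stderr=q_err,
        n_traj=counts,
        mask=mask,
        manifest={
            "seed": seed,
            "n_traj": n_traj,
            "sweeps_per_rung": schedule.sweeps_per_rung,
            "hold_sweeps_at_extremes": schedule.hold_sweeps_at_extremes,
            "failures": failures,
        },
    )


@dataclass(frozen=True)
class Breakpoint:
    index: int  # grid index of the cell left of the transition
    location: float  # control-parameter value (midpoint for jumps)
    kind: str  # "slope-change" | "jump"
    magnitude: float


def detect_breakpoints(
    x,
    y,
    noise=None,
    *,
    z: float = 3.0,
    jump_floor: float = 0.0,
    robust_kappa: float = 5.0,
):
    """Locate slope changes and jumps in an observable-vs-control curve.

    Jumps are first differences exceeding ``z``× the propagated noise, the
    absolute ``jump_floor``, and a robust outlier scale of the remaining
    differences; slope changes are second-difference outliers by the same
    combined rule.  With zero noise the robust scale alone separates a
    genuine knee (isolated nonzero curvature) from smooth curvature.
    Affine rescalings of (y, noise, jump_floor) leave the detections
    unchanged.  Returns breakpoints ordered along x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 grid points")
    sig = np.zeros(n) if noise is None else np.asarray(noise, dtype=float)
    scale = max(np.ptp(y), 1e-300)

    def robust_scale(v):
        med = np.median(v)
        return 1.4826 * np.median(np.abs(v - med))

    out = []
    d1 = np.diff(y)
    s1 = np.sqrt(sig[:-1] ** 2 + sig[1:] ** 2)
    r1 = np.abs(d1 - np.median(d1))
    thr1 = np.maximum(z * s1, robust_kappa * robust_scale(d1))
    thr1 = np.maximum(thr1, max(jump_floor, 1e-9 * scale))
    jump_idx = [i for i in range(n - 1) if r1[i] > thr1[i] and _is_local_max(r1, i)]
    for i in jump_idx:
        out.append(
            Breakpoint(
                index=i,
                location=float(0.5 * (x[i] + x[i + 1])),
                kind="jump",
                magnitude=float(d1[i]),
            )
        )

    d2 = y[2:] - 2.0 * y[1:-1] + y[:-2]  # centred at i = 1 … n-2
    s2 = np.sqrt(sig[:-2] ** 2 + 4.0 * sig[1:-1] ** 2 + sig[2:] ** 2)
    thr2 = np.maximum(z * s2, robust_kappa * robust_scale(d2))
    thr2 = np.maximum(thr2, 1e-9 * scale)
    a2 = np.abs(d2)
    blocked = {i for i in jump_idx} | {i + 1 for i in jump_idx} | {i - 1 for i in jump_idx}
    for i in range(len(d2)):
        site = i + 1
        if site in blocked:
            continue
        if a2[i] > thr2[i] and _is_local_max(a2, i):
            out.append(
                Breakpoint(
                    index=site,
                    location=float(x[site]),
                    kind="slope-change",
                    magnitude=float(d2[i]),
                )
            )
    out.sort(key=lambda bp: bp.location)
    return out


def _is_local_max(v, i):
    left = v[i - 1] if i > 0 else -np.inf
    right = v[i + 1] if i < len(v) - 1 else -np.inf
    return v[i] > left and v[i] >= right


@dataclass(frozen=True)
class TemperatureCalibration:
    """Affine map °C = alpha·log(T_sim) + gamma, fixed by melting-curve shape."""

    alpha: float
    gamma: float
    anchors: dict

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("calibration must be strictly increasing in T_sim")

    def celsius(self, t_sim):
        return self.alpha * np.log(np.asarray(t_sim, dtype=float)) + self.gamma


def _crossings(x, y, level):
    """Interpolated x where a decreasing-trend curve crosses ``level``."""
    hits = []
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            t = (level - y0) / (y1 - y0)
            hits.append(x[i] + t * (x[i + 1] - x[i]))
    return hits


def calibrate_temperature(sim_T, sim_q, ref_C, ref_h) -> TemperatureCalibration:
    """Match midpoints and 10–90% widths of two sigmoidal melting curves.

    ``sim_q`` is ⟨Qα⟩ vs simulation temperature, ``ref_h`` a reference
    helicity vs °C; both must be overall decreasing with a midpoint
    crossing.  The map is affine in log simulation temperature.
    """
    sim_T = np.asarray(sim_T, dtype=float)
    sim_q = np.asarray(sim_q, dtype=float)
    ref_C = np.asarray(ref_C, dtype=float)
    ref_h = np.asarray(ref_h, dtype=float)

    def landmarks(x, y, logx=False):
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi - lo <= 0:
            raise ValueError("flat curve: no melting transition to match")
        xs = np.log(x) if logx else x
        marks = {}
        for frac, name in ((0.5, "mid"), (0.9, "p90"), (0.1, "p10")):
            level = lo + frac * (hi - lo)
            hits = _crossings(xs, y, level)
            if not hits:
                raise ValueError(f"curve never crosses its {name} level: not sigmoidal")
            marks[name] = float(hits[0])
        return marks

    s = landmarks(sim_T, sim_q, logx=True)
    r = landmarks(ref_C, ref_h, logx=False)
    width_s = s["p10"] - s["p90"]  # decreasing curves: p90 crossing comes first
    width_r = r["p10"] - r["p90"]
    if width_s == 0:
        raise ValueError("degenerate simulated melting width")
    alpha = width_r / width_s
    gamma = r["mid"] - alpha * s["mid"]
    return TemperatureCalibration(alpha=alpha, gamma=gamma, anchors={"sim": s, "ref": r})


def classify_regions(
    grid: PhaseGrid,
    breakpoints: dict | None = None,
    *,
    coil_fraction: float = 0.25,
    jump_floor: float = 2.0,
) -> PhaseGrid:
    """Label grid cells N / F / I_b / I_a / U from the μ-transition lines.

    Per temperature row, slope-change boundaries along μ advance the label
    through N → F → I_b and a jump boundary opens I_a; cells whose ⟨Qα⟩
    has dropped below ``coil_fraction`` of the grid maximum are random
    coil (U).  The highest temperature still showing an I_b/I_a jump is
    reported as the tricritical-point estimate.  ``breakpoints`` may be
    supplied (a dict row-index → list of :class:`Breakpoint`); otherwise
    they are detected from the Rg rows.
    """
    nT, nM = len(grid.t_values), len(grid.mu_values)
    labels = np.full((nT, nM), "?", dtype=object)
    q_ref = np.nanmax(grid.qalpha_mean)
    tric = None
    for it in range(nT):
        if not np.all(grid.mask[it]):
            continue
        if breakpoints is not None and it in breakpoints:
            bps = breakpoints[it]
        elif nM >= 5:
            bps = detect_breakpoints(
                grid.mu_values,
                grid.rg_mean[it],
                grid.rg_stderr[it],
                jump_floor=jump_floor,
            )
        else:
            bps = []
        # the I_b -> I_a boundary is the jump-like DROP in Rg with
        # increasing μ; upward jumps are read as steep slope changes
        jump_mus = [bp.location for bp in bps if bp.kind == "jump" and bp.magnitude < 0]
        slope_mus = [
            bp.location
            for bp in bps
            if bp.kind == "slope-change" or (bp.kind == "jump" and bp.magnitude >= 0)
        ]
        if jump_mus:
            tric = grid.t_values[it] if tric is None else max(tric, grid.t_values[it])
        # boundaries in μ order advance the label sequence; jumps always
        # open the I_a region
        bounds = sorted([(m, "slope") for m in slope_mus] + [(m, "jump") for m in jump_mus])
        for im, mu in enumerate(grid.mu_values):
            level = 0
            # a knee cell belongs to the regime it opens (inclusive); jump
            # locations sit between cells so strictness is immaterial there
            for m, kindb in bounds:
                if mu >= m - 1e-12:
                    level = 3 if kindb == "jump" else min(level + 1, 2)
            labels[it, im] = REGION_ORDER[level]
            if grid.qalpha_mean[it, im] < coil_fraction * q_ref:
                labels[it, im] = "U"
    grid.labels = labels
    grid.tricritical_t = None if tric is None else float(tric)
    return grid


# ---------------------------------------------------------------------------
# persistence: plain columnar text with a JSON manifest header

_GRID_FORMAT = "frenetfold-phasegrid/1"


def write_grid(grid: PhaseGrid, destination) -> None:
    """Persist a grid as a TSV table with a JSON manifest header line."""
    head = {
        "format": _GRID_FORMAT,
        "tricritical_t": grid.tricritical_t,
        "has_labels": grid.labels is not None,
        "has_celsius": grid.t_celsius is not None,
        "manifest": grid.manifest,
    }
    rows = []
    for it, t in enumerate(grid.t_values):
        for im, mu in enumerate(grid.mu_values):
            rows.append(
                {
                    "T_sim": t,
                    "T_celsius": grid.t_celsius[it] if grid.t_celsius is not None else np.nan,
                    "mu": mu,
                    "rg_mean": grid.rg_mean[it, im],
                    "rg_stderr": grid.rg_stderr[it, im],
                    "qalpha_mean": grid.qalpha_mean[it, im],
                    "qalpha_stderr": grid.qalpha_stderr[it, im],
                    "n_traj": grid.n_traj[it, im],
                    "mask": int(grid.mask[it, im]),
                    "label": grid.labels[it, im] if grid.labels is not None else "",
                }
            )
    df = pd.DataFrame(rows)
    with open(destination, "w") as fh:
        fh.write("# " + json.dumps(head) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_grid(source) -> PhaseGrid:
    """Round-trip counterpart of :func:`write_grid`."""
    with open(source) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError("missing grid manifest header")
        head = json.loads(header[2:])
        if head.get("format") != _GRID_FORMAT:
            raise ValueError(f"unrecognised grid format: {head.get('format')!r}")
        df = pd.read_csv(fh, sep="\t")
    t_values = np.unique(df["T_sim"].to_numpy())
    mu_values = np.unique(df["mu"].to_numpy())
    nT, nM = len(t_values), len(mu_values)
    shape = (nT, nM)
    arrays = {
        k: np.full(shape, np.nan)
        for k in ("rg_mean", "rg_stderr", "qalpha_mean", "qalpha_stderr")
    }
    n_traj = np.zeros(shape, dtype=int)
    mask = np.zeros(shape, dtype=bool)
    labels = np.full(shape, "", dtype=object) if head["has_labels"] else None
    t_celsius = np.full(nT, np.nan) if head["has_celsius"] else None
    t_index = {t: i for i, t in enumerate(t_values)}
    m_index = {m: i for i, m in enumerate(mu_values)}
    for _, row in df.iterrows():
        it, im = t_index[row["T_sim"]], m_index[row["mu"]]
        for k in arrays:
            arrays[k][it, im] = row[k]
        n_traj[it, im] = int(row["n_traj"])
        mask[it, im] = bool(row["mask"])
        if labels is not None:
            labels[it, im] = row["label"]
        if t_celsius is not None:
            t_celsius[it] = row["T_celsius"]
    return PhaseGrid(
        t_values=t_values,
        mu_values=mu_values,
        **arrays,
        n_traj=n_traj,
        mask=mask,
        labels=labels,
        t_celsius=t_celsius,
        tricritical_t=head.get("tricritical_t"),
        manifest=head.get("manifest", {}),
    )
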