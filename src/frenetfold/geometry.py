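"""Discrete Frenet-frame geometry of a Cα backbone.

A protein Cα trace ``r_0 … r_{n-1}`` is framed by unit tangents
``t_i = (r_{i+1} - r_i)/|r_{i+1} - r_i|``, binormals
``b_i = (t_{i-1} × t_i)/|t_{i-1} × t_i|`` and normals ``n_i = b_i × t_i``.
The triad at consecutive sites is related by a transfer rotation

    F_{i+1} = exp(-θ T²) · exp(-φ T³) · F_i ,      (T^a)_{jk} = ε_{ajk},

whose two angles — the virtual bond angle θ and torsion angle φ — are the
coarse-grained conformational coordinates used throughout this package.
Conversely, a chain is rebuilt from (θ, φ) by propagating the triad and
stepping ``r_{i+1} = r_i + L t_i`` with a fixed virtual bond length
L ≈ 3.8 Å.

Index convention (0-based): θ is defined at sites ``1 … n-2`` (it needs the
two flanking tangents), φ at sites ``2 … n-2``.  Both arrays are stored with
length ``n-2`` aligned at ``site_offset = 1``; the first φ slot is a pure
gauge degree of freedom (it only rotates the whole chain rigidly about the
first bond) and is fixed to 0 by ``angles_from_coords``.

The model's θ field lives on the double-well ±m, so θ may be stored signed;
the transfer rotation accepts signed θ directly, and sign flips are related
to the canonical non-negative-θ representation by the gauge transformation
implemented in :func:`apply_gauge`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "CalphaTrace",
    "FrenetAngles",
    "FrenetFrames",
    "frames_from_coords",
    "angles_from_coords",
    "coords_from_angles",
    "apply_gauge",
    "transfer_rotation",
    "wrap_angle",
    "DEFAULT_BOND_LENGTH",
]

DEFAULT_BOND_LENGTH = 3.8  # Å, mean Cα-Cα virtual bond
_DEGENERACY_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when consecutive bonds are (anti)parallel and no frame exists."""


def wrap_angle(x):
    """Wrap angle(s) to the half-open interval (-π, π]."""
    x = np.asarray(x, dtype=float)
    out = -((-x + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalphaTrace:
    """Ordered Cα coordinates with residue identities."""

    positions: np.ndarray  # (n, 3) Å
    residue_names: tuple = ()
    residue_numbers: tuple = ()
    chain_id: str = "A"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        object.__setattr__(self, "positions", pos)
        if not self.residue_names:
            object.__setattr__(self, "residue_names", ("ALA",) * len(pos))
        if not self.residue_numbers:
            object.__setattr__(self, "residue_numbers", tuple(range(1, len(pos) + 1)))
        if len(self.residue_names) != len(pos) or len(self.residue_numbers) != len(pos):
            raise ValueError("residue annotations must match the number of positions")

    def __len__(self) -> int:
        return len(self.positions)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def histidine_sites(self) -> tuple:
        """0-based indices of HIS residues (all protonation variants)."""
        his = {"HIS", "HSD", "HSE", "HSP", "HID", "HIE", "HIP"}
        return tuple(i for i, nm in enumerate(self.residue_names) if nm.upper() in his)


@dataclass(frozen=True)
class FrenetAngles:
    """Bond (θ) and torsion (φ) angles of a Cα chain.

    ``theta[j]``/``phi[j]`` belong to chain site ``site_offset + j``.  θ may
    be signed (double-well convention); ``phi[0]`` is the gauge slot used
    only to seed reconstruction.
    """

    theta: np.ndarray
    phi: np.ndarray
    bond_length: float = DEFAULT_BOND_LENGTH
    site_offset: int = 1

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        ph = np.asarray(self.phi, dtype=float)
        if th.shape != ph.shape or th.ndim != 1:
            raise ValueError("theta and phi must be 1-d arrays of equal length")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "phi", ph)

    @property
    def n_sites(self) -> int:
        """Number of Cα sites of the parent chain."""
        return len(self.theta) + 2

    def __len__(self) -> int:
        return len(self.theta)

    def copy(self) -> "FrenetAngles":
        return replace(self, theta=self.theta.copy(), phi=self.phi.copy())


@dataclass(frozen=True)
class FrenetFrames:
    """Orthonormal (tangent, binormal, normal) triads at sites 1 … n-2."""

    tangent: np.ndarray  # (n-2, 3), t_i
    binormal: np.ndarray
    normal: np.ndarray
    site_offset: int = 1

    def triad(self, j: int) -> np.ndarray:
        """Row-stacked 3×3 frame [n; b; t] at array index ``j``."""
        return np.vstack([self.normal[j], self.binormal[j], self.tangent[j]])


def transfer_rotation(theta: float, phi: float) -> np.ndarray:
    """Transfer matrix R(θ, φ) = exp(-θ T²) · exp(-φ T³).

    Acting on the row-stacked frame [n; b; t], ``F_new = R @ F_old``.
    """
    ct, st = np.cos(theta), np.sin(theta)
    # sign of φ chosen so a right-handed α-helix carries φ = +0.9 rad
    cp, sp = np.cos(phi), -np.sin(phi)
    return np.array(
        [
            [ct * cp, -ct * sp, st],
            [sp, cp, 0.0],
            [-st * cp, st * sp, ct],
        ]
    )


def _tangents(positions: np.ndarray) -> np.ndarray:
    d = np.diff(positions, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < _DEGENERACY_TOL):
        bad = int(np.argmin(norms))
        raise DegenerateGeometryError(f"zero-length bond between sites {bad} and {bad + 1}")
    return d / norms[:, None]


def frames_from_coords(trace: CalphaTrace) -> FrenetFrames:
    """Discrete Frenet triads (t, b, n) at the interior sites of a trace.

    Raises :class:`DegenerateGeometryError` (naming the site) wherever
    consecutive bonds are collinear, since the binormal is then undefined.
    """
    pos = trace.positions
    if len(pos) < 3:
        raise ValueError("need at least 3 points to build a Frenet frame")
    t = _tangents(pos)
    cross = np.cross(t[:-1], t[1:])
    norms = np.linalg.norm(cross, axis=1)
    if np.any(norms < _DEGENERACY_TOL):
        bad = int(np.argmin(norms)) + 1
        raise DegenerateGeometryError(
            f"collinear consecutive bonds at site {bad}: binormal undefined"
        )
    b = cross / norms[:, None]
    tangent = t[1:]  # t_i for sites 1 … n-2
    normal = np.cross(b, tangent)
    return FrenetFrames(tangent=tangent, binormal=b, normal=normal)


def angles_from_coords(trace: CalphaTrace) -> FrenetAngles:
    """Extract (θ, φ) from a Cα trace.

    θ_i ∈ [0, π) is the angle between t_{i-1} and t_i; φ_i is the signed
    rotation of the binormal about the preceding tangent, with the sign
    fixed so an ideal right-handed α-helix yields φ ≈ +0.9 rad.  The gauge
    slot φ at the first defined site is set to 0.
    """
    pos = trace.positions
    if len(pos) < 5:
        raise ValueError("need at least 5 residues to define interior angles")
    frames = frames_from_coords(trace)
    t_all = _tangents(pos)  # t_0 … t_{n-2}
    dots = np.clip(np.einsum("ij,ij->i", t_all[:-1], t_all[1:]), -1.0, 1.0)
    sins = np.linalg.norm(np.cross(t_all[:-1], t_all[1:]), axis=1)
    theta = np.arctan2(sins, dots)  # sites 1 … n-2, in [0, π)
    # φ_i from b_i = sinφ n_{i-1} + cosφ b_{i-1}
    b, n = frames.binormal, frames.normal
    sphi = -np.einsum("ij,ij->i", b[1:], n[:-1])
    cphi = np.einsum("ij,ij->i", b[1:], b[:-1])
    phi = np.zeros_like(theta)
    phi[1:] = np.arctan2(sphi, cphi)
    bl = float(np.mean(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    return FrenetAngles(theta=theta, phi=phi, bond_length=bl)


def coords_from_angles(
    angles: FrenetAngles,
    seed_frame: np.ndarray | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> CalphaTrace:
    """Rebuild a Cα trace from (θ, φ) by propagating the Frenet triad.

    ``r_{i+1} = r_i + L t_i`` with the triad advanced through
    ``R(θ, φ) = exp(-θT²)exp(-φT³)`` at every interior site.  Signed θ is
    accepted as-is (gauge-equivalent to the |θ| representation).  The
    result is unique up to the rigid motion set by ``seed_frame``/``origin``.
    """
    th, ph = angles.theta, angles.phi
    L = angles.bond_length
    n = angles.n_sites
    F = np.eye(3) if seed_frame is None else np.array(seed_frame, dtype=float)
    pos = np.empty((n, 3))
    pos[0] = np.asarray(origin, dtype=float)
    pos[1] = pos[0] + L * F[2]
    for j in range(len(th)):
        F = transfer_rotation(th[j], ph[j]) @ F
        pos[j + 2] = pos[j + 1] + L * F[2]
    return CalphaTrace(positions=pos)


def apply_gauge(angles: FrenetAngles, sites: Iterable[int]) -> FrenetAngles:
    """Flip the sign of θ at ``sites`` (chain-site indices) without moving the chain.

    The discrete Frenet transfer satisfies R(-θ, φ+π) = P·R(θ, φ) with
    P = diag(-1, -1, 1), so a sign pattern s_i on θ reconstructs identical
    coordinates when φ picks up a π shift at every boundary where s
    changes (including the entry into the first flipped site).  This is
    the double-well gauge freedom: kinks may equivalently be stored as θ
    passing through zero or as |θ| with torsion offsets.
    """
    out = angles.copy()
    flip = np.zeros(len(out), dtype=bool)
    for s in sites:
        j = s - out.site_offset
        if not 0 <= j < len(out):
            raise IndexError(f"site {s} has no defined angles")
        flip[j] = True
    signs = np.where(flip, -1.0, 1.0)
    boundaries = np.flatnonzero(np.diff(np.concatenate(([1.0], signs))) != 0)
    theta = out.theta * signs
    phi = out.phi.copy()
    phi[boundaries] = wrap_angle(phi[boundaries] + np.pi)
    return replace(out, theta=theta, phi=phi)
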