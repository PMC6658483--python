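"""Order parameters: radius of gyration, α-helical content, torsion means.

Rg measures compactness (unweighted over Cα positions).  The helical
content Qα counts the fraction of residues whose (θ, φ) sit within fixed
tolerances of the ideal α-helix values (θ₀, φ₀) = (1.55, 0.9) rad:
|θ-θ₀| ≤ 0.14 (inclusive) and |φ-φ₀| < 0.3 (exclusive).  θ is compared as
|θ| (gauge-normalised, since the double-well field may be signed); φ
differences are taken on the circle.  Per-segment torsion averages use the
circular mean so disordered segments with φ wrapping at ±π average to ≈ 0
rather than to a wrap artefact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CalphaTrace, FrenetAngles, wrap_angle

__all__ = [
    "HelixCriterion",
    "radius_of_gyration",
    "helical_content",
    "segment_torsion_average",
]


@dataclass(frozen=True)
class HelixCriterion:
    """Angular window around the ideal α-helix posture."""

    theta0: float = 1.55
    phi0: float = 0.9
    theta_tol: float = 0.14  # inclusive bound
    phi_tol: float = 0.3  # exclusive bound

    def __post_init__(self):
        if self.theta_tol <= 0 or self.phi_tol <= 0:
            raise ValueError("tolerances must be positive")


def radius_of_gyration(trace: CalphaTrace) -> float:
    """Root-mean-square distance of the Cα positions from their centroid (Å)."""
    pos = np.asarray(trace.positions, dtype=float)
    if len(pos) == 0:
        raise ValueError("empty trace")
    centred = pos - pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def helical_content(angles: FrenetAngles, criterion: HelixCriterion | None = None) -> float:
    """Fraction of sites in α-helical posture.

    The denominator is the number of sites where both θ and φ are defined
    (chain ends and the gauge slot excluded).
    """
    c = criterion or HelixCriterion()
    theta = np.abs(angles.theta[1:])  # sites with a defined torsion
    phi = angles.phi[1:]
    if len(theta) == 0:
        raise ValueError("no sites with both angles defined")
    ok_theta = np.abs(theta - c.theta0) <= c.theta_tol
    dphi = np.abs(phi - c.phi0)
    # wrap only when needed: the modular reduction costs an ulp, which
    # matters for the exclusive boundary semantics of the φ window
    dphi = np.where(dphi > np.pi, np.abs(wrap_angle(dphi)), dphi)
    ok_phi = dphi < c.phi_tol
    return float(np.mean(ok_theta & ok_phi))


def segment_torsion_average(angles: FrenetAngles, segments: dict) -> dict:
    """Circular mean and resultant length of φ over named site ranges.

    ``segments`` maps name -> (first_site, last_site) inclusive chain-site
    indices.  Returns name -> (mean, R) where R ∈ [0, 1] is the resultant
    length (R ≈ 1: tightly ordered; R ≈ 0: uniform/disordered — treat the
    mean as meaningless).
    """
    out = {}
    for name, (first, last) in segments.items():
        j0 = max(first - angles.site_offset, 1)  # gauge slot carries no torsion
        j1 = last - angles.site_offset + 1
        if j1 <= j0:
            raise ValueError(f"segment {name!r} has no sites with defined torsion")
        phi = angles.phi[j0:j1]
        z = np.mean(np.exp(1j * phi))
        out[name] = (float(np.angle(z)), float(np.abs(z)))
    return out
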