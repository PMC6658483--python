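"""pH → chemical potential mapping via Henderson–Hasselbalch.

A titratable site with dissociation constant pKa is protonated with
probability P_H = 1/(1 + 10^{pH-pKa}).  The acidity contribution to the
Gibbs free energy, to leading order over the N titratable sites, is

    ΔG ≈ RT ln(10) (pH - pKa) · N · P_H(pH),

which has the same functional form as the Glauber transition probability.
In the grand-canonical backbone ensemble, acidity enters through the
chemical potential μ conjugate to the DNLS number operator N = Σ θ² over
the histidine sites; to leading order μ depends linearly on pH.  The
histidine pKa ≈ 6.0 makes histidines the only strongly pH-reactive
residues between pH ~ 4 and neutral, which bounds the model's validity
window; μ is normalised to 0 at the reference pH of the decoy structure
(9.0 for the myoglobin study system).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TitrationSpec",
    "protonation_probability",
    "gibbs_shift",
    "mu_from_ph",
]

# default slope maps pH 4 -> μ = 0.05, the top of the simulated μ window
DEFAULT_SLOPE = 0.05 / (9.0 - 4.0)


@dataclass(frozen=True)
class TitrationSpec:
    """Titratable-site bookkeeping and the μ(pH) calibration."""

    pKa: float = 6.0  # histidine
    site_count: int = 12
    pH_ref: float = 9.0  # μ = 0 here
    slope: float = DEFAULT_SLOPE  # μ per pH unit

    def __post_init__(self):
        if self.site_count < 0:
            raise ValueError("site_count must be non-negative")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


def protonation_probability(pH: float, pKa: float = 6.0) -> float:
    """Henderson–Hasselbalch protonation probability 1/(1 + 10^{pH-pKa})."""
    return float(1.0 / (1.0 + 10.0 ** (np.clip(pH - pKa, -300, 300))))


def gibbs_shift(pH: float, titration: TitrationSpec, temperature: float = 1.0) -> float:
    """Leading-order acidity shift RT ln(10)(pH-pKa) · N · P_H(pH).

    ``temperature`` is RT in whatever unit system the caller wants the
    shift reported in; the backbone model itself works in RT = 1 units.
    """
    ph_term = pH - titration.pKa
    p_h = protonation_probability(pH, titration.pKa)
    return float(temperature * np.log(10.0) * ph_term * titration.site_count * p_h)


def mu_from_ph(pH: float, titration: TitrationSpec) -> float:
    """Linear μ(pH), zero at pH_ref and clamped at 0 for pH ≥ pH_ref."""
    return float(max(0.0, titration.slope * (titration.pH_ref - pH)))
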