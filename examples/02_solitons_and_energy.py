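"""The multi-soliton free energy and its variational equations.

Generates a two-kink decoy — two α-helices joined by loops where the
double-well θ field crosses between its minima ±m — and shows that the
generated profile is a stationary point of the free energy: both
variational residuals vanish, and the torsion angle is exactly the
minimiser φ = (bθ² + a)/(dθ² + c) of the torsion sector.
"""

import numpy as np

from frenetfold import (
    SyntheticDecoySpec,
    free_energy,
    make_synthetic_decoy,
    radius_of_gyration,
    variational_residuals,
)

trace, angles, spec = make_synthetic_decoy(
    SyntheticDecoySpec(n_sites=60, kink_positions=(20, 40))
)
breakdown = free_energy(angles, spec)
r_theta, r_phi = variational_residuals(angles, spec)

print(f"residues:                {len(trace)}")
print(f"soliton segments:        {len(spec.segments)}")
print(f"radius of gyration (Å):  {radius_of_gyration(trace):.2f}")
print(f"free energy (model u.):  {breakdown.total:.4f}")
print(f"  θ sector:              {breakdown.theta_sector:.4f}")
print(f"  torsion sector:        {breakdown.torsion_sector:.4f}")
print(f"hard core satisfied:     {breakdown.excluded_volume_ok}")
print(f"max |r_θ| residual:      {np.nanmax(np.abs(r_theta)):.2e}")
print(f"max |r_φ| residual:      {np.nanmax(np.abs(r_phi)):.2e}")
print()
print("Near-zero residuals mean the kinked profile is a genuine")
print("multi-soliton minimum of the energy — the model's native state.")
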