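"""Discrete Frenet coordinates of a Cα backbone.

Builds an ideal α-helix from the canonical bond/torsion angles
(θ₀, φ₀) = (1.55, 0.9) rad, extracts the angles back from the
coordinates, and shows the roundtrip is exact: the (θ, φ) pair per
residue is a complete, bond-length-preserving parameterization of the
backbone shape.
"""

import numpy as np

from frenetfold import angles_from_coords, coords_from_angles, make_ideal_helix, rmsd_superposed

helix = make_ideal_helix(30)
angles = angles_from_coords(helix)
rebuilt = coords_from_angles(angles)

print(f"residues:              {len(helix)}")
print(f"bond lengths (Å):      {helix.bond_lengths().min():.6f} … {helix.bond_lengths().max():.6f}")
print(f"recovered θ (rad):     {angles.theta.min():.6f} … {angles.theta.max():.6f}")
print(f"recovered φ (rad):     {angles.phi[1:].min():.6f} … {angles.phi[1:].max():.6f}")
print(f"roundtrip RMSD (Å):    {rmsd_superposed(helix, rebuilt):.2e}")
print()
print("θ is the bond angle between consecutive tangents, φ the binormal")
print("torsion; (1.55, 0.9) is the α-helical point, and the roundtrip RMSD")
print("shows the angles encode the full 3D trace up to a rigid motion.")
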