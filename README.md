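# frenetfold

Effective-theory thermodynamics of globular proteins on the Cα backbone:
discrete Frenet angles, a multi-soliton free energy of the discretized
non-linear Schrödinger (DNLS) family, and grand-canonical Glauber Monte
Carlo over temperature and a pH-mapped chemical potential.

## Who this is for

Researchers who want protein *phase behaviour* — melting curves,
(un)folding intermediates, temperature × acidity phase diagrams — at a
computational cost where molecular dynamics is unthinkable.  Instead of
atoms, the degrees of freedom are the virtual bond angle θᵢ and torsion
angle φᵢ of each Cα site, and the native fold is not simulated but *built
in*: it is the minimum of the energy function, a multi-soliton of the
DNLS equation fitted to a single experimental structure.

## The model

A Cα trace **r**₁…**r**ₙ is framed by unit tangents, binormals and
normals; the frame transfer `exp(-θT²)·exp(-φT³)` defines the (θ, φ)
coordinates, and conversely the chain is rebuilt from them with a fixed
3.8 Å virtual bond.  The conformational free energy is

```
F = Σᵢ [ -2θᵢ₊₁θᵢ + 2θᵢ² + λ(θᵢ² - m²)² + (d/2)θᵢ²φᵢ² ]
  + Σᵢ [ -b θᵢ²φᵢ - a φᵢ + (c/2)φᵢ² ]  +  hard core (rᵢⱼ ≥ 3.8 Å)
```

with couplings (λ, m, a, b, c, d) uniform over each *soliton* — one
helix-loop unit.  The double well ±m holds helices; its kinks are loops.
Stationarity gives the variational equations, and the torsion is slaved
to θ via φ = (bθ² + a)/(dθ² + c).  Thermodynamics is the grand-canonical
average with weight `exp(-β(F - μN))`, sampled by single-site Glauber
dynamics, where N = Σθᵢ² over the histidine sites and μ is an affine
function of pH anchored by the Henderson–Hasselbalch relation (μ = 0 at
the decoy's pH, pKa ≈ 6).  Order parameters: radius of gyration R_g and
helical content Qα (fraction of sites with |θ-1.55| ≤ 0.14 and
|φ-0.9| < 0.3 rad).

## Worked example

Fit the shipped 154-residue globin-scale synthetic decoy with ten
solitons and read off its order parameters:

```python
from frenetfold import (angles_from_coords, canonicalize_gauge, fit_parameters,
                        helical_content, make_globin_like_decoy,
                        radius_of_gyration, segment_chain)

decoy, angles, _ = make_globin_like_decoy()
print(round(radius_of_gyration(decoy), 2), round(helical_content(angles), 3))
ext = canonicalize_gauge(angles_from_coords(decoy))
fit = fit_parameters(decoy, segment_chain(ext, 10), budget=150, seed=0)
print(f"{fit.rmsd:.2e}")
```

prints

```
21.82 0.841
2.45e-05
```

— the decoy is a compact (R_g ≈ 21.8 Å), 84% helical ten-helix bundle,
and the fitted model's multi-soliton minimum reproduces it to
2.5 × 10⁻⁵ Å Cα RMSD.  The scripts in `examples/` walk through each
capability (Frenet roundtrips, soliton energetics, fitting, melting
curves with Celsius calibration, (T, pH) phase grids, the pH → μ map),
each printing the numbers it computes and what they mean.  A thin CLI
(`frenetfold fit|observe|simulate|scan|gen`) wraps the same pipeline for
shell use.

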