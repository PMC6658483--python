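# Methods

## Geometry: discrete Frenet coordinates

Each Cα trace is framed by tangents **t**ᵢ = (**r**ᵢ₊₁-**r**ᵢ)/|·|,
binormals **b**ᵢ = (**t**ᵢ₋₁×**t**ᵢ)/|·| and normals **n**ᵢ = **b**ᵢ×**t**ᵢ.
The transfer between consecutive row-stacked frames is
R(θ, φ) = exp(-θT²)·exp(-φT³) with (Tᵃ)ⱼₖ = ε_aⱼₖ; θᵢ ∈ [0, π) is the
bond angle between t_{i-1} and t_i and φᵢ the signed binormal rotation.
Conventions the package fixes (the formalism leaves them open):

* **Index ranges.** θ lives on sites 1…n-2 (0-based), φ on 2…n-2; both
  arrays are stored with `site_offset = 1`, and the first φ slot is a pure
  gauge degree of freedom (it only re-orients the chain rigidly about the
  first bond), set to 0 on extraction and excluded from the energy and
  the sampler's move set.
* **Torsion sign.** Fixed so that a right-handed α-helix carries
  φ = +0.9 rad; verified against the sign of the Cα virtual dihedral.
* **Signed θ.** The double-well field may sit in either well ±m.  The
  transfer rotation accepts signed θ directly, and sign patterns are
  gauge-equivalent to the non-negative representation: flipping the sign
  of θ over a set of sites leaves the reconstructed coordinates unchanged
  provided φ picks up a π shift at every *boundary* where the sign
  pattern changes (algebraically, R(-θ, φ+π) = diag(-1,-1,1)·R(θ, φ)).
  `apply_gauge` implements this boundary rule; a naive per-site
  "(θ, φ) → (-θ, φ+π)" does not preserve geometry on the lattice.
* **Degeneracy.** Cross products below 1e-12 raise instead of being
  perturbed: collinear bonds have no frame, and silently nudging them
  would corrupt the energy bookkeeping downstream.
* The virtual bond length is fixed at 3.8 Å for all reconstructions; raw
  PDB bond lengths are not rescaled when only angles are extracted.

## The free energy

```
F = Σᵢ [ -2θᵢ₊₁θᵢ + 2θᵢ² + λ(θᵢ² - m²)² + (d/2)θᵢ²φᵢ² ]
  + Σᵢ [ -b θᵢ²φᵢ - a φᵢ + (c/2)φᵢ² ]  +  V_hard-core
```

* **End handling.** The kinetic pair -2θᵢ₊₁θᵢ + 2θᵢ² is summed over
  sites with a right neighbour, so a uniform field at a well bottom has
  exactly zero energy; the double-well potential runs over every defined
  site and the torsion terms over every site with a defined φ.  With
  this convention the interior stationarity conditions are exactly
  2(2θᵢ-θᵢ₊₁-θᵢ₋₁) + 4λ(θᵢ²-m²)θᵢ + (dφᵢ²-2bφᵢ)θᵢ = 0 and
  (dθᵢ²+c)φᵢ - bθᵢ² - a = 0, and `variational_residuals` is the exact
  partial derivative of `free_energy` (checked against central
  differences to 1e-6 in the tests).  Open ends relax over a few sites;
  all stated plateau relations hold in the deep interior.
* **Segment boundaries.** The parameter-free kinetic pair at a boundary
  needs no ownership convention; parameterized terms use the segment the
  site belongs to.
* **Excluded volume** is an infinite step: any pair |i-j| ≥ 2 closer
  than 3.8 Å makes the energy the +inf sentinel.  The sampler enforces it
  by rejection; no soft long-range tail is added (the soliton solution
  itself carries the long-range structure).
* **Units.** Model units throughout; no conversion to kcal/mol is
  attempted.  RT = 1 for the μN term.

## Fitting a decoy

The decoy trace is converted to angles, gauge-canonicalised to the
signed-θ representation (π offsets in φ at kink centres are detected and
folded back into θ signs), and segmented into solitons at the loop
centres — the strongest local maxima of a 3-site-smoothed distance of
(|θ|, φ) from the α-helical point, ties broken leftmost, boundaries then
refined (±2 sites, iterated to a fixpoint) by minimising the
stationarity-violation residual below.

**Coupling initialisation by linear inversion.**  If the decoy were an
exact model minimum its residuals would vanish, and within the (c = 1,
d = 0) normalisation the θ-residual is *linear* in (λ, λm²) given b,
while the torsion condition φ = bθ² + a is linear in (a, b).  Solving
these per segment in the least-squares sense (with a small ridge toward
λ = 1, m = θ* for kink-free segments, where only the plateau combination
is identified) recovers self-consistent decoys exactly and gives a
strong start otherwise.  The (c = 1, d = 0) normalisation resolves a
genuine degeneracy: a given stationary profile is stationary for a whole
family of coupling sets, some outside the stable region (c ≤ 0).

**Refinement on the profile misfit.**  A budget-limited stochastic
stage — simulated annealing over one (segment, parameter) at a time,
then Brent line searches over (λ, m, a, b) per segment — minimises the
*angle-space* misfit between the solved minimum and the decoy profile.
Angle space is used deliberately: decoy noise and model mismatch are
local in (θ, φ) but integrate through helix lever arms into long-range
coordinate displacements, which makes the raw Cα-RMSD landscape
ill-conditioned (compensating valleys across segments); on ten-soliton
chains direct RMSD search stalled Ångströms away from an exactly
attainable zero.  The final Cα RMSD after Kabsch superposition is
computed from the best profile and reported as the fit quality.

**Inner solver.**  θ is relaxed with φ eliminated exactly at every step
(the torsion sector is quadratic in φ with curvature dθ² + c > 0, so the
elimination is its unique minimiser and the reduced gradient equals the
θ-residual by the envelope theorem): bounded L-BFGS-B on θ ∈ [-π, π],
then damped Newton steps using the tridiagonal Hessian of the reduced
energy, stopping at a residual max-norm of 1e-8 (typically reaching
1e-12).  Excluded volume is not enforced during relaxation — fitting
operates in the native basin — and is validated on the result.

## Sampling

Single-site Glauber dynamics: sites in random order, symmetric Gaussian
proposals on (θᵢ, φᵢ) (defaults σ_θ = 0.1, σ_φ = 0.3 rad), acceptance
e^{-βΔ}/(1+e^{-βΔ}) with Δ = Δ(F - μN).  A move at site i re-orients one
transfer, so the downstream tail rotates rigidly about r_i; the energy
difference is local and the hard-core check only needs head × moved-tail
pairs, giving O(n) work per typical move.  The tail rotation matrix is
re-orthonormalised (Gram–Schmidt) on every accepted move — without this
the frames' orthogonality error feeds back through the update and
compounds exponentially — and the full state (frames, positions, cached
energy) is recomputed from the angles at every temperature rung, so
drift cannot accumulate across a trajectory.  A debug mode cross-checks
the incremental energy against a full recomputation and asserts that no
accepted state violates the hard core.

Trajectories walk a geometric β ladder adiabatically (default scaled-down
protocol: 10–16 rungs, hundreds to a couple thousand sweeps per rung,
long holds at the extremes), record post-burn-in means per rung
(burn-in fraction 0.5), and are bit-reproducible from the schedule seed.
Ensemble averages carry batch-means standard errors (20 batches), which
inflate with the integrated autocorrelation time.

Phase grids pool independent heating trajectories per μ; with several
trajectories the cell standard error is the across-trajectory spread,
with one it falls back to the within-trajectory batch error.

## pH and the chemical potential

Histidine (pKa ≈ 6) is the only strongly pH-reactive residue between
pH ~4 and neutral, which bounds the model's validity window.  Its
Henderson–Hasselbalch protonation gives the leading-order acidity term
ΔG ≈ RT ln10 (pH-pKa)·N_his·P_H, absorbed as a chemical potential μ
conjugate to the conserved DNLS number operator N = Σθ² over the
histidine sites.  μ(pH) is affine, zero at the decoy's reference pH
(9.0) and clamped at zero above it; the default slope maps pH 4 to
μ = 0.05, the top of the simulated μ window.  The slope is a calibration
constant, not derivable within the leading-order treatment, and is
exposed in `TitrationSpec`.

## Temperature calibration

The Glauber temperature is not Kelvin.  The principled bridge is a
renormalisation-group argument, which is out of scope here; instead the
package uses the operational two-anchor device: an affine map in
log T_sim matching the midpoint and 10–90 % width of the simulated
melting curve ⟨Qα⟩(T_sim) to a reference helicity-vs-°C curve.  The
shipped reference (`data/reference_helicity.tsv`) is a *stylized
synthetic* logistic (midpoint 75 °C, width 40 °C, plateaus 0.72 → 0.08),
standing in for experimental thermal-denaturation data; calibrated
Celsius values are therefore illustrative, not literal.

## Transition detection and region labels

On one-dimensional cuts of the grid, jump transitions are first
differences that exceed 3× the propagated sampling noise, an absolute
floor (2 Å for R_g), and a robust (MAD-based) outlier scale of the
remaining differences; slope changes are second-difference outliers by
the same combined rule, away from detected jumps.  The rules are
invariant under affine rescaling of (observable, noise, floor).  Region
labels advance N → F → I_b along increasing μ at slope changes, the
jump-like *drop* in R_g opens I_a (upward jumps are read as steep slope
changes), cells whose ⟨Qα⟩ falls below a quarter of the grid maximum are
random coil U, and the highest temperature still showing an I_b/I_a jump
is reported as the tricritical-point estimate — nothing more than the
jump-line terminus.

## Synthetic study systems

The generator builds decoys directly in angle space: θ crosses between
±m through tanh kinks at chosen loop sites (kinks centred *between*
lattice sites — the bond-centred kink is the stable lattice
configuration, the site-centred one a saddle), φ slaved by torsion
elimination under per-segment ground-truth couplings, and the ansatz
polished into the exact stationary profile of its own spec by default,
so every clean decoy is a genuine model minimum with known parameters.
Gaussian angle noise is optional; excluded-volume violations retry the
noise draw.

Two canonical systems set the study conditions:

* a 60-residue two-kink hairpin (kinks at sites 20/40) for sampler and
  recovery work, and
* a 154-residue ten-soliton globin-scale bundle with twelve titratable
  sites.  Helix lengths (12–20 residues) echo an all-α globin; each
  segment's loop torsion a and stiffness λ are free while b and m are
  pinned analytically so every helical plateau sits at (1.55, 0.9), and
  the particular (a, λ) pattern was chosen once so the ten helices pack
  into a self-avoiding bundle (R_g ≈ 21.8 Å, Qα ≈ 0.84).

What these do *not* emulate: side-chain packing (the synthetic bundle is
looser than a real globin — myoglobin's native R_g is ~17 Å — so
absolute R_g values in its disordered regions run a few Å high),
sequence heterogeneity within helices, and real loop geometries.
Passing tests on these systems validate the machinery — exact geometry,
energy/gradient consistency, Boltzmann-correct sampling, parameter
recovery, qualitative unfolding physics — not agreement with any
specific protein's numbers, for which a real decoy structure (e.g. PDB
1ABS for sperm whale myoglobin) must be supplied.

## Known limitations

* Parameter recovery from a *noisy* decoy is information-limited: with
  σ = 0.05 rad angle noise and ~20-site segments, plateau angles are
  estimable only to ~0.01 rad, and helix lever arms turn that into a few
  tenths of an Å (one segment) to a few Å (three segments) of
  reconstruction error regardless of estimator; the package lands within
  ~2–4× of an oracle fit started at the true parameters.
* The Glauber-to-Celsius map is a two-anchor affine calibration against
  a stylized curve.
* The full-scale protocol (thousands of trajectories over 50 μ values)
  is configuration-reachable but the defaults are scaled down to
  desk-size runs; all problem sizes used by the tests and the
  acceptance script are stated in their code.
* No all-atom reconstruction, no replica exchange or cluster moves, no
  glutamate/aspartate titration below pH ≈ 4.
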