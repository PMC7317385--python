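# Methods

This note records what each component of `arboretum` computes, the
numerical choices behind it, and what the synthetic test scenes do and do
not demonstrate.

## Units, conventions, containers

All internal quantities are atomic units: lengths in Bohr, energies in
Hartree, charges in elementary charges. Conversion happens only at I/O
boundaries (XYZ files are Å; CHELPG spacing and CM5 radii are quoted in
Å, as those schemes conventionally are). Atom indices are 0-based in
memory and 1-based in printed reports. The wavefunction container stores
the overlap matrix S explicitly, so no integral engine is needed;
analytic overlaps are computed only for s-type Gaussian fixtures. All
charge vectors carry a `diagnostics` dict recording convergence and
conservation metadata, so runs are auditable.

## Orbital-partition charges

With the gross overlap population `q_ij = P_ij S_ij` (total = electron
count), the two condensations are

- Mulliken: `Q'_ii = q_ii + 1/2 Σ_{j≠i} (q_ij + q_ji)`;
- Bickelhaupt: `Q'_ii = q_ii + Σ_{j≠i} q_ii/(q_ii+q_jj) (q_ij + q_ji)`.

Both redistribute population, so `Σ_A q_A` equals the molecular charge to
machine precision. When a pair's diagonal populations sum to less than
1e-10 the Bickelhaupt weight is undefined; we fall back to the even split
for that pair and record it in diagnostics, which preserves conservation.
Löwdin populations are the diagonal of `S^1/2 P S^1/2` (symmetric
eigendecomposition).

Minimal-basis projection: occupied orbitals are recovered as natural
orbitals of `S^1/2 P S^1/2` with occupation ≈ 2 (closed-shell only;
open-shell users supply the spin-summed P at their own risk), projected
as `C_m = S_mm⁻¹ S_mf C_occ`, then Löwdin-orthonormalized inside the
minimal basis. This restores idempotency and the electron count without
ad hoc rescaling. Whether per-orbital or global renormalization is the
"right" contract is genuinely open; the orthonormalized-occupied-space
choice is deliberate and is stable under adding redundant working-basis
functions (tested). Rank deficiency of the projected occupied space
raises with the Gram condition number rather than silently regularizing.

## Quadrature

Real-space schemes integrate on a Becke fuzzy-cell molecular grid:
per-atom products of a 75-point Gauss–Chebyshev radial rule (mapped to
(0,∞) by r = (1+x)/(1−x)) and a Gauss–Legendre × uniform-azimuth angular
product rule of order 16 (512 angular points, exact to spherical-harmonic
degree ~31 — comparable to an octahedral rule of similar size; no table
of octahedrally symmetric nodes is shipped, which keeps the angular code
twenty lines). Cells use the k=3 smoothed step function, giving a
partition of unity to 1e-12. The defaults integrate the Slater test
densities to ~1e-6 relative; the contracted contract is 1e-4.

Proatoms: the bundled database is an analytic single-ζ Slater model,
ρ(r) = N ζ³/(8π) e^(−ζr) with N = Z − q, ζ(Z, q) = ζ₀(Z)(1 + 0.15 q),
for H–Ar and charges −1…+2. The ζ₀ are single-zeta valence-like values
(H 1.00, C 1.57, N 1.92, O 2.25, …). This is a model choice, made so the
package is self-contained and stockholder parameter-recovery tests are
exact-in-family; it is not an ab initio atomic density, and users with
tabulated profiles can load them (`ProatomDatabase.from_files`), where
radial tables get an exponential tail beyond the last point and a
constant below the first so stockholder weights stay positive.

## Stockholder schemes

All four share `w_A = ρ_A / Σ_B ρ_B`; grid points where the promolecule
falls below 1e-12 e/Bohr³ get zero weight and are excluded (avoids 0/0 in
vacuum). Defaults: population tolerance 1e-6, 500 iterations, recorded in
diagnostics.

- Hirshfeld: fixed neutral proatoms.
- Hirshfeld-I: populations iterated with proatom densities linearly
  interpolated between integer charge states; iteration 0 is exactly
  plain Hirshfeld. Populations leaving the available charge-state bracket
  raise (extrapolated proatoms are unphysical) naming the needed state.
- ISA: profiles on 64 log-spaced shells (0.02–20 Bohr, linear
  interpolation between shells, zero beyond), initialized to e^(−r),
  updated as the spherical average of `w_A ρ` on a per-atom angular grid.
  Convergence on the maximum relative per-shell change (default 1e-5).
- MBIS: per-atom sums of Slater shells, one per periodic-table row
  (H,He: 1; Li–Ne: 2; Na–Ar: 3), with the standard self-consistent
  updates for shell populations N_k and widths σ_k. Two practical
  safeguards: shells whose population collapses below 1e-6 e are pruned,
  and shells on one atom whose widths coalesce within 10% are merged
  (two equal-width Slater shells are a single shell with an unidentified
  population split — on single-exponential test densities the split
  otherwise drifts forever at fixed total). Real atomic core/valence
  widths differ by factors of 3–5, far outside the merge window. Both
  events are recorded in diagnostics.

Determinism: no stockholder loop contains randomness; reruns are
bitwise-identical.

## Space-partition schemes

- VDD: q_A = −∫ over the Voronoi cell of A of (ρ − ρ_promolecule).
  Boundary voxels (exactly equidistant) go to the lower atom index; the
  effect vanishes with refinement.
- Grid Bader: deterministic near-grid steepest ascent over the 26-voxel
  stencil (gain = density difference / physical step length; ties to the
  lowest flat voxel index), followed by pointer-jumping to resolve every
  voxel to its attractor. Maxima within 0.4 Bohr of a nucleus belong to
  it; non-nuclear attractors are merged into the nearest nucleus with a
  logged warning; a nucleus with no nearby maximum aborts with a
  "grid too coarse" error. Voxels below 1e-8 e/Bohr³ are vacuum and
  unassigned (affects charges at the ~1e-4 e level on test scenes). This
  is an approximation to analytic zero-flux QTAIM: basin boundaries are
  voxelized, and parity with analytic-basin codes is approximate by
  construction, improving with grid refinement (tested over three
  halvings).

Box truncation matters as much as voxel size for cube-based charges: a
Slater atom with ζ ≈ 1.9 keeps ~4e-3 e outside a 5 Bohr margin and ~3e-5
outside 8 Bohr. The planted-transfer tests use 8 Bohr margins for this
reason.

## ESP fitting and empirical models

One generic constrained least-squares fitter: minimize
Σ_k (V_k − Σ_A q_A/|r_k − R_A|)² subject to Σ q_A = Q, solved as a single
bordered linear system; the relative RMS of the fit is reported. The
bundled point selector is CHELPG-style — a rectangular lattice (default
0.3 Å) clipped between the scaled Bondi vdW surface and a 2.8 Å outer
envelope. Shell-based Merz–Kollman point sets, HLY density weighting and
RESP restraints are intentionally not implemented; outputs are labelled
`esp-chelpg` so nothing overclaims. Whenever the field is generated by
nuclear-centered point charges the fit is exact (residual < 1e-10) for
any geometry and valid point set.

CM5 adds the published pairwise exponential correction to Hirshfeld
charges (atomwise D_Z for H–Ar, the six pairwise H/C/N/O overrides,
α = 2.474 Å⁻¹, Pyykkö–Atsumi covalent radii). T is antisymmetric, so the
total charge is conserved identically; elements beyond Ar raise rather
than silently contributing zero.

EEQ minimizes Σ_A (χ_A q_A + ½ η_A q_A²) + ½ Σ_{A≠B} q_A q_B
erf(r_AB/γ_AB)/r_AB with γ_AB = √(a_A² + a_B²) under the total-charge
constraint, as one (n+1)×(n+1) solve. The bundled χ/η/a table is a
self-contained model (χ a linear map of Pauling electronegativities; η
chosen to dominate the screened Coulomb coupling at bonding distances,
without which the equalization changes sign; a grows with the period).
It does not reproduce any external program's fitted constants, and the
coordination-number-dependent electronegativities of production EEQ
implementations are out of scope. All three parameter sets are
overridable per call.

## Meta-analysis

One atom = one observation; atoms are pooled across molecules,
unweighted, and only complete cases across the selected methods enter
(holes are never imputed; the dropped-row count is returned). Pooling
unweighted is a deliberate choice — per-molecule weighting or
element-stratified sampling would answer different questions, and heavy
hydrogen representation in pooled molecular datasets is a known caveat.

- Correlation/covariance: Pearson, denominator n−1, unit diagonal
  enforced; zero-variance columns raise with the method named.
- PCA: dense symmetric eigendecomposition, eigenvalues descending,
  each loading's sign fixed so its largest-magnitude entry is negative
  (a cosmetic convention that makes the leading "ionicity" component of
  pooled charge data print with all-negative coefficients; recorded in
  the result).
- Backward elimination (Jolliffe): repeatedly remove the variable with
  the largest coefficient in the smallest-eigenvalue eigenvector,
  recomputing each round.
- GCD subset selection: GCD(S, k) = trace(P_S P_K)/k with P_S the
  projector onto the subset's centered data columns and P_K onto the
  first k covariance-PC score vectors; 1 iff the subspaces coincide.
  Exhaustive search up to 20 variables; otherwise simulated annealing
  with single-swap moves, geometric cooling (T₀ = 0.2, α = 0.9, 40
  moves per temperature, floor 1e-4), seeded and reproducible. On every
  ≤ 12-variable fixture the annealer matches the exhaustive optimum.
- Noise robustness: append ⌈fraction·n⌉ rows drawn independently per
  column from its empirical marginal (destroying cross-correlation; a
  uniform-over-range variant is available via `model="uniform"`),
  recompute the PCA, and report eigenvalue shifts plus the largest
  principal angle between original and perturbed leading-d loading
  subspaces, per repetition and seed.

Dataset curation: species whose atoms are all equivalent under a
sorted-distance-matrix fingerprint (atoms, homonuclear diatomics,
P4-like clusters) carry no charge information and are dropped.
Duplicates are geometries with identical stoichiometry whose three
principal moments of inertia agree within a relative tolerance (default
1e-4); enantiomers are indistinguishable under this criterion and are
collapsed — a documented limitation.

## What the synthetic scenes show — and what they do not

The generators plant ground truth inside each scheme's own model family:
Slater superpositions for the real-space partitioners, exact point-charge
fields for the ESP fitter, two-orbital closed forms for the
orbital schemes, low-rank factor models (covariance ΛΛᵀ + diag(σ²)) for
the statistics. Passing tests therefore demonstrate correctness of the
implementations — conservation, fixed points, parameter recovery, search
optimality — not chemical accuracy on real molecular densities, where
proatoms are not single Slater functions and method disagreements are
the object of study rather than an error. Numeric parity with published
per-molecule charge values is deliberately not asserted anywhere; the
full-dataset statistics can be reproduced by dropping the published
supplementary workbook into `data/si/` (see the README there).

## Problem sizes

Default test/verification sizes, chosen to exercise every code path at
interactive cost: diatomic Slater scenes on 0.15–0.3 Bohr cubes
(≤ ~2×10⁶ voxels), Becke grids of 75×512 points per atom, factor tables
of 2500–5000 observations × 5–7 methods, subset searches over ≤ 7
variables with 3 annealing seeds. The whole suite runs in about a
minute on one CPU.
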