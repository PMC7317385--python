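# arboretum

Atomic partial charges are the workhorse interpretive tool of quantum
chemistry, yet dozens of inequivalent "population analyses" coexist:
orbital partitionings (Mulliken and its Löwdin/Bickelhaupt variants,
with or without minimal-basis projection), real-space stockholder
partitionings (Hirshfeld, Hirshfeld-I, ISA, MBIS), discrete space
partitionings (Voronoi deformation density, Bader/QTAIM basins),
electrostatic-potential fits (CHELPG-style), and empirical models (CM5,
EEQ). Each is best read as a proxy for a latent "ionicity" rather than
as a measurement of it.

`arboretum` is a toolkit for computational chemists who want to

1. **compute** many charge flavors from common density/wavefunction
   representations (Gaussian cube files, a documented JSON wavefunction
   container, XYZ geometries), and
2. **compare** them statistically: pool per-atom charges across a
   molecule set, build correlation/covariance matrices, extract
   "principal components of ionicity" by PCA, select maximally
   informative variable subsets with the GCD (generalized coefficient of
   determination) criterion via exhaustive search or simulated
   annealing, run backward elimination and regressions, and check how
   robust the component structure is to sample adulteration.

## The core quantities

Every scheme produces per-atom charges `q_A = Z_A − N_A`, differing in
how the electron count N_A is attributed:

- orbital partitioning condenses the overlap populations
  `q_ij = P_ij S_ij`; Mulliken splits off-diagonal pairs evenly, the
  Bickelhaupt weighting splits them as `q_ii/(q_ii + q_jj)`, and a
  minimal-basis projection of the occupied orbitals
  (`C_m = S_mm⁻¹ S_mf C_occ`, Löwdin re-orthonormalized) removes the
  basis-set hypersensitivity, giving MBS-Mulliken and MBS-Bickelhaupt;
- stockholder schemes share each grid point as
  `w_A = ρ_A^proatom / Σ_B ρ_B^proatom` and differ in where the proatom
  comes from (fixed, iterated over charge states, spherical averages, or
  Slater shells);
- VDD integrates the deformation density over Voronoi cells; grid Bader
  assigns voxels to density maxima by steepest ascent;
- the ESP fitter solves a total-charge-constrained least squares on
  CHELPG-style points; CM5 and EEQ are closed-form/linear-solve models.

The meta-analysis treats each atom as one observation and each method as
one variable. On a correlation matrix R the PCA eigenvalues sum to the
dimension; the GCD of a k-subset S is `trace(P_S · P_K)/k`, the overlap
between the subset's column span and the leading-k principal-component
span.

## Worked example

Rebuild the correlation block of the four iterative stockholder-family
methods from its published squared correlations and look at its spectrum:

```python
import arboretum as ab
from arboretum.ionicity_meta import (
    TABLE_IIB1_SQUARED_CORRELATIONS, correlation_from_squared,
)

corr = correlation_from_squared(TABLE_IIB1_SQUARED_CORRELATIONS)
res = ab.pca(corr, "correlation")
print(res.eigenvalues.round(4))
# [3.9342 0.0468 0.0148 0.0042]
```

The leading eigenvalue (3.93 of a possible 4) says the four methods move
almost entirely in lockstep — one shared "ionicity" axis; the tiny
remainder is mostly ISA pulling against the other three.

Partition a planted density with iterative Hirshfeld and recover the
transferred charge:

```python
import numpy as np
from arboretum.synthetic_fixtures import (
    SlaterAtom, SlaterSceneSpec, make_slater_scene,
)

scene = make_slater_scene(SlaterSceneSpec(
    atoms=[SlaterAtom("N", np.zeros(3), 7.3, 1.92),
           SlaterAtom("N", np.array([0.0, 0.0, 12.0]), 6.7, 1.92)],
    spacing=0.25))
grid = ab.build_becke_grid(scene.geometry)
density = ab.promolecule_density(
    scene.geometry, scene.database, populations=np.array([7.3, 6.7]))
charges, trace = ab.hirshfeld_iterative(
    density, scene.geometry, scene.database, grid)
print(charges.charges.round(6), trace.n_iterations)
# [-0.300003  0.299998] 3
```

The scene plants 0.3 electrons moved from one nitrogen-like Slater atom
to the other; the iteration lands on the planted populations (charges
∓0.3) because the density is a fixed point of the proatom interpolation.

The same operations are available from the shell:

```
arboretum fixtures slater-scene --spacing 0.25 --out scene.cube
arboretum charges hirshfeld-i --cube scene.cube
arboretum charges eeq --geometry mol.xyz --charge 0
arboretum ionicity pca --table charges.csv --methods hirshfeld,mbis,qtaim \
    --matrix covariance
arboretum ionicity select --table charges.csv --methods ... --k 3 --search anneal
```

## Layout

- `src/arboretum/core_io.py` — domain types; XYZ/cube/CSV/XLSX/JSON readers
  and writers (`docs/wavefunction.md` documents the JSON schema)
- `src/arboretum/quadrature.py` — Becke grids, Slater proatom database,
  promolecules
- `src/arboretum/orbital_charges.py` — Mulliken/Löwdin/Bickelhaupt and
  minimal-basis projections
- `src/arboretum/stockholder_charges.py` — Hirshfeld, Hirshfeld-I, ISA, MBIS
- `src/arboretum/space_partition_charges.py` — VDD and grid Bader
- `src/arboretum/esp_empirical_charges.py` — CHELPG points, constrained ESP
  fit, CM5, EEQ
- `src/arboretum/ionicity_meta.py` — observation assembly, curation, PCA,
  GCD selection, regression, noise robustness
- `src/arboretum/synthetic_fixtures.py` — deterministic generators with
  closed-form oracles
- `docs/methods.md` — models, parameters, numerics, and limitations
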