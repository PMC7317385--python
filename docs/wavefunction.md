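# JSON wavefunction container

A self-describing, code-agnostic carrier for everything the
orbital-partition charges need: geometry, Gaussian basis, one-particle
density matrix, and overlap matrix. Produced by
`arboretum.write_wavefunction`, consumed by `arboretum.read_wavefunction`
and `arboretum charges mulliken|lowdin|bickelhaupt|mbs-* --wavefn`.

```json
{
  "geometry": {
    "symbols": ["H", "F"],
    "positions_bohr": [[0.0, 0.0, 0.0], [0.0, 0.0, 1.733]],
    "total_charge": 0,
    "label": "hf"
  },
  "basis": {
    "shells": [
      {"atom": 0, "l": 0, "exponents": [1.0], "coefficients": [1.0]},
      {"atom": 1, "l": 0, "exponents": [1.0], "coefficients": [1.0]}
    ]
  },
  "density_matrix": [[...], [...]],
  "overlap_matrix": [[...], [...]],
  "n_electrons": 2.0
}
```

Rules enforced on load:

- `overlap_matrix` is required ("overlap required"): the toolkit ships no
  integral engine, so S travels with the data. Analytic overlaps are
  computed internally only for s-function fixture bases.
- P and S must be symmetric, S positive definite, and
  `trace(P S) = n_electrons` within 1e-6 ("inconsistent electron count").
- `density_matrix` is the total (spin-summed) matrix; closed-shell
  idempotency (`P S P = 2 P`) is required only by the minimal-basis
  projection, which recovers occupied natural orbitals from it.
- AO ordering follows shell order, each shell contributing its 2l+1
  spherical components contiguously; `atom` indices are 0-based.

Producers with real electronic-structure output (e.g. via cclib) should
export the AO-basis density and overlap matrices in this layout and may
attach any minimal basis the same way (a second container whose `basis`
is the minimal set, passed to `--minimal-basis`).
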