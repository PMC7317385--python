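"""Orbital-partition charges: Mulliken, Löwdin, Bickelhaupt, and their
minimal-basis-projected (MBS) variants.

The common object is the gross overlap-population matrix
q_ij = P_ij * S_ij, whose total equals the electron count.  Mulliken
condenses it by splitting each off-diagonal pair evenly,

    Q'_ii = q_ii + 1/2 * sum_{j != i} (q_ij + q_ji),

while the Bickelhaupt weighting splits in proportion to the diagonal
populations,

    Q'_ii = q_ii + sum_{j != i} q_ii / (q_ii + q_jj) * (q_ij + q_ji).

Both redistribute — never create — population, so atomic charges sum to
the molecular charge to machine precision.

Minimal-basis projection removes the pathological basis-set sensitivity
of Mulliken-type analyses: the occupied orbitals are projected onto one
minimal function set per atom and re-orthonormalized (Löwdin) within it,
which preserves idempotency and the electron count; Mulliken or
Bickelhaupt condensation in the projected basis then yields MBS-Mulliken
and MBS-Bickelhaupt charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ChargeVector, GaussianBasis, Geometry, WavefunctionState

__all__ = [
    "OverlapPopulationMatrix",
    "ShellPopulation",
    "overlap_populations",
    "condense",
    "atom_charges",
    "mulliken_charges",
    "bickelhaupt_charges",
    "lowdin_charges",
    "build_overlap",
    "project_minimal_basis",
    "mbs_charges",
]

ZERO_DENOMINATOR = 1e-10


@dataclass
class OverlapPopulationMatrix:
    """Gross overlap populations q_ij = P_ij S_ij (electrons)."""

    q: np.ndarray
    ao_to_atom: np.ndarray
    n_electrons: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.ao_to_atom = np.asarray(self.ao_to_atom, dtype=int)
        total = float(self.q.sum())
        if abs(total - self.n_electrons) > 1e-8 * max(1.0, abs(self.n_electrons)):
            raise ValueError(
                f"overlap populations sum to {total}, expected {self.n_electrons}"
            )


@dataclass
class ShellPopulation:
    """Condensed per-AO populations Q'_ii."""

    populations: np.ndarray
    variant: str
    ao_to_atom: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def overlap_populations(wavefn: WavefunctionState) -> OverlapPopulationMatrix:
    q = wavefn.density_matrix * wavefn.overlap_matrix
    return OverlapPopulationMatrix(q, wavefn.basis.ao_to_atom(), wavefn.n_electrons)


def condense(opm: OverlapPopulationMatrix, variant: str) -> ShellPopulation:
    """Condense off-diagonal overlap populations onto the diagonal.

    variant="mulliken": even split.  variant="bickelhaupt":
    diagonal-population-weighted split; pairs whose diagonal populations
    sum to ~0 fall back to the even split (recorded in diagnostics).
    """
    q = opm.q
    n = len(q)
    diag = np.diag(q).copy()
    off = q + q.T
    np.fill_diagonal(off, 0.0)
    diagnostics: dict = {}
    if variant == "mulliken":
        pops = diag + 0.5 * off.sum(axis=1)
    elif variant == "bickelhaupt":
        denom = diag[:, None] + diag[None, :]
        bad = np.abs(denom) < ZERO_DENOMINATOR
        weights = np.empty_like(denom)
        safe = ~bad
        weights[safe] = diag[:, None].repeat(n, axis=1)[safe] / denom[safe]
        weights[bad] = 0.5
        np.fill_diagonal(weights, 0.0)
        np.fill_diagonal(bad, False)
        if np.any(bad & (off != 0.0)):
            pairs = [tuple(int(v) for v in ij) for ij in np.argwhere(bad & (off != 0.0)) if ij[0] < ij[1]]
            diagnostics["zero_denominator_pairs"] = pairs
        pops = diag + (weights * off).sum(axis=1)
    else:
        raise ValueError(f"unknown condensation variant {variant!r}")
    total = float(pops.sum())
    if abs(total - opm.n_electrons) > 1e-8 * max(1.0, abs(opm.n_electrons)):
        raise AssertionError(
            f"condensation lost population: {total} vs {opm.n_electrons}"
        )
    return ShellPopulation(pops, variant, opm.ao_to_atom, diagnostics)


def atom_charges(
    shell_pop: ShellPopulation, geometry: Geometry, basis: GaussianBasis | None = None
) -> ChargeVector:
    """q_A = Z_A - sum of condensed populations on atom A."""
    ao_to_atom = shell_pop.ao_to_atom if basis is None else basis.ao_to_atom()
    pops = np.zeros(geometry.n_atoms)
    np.add.at(pops, ao_to_atom, shell_pop.populations)
    charges = geometry.numbers - pops
    return ChargeVector(
        charges,
        method=shell_pop.variant,
        geometry=geometry,
        diagnostics=dict(shell_pop.diagnostics),
    )


def mulliken_charges(wavefn: WavefunctionState) -> ChargeVector:
    cv = atom_charges(condense(overlap_populations(wavefn), "mulliken"), wavefn.geometry)
    cv.method = "mulliken"
    return cv


def bickelhaupt_charges(wavefn: WavefunctionState) -> ChargeVector:
    cv = atom_charges(
        condense(overlap_populations(wavefn), "bickelhaupt"), wavefn.geometry
    )
    cv.method = "bickelhaupt"
    return cv


def _matrix_half(S: np.ndarray, inverse: bool = False) -> np.ndarray:
    ev, U = np.linalg.eigh(S)
    if ev.min() <= 0:
        raise ValueError(
            f"overlap matrix not positive definite (min eigenvalue {ev.min():.3e})"
        )
    power = -0.5 if inverse else 0.5
    return (U * ev**power) @ U.T


def lowdin_charges(wavefn: WavefunctionState) -> ChargeVector:
    """Löwdin populations: diagonal of S^1/2 P S^1/2 summed per atom."""
    s_half = _matrix_half(wavefn.overlap_matrix)
    pops_ao = np.diag(s_half @ wavefn.density_matrix @ s_half)
    pops = np.zeros(wavefn.geometry.n_atoms)
    np.add.at(pops, wavefn.basis.ao_to_atom(), pops_ao)
    return ChargeVector(
        wavefn.geometry.numbers - pops, method="lowdin", geometry=wavefn.geometry
    )


# ---------------------------------------------------------------------------
# Analytic overlaps for s-type contracted Gaussians (fixture support)
# ---------------------------------------------------------------------------

def _s_primitive_overlap(alpha: float, beta: float, r2: float) -> float:
    """Overlap of two normalized s-type Gaussian primitives a distance
    sqrt(r2) apart."""
    na = (2 * alpha / math.pi) ** 0.75
    nb = (2 * beta / math.pi) ** 0.75
    return (
        na * nb * (math.pi / (alpha + beta)) ** 1.5
        * math.exp(-alpha * beta / (alpha + beta) * r2)
    )


def _contracted_s_overlap(sh_a, sh_b, r2: float) -> float:
    s = 0.0
    for ea, ca in zip(sh_a.exponents, sh_a.coefficients):
        for eb, cb in zip(sh_b.exponents, sh_b.coefficients):
            s += ca * cb * _s_primitive_overlap(ea, eb, r2)
    return s


def build_overlap(
    basis_a: GaussianBasis,
    basis_b: GaussianBasis,
    geometry_a: Geometry,
    geometry_b: Geometry | None = None,
) -> np.ndarray:
    """Analytic overlap between two s-function-only bases.

    Contracted functions are normalized.  Raises for l > 0 shells: higher
    angular momenta must come with externally supplied overlap matrices
    (the wavefunction container stores S; no general integral engine is
    shipped).
    """
    geometry_b = geometry_b or geometry_a
    for b in (basis_a, basis_b):
        if any(sh.l != 0 for sh in b.shells):
            raise NotImplementedError(
                "analytic overlaps implemented for s shells only; supply "
                "overlap matrices for higher angular momenta"
            )
    norm_a = [
        1.0 / math.sqrt(_contracted_s_overlap(sh, sh, 0.0)) for sh in basis_a.shells
    ]
    norm_b = [
        1.0 / math.sqrt(_contracted_s_overlap(sh, sh, 0.0)) for sh in basis_b.shells
    ]
    S = np.empty((len(basis_a.shells), len(basis_b.shells)))
    for i, sh_a in enumerate(basis_a.shells):
        for j, sh_b in enumerate(basis_b.shells):
            r2 = float(
                np.sum(
                    (
                        geometry_a.positions[sh_a.atom]
                        - geometry_b.positions[sh_b.atom]
                    )
                    ** 2
                )
            )
            S[i, j] = norm_a[i] * norm_b[j] * _contracted_s_overlap(sh_a, sh_b, r2)
    return S


# ---------------------------------------------------------------------------
# Minimal-basis projection
# ---------------------------------------------------------------------------

def _occupied_orbitals(wavefn: WavefunctionState) -> np.ndarray:
    """Recover S-orthonormal occupied orbitals from a closed-shell P.

    Natural orbitals of S^1/2 P S^1/2 with occupation > 1 (i.e. ~2 for an
    idempotent closed-shell P) are taken as occupied.
    """
    s_half = _matrix_half(wavefn.overlap_matrix)
    s_inv_half = _matrix_half(wavefn.overlap_matrix, inverse=True)
    occ_mat = s_half @ wavefn.density_matrix @ s_half
    ev, U = np.linalg.eigh(occ_mat)
    occupied = ev > 1.0
    n_occ = int(round(wavefn.n_electrons / 2.0))
    if occupied.sum() != n_occ:
        raise ValueError(
            f"density matrix is not a closed-shell idempotent: found "
            f"{int(occupied.sum())} occupied natural orbitals, expected {n_occ}"
        )
    return s_inv_half @ U[:, occupied]


def project_minimal_basis(
    wavefn: WavefunctionState,
    minimal_basis: GaussianBasis,
    s_mm: np.ndarray | None = None,
    s_mf: np.ndarray | None = None,
    cond_limit: float = 1e10,
) -> WavefunctionState:
    """Project the occupied orbitals onto a minimal basis.

    C_m = S_mm^-1 S_mf C_occ, followed by Löwdin orthonormalization of the
    projected occupieds within the minimal basis, which restores
    idempotency and the electron count.  S_mm / S_mf may be supplied; for
    s-function bases they are computed analytically.
    """
    minimal_basis.validate_against(wavefn.geometry)
    present = set(wavefn.geometry.numbers[
        [sh.atom for sh in wavefn.basis.shells]
    ].tolist())
    covered = set(wavefn.geometry.numbers[
        [sh.atom for sh in minimal_basis.shells]
    ].tolist())
    atoms_with_min = {sh.atom for sh in minimal_basis.shells}
    if atoms_with_min != set(range(wavefn.geometry.n_atoms)):
        missing = sorted(set(range(wavefn.geometry.n_atoms)) - atoms_with_min)
        raise ValueError(f"minimal basis lacks functions on atoms {missing}")
    del present, covered

    if s_mm is None:
        s_mm = build_overlap(minimal_basis, minimal_basis, wavefn.geometry)
    if s_mf is None:
        s_mf = build_overlap(minimal_basis, wavefn.basis, wavefn.geometry)
    s_mm = np.asarray(s_mm, dtype=float)
    s_mf = np.asarray(s_mf, dtype=float)

    c_occ = _occupied_orbitals(wavefn)
    c_m = np.linalg.solve(s_mm, s_mf @ c_occ)
    gram = c_m.T @ s_mm @ c_m
    cond = float(np.linalg.cond(gram))
    ev_min = float(np.linalg.eigvalsh(gram).min())
    if ev_min <= 0 or cond > cond_limit:
        raise ValueError(
            "projected occupied orbitals are (nearly) linearly dependent in "
            f"the minimal basis: Gram condition number {cond:.3e}"
        )
    c_tilde = c_m @ _matrix_half(gram, inverse=True)
    p_m = 2.0 * c_tilde @ c_tilde.T
    return WavefunctionState(
        wavefn.geometry, minimal_basis, p_m, s_mm, wavefn.n_electrons
    )


def mbs_charges(
    wavefn: WavefunctionState,
    minimal_basis: GaussianBasis,
    variant: str = "mulliken",
    s_mm: np.ndarray | None = None,
    s_mf: np.ndarray | None = None,
) -> ChargeVector:
    """MBS-Mulliken / MBS-Bickelhaupt: project, condense, take charges."""
    projected = project_minimal_basis(wavefn, minimal_basis, s_mm=s_mm, s_mf=s_mf)
    cv = atom_charges(
        condense(overlap_populations(projected), variant), wavefn.geometry
    )
    cv.method = f"mbs-{variant}"
    return cv
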