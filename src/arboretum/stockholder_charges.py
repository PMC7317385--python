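"""Stockholder (fuzzy-domain) charges: Hirshfeld, Hirshfeld-I, ISA, MBIS.

All four share one primitive: at every grid point the molecular density
is divided among atoms in proportion to per-atom proatom densities,
w_A = rho_A / sum_B rho_B.  They differ in where the proatoms come from:

* Hirshfeld: fixed neutral proatoms from a database.
* Hirshfeld-I: proatom populations iterated to self-consistency, with
  densities linearly interpolated between integer ionization states.
* ISA: no database at all — each proatom profile is the spherical average
  of that atom's share of the molecular density, iterated to a fixed
  point.
* MBIS: proatoms are sums of Slater shells (one per periodic-table row of
  the element), with shell populations and widths updated
  self-consistently.

Grid points where the promolecule density underflows (< 1e-12 e/Bohr^3)
receive zero weight for every atom and are excluded from integrals,
avoiding 0/0 in near-vacuum regions.

Every loop here is deterministic: identical inputs give bitwise-identical
iteration traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import ChargeVector, Geometry, VolumetricField
from .ptable import symbol_of
from .quadrature import ProatomDatabase, QuadratureGrid, _angular_rule, integrate

__all__ = [
    "StockholderWeights",
    "IterationTrace",
    "MBISProatom",
    "hirshfeld",
    "hirshfeld_iterative",
    "isa",
    "mbis",
]

PROMOLECULE_UNDERFLOW = 1e-12
# two Slater shells of near-equal width are one shell with an unidentified
# population split; real core/valence shells differ by 3-5x in width
MERGE_RELATIVE_WIDTH = 0.10


@dataclass
class StockholderWeights:
    """Per-atom stockholder shares on a grid, rows = atoms."""

    w: np.ndarray  # (n_atoms, n_points)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.min() < 0:
            raise ValueError("negative stockholder weight")


@dataclass
class IterationTrace:
    """Convergence record: per-iteration populations and max parameter change."""

    populations: list = field(default_factory=list)
    deltas: list = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0


@dataclass
class MBISProatom:
    """Converged MBIS shell parameters for one atom."""

    atom: int
    shell_populations: np.ndarray   # N_k, electrons
    shell_widths: np.ndarray        # sigma_k, Bohr

    def density(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for n_k, s_k in zip(self.shell_populations, self.shell_widths):
            out += n_k / (8.0 * math.pi * s_k**3) * np.exp(-r / s_k)
        return out


# ---------------------------------------------------------------------------
# plumbing
# ---------------------------------------------------------------------------

def density_values(density, grid: QuadratureGrid) -> np.ndarray:
    """Evaluate a density (callable, VolumetricField, or pre-aligned array)
    on grid points."""
    if isinstance(density, VolumetricField):
        return np.asarray(density.interpolator()(grid.points), dtype=float)
    if callable(density):
        return np.asarray(density(grid.points), dtype=float)
    values = np.asarray(density, dtype=float).ravel()
    if len(values) != len(grid):
        raise ValueError("density array does not align with the grid")
    return values


def _density_callable(density):
    if isinstance(density, VolumetricField):
        return density.interpolator()
    if callable(density):
        return density
    raise TypeError(
        "this scheme needs a density evaluable at arbitrary points: pass a "
        "callable or a VolumetricField, not a bare array"
    )


def _atom_distances(geometry: Geometry, points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(
        points[None, :, :] - geometry.positions[:, None, :], axis=-1
    )


def _weights_from_proatoms(pro: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stockholder weights from per-atom proatom values (n_atoms, n_pts);
    returns (weights, valid mask)."""
    promol = pro.sum(axis=0)
    valid = promol >= PROMOLECULE_UNDERFLOW
    w = np.zeros_like(pro)
    w[:, valid] = pro[:, valid] / promol[valid]
    return w, valid


def _charges_from_populations(
    geometry: Geometry, populations: np.ndarray, method: str, diagnostics: dict
) -> ChargeVector:
    charges = geometry.numbers - populations
    diagnostics = dict(diagnostics)
    diagnostics["charge_sum_defect"] = float(
        charges.sum() - geometry.total_charge
    )
    return ChargeVector(charges, method=method, geometry=geometry,
                        diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Hirshfeld
# ---------------------------------------------------------------------------

def hirshfeld(
    density,
    geometry: Geometry,
    proatom_db: ProatomDatabase,
    grid: QuadratureGrid,
) -> ChargeVector:
    """Original stockholder charges with fixed neutral proatoms:
    q_A = Z_A - int w_A rho with w_A = rho_A^0 / sum_B rho_B^0."""
    rho = density_values(density, grid)
    dists = _atom_distances(geometry, grid.points)
    pro = np.stack(
        [
            proatom_db.density(z, 0, dists[a])
            for a, z in enumerate(geometry.numbers)
        ]
    )
    w, valid = _weights_from_proatoms(pro)
    rho_masked = np.where(valid, rho, 0.0)
    populations = np.array(
        [integrate(w[a] * rho_masked, grid) for a in range(geometry.n_atoms)]
    )
    return _charges_from_populations(
        geometry, populations, "hirshfeld",
        {"excluded_points": int((~valid).sum())},
    )


# ---------------------------------------------------------------------------
# Hirshfeld-I
# ---------------------------------------------------------------------------

def _interpolated_proatoms(
    geometry: Geometry,
    proatom_db: ProatomDatabase,
    populations: np.ndarray,
    dists: np.ndarray,
) -> np.ndarray:
    """Per-atom proatom densities at (possibly fractional) populations via
    linear interpolation between integer charge states."""
    pro = np.zeros_like(dists)
    for a, (z, n_pop) in enumerate(zip(geometry.numbers, populations)):
        available = proatom_db.available_charges(z)
        pops_avail = sorted(z - q for q in available)
        if not pops_avail or n_pop < pops_avail[0] - 1e-9 or n_pop > pops_avail[-1] + 1e-9:
            lo_q = int(z - math.floor(n_pop))
            raise ValueError(
                f"atom {a} ({symbol_of(z)}) population {n_pop:.6f} exits the "
                f"available charge-state bracket {available}; add the "
                f"charge {lo_q:+d} proatom to the database"
            )
        lo = math.floor(n_pop)
        frac = n_pop - lo
        if abs(frac) < 1e-12:
            pro[a] = proatom_db.density(z, int(z - lo), dists[a])
        else:
            pro[a] = (1.0 - frac) * proatom_db.density(z, int(z - lo), dists[a]) \
                + frac * proatom_db.density(z, int(z - lo - 1), dists[a])
    return pro


def hirshfeld_iterative(
    density,
    geometry: Geometry,
    proatom_db: ProatomDatabase,
    grid: QuadratureGrid,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[ChargeVector, IterationTrace]:
    """Hirshfeld-I: fixed-point iteration of the proatom populations.

    Iteration 0 uses neutral proatoms, so its populations are exactly the
    plain Hirshfeld result on the same grid; tol=inf therefore returns
    Hirshfeld after one evaluation.
    """
    rho = density_values(density, grid)
    dists = _atom_distances(geometry, grid.points)
    populations = geometry.numbers.astype(float)
    trace = IterationTrace()
    for it in range(max_iter):
        pro = _interpolated_proatoms(geometry, proatom_db, populations, dists)
        w, valid = _weights_from_proatoms(pro)
        rho_masked = np.where(valid, rho, 0.0)
        new_pops = np.array(
            [integrate(w[a] * rho_masked, grid) for a in range(geometry.n_atoms)]
        )
        delta = float(np.max(np.abs(new_pops - populations)))
        trace.populations.append(new_pops.copy())
        trace.deltas.append(delta)
        populations = new_pops
        trace.n_iterations = it + 1
        if delta < tol:
            trace.converged = True
            break
    if not trace.converged and not math.isinf(tol):
        raise RuntimeError(
            f"Hirshfeld-I did not converge in {max_iter} iterations "
            f"(last max|dN| = {trace.deltas[-1]:.3e}); trace attached",
        )
    if math.isinf(tol):
        trace.converged = True
    cv = _charges_from_populations(
        geometry, populations, "hirshfeld-i",
        {"iterations": trace.n_iterations, "final_delta": trace.deltas[-1],
         "tolerance": tol},
    )
    return cv, trace


# ---------------------------------------------------------------------------
# ISA
# ---------------------------------------------------------------------------

def isa(
    density,
    geometry: Geometry,
    grid: QuadratureGrid,
    tol: float = 1e-5,
    max_iter: int = 500,
    n_shells: int = 64,
    r_min: float = 0.02,
    r_max: float = 20.0,
    angular_order: int = 14,
) -> tuple[ChargeVector, IterationTrace]:
    """Iterative Stockholder Approach: proatom profiles are the spherical
    averages of each atom's share of rho, iterated to a fixed point.

    Profiles live on log-spaced radial shells with linear interpolation in
    between; initial profiles are exp(-r).  Convergence is on the maximum
    relative per-shell profile change.
    """
    rho_eval = _density_callable(density)
    n_at = geometry.n_atoms
    radii = np.geomspace(r_min, r_max, n_shells)
    ang_pts, ang_wts = _angular_rule(angular_order)
    ang_wts = ang_wts / (4.0 * math.pi)  # spherical mean weights

    # sampling points for spherical averaging, per atom: (shells, ang, 3)
    sphere_pts = []
    sphere_rho = []
    for a in range(n_at):
        pts = geometry.positions[a] + radii[:, None, None] * ang_pts[None, :, :]
        pts = pts.reshape(-1, 3)
        sphere_pts.append(pts)
        sphere_rho.append(np.asarray(rho_eval(pts), dtype=float))

    # distances from every atom to every sampling point of every atom
    dists_to_samples = [
        _atom_distances(geometry, sphere_pts[a]) for a in range(n_at)
    ]

    profiles = np.exp(-radii)[None, :].repeat(n_at, axis=0)

    def profile_at(a: int, r: np.ndarray) -> np.ndarray:
        return np.interp(r, radii, profiles[a], left=profiles[a][0], right=0.0)

    trace = IterationTrace()
    for it in range(max_iter):
        new_profiles = np.empty_like(profiles)
        for a in range(n_at):
            pro = np.stack(
                [profile_at(b, dists_to_samples[a][b]) for b in range(n_at)]
            )
            w_a, valid = _weights_from_proatoms(pro)
            shared = np.where(valid, w_a[a] * sphere_rho[a], 0.0)
            new_profiles[a] = (
                shared.reshape(len(radii), -1) * ang_wts[None, :]
            ).sum(axis=1)
        rel = np.abs(new_profiles - profiles) / (profiles + 1e-12)
        delta = float(rel.max())
        profiles = new_profiles
        pops_shell = 4.0 * math.pi * np.trapezoid(
            profiles * radii[None, :] ** 2, radii, axis=1
        )
        trace.populations.append(pops_shell.copy())
        trace.deltas.append(delta)
        trace.n_iterations = it + 1
        starved = np.where(pops_shell < 1e-8)[0]
        if starved.size:
            a = int(starved[0])
            raise RuntimeError(
                f"ISA profile collapsed: atom {a} ({geometry.symbols[a]}) is "
                "starved (population ~ 0)"
            )
        if delta < tol:
            trace.converged = True
            break
    if not trace.converged:
        raise RuntimeError(
            f"ISA did not converge in {max_iter} iterations "
            f"(last max relative change = {trace.deltas[-1]:.3e})"
        )

    # final charges on the molecular grid
    rho = density_values(density, grid)
    dists = _atom_distances(geometry, grid.points)
    pro = np.stack([profile_at(a, dists[a]) for a in range(n_at)])
    w, valid = _weights_from_proatoms(pro)
    rho_masked = np.where(valid, rho, 0.0)
    populations = np.array(
        [integrate(w[a] * rho_masked, grid) for a in range(n_at)]
    )
    cv = _charges_from_populations(
        geometry, populations, "isa",
        {"iterations": trace.n_iterations, "final_delta": trace.deltas[-1],
         "n_shells": n_shells},
    )
    return cv, trace


# ---------------------------------------------------------------------------
# MBIS
# ---------------------------------------------------------------------------

def _mbis_shell_count(z: int) -> int:
    if z <= 2:
        return 1
    if z <= 10:
        return 2
    if z <= 18:
        return 3
    raise ValueError(f"MBIS shell counts tabulated for Z <= 18 only (got {z})")


def _mbis_initial(z: int) -> tuple[np.ndarray, np.ndarray]:
    """Aufbau-style initial shell populations and widths."""
    caps = [2.0, 8.0, 8.0]
    n_shells = _mbis_shell_count(z)
    pops = []
    remaining = float(z)
    for k in range(n_shells):
        take = min(caps[k], remaining) if k < n_shells - 1 else remaining
        pops.append(take)
        remaining -= take
    sigma = np.array([(k + 1.0) / z for k in range(n_shells)])
    return np.asarray(pops), sigma


def mbis(
    density,
    geometry: Geometry,
    grid: QuadratureGrid,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[ChargeVector, list[MBISProatom], IterationTrace]:
    """Minimal Basis Iterative Stockholder.

    Proatoms are sums of Slater shells rho_A(r) = sum_k N_k/(8 pi s_k^3)
    exp(-r/s_k), one shell per periodic-table row of the element.  The
    self-consistent updates are

        N_k     <- int rho w_A (shell_k / proatom_A)
        sigma_k <- 1/(3 N_k) int rho w_A (shell_k / proatom_A) |r - R_A|

    converged when no parameter moves more than tol.  Shells whose
    population collapses (N_k < 1e-6) or whose width vanishes are pruned,
    and shells on one atom whose widths coalesce (within 10% relative) are
    merged: two equal-width Slater shells are one shell with an
    unidentified population split, along which the iteration would
    otherwise drift forever.  Both events are recorded in the
    diagnostics.
    """
    rho = density_values(density, grid)
    dists = _atom_distances(geometry, grid.points)
    n_at = geometry.n_atoms
    pops = []
    sigmas = []
    for z in geometry.numbers:
        p, s = _mbis_initial(int(z))
        pops.append(p.copy())
        sigmas.append(s.copy())

    pruned: list[tuple[int, int]] = []
    merged: list[tuple[int, int]] = []
    trace = IterationTrace()

    def shell_values(a: int) -> np.ndarray:
        """(n_shells_a, n_pts) Slater shell densities for atom a."""
        r = dists[a]
        return np.stack(
            [
                n_k / (8.0 * math.pi * s_k**3) * np.exp(-r / s_k)
                for n_k, s_k in zip(pops[a], sigmas[a])
            ]
        )

    for it in range(max_iter):
        shells = [shell_values(a) for a in range(n_at)]
        pro = np.stack([sh.sum(axis=0) for sh in shells])
        w, valid = _weights_from_proatoms(pro)
        rho_masked = np.where(valid, rho, 0.0)
        max_change = 0.0
        for a in range(n_at):
            pro_a = pro[a]
            safe = pro_a > PROMOLECULE_UNDERFLOW
            share = np.zeros_like(pro_a)
            new_n = np.empty_like(pops[a])
            new_s = np.empty_like(sigmas[a])
            for k in range(len(pops[a])):
                share[:] = 0.0
                share[safe] = shells[a][k][safe] / pro_a[safe]
                take = rho_masked * w[a] * share
                n_k = integrate(take, grid)
                new_n[k] = n_k
                if n_k > 1e-12:
                    new_s[k] = integrate(take * dists[a], grid) / (3.0 * n_k)
                else:
                    new_s[k] = sigmas[a][k]
            max_change = max(
                max_change,
                float(np.max(np.abs(new_n - pops[a]))),
                float(np.max(np.abs(new_s - sigmas[a]))),
            )
            pops[a], sigmas[a] = new_n, new_s
            # prune collapsed shells
            keep = (pops[a] >= 1e-6) & (sigmas[a] >= 1e-8)
            if not keep.all():
                for k in np.where(~keep)[0]:
                    pruned.append((a, int(k)))
                pops[a] = pops[a][keep]
                sigmas[a] = sigmas[a][keep]
                if len(pops[a]) == 0:
                    raise RuntimeError(
                        f"all MBIS shells pruned on atom {a} "
                        f"({geometry.symbols[a]})"
                    )
            # merge coalesced (degenerate) shells, scanning widths in order
            order = np.argsort(sigmas[a])
            pops[a], sigmas[a] = pops[a][order], sigmas[a][order]
            k = 0
            while k + 1 < len(pops[a]):
                s1, s2 = sigmas[a][k], sigmas[a][k + 1]
                if abs(s1 - s2) < MERGE_RELATIVE_WIDTH * 0.5 * (s1 + s2):
                    n_total = pops[a][k] + pops[a][k + 1]
                    s_mean = (pops[a][k] * s1 + pops[a][k + 1] * s2) / n_total
                    pops[a] = np.concatenate(
                        [pops[a][:k], [n_total], pops[a][k + 2:]]
                    )
                    sigmas[a] = np.concatenate(
                        [sigmas[a][:k], [s_mean], sigmas[a][k + 2:]]
                    )
                    merged.append((a, int(k)))
                else:
                    k += 1
        atom_pops = np.array([p.sum() for p in pops])
        trace.populations.append(atom_pops.copy())
        trace.deltas.append(max_change)
        trace.n_iterations = it + 1
        if max_change < tol:
            trace.converged = True
            break
    if not trace.converged:
        raise RuntimeError(
            f"MBIS did not converge in {max_iter} iterations "
            f"(last max parameter change = {trace.deltas[-1]:.3e})"
        )
    proatoms = [
        MBISProatom(a, pops[a].copy(), sigmas[a].copy()) for a in range(n_at)
    ]
    diagnostics = {
        "iterations": trace.n_iterations,
        "final_delta": trace.deltas[-1],
    }
    if pruned:
        diagnostics["pruned_shells"] = pruned
    if merged:
        diagnostics["merged_shells"] = merged
    cv = _charges_from_populations(
        geometry, np.array([p.sum() for p in pops]), "mbis", diagnostics
    )
    return cv, proatoms, trace
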