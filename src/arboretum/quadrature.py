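"""Molecular quadrature and proatom models.

Fuzzy-cell (Becke) multicenter grids provide the numerical substrate for
all real-space charge partitioning.  Each atomic grid is a product of a
Gauss–Chebyshev radial rule (mapped to (0, inf) by the rational Becke
transformation) and a Gauss–Legendre x uniform-azimuth angular product
rule, exact for spherical harmonics up to degree ~2*order-1 — comparable
to an octahedral (Lebedev-style) rule at a similar point count.  Atomic
cells are stitched together with the k=3 smoothed Voronoi step function,
which makes the cell weights a partition of unity.

Proatoms are spherically symmetric atomic densities per (element,
integer charge).  The bundled database is an analytic single-zeta Slater
model, rho(r) = N * zeta^3/(8*pi) * exp(-zeta*r) with N = Z - q, which
integrates exactly to N electrons; users with tabulated ab initio
profiles can register radial tables instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.special import roots_legendre

from .core_io import Geometry, VolumetricField
from .ptable import symbol_of, z_of

__all__ = [
    "QuadratureGrid",
    "ProatomDatabase",
    "SlaterProfile",
    "RadialTableProfile",
    "build_becke_grid",
    "promolecule_density",
    "integrate",
    "cube_to_grid",
]

SUPPORTED_ANGULAR_ORDERS = tuple(range(6, 65, 2))


@dataclass
class QuadratureGrid:
    """Flat molecular grid: points (Bohr), weights (Bohr^3), owning atom."""

    points: np.ndarray
    weights: np.ndarray
    owner_atom: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.owner_atom = np.asarray(self.owner_atom, dtype=int).ravel()
        if not (len(self.points) == len(self.weights) == len(self.owner_atom)):
            raise ValueError("points/weights/owner_atom length mismatch")
        if len(self.weights) and self.weights.min() < -1e-14:
            raise ValueError("negative quadrature weight")

    def __len__(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# Proatom profiles
# ---------------------------------------------------------------------------

@dataclass
class SlaterProfile:
    """Analytic single-zeta Slater proatom: N*zeta^3/(8 pi)*exp(-zeta r)."""

    n_electrons: float
    zeta: float

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.n_electrons == 0.0:
            return np.zeros_like(r)
        return self.n_electrons * self.zeta**3 / (8.0 * math.pi) * np.exp(-self.zeta * r)


@dataclass
class RadialTableProfile:
    """Tabulated radial density with exponential tail extrapolation.

    Below the first grid point the density is held constant; beyond the
    last point an exponential fitted to the final decade keeps stockholder
    weights strictly positive.
    """

    r: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(self.rho < 0):
            raise ValueError("negative proatom density in table")
        # fit tail rho ~ A exp(-b r) over the last decade of radii
        rmax = self.r[-1]
        mask = self.r >= 0.1 * rmax
        rr, dd = self.r[mask], self.rho[mask]
        pos = dd > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(rr[pos], np.log(dd[pos]), 1)
            self._tail_b = -slope
            self._tail_a = math.exp(intercept)
        else:
            self._tail_b, self._tail_a = 1.0, 0.0

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.interp(r, self.r, self.rho, left=self.rho[0])
        tail = r > self.r[-1]
        if np.any(tail):
            out[tail] = self._tail_a * np.exp(-self._tail_b * r[tail])
        return out


# Single-zeta valence-like exponents (Bohr^-1) for the neutral atoms H-Ar.
# A model choice, documented in docs/methods.md: charge states scale as
# zeta(q) = zeta0 * (1 + 0.15 q), cations tighter and anions more diffuse.
SLATER_ZETA0 = {
    1: 1.00, 2: 1.69,
    3: 0.64, 4: 0.96, 5: 1.21, 6: 1.57, 7: 1.92, 8: 2.25, 9: 2.56, 10: 2.88,
    11: 0.84, 12: 1.10, 13: 1.17, 14: 1.38, 15: 1.57, 16: 1.80, 17: 2.04,
    18: 2.26,
}
ZETA_CHARGE_SLOPE = 0.15


@dataclass
class ProatomDatabase:
    """Radial atomic densities keyed by (Z, integer charge)."""

    profiles: dict = field(default_factory=dict)
    provenance: str = "analytic-slater"

    def add(self, z: int, charge: int, profile) -> None:
        self.profiles[(int(z), int(charge))] = profile

    def has(self, z: int, charge: int) -> bool:
        return (int(z), int(charge)) in self.profiles

    def density(self, z: int, charge: int, r: np.ndarray) -> np.ndarray:
        try:
            profile = self.profiles[(int(z), int(charge))]
        except KeyError:
            raise KeyError(
                f"proatom database has no entry for element {symbol_of(z)} "
                f"(Z={z}) with charge {charge:+d}"
            ) from None
        return profile(r)

    def available_charges(self, z: int) -> list[int]:
        return sorted(q for (zz, q) in self.profiles if zz == int(z))

    @classmethod
    def from_files(cls, paths) -> "ProatomDatabase":
        """Load proatoms from JSON files, one per element:

        {"element": "O", "entries": [
            {"charge": 0, "zeta": 2.25},                  # Slater form
            {"charge": -1, "r": [...], "rho": [...]}      # radial table
        ]}

        Slater entries integrate to Z - charge by construction; tabulated
        entries get an exponential tail beyond the last radius.
        """
        import json
        from pathlib import Path

        db = cls(provenance="user-files")
        for p in paths:
            doc = json.loads(Path(p).read_text())
            z = z_of(doc["element"])
            for entry in doc["entries"]:
                q = int(entry["charge"])
                if "zeta" in entry:
                    db.add(z, q, SlaterProfile(float(z - q), float(entry["zeta"])))
                else:
                    db.add(
                        z, q,
                        RadialTableProfile(
                            np.asarray(entry["r"], dtype=float),
                            np.asarray(entry["rho"], dtype=float),
                        ),
                    )
        return db

    @classmethod
    def slater(cls, z_list=None, charges=(-1, 0, 1, 2)) -> "ProatomDatabase":
        """Bundled analytic model: Slater proatoms for H-Ar, charges -1..+2
        (capped so populations stay non-negative)."""
        db = cls()
        zs = z_list if z_list is not None else sorted(SLATER_ZETA0)
        for z in zs:
            zeta0 = SLATER_ZETA0.get(int(z))
            if zeta0 is None:
                raise KeyError(
                    f"no bundled Slater exponent for Z={z}; supply a custom database"
                )
            for q in charges:
                n = z - q
                if n < 0:
                    continue
                zeta = zeta0 * (1.0 + ZETA_CHARGE_SLOPE * q)
                db.add(z, q, SlaterProfile(float(n), float(zeta)))
        return db


# ---------------------------------------------------------------------------
# Becke grid
# ---------------------------------------------------------------------------

def _radial_rule(n: int, r_m: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Chebyshev (2nd kind) nodes mapped by r = r_m (1+x)/(1-x).

    Returns radii and weights such that sum(w_i f(r_i)) ~ int_0^inf f r^2 dr.
    """
    i = np.arange(1, n + 1)
    x = np.cos(i * math.pi / (n + 1))
    w_cheb = math.pi / (n + 1) * np.sin(i * math.pi / (n + 1)) ** 2
    r = r_m * (1 + x) / (1 - x)
    drdx = 2 * r_m / (1 - x) ** 2
    w = w_cheb / np.sqrt(1 - x**2) * drdx * r**2
    order = np.argsort(r)
    return r[order], w[order]


def _angular_rule(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Product angular rule: `order` Gauss-Legendre polar nodes x 2*order
    uniform azimuths.  Returns unit vectors and weights summing to 4*pi."""
    ct, w_polar = roots_legendre(order)
    st = np.sqrt(1 - ct**2)
    n_phi = 2 * order
    phi = 2 * math.pi * (np.arange(n_phi) + 0.5) / n_phi
    w_phi = 2 * math.pi / n_phi
    cp, sp = np.cos(phi), np.sin(phi)
    pts = np.empty((order * n_phi, 3))
    wts = np.empty(order * n_phi)
    k = 0
    for j in range(order):
        pts[k : k + n_phi, 0] = st[j] * cp
        pts[k : k + n_phi, 1] = st[j] * sp
        pts[k : k + n_phi, 2] = ct[j]
        wts[k : k + n_phi] = w_polar[j] * w_phi
        k += n_phi
    return pts, wts


def _becke_step(mu: np.ndarray, k: int = 3) -> np.ndarray:
    p = mu
    for _ in range(k):
        p = 1.5 * p - 0.5 * p**3
    return 0.5 * (1.0 - p)


def becke_weights(points: np.ndarray, geometry: Geometry, k: int = 3) -> np.ndarray:
    """Becke cell weights, shape (n_atoms, n_points); columns sum to 1."""
    pos = geometry.positions
    n_at = geometry.n_atoms
    d = np.linalg.norm(points[None, :, :] - pos[:, None, :], axis=-1)  # (A, N)
    if n_at == 1:
        return np.ones((1, len(points)))
    cell = np.ones((n_at, len(points)))
    rab = geometry.distance_matrix()
    for a in range(n_at):
        for b in range(n_at):
            if a == b:
                continue
            mu = (d[a] - d[b]) / rab[a, b]
            cell[a] *= _becke_step(mu, k)
    total = cell.sum(axis=0)
    total[total == 0] = 1.0
    return cell / total


def build_becke_grid(
    geometry: Geometry,
    radial_points: int = 75,
    angular_order: int = 16,
    becke_k: int = 3,
) -> QuadratureGrid:
    """Molecular Becke grid: per-atom radial x angular product grids glued
    with k-iterated smooth Voronoi cell weights."""
    if geometry.n_atoms == 0:  # unreachable through Geometry, kept for rawer callers
        raise ValueError("cannot build a grid for a zero-atom geometry")
    if radial_points < 20:
        raise ValueError("radial_points must be >= 20")
    if angular_order not in SUPPORTED_ANGULAR_ORDERS:
        raise ValueError(
            f"unsupported angular order {angular_order}; supported: "
            f"{list(SUPPORTED_ANGULAR_ORDERS)}"
        )
    ang_pts, ang_wts = _angular_rule(angular_order)
    all_pts, all_wts, all_owner = [], [], []
    for a in range(geometry.n_atoms):
        r, wr = _radial_rule(radial_points)
        pts = (r[:, None, None] * ang_pts[None, :, :]).reshape(-1, 3)
        pts += geometry.positions[a]
        wts = (wr[:, None] * ang_wts[None, :]).ravel()
        all_pts.append(pts)
        all_wts.append(wts)
        all_owner.append(np.full(len(wts), a))
    points = np.concatenate(all_pts)
    weights = np.concatenate(all_wts)
    owner = np.concatenate(all_owner)
    cell = becke_weights(points, geometry, becke_k)
    weights = weights * cell[owner, np.arange(len(points))]
    return QuadratureGrid(points, weights, owner)


# ---------------------------------------------------------------------------
# Promolecule
# ---------------------------------------------------------------------------

def promolecule_density(
    geometry: Geometry,
    proatom_db: ProatomDatabase,
    populations: np.ndarray | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Evaluator for the promolecular density at given per-atom populations.

    A fractional population N in (n, n+1) is the Hirshfeld-I linear
    interpolation (n+1-N)*rho^(pop n) + (N-n)*rho^(pop n+1), where pop n
    corresponds to integer charge Z-n.  Default: neutral atoms (N = Z).
    """
    if populations is None:
        populations = geometry.numbers.astype(float)
    populations = np.asarray(populations, dtype=float)
    if populations.shape != (geometry.n_atoms,):
        raise ValueError("populations must have one entry per atom")

    terms = []  # (atom index, weight, profile charge)
    for a, (z, n_pop) in enumerate(zip(geometry.numbers, populations)):
        lo = math.floor(n_pop)
        hi = lo + 1
        frac = n_pop - lo
        if abs(frac) < 1e-12:
            pieces = [(1.0, int(z - lo))]
        else:
            pieces = [(1.0 - frac, int(z - lo)), (frac, int(z - hi))]
        for wgt, q in pieces:
            if wgt == 0.0:
                continue
            if not proatom_db.has(z, q):
                raise KeyError(
                    f"proatom database lacks ({symbol_of(z)}, charge {q:+d}) "
                    f"needed for population {n_pop} on atom {a}"
                )
            terms.append((a, wgt, q))

    positions = geometry.positions
    numbers = geometry.numbers

    def evaluate(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = np.zeros(len(pts))
        for a, wgt, q in terms:
            r = np.linalg.norm(pts - positions[a], axis=1)
            out += wgt * proatom_db.density(numbers[a], q, r)
        return out

    return evaluate


# ---------------------------------------------------------------------------
# Integration helpers
# ---------------------------------------------------------------------------

def integrate(values: np.ndarray, grid: QuadratureGrid) -> float:
    """Quadrature sum; linear in values; empty grids integrate to 0."""
    values = np.asarray(values, dtype=float).ravel()
    if len(values) != len(grid):
        raise ValueError(
            f"values length {len(values)} does not match grid size {len(grid)}"
        )
    if len(values) == 0:
        return 0.0
    return float(np.dot(values, grid.weights))


def cube_to_grid(fieldv: VolumetricField) -> QuadratureGrid:
    """Treat cube voxels as a uniform-weight grid (weight = voxel volume);
    voxels are owned by their nearest atom (ties to the lower index)."""
    pts = fieldv.grid_points()
    w = np.full(len(pts), fieldv.voxel_volume())
    d = np.linalg.norm(
        pts[:, None, :] - fieldv.geometry.positions[None, :, :], axis=-1
    )
    owner = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    return QuadratureGrid(pts, w, owner)
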