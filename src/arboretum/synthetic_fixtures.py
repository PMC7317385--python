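"""Deterministic generators with closed-form oracles.

Everything every charge scheme and meta-analysis stage needs can be
manufactured here with known ground truth:

* polar diatomics in a two-function basis whose Mulliken charges have a
  closed form, q_A = Z_A - 2 (c_A^2 + c_A c_B s);
* molecular densities as superpositions of Slater-type proatoms with
  planted per-atom populations (so real-space partitioners should
  recover the planted charges);
* exact point-charge ESP fields at CHELPG-style points;
* low-rank factor-model charge tables, rows q = Lambda f + eps, whose
  population covariance Lambda Lambda^T + diag(sd^2) is returned for
  assertions.

All generators are deterministic under a fixed seed, and every oracle is
computed by code paths independent of the modules under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ChargeTable,
    ChargeVector,
    GaussianBasis,
    Geometry,
    Shell,
    VolumetricField,
    WavefunctionState,
)
from .esp_empirical_charges import ESPPointSet, build_chelpg_points, point_charge_esp
from .ptable import symbol_of, z_of
from .quadrature import ProatomDatabase, SlaterProfile, ZETA_CHARGE_SLOPE

__all__ = [
    "PolarDiatomicSpec",
    "SlaterSceneSpec",
    "SlaterAtom",
    "PlantedFactorSpec",
    "make_polar_diatomic",
    "make_rich_diatomic",
    "make_slater_scene",
    "make_esp_case",
    "make_planted_factor_table",
]


# ---------------------------------------------------------------------------
# Polar diatomic wavefunction
# ---------------------------------------------------------------------------

@dataclass
class PolarDiatomicSpec:
    """Two-AO closed-shell diatomic: one s function per atom, overlap s,
    doubly occupied MO = c_A |A> + c_B |B> with c_B > 0 solving the
    normalization c_A^2 + c_B^2 + 2 c_A c_B s = 1."""

    s: float = 0.5
    c_a: float = 0.8
    z: tuple[int, int] = (1, 1)
    label: str = "polar-diatomic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.s < 1.0):
            raise ValueError("overlap s must lie in [0, 1)")


def _solve_cb(s: float, c_a: float) -> float:
    disc = s * s * c_a * c_a + 1.0 - c_a * c_a
    if disc < 0:
        raise ValueError(f"no real c_B for s={s}, c_A={c_a}")
    c_b = -s * c_a + math.sqrt(disc)
    if c_b <= 0:
        raise ValueError(f"no positive c_B root for s={s}, c_A={c_a}")
    return c_b


def make_polar_diatomic(
    spec: PolarDiatomicSpec | None = None, **kwargs
) -> tuple[WavefunctionState, ChargeVector]:
    """Build the wavefunction container plus its closed-form Mulliken
    charge oracle.

    The bond length is chosen so that the analytic overlap of the two
    unit-exponent s Gaussians equals the requested s (R = sqrt(-2 ln s)),
    making the stored S consistent with the stored basis; for s = 0 the
    atoms are placed far apart.
    """
    spec = spec or PolarDiatomicSpec(**kwargs)
    s, c_a = spec.s, spec.c_a
    c_b = _solve_cb(s, c_a)
    r = math.sqrt(-2.0 * math.log(s)) if s > 0 else 40.0
    z1, z2 = spec.z
    geometry = Geometry(
        [symbol_of(z1), symbol_of(z2)],
        np.array([z1, z2]),
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]),
        total_charge=int(z1 + z2 - 2),
        label=spec.label,
    )
    basis = GaussianBasis(
        [Shell(0, 0, [1.0], [1.0]), Shell(1, 0, [1.0], [1.0])]
    )
    c = np.array([c_a, c_b])
    P = 2.0 * np.outer(c, c)
    S = np.array([[1.0, s], [s, 1.0]])
    wfn = WavefunctionState(geometry, basis, P, S, 2.0)
    # closed-form gross populations, independent of the analysis code
    n_a = 2.0 * (c_a**2 + c_a * c_b * s)
    n_b = 2.0 * (c_b**2 + c_a * c_b * s)
    oracle = ChargeVector(
        np.array([z1 - n_a, z2 - n_b]), method="mulliken-oracle",
        geometry=geometry,
    )
    return wfn, oracle


def make_rich_diatomic(
    exponents: tuple[float, float] = (1.3, 0.4),
    mix: float = 0.7,
    r: float = 1.4,
    z: tuple[int, int] = (1, 1),
) -> tuple[WavefunctionState, GaussianBasis]:
    """Four-function diatomic (two s shells per atom) plus a two-function
    minimal basis (one s shell per atom), with analytic overlaps.

    The doubly occupied MO is an S-normalized blend that weights atom A by
    ``mix`` and atom B by 1 - mix, giving a polar density in a redundant
    basis — the projection test bed.
    """
    from .orbital_charges import build_overlap

    z1, z2 = z
    geometry = Geometry(
        [symbol_of(z1), symbol_of(z2)],
        np.array([z1, z2]),
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]),
        total_charge=int(z1 + z2 - 2),
        label="rich-diatomic",
    )
    a1, a2 = exponents
    basis = GaussianBasis(
        [
            Shell(0, 0, [a1], [1.0]),
            Shell(0, 0, [a2], [1.0]),
            Shell(1, 0, [a1], [1.0]),
            Shell(1, 0, [a2], [1.0]),
        ]
    )
    S = build_overlap(basis, basis, geometry)
    raw = np.array([mix, mix, 1.0 - mix, 1.0 - mix])
    c = raw / math.sqrt(raw @ S @ raw)
    P = 2.0 * np.outer(c, c)
    wfn = WavefunctionState(geometry, basis, P, S, 2.0)
    minimal = GaussianBasis([Shell(0, 0, [1.0], [1.0]), Shell(1, 0, [1.0], [1.0])])
    return wfn, minimal


# ---------------------------------------------------------------------------
# Slater scenes
# ---------------------------------------------------------------------------

@dataclass
class SlaterAtom:
    element: str
    position: np.ndarray      # Bohr
    population: float         # planted electron count
    zeta: float               # Bohr^-1

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.population <= 0 or self.zeta <= 0:
            raise ValueError("population and zeta must be positive")


@dataclass
class SlaterSceneSpec:
    atoms: list[SlaterAtom]
    spacing: float = 0.2      # Bohr
    margin: float = 6.0       # Bohr beyond the nuclei on every side
    label: str = "slater-scene"


@dataclass
class SlaterScene:
    """A planted Slater superposition with everything partitioners need."""

    field: VolumetricField
    database: ProatomDatabase
    planted_charges: ChargeVector
    density: object           # callable(points) -> values
    geometry: Geometry
    spec: SlaterSceneSpec
    warnings: list = field(default_factory=list)


def make_slater_scene(spec: SlaterSceneSpec) -> SlaterScene:
    """Cube + analytic density rho(r) = sum_A N_A zeta_A^3/(8 pi)
    exp(-zeta_A |r - R_A|), a matching proatom database (neutral entries
    use the scene's own exponents; charged states scale them the standard
    way), and the planted charges q_A = Z_A - N_A."""
    numbers = np.array([z_of(a.element) for a in spec.atoms])
    positions = np.stack([a.position for a in spec.atoms])
    pops = np.array([a.population for a in spec.atoms])
    zetas = np.array([a.zeta for a in spec.atoms])
    total_charge = int(round(float(numbers.sum() - pops.sum())))
    geometry = Geometry(
        [a.element for a in spec.atoms], numbers, positions,
        total_charge, label=spec.label,
    )

    def density(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = np.zeros(len(pts))
        for pos, n, zeta in zip(positions, pops, zetas):
            r = np.linalg.norm(pts - pos, axis=1)
            out += n * zeta**3 / (8.0 * math.pi) * np.exp(-zeta * r)
        return out

    lo = positions.min(axis=0) - spec.margin
    hi = positions.max(axis=0) + spec.margin
    shape = np.maximum(np.ceil((hi - lo) / spec.spacing).astype(int) + 1, 2)
    axes = np.diag([spec.spacing] * 3)
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    values = density(lo + idx @ axes).reshape(shape)
    fieldv = VolumetricField(lo, axes, values, geometry)

    warnings = []
    # 99.9 % of a Slater atom lies within r with exp tail; check box size
    for atom, zeta in zip(spec.atoms, zetas):
        r999 = 11.0 / zeta   # exp(-x)(1+x+x^2/2) < 1e-3 for x ~ 11
        if np.any(atom.position - lo < r999) or np.any(hi - atom.position < r999):
            warnings.append(
                f"cube may clip >0.1% of {atom.element} density "
                f"(zeta={zeta}, margin={spec.margin})"
            )

    db = ProatomDatabase()
    for z, zeta in zip(numbers, zetas):
        for q in (-1, 0, 1, 2):
            n = int(z) - q
            if n < 0:
                continue
            db.add(int(z), q, SlaterProfile(float(n), float(zeta) * (1.0 + ZETA_CHARGE_SLOPE * q)))

    planted = ChargeVector(
        numbers - pops, method="planted", geometry=geometry,
        diagnostics={"populations": pops.tolist()},
    )
    return SlaterScene(fieldv, db, planted, density, geometry, spec, warnings)


# ---------------------------------------------------------------------------
# ESP cases
# ---------------------------------------------------------------------------

def make_esp_case(
    geometry: Geometry,
    planted_charges: np.ndarray,
    spacing: float = 0.5,
    vdw_scale: float = 1.0,
    outer_margin: float = 2.8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ESPPointSet:
    """Exact point-charge ESP sampled at CHELPG-style points (optionally
    with Gaussian noise); fitting must recover the planted charges."""
    pts = build_chelpg_points(
        geometry, spacing=spacing, vdw_scale=vdw_scale, outer_margin=outer_margin
    )
    values = point_charge_esp(pts, geometry, planted_charges)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return ESPPointSet(
        pts, values,
        metadata={"spacing": spacing, "vdw_scale": vdw_scale,
                  "outer_margin": outer_margin, "noise_sd": noise_sd,
                  "seed": seed,
                  "planted_charges": np.asarray(planted_charges).tolist()},
    )


# ---------------------------------------------------------------------------
# Planted factor tables
# ---------------------------------------------------------------------------

@dataclass
class PlantedFactorSpec:
    """Low-rank 'charge table' generator: rows q = Lambda f + eps with
    f ~ N(0, I) and independent per-method noise.  Mirrors pooled charge
    data: a dominant all-positive ionicity factor, optionally a second
    factor opposing one method against the rest."""

    n_obs: int
    loadings: np.ndarray          # (n_methods, n_factors)
    noise_sd: np.ndarray | float = 0.0
    method_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        p = self.loadings.shape[0]
        if np.isscalar(self.noise_sd):
            self.noise_sd = np.full(p, float(self.noise_sd))
        else:
            self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if self.loadings.shape[1] > p:
            raise ValueError("more factors than methods")
        if self.method_names is None:
            self.method_names = [f"m{i}" for i in range(p)]


def make_planted_factor_table(
    spec: PlantedFactorSpec,
) -> tuple[ChargeTable, np.ndarray]:
    """Generate the table and return it with the exact population
    covariance Lambda Lambda^T + diag(sd^2)."""
    rng = np.random.default_rng(spec.seed)
    p, n_fac = spec.loadings.shape
    f = rng.standard_normal((spec.n_obs, n_fac))
    eps = rng.standard_normal((spec.n_obs, p)) * spec.noise_sd[None, :]
    data = f @ spec.loadings.T + eps
    records = []
    for i in range(spec.n_obs):
        for j, name in enumerate(spec.method_names):
            records.append((f"mol{i}", 0, "X", name, float(data[i, j])))
    frame = pd.DataFrame(records, columns=list(ChargeTable.COLUMNS))
    cov = spec.loadings @ spec.loadings.T + np.diag(spec.noise_sd**2)
    return ChargeTable(frame), cov
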