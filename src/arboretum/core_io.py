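"""Domain types and file formats.

All internal quantities are in atomic units (Bohr, Hartree, elementary
charge); conversions happen only at I/O boundaries.  Atom indices are
0-based in memory and 1-based in printed reports.

Formats handled here: XYZ geometries (Å), Gaussian cube volumetric fields
(Bohr), long-format charge CSV, the supporting-information XLSX dialect
(one charge-method column per sheet column), and a JSON wavefunction
container carrying geometry + Gaussian basis + density and overlap
matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ptable import symbol_of, z_of

logger = logging.getLogger("arboretum")

BOHR_PER_ANGSTROM = 1.8897261246
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM


class ParseError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class Geometry:
    """Nuclear frame: element symbols, atomic numbers, positions in Bohr.

    ``total_charge`` is the net molecular charge in elementary charges.
    """

    symbols: list[str]
    numbers: np.ndarray          # (n,) int
    positions: np.ndarray        # (n, 3) Bohr
    total_charge: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.numbers = np.asarray(self.numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.symbols)
        if n == 0:
            raise ValueError("geometry must contain at least one atom")
        if self.numbers.shape != (n,) or self.positions.shape != (n, 3):
            raise ValueError("inconsistent geometry array shapes")
        if np.any(self.numbers < 1):
            raise ValueError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atomic position")
        if n > 1:
            d = np.linalg.norm(
                self.positions[:, None, :] - self.positions[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < 1e-6:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(f"coincident atoms {i} and {j}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def distance_matrix(self) -> np.ndarray:
        return np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )


# ---------------------------------------------------------------------------
# Gaussian basis & wavefunction container
# ---------------------------------------------------------------------------

@dataclass
class Shell:
    atom: int
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.exponents.shape != self.coefficients.shape:
            raise ValueError("exponent/coefficient length mismatch")
        if np.any(self.exponents <= 0):
            raise ValueError("Gaussian exponents must be positive")
        if self.l < 0:
            raise ValueError("angular momentum must be >= 0")


@dataclass
class GaussianBasis:
    """Contracted Gaussian shells; AO ordering follows shell order, each
    shell contributing its 2l+1 spherical components contiguously."""

    shells: list[Shell]

    def __post_init__(self) -> None:
        if not self.shells:
            raise ValueError("basis must contain at least one shell")

    def n_ao(self) -> int:
        return sum(2 * sh.l + 1 for sh in self.shells)

    def ao_to_atom(self) -> np.ndarray:
        out: list[int] = []
        for sh in self.shells:
            out.extend([sh.atom] * (2 * sh.l + 1))
        return np.asarray(out, dtype=int)

    def validate_against(self, geometry: Geometry) -> None:
        for sh in self.shells:
            if not (0 <= sh.atom < geometry.n_atoms):
                raise ValueError(f"shell references invalid atom {sh.atom}")


@dataclass
class WavefunctionState:
    """Geometry + basis + one-particle density matrix P + overlap S.

    P is the total (spin-summed) density matrix, so trace(P S) equals the
    electron count.
    """

    geometry: Geometry
    basis: GaussianBasis
    density_matrix: np.ndarray
    overlap_matrix: np.ndarray
    n_electrons: float

    def __post_init__(self) -> None:
        P = np.asarray(self.density_matrix, dtype=float)
        S = np.asarray(self.overlap_matrix, dtype=float)
        n = self.basis.n_ao()
        if P.shape != (n, n) or S.shape != (n, n):
            raise ValueError("P/S shape does not match basis size")
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("density matrix must be symmetric")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("overlap matrix must be symmetric")
        ev = np.linalg.eigvalsh(S)
        if ev.min() <= 0:
            raise ValueError(
                f"overlap matrix not positive definite (min eigenvalue {ev.min():.3e})"
            )
        self.basis.validate_against(self.geometry)
        tr = float(np.sum(P * S))
        if abs(tr - self.n_electrons) > 1e-6:
            raise ValueError(
                f"inconsistent electron count: trace(PS)={tr:.8f} "
                f"but n_electrons={self.n_electrons}"
            )
        self.density_matrix = P
        self.overlap_matrix = S


# ---------------------------------------------------------------------------
# Volumetric fields (cube)
# ---------------------------------------------------------------------------

@dataclass
class VolumetricField:
    """Scalar field on a regular 3-D lattice (origin/axes in Bohr).

    ``values[i, j, k]`` sits at origin + i*axes[0] + j*axes[1] + k*axes[2].
    """

    origin: np.ndarray           # (3,)
    axes: np.ndarray             # (3, 3) step vectors, rows
    values: np.ndarray           # (n1, n2, n3)
    geometry: Geometry

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix of step vectors")
        if abs(np.linalg.det(self.axes)) < 1e-14:
            raise ValueError("axes are linearly dependent")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite field values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        return abs(float(np.linalg.det(self.axes)))

    def grid_points(self) -> np.ndarray:
        """Cartesian coordinates of all voxel centers, shape (N, 3),
        flattened in C order (last axis fastest, matching values.ravel())."""
        n1, n2, n3 = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.origin + idx @ self.axes

    def integrate(self) -> float:
        return float(self.values.sum() * self.voxel_volume())

    def interpolator(self):
        """Trilinear interpolating callable points(N,3) -> values(N,),
        zero outside the box."""
        from scipy.interpolate import RegularGridInterpolator

        n1, n2, n3 = self.shape
        inv = np.linalg.inv(self.axes)
        rgi = RegularGridInterpolator(
            (np.arange(n1), np.arange(n2), np.arange(n3)),
            self.values,
            bounds_error=False,
            fill_value=0.0,
        )

        def evaluate(points: np.ndarray) -> np.ndarray:
            frac = (np.asarray(points, dtype=float) - self.origin) @ inv
            return rgi(frac)

        return evaluate


# ---------------------------------------------------------------------------
# Charge containers
# ---------------------------------------------------------------------------

@dataclass
class ChargeVector:
    """Per-atom charges (e) for one geometry and one method."""

    charges: np.ndarray
    method: str
    geometry: Geometry | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.geometry is not None and len(self.charges) != self.geometry.n_atoms:
            raise ValueError("charge vector length does not match atom count")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite charge")

    def total(self) -> float:
        return float(self.charges.sum())


@dataclass
class ChargeTable:
    """Long-format per-atom charge records.

    One row per (molecule_id, atom_index, method); ``charge`` may be NaN,
    which is an explicit hole (value unavailable), never an implicit zero.
    """

    frame: pd.DataFrame

    COLUMNS = ("molecule_id", "atom_index", "element", "method", "charge")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"charge table missing columns {missing}")
        self.frame = self.frame[list(self.COLUMNS)].reset_index(drop=True)
        key = self.frame[["molecule_id", "atom_index", "method"]]
        dup = key.duplicated()
        if dup.any():
            first = self.frame[dup].iloc[0]
            raise ValueError(
                "duplicate charge record for "
                f"({first.molecule_id!r}, {first.atom_index}, {first.method!r})"
            )
        finite = self.frame["charge"].dropna()
        if not np.all(np.isfinite(finite.to_numpy(dtype=float))):
            raise ValueError("non-finite charge value")

    @property
    def methods(self) -> list[str]:
        return sorted(self.frame["method"].unique())

    def n_records(self) -> int:
        return len(self.frame)

    def pivot(self) -> pd.DataFrame:
        """Wide form: one row per (molecule, atom), one column per method;
        holes appear as NaN."""
        wide = self.frame.pivot_table(
            index=["molecule_id", "atom_index", "element"],
            columns="method",
            values="charge",
            aggfunc="first",
            dropna=False,
        )
        wide.columns.name = None
        return wide

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "ChargeTable":
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> Geometry:
    """Read a standard XYZ file (coordinates in Å, converted to Bohr).

    The comment line may carry a ``charge=N`` token setting the total
    molecular charge (default 0).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}: line 1: malformed atom count {lines[0]!r}")
    if len(lines) < natoms + 2:
        raise ParseError(
            f"{path}: expected {natoms + 2} lines for {natoms} atoms, got {len(lines)}"
        )
    comment = lines[1] if len(lines) > 1 else ""
    total_charge = 0
    for token in comment.replace(",", " ").split():
        if token.lower().startswith("charge="):
            try:
                total_charge = int(token.split("=", 1)[1])
            except ValueError:
                raise ParseError(f"{path}: line 2: bad charge token {token!r}")
    symbols, numbers, positions = [], [], []
    for i, line in enumerate(lines[2 : 2 + natoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {i}: expected 'element x y z'")
        sym = parts[0]
        try:
            z = z_of(sym)
        except ValueError:
            raise ParseError(f"{path}: line {i}: unknown element symbol {sym!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {i}: malformed coordinates")
        symbols.append(sym)
        numbers.append(z)
        positions.append(xyz)
    pos = np.asarray(positions) * BOHR_PER_ANGSTROM
    return Geometry(symbols, np.asarray(numbers), pos, total_charge, label=path.stem)


def write_xyz(geometry: Geometry, path: str | Path) -> None:
    path = Path(path)
    lines = [str(geometry.n_atoms), f"{geometry.label} charge={geometry.total_charge}"]
    for sym, p in zip(geometry.symbols, geometry.positions * ANGSTROM_PER_BOHR):
        lines.append(f"{sym:<3s} {p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gaussian cube
# ---------------------------------------------------------------------------

def read_cube(path: str | Path) -> VolumetricField:
    """Read a Gaussian cube file (all lengths in Bohr, z-fastest values).

    The negative-natoms orbital-cube convention (extra DSET line) is
    rejected: this reader handles plain scalar fields only.
    """
    path = Path(path)
    tokens_lines = path.read_text().splitlines()
    if len(tokens_lines) < 6:
        raise ParseError(f"{path}: truncated cube header")
    comment2 = tokens_lines[1]
    head = tokens_lines[2].split()
    natoms = int(head[0])
    if natoms < 0:
        raise ParseError(
            f"{path}: negative atom count ({natoms}) signals an orbital cube "
            "with a DSET record; this reader handles scalar-field cubes only"
        )
    origin = np.array([float(v) for v in head[1:4]])
    shape = []
    axes = []
    for k in range(3):
        parts = tokens_lines[3 + k].split()
        n = int(parts[0])
        if n <= 0:
            raise ParseError(f"{path}: non-positive grid dimension {n}")
        shape.append(n)
        axes.append([float(v) for v in parts[1:4]])
    symbols, numbers, positions = [], [], []
    for i in range(natoms):
        try:
            parts = tokens_lines[6 + i].split()
            if len(parts) < 5:
                raise ValueError
            z = int(parts[0])
            positions.append([float(v) for v in parts[2:5]])
        except (ValueError, IndexError):
            raise ParseError(
                f"{path}: truncated or malformed atom block at atom {i + 1} "
                f"(natoms={natoms})"
            ) from None
        numbers.append(z)
        symbols.append(symbol_of(z))
    total_charge = 0
    for token in comment2.replace(",", " ").split():
        if token.lower().startswith("charge="):
            try:
                total_charge = int(token.split("=", 1)[1])
            except ValueError:
                pass
    geometry = Geometry(symbols, np.asarray(numbers), np.asarray(positions),
                        total_charge, label=tokens_lines[0].strip())
    nval = int(np.prod(shape))
    flat: list[float] = []
    for line in tokens_lines[6 + natoms:]:
        flat.extend(float(v) for v in line.split())
    if len(flat) != nval:
        raise ParseError(
            f"{path}: value block has {len(flat)} entries, expected {nval}"
        )
    values = np.asarray(flat).reshape(shape)
    return VolumetricField(origin, np.asarray(axes), values, geometry)


def write_cube(fieldv: VolumetricField, path: str | Path) -> None:
    path = Path(path)
    g = fieldv.geometry
    out = [
        g.label or "arboretum cube",
        f"scalar field charge={g.total_charge}",
        f"{g.n_atoms:5d} {fieldv.origin[0]:12.6f} {fieldv.origin[1]:12.6f} "
        f"{fieldv.origin[2]:12.6f}",
    ]
    for n, ax in zip(fieldv.shape, fieldv.axes):
        out.append(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}")
    for z, p in zip(g.numbers, g.positions):
        out.append(f"{z:5d} {float(z):12.6f} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}")
    flat = fieldv.values.ravel()
    for start in range(0, len(flat), 6):
        out.append(" ".join(f"{v: .6E}" for v in flat[start : start + 6]))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Charge tables: long CSV and SI-workbook dialects
# ---------------------------------------------------------------------------

def read_charge_table(
    path: str | Path,
    dialect: str = "csv",
    method_map: Mapping[str, str] | None = None,
    sheet: str | int = 0,
    id_columns: Sequence[str] = ("molecule_id", "atom_index", "element"),
) -> ChargeTable:
    """Read per-atom charges.

    dialect="csv": long format with columns
    molecule_id,atom_index,element,method,charge; empty charge cells are
    holes.

    dialect="workbook": an XLSX sheet with identifier columns plus one
    column per charge method; ``method_map`` maps spreadsheet column names
    to canonical method names and must cover every non-identifier column.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in ChargeTable.COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        return ChargeTable(df)
    if dialect == "workbook":
        wide = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
        id_cols = [c for c in id_columns if c in wide.columns]
        if len(id_cols) < 2:
            raise ParseError(
                f"{path}: workbook sheet lacks identifier columns {list(id_columns)}"
            )
        data_cols = [c for c in wide.columns if c not in id_cols]
        method_map = dict(method_map or {})
        unmapped = [c for c in data_cols if c not in method_map]
        if unmapped:
            raise ParseError(
                f"{path}: unmapped method columns {unmapped}; supply a "
                "column-to-method mapping for every charge column"
            )
        long = wide.melt(
            id_vars=id_cols, value_vars=data_cols,
            var_name="method", value_name="charge",
        )
        long["method"] = long["method"].map(method_map)
        if "element" not in long.columns:
            long["element"] = ""
        long = long.rename(columns={id_cols[0]: "molecule_id"})
        if "atom_index" not in long.columns:
            long = long.rename(columns={id_cols[1]: "atom_index"})
        return ChargeTable(long[list(ChargeTable.COLUMNS)])
    raise ValueError(f"unknown charge-table dialect {dialect!r}")


def write_charge_table(table: ChargeTable, path: str | Path) -> None:
    table.frame.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Wavefunction JSON container
# ---------------------------------------------------------------------------

def _geometry_to_dict(g: Geometry) -> dict:
    return {
        "symbols": g.symbols,
        "positions_bohr": g.positions.tolist(),
        "total_charge": int(g.total_charge),
        "label": g.label,
    }


def _geometry_from_dict(d: dict) -> Geometry:
    symbols = list(d["symbols"])
    return Geometry(
        symbols,
        np.array([z_of(s) for s in symbols]),
        np.asarray(d["positions_bohr"], dtype=float),
        int(d.get("total_charge", 0)),
        label=d.get("label", ""),
    )


def _basis_to_dict(b: GaussianBasis) -> dict:
    return {
        "shells": [
            {
                "atom": sh.atom,
                "l": sh.l,
                "exponents": sh.exponents.tolist(),
                "coefficients": sh.coefficients.tolist(),
            }
            for sh in b.shells
        ]
    }


def _basis_from_dict(d: dict) -> GaussianBasis:
    return GaussianBasis(
        [
            Shell(int(s["atom"]), int(s["l"]), s["exponents"], s["coefficients"])
            for s in d["shells"]
        ]
    )


def read_wavefunction(path: str | Path) -> WavefunctionState:
    """Load the JSON wavefunction container (schema in docs/wavefunction.md)."""
    path = Path(path)
    doc = json.loads(path.read_text())
    for key in ("geometry", "basis", "density_matrix", "n_electrons"):
        if key not in doc:
            raise ParseError(f"{path}: missing required field {key!r}")
    if "overlap_matrix" not in doc:
        raise ParseError(f"{path}: overlap required (field 'overlap_matrix')")
    geometry = _geometry_from_dict(doc["geometry"])
    basis = _basis_from_dict(doc["basis"])
    return WavefunctionState(
        geometry,
        basis,
        np.asarray(doc["density_matrix"], dtype=float),
        np.asarray(doc["overlap_matrix"], dtype=float),
        float(doc["n_electrons"]),
    )


def write_wavefunction(wfn: WavefunctionState, path: str | Path) -> None:
    doc = {
        "geometry": _geometry_to_dict(wfn.geometry),
        "basis": _basis_to_dict(wfn.basis),
        "density_matrix": wfn.density_matrix.tolist(),
        "overlap_matrix": wfn.overlap_matrix.tolist(),
        "n_electrons": wfn.n_electrons,
    }
    Path(path).write_text(json.dumps(doc))
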