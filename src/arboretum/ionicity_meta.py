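"""Statistical meta-analysis of per-atom charge tables.

The observation unit is one atom; atoms are pooled across molecules,
unweighted, and only complete cases (atoms with a value for every
selected method) enter the analysis.  On that observation matrix the
module provides correlation/covariance construction, eigen-analysis
(PCA on either matrix), Jolliffe backward elimination, GCD-criterion
variable-subset selection (exhaustive or simulated annealing),
multiple regression, per-method fits against leading principal
components, and a noise-robustness check that recomputes the PCA after
appending rows resampled from the column marginals.

Dataset curation helpers mirror standard practice for pooled charge
datasets: species in which all atoms are symmetry-equivalent (atoms,
homonuclear diatomics, P4-like clusters) carry no charge information and
are dropped, and duplicate geometries are detected by comparing
principal moments of inertia at matching stoichiometry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles

from .core_io import ChargeTable, Geometry
from .ptable import mass_of

__all__ = [
    "ObservationMatrix",
    "PCAResult",
    "SubsetSearchResult",
    "assemble",
    "filter_trivial",
    "deduplicate",
    "correlation",
    "covariance",
    "correlation_from_squared",
    "pca",
    "pca_from_data",
    "backward_eliminate",
    "gcd_score",
    "select_subset",
    "regress",
    "pc_fit_table",
    "noise_robustness",
    "TABLE_IIB1_SQUARED_CORRELATIONS",
]

# Printed squared correlations between the four iterative stockholder-family
# charge methods (pooled main-group dataset); used as a desk-scale input for
# eigenvalue analysis.
TABLE_IIB1_SQUARED_CORRELATIONS = pd.DataFrame(
    [
        [1.00, 0.94, 0.94, 0.92],
        [0.94, 1.00, 0.99, 0.98],
        [0.94, 0.99, 1.00, 0.97],
        [0.92, 0.98, 0.97, 1.00],
    ],
    index=["ISA", "DDEC6", "MBIS", "Hirshfeld-I"],
    columns=["ISA", "DDEC6", "MBIS", "Hirshfeld-I"],
)


# ---------------------------------------------------------------------------
# Observation assembly and dataset curation
# ---------------------------------------------------------------------------

@dataclass
class ObservationMatrix:
    """Complete-case atoms x methods matrix with row metadata."""

    data: pd.DataFrame            # rows: atoms, columns: methods
    row_info: pd.DataFrame        # molecule_id, atom_index, element
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("observation matrix contains missing entries")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"observation matrix needs >= 2 rows and >= 2 columns, got "
                f"{self.data.shape}"
            )

    @property
    def methods(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def centered(self) -> np.ndarray:
        x = self.values()
        return x - x.mean(axis=0)


def assemble(table: ChargeTable, methods: list[str]) -> ObservationMatrix:
    """Pool atoms across molecules for the requested methods,
    complete cases only; the dropped-row count is recorded."""
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    wide = table.pivot()
    missing = [m for m in methods if m not in wide.columns]
    if missing:
        raise KeyError(f"methods absent from the charge table: {missing}")
    sub = wide[list(methods)]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if len(complete) < 2:
        raise ValueError(
            f"fewer than 2 complete-case rows remain ({len(complete)}); "
            f"{n_dropped} incomplete rows dropped"
        )
    row_info = complete.index.to_frame(index=False)
    return ObservationMatrix(
        complete.reset_index(drop=True), row_info, n_dropped
    )


def _atom_fingerprints(geometry: Geometry, decimals: int = 6) -> list[tuple]:
    """Per-atom environment fingerprint: own element + sorted (distance,
    element) list to all other atoms."""
    d = geometry.distance_matrix()
    out = []
    for a in range(geometry.n_atoms):
        pairs = sorted(
            (round(float(d[a, b]), decimals), int(geometry.numbers[b]))
            for b in range(geometry.n_atoms) if b != a
        )
        out.append((int(geometry.numbers[a]), tuple(pairs)))
    return out


def filter_trivial(geometries: dict[str, Geometry] | list[Geometry]) -> list[str]:
    """Drop species with trivial charge distributions: molecules whose
    atoms are all mutually equivalent under the sorted-distance-matrix
    fingerprint (single atoms, homonuclear diatomics, P4-like clusters).
    Returns the kept molecule ids in input order."""
    if not isinstance(geometries, dict):
        geometries = {g.label or str(i): g for i, g in enumerate(geometries)}
    kept = []
    for mol_id, g in geometries.items():
        fps = _atom_fingerprints(g)
        if g.n_atoms == 1 or len(set(fps)) == 1:
            continue
        kept.append(mol_id)
    return kept


def _inertia_moments(geometry: Geometry) -> np.ndarray:
    masses = np.array([mass_of(int(z)) for z in geometry.numbers])
    com = (masses[:, None] * geometry.positions).sum(axis=0) / masses.sum()
    x = geometry.positions - com
    r2 = (x**2).sum(axis=1)
    I = np.zeros((3, 3))
    for m, v, rr in zip(masses, x, r2):
        I += m * (rr * np.eye(3) - np.outer(v, v))
    return np.sort(np.linalg.eigvalsh(I))


def _stoichiometry(geometry: Geometry) -> tuple:
    z, counts = np.unique(geometry.numbers, return_counts=True)
    return tuple(zip(z.tolist(), counts.tolist()))


def deduplicate(
    geometries: dict[str, Geometry], rel_tol: float = 1e-4
) -> list[str]:
    """Unique molecule ids: duplicates have identical stoichiometry and all
    three principal moments of inertia equal within rel_tol (first
    occurrence kept).  Enantiomers share both and are collapsed — a
    documented limitation of the rotational-constant criterion."""
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    kept: list[str] = []
    seen: list[tuple[tuple, np.ndarray, str]] = []
    for mol_id, g in geometries.items():
        stoich = _stoichiometry(g)
        moments = _inertia_moments(g)
        duplicate = False
        for s, m, _ in seen:
            if s != stoich:
                continue
            scale = np.maximum(np.abs(m), 1e-12)
            if np.all(np.abs(moments - m) / scale < rel_tol):
                duplicate = True
                break
        if not duplicate:
            kept.append(mol_id)
            seen.append((stoich, moments, mol_id))
    return kept


# ---------------------------------------------------------------------------
# Correlation / covariance and PCA
# ---------------------------------------------------------------------------

def _as_frame(m) -> pd.DataFrame:
    if isinstance(m, ObservationMatrix):
        return m.data
    if isinstance(m, pd.DataFrame):
        return m
    arr = np.asarray(m, dtype=float)
    return pd.DataFrame(arr, columns=[f"v{i}" for i in range(arr.shape[1])])


def covariance(m) -> pd.DataFrame:
    """Sample covariance (denominator n-1) of the observation columns."""
    df = _as_frame(m)
    if len(df) < 2:
        raise ValueError("need >= 2 rows")
    return df.cov()


def correlation(m) -> pd.DataFrame:
    """Pearson correlation; errors on zero-variance columns (naming them)."""
    df = _as_frame(m)
    if len(df) < 2:
        raise ValueError("need >= 2 rows")
    sd = df.std()
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance columns: {dead}")
    corr = df.corr()
    np.fill_diagonal(corr.values, 1.0)
    return corr


def correlation_from_squared(r_squared: pd.DataFrame) -> pd.DataFrame:
    """Rebuild a correlation matrix from a table of squared correlations
    using positive square roots and a unit diagonal."""
    r = np.sqrt(np.asarray(r_squared, dtype=float))
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=r_squared.index, columns=r_squared.columns)


@dataclass
class PCAResult:
    """Eigen-analysis of a correlation or covariance matrix.

    Loadings are unit-norm eigenvector columns in descending eigenvalue
    order, with each column's sign fixed so its largest-magnitude entry is
    negative (the convention under which the leading 'ionicity' component
    of pooled charge data prints with all-negative coefficients).
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray          # (n_vars, n_vars), columns = PCs
    variables: list[str]
    kind: str                     # "correlation" | "covariance"
    scores: np.ndarray | None = None   # (n_obs, n_vars) when data supplied
    sign_convention: str = "largest-entry-negative"

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] > 0:
            out[:, j] = -out[:, j]
    return out


def pca(matrix, kind: str = "correlation") -> PCAResult:
    """Eigen-decomposition of a symmetric correlation/covariance matrix,
    eigenvalues descending."""
    if kind not in ("correlation", "covariance"):
        raise ValueError(f"kind must be correlation|covariance, got {kind!r}")
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        names = [f"v{i}" for i in range(arr.shape[1])]
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("input matrix must be symmetric")
    ev, vec = np.linalg.eigh(arr)
    order = np.argsort(ev)[::-1]
    ev = ev[order]
    vec = _fix_signs(vec[:, order])
    return PCAResult(ev, vec, names, kind)


def pca_from_data(m, kind: str = "covariance") -> PCAResult:
    """PCA of an observation matrix; also returns scores (projections of
    the centered — and, for kind="correlation", standardized — data)."""
    df = _as_frame(m)
    mat = correlation(df) if kind == "correlation" else covariance(df)
    res = pca(mat, kind)
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if kind == "correlation":
        x = x / x.std(axis=0, ddof=1)
    res.scores = x @ res.loadings
    return res


# ---------------------------------------------------------------------------
# Variable selection
# ---------------------------------------------------------------------------

def backward_eliminate(corr_matrix: pd.DataFrame, n_remove: int) -> list[str]:
    """Jolliffe backward elimination: repeatedly drop the variable with the
    largest |coefficient| in the smallest-eigenvalue eigenvector of the
    (recomputed) correlation matrix.  Returns names in elimination order."""
    corr = corr_matrix.copy()
    if n_remove >= corr.shape[0]:
        raise ValueError("n_remove must be smaller than the dimension")
    eliminated: list[str] = []
    for _ in range(n_remove):
        arr = corr.to_numpy(dtype=float)
        ev, vec = np.linalg.eigh(arr)
        smallest = vec[:, 0]          # eigh: ascending eigenvalues
        victim = corr.columns[int(np.argmax(np.abs(smallest)))]
        eliminated.append(victim)
        corr = corr.drop(index=victim, columns=victim)
    return eliminated


def gcd_score(m: ObservationMatrix, subset: list[str], k: int | None = None) -> float:
    """Generalized coefficient of determination of a variable subset:
    trace(P_S P_K)/k, with P_S the projector onto the span of the subset's
    centered data columns and P_K onto the span of the first k principal
    component score vectors (k = |subset| by default).  1 iff the
    subspaces coincide; 0 iff orthogonal."""
    if k is None:
        k = len(subset)
    if k != len(subset):
        raise ValueError("k must equal the subset size")
    if k > len(m.methods):
        raise ValueError("k exceeds the number of variables")
    x = m.centered()
    cols = [m.methods.index(s) for s in subset]
    xs = x[:, cols]
    # orthonormal bases of the two subspaces
    qs, rs = np.linalg.qr(xs)
    if np.min(np.abs(np.diag(rs))) < 1e-10 * max(1.0, np.max(np.abs(rs))):
        raise ValueError(f"rank-deficient subset {subset}")
    res = pca_from_data(m, kind="covariance")
    scores = res.scores[:, :k]
    qk, _ = np.linalg.qr(scores)
    overlap = qs.T @ qk
    return float(np.sum(overlap**2) / k)


@dataclass
class SubsetSearchResult:
    subset: tuple[str, ...]
    criterion: float
    search: str
    seed: int | None = None
    trace: list = field(default_factory=list)


def _anneal_select(
    m: ObservationMatrix, k: int, seed: int, schedule: dict | None
) -> SubsetSearchResult:
    rng = np.random.default_rng(seed)
    names = m.methods
    sched = {"t0": 0.2, "alpha": 0.9, "steps_per_t": 40, "t_min": 1e-4}
    sched.update(schedule or {})
    current = list(rng.choice(len(names), size=k, replace=False))

    def score(ix: list[int]) -> float:
        try:
            return gcd_score(m, [names[i] for i in ix])
        except ValueError:
            return -np.inf

    cur_val = score(current)
    best, best_val = list(current), cur_val
    trace = []
    t = sched["t0"]
    while t > sched["t_min"]:
        for _ in range(sched["steps_per_t"]):
            outside = [i for i in range(len(names)) if i not in current]
            if not outside:
                break
            swap_out = int(rng.integers(k))
            swap_in = int(rng.choice(outside))
            cand = list(current)
            cand[swap_out] = swap_in
            val = score(cand)
            if val >= cur_val or rng.random() < math.exp((val - cur_val) / t):
                current, cur_val = cand, val
                trace.append((tuple(sorted(names[i] for i in current)), cur_val))
                if cur_val > best_val:
                    best, best_val = list(current), cur_val
        t *= sched["alpha"]
    return SubsetSearchResult(
        tuple(sorted(names[i] for i in best)), best_val, "anneal", seed, trace
    )


def select_subset(
    m: ObservationMatrix,
    k: int,
    method: str = "exhaustive",
    seed: int = 0,
    schedule: dict | None = None,
) -> SubsetSearchResult:
    """Best k-variable subset under the GCD criterion.

    method="exhaustive" (allowed up to 20 variables) scans all subsets and
    returns the global optimum; method="anneal" runs seeded simulated
    annealing with swap moves and geometric cooling.
    """
    names = m.methods
    if k >= len(names):
        raise ValueError("k must be smaller than the number of variables")
    if method == "exhaustive":
        if len(names) > 20:
            raise ValueError(
                "exhaustive search limited to <= 20 variables; use anneal"
            )
        best, best_val = None, -np.inf
        for combo in itertools.combinations(names, k):
            try:
                val = gcd_score(m, list(combo))
            except ValueError:
                continue
            if val > best_val:
                best, best_val = combo, val
        if best is None:
            raise ValueError("no full-rank subset found")
        return SubsetSearchResult(tuple(sorted(best)), best_val, "exhaustive")
    if method == "anneal":
        return _anneal_select(m, k, seed, schedule)
    raise ValueError(f"unknown search method {method!r}")


# ---------------------------------------------------------------------------
# Regression and PC fits
# ---------------------------------------------------------------------------

def regress(
    m: ObservationMatrix, target_method: str, predictor_methods: list[str]
) -> tuple[np.ndarray, float, float]:
    """OLS of one method's charges on others (with intercept).
    Returns (coefficients, intercept, R^2)."""
    y = m.data[target_method].to_numpy(dtype=float)
    X = m.data[list(predictor_methods)].to_numpy(dtype=float)
    design = np.column_stack([X, np.ones(len(X))])
    cond = np.linalg.cond(design)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError(
            f"collinear predictors {predictor_methods} "
            f"(condition number {cond:.3e})"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return beta[:-1], float(beta[-1]), r2


def pc_fit_table(m: ObservationMatrix, max_pcs: int,
                 kind: str = "covariance") -> pd.DataFrame:
    """R^2 of each method's charges regressed on the first 1..max_pcs
    principal-component scores; non-decreasing along each row."""
    if max_pcs > len(m.methods):
        raise ValueError("max_pcs exceeds the dimension")
    res = pca_from_data(m, kind=kind)
    scores = res.scores
    out = {}
    for method in m.methods:
        y = m.data[method].to_numpy(dtype=float)
        row = []
        for k in range(1, max_pcs + 1):
            design = np.column_stack([scores[:, :k], np.ones(len(y))])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
            r2 = 1.0 - float(resid @ resid) / float(np.sum((y - y.mean()) ** 2))
            row.append(r2)
        out[method] = row
    return pd.DataFrame(
        out, index=[f"R2(PC1..{k})" for k in range(1, max_pcs + 1)]
    ).T


# ---------------------------------------------------------------------------
# Noise robustness
# ---------------------------------------------------------------------------

@dataclass
class NoiseReport:
    fraction: float
    n_added: int
    eigenvalues_original: np.ndarray
    eigenvalues_perturbed: list        # one array per repetition
    eigenvalue_shifts: list            # per repetition
    principal_angles_deg: list         # per repetition: angle per PC depth
    seeds: list


def noise_robustness(
    m: ObservationMatrix,
    fraction: float = 0.10,
    seed: int = 0,
    n_rep: int = 3,
    kind: str = "covariance",
    n_components: int | None = None,
    model: str = "marginal",
) -> NoiseReport:
    """Stability of the PCA under sample adulteration.

    Appends ceil(fraction * n) rows whose entries are drawn independently
    per column — from the column's empirical marginal (model="marginal")
    or uniformly over its range (model="uniform") — destroying
    cross-correlation, then recomputes the PCA.  Reports per-PC eigenvalue
    shifts and, for each depth d <= n_components, the largest principal
    angle between the original and perturbed leading-d loading subspaces.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if model not in ("marginal", "uniform"):
        raise ValueError(f"unknown noise model {model!r}")
    x = m.values()
    n, p = x.shape
    if n_components is None:
        n_components = min(4, p)
    base = pca_from_data(m, kind=kind)
    n_add = math.ceil(fraction * n)
    report = NoiseReport(fraction, n_add, base.eigenvalues, [], [], [], [])
    for rep in range(n_rep):
        rng = np.random.default_rng([seed, rep])
        if model == "marginal":
            noise = np.column_stack(
                [rng.choice(x[:, j], size=n_add, replace=True) for j in range(p)]
            )
        else:
            lo, hi = x.min(axis=0), x.max(axis=0)
            noise = rng.uniform(lo, hi, size=(n_add, p))
        aug = pd.DataFrame(np.vstack([x, noise]), columns=m.methods)
        pert = pca_from_data(aug, kind=kind)
        report.eigenvalues_perturbed.append(pert.eigenvalues)
        report.eigenvalue_shifts.append(pert.eigenvalues - base.eigenvalues)
        angles = []
        for depth in range(1, n_components + 1):
            ang = subspace_angles(
                base.loadings[:, :depth], pert.loadings[:, :depth]
            )
            angles.append(math.degrees(float(np.max(ang))))
        report.principal_angles_deg.append(np.array(angles))
        report.seeds.append([seed, rep])
    return report
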