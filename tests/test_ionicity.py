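"""Meta-analysis engine: assembly, curation, PCA, selection, robustness."""

import numpy as np
import pandas as pd
import pytest

import arboretum as ab
from arboretum.ionicity_meta import (
    ObservationMatrix,
    backward_eliminate,
    correlation,
    covariance,
    gcd_score,
    noise_robustness,
    pc_fit_table,
)
from arboretum.synthetic_fixtures import PlantedFactorSpec, make_planted_factor_table


def _matrix_from_array(x, names=None):
    x = np.asarray(x, dtype=float)
    names = names or [f"m{i}" for i in range(x.shape[1])]
    data = pd.DataFrame(x, columns=names)
    info = pd.DataFrame({"molecule_id": [f"r{i}" for i in range(len(x))],
                         "atom_index": 0, "element": "X"})
    return ObservationMatrix(data, info)


# ---------------------------------------------------------------------------
# assemble
# ---------------------------------------------------------------------------

def _small_table(holes=()):
    rows = []
    for atom in range(5):
        for method in ("a", "b", "c"):
            val = np.nan if (atom, method) in holes else 0.1 * atom + len(method)
            rows.append(("mol", atom, "C", method, val))
    return ab.ChargeTable.from_records(rows)


def test_assemble_full_table():
    m = ab.assemble(_small_table(), ["a", "b", "c"])
    assert m.data.shape == (5, 3)
    assert m.n_dropped == 0


def test_assemble_drops_incomplete_rows():
    m = ab.assemble(_small_table(holes={(2, "b")}), ["a", "b", "c"])
    assert m.data.shape == (4, 3)
    assert m.n_dropped == 1


def test_assemble_all_rows_incomplete_errors():
    holes = {(i, "b") for i in range(5)}
    with pytest.raises(ValueError, match="complete-case"):
        ab.assemble(_small_table(holes=holes), ["a", "b", "c"])


def test_assemble_needs_two_methods():
    with pytest.raises(ValueError, match="2 methods"):
        ab.assemble(_small_table(), ["a"])


# ---------------------------------------------------------------------------
# trivial-species filtering and deduplication
# ---------------------------------------------------------------------------

def test_filter_trivial_species(water):
    he = ab.Geometry(["He"], np.array([2]), np.zeros((1, 3)), 0, "He")
    n2 = ab.Geometry(["N", "N"], np.array([7, 7]),
                     np.array([[0, 0, 0], [0, 0, 2.1]]), 0, "N2")
    # regular tetrahedron: all atoms equivalent
    t = 2.2 / np.sqrt(2)
    p4 = ab.Geometry(
        ["P"] * 4, np.full(4, 15),
        np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]]), 0, "P4",
    )
    kept = ab.filter_trivial({"He": he, "N2": n2, "H2O": water, "P4": p4})
    assert kept == ["H2O"]


def test_deduplicate_collapses_rotated_copies(water):
    theta = 0.9
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = ab.Geometry(
        water.symbols, water.numbers,
        water.positions @ rot.T + np.array([3.0, -1.0, 2.0]),
        water.total_charge, "copy",
    )
    kept = ab.deduplicate({"orig": water, "copy": moved})
    assert kept == ["orig"]


def test_deduplicate_keeps_distinct_conformers(water):
    stretched = ab.Geometry(
        water.symbols, water.numbers,
        water.positions * np.array([1.0, 1.15, 1.0]), 0, "stretched",
    )
    kept = ab.deduplicate({"orig": water, "str": stretched})
    assert kept == ["orig", "str"]


def test_deduplicate_collapses_enantiomers():
    """Mirror images share stoichiometry and inertia moments: the
    rotational-constant criterion cannot distinguish them (documented
    limitation)."""
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.2, 0], [0, 0, 2.5]])
    chiral = ab.Geometry(["C", "H", "F", "Cl"], np.array([6, 1, 9, 17]),
                         pos, 0, "R")
    mirror = ab.Geometry(["C", "H", "F", "Cl"], np.array([6, 1, 9, 17]),
                         pos * np.array([1, 1, -1.0]), 0, "S")
    kept = ab.deduplicate({"R": chiral, "S": mirror})
    assert kept == ["R"]


# ---------------------------------------------------------------------------
# correlation / covariance
# ---------------------------------------------------------------------------

def test_correlation_of_linear_pair_is_one():
    x = np.arange(10.0)
    m = _matrix_from_array(np.column_stack([x, 3 * x + 1]))
    assert correlation(m).iloc[0, 1] == pytest.approx(1.0)


def test_correlation_eigenvalues_sum_to_dimension():
    rng = np.random.default_rng(0)
    m = _matrix_from_array(rng.normal(size=(50, 6)))
    ev = np.linalg.eigvalsh(correlation(m).to_numpy())
    assert ev.sum() == pytest.approx(6.0, abs=1e-10)


def test_zero_variance_column_is_named():
    x = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
    m = _matrix_from_array(x, names=["live", "dead"])
    with pytest.raises(ValueError, match="dead"):
        correlation(m)


def test_covariance_uses_n_minus_one():
    x = np.array([[0.0, 0.0], [2.0, 4.0]])
    c = covariance(_matrix_from_array(x))
    assert c.iloc[0, 0] == pytest.approx(2.0)   # var = (1+1)*... / (n-1)
    assert c.iloc[0, 1] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_identity_matrix():
    res = ab.pca(np.eye(4), "correlation")
    assert np.allclose(res.eigenvalues, 1.0)
    assert np.allclose(res.loadings @ res.loadings.T, np.eye(4), atol=1e-10)


def test_pca_rank_one_matrix():
    v = np.array([0.5, 0.5, 0.5, 0.5])
    res = ab.pca(3.0 * np.outer(v, v), "covariance")
    assert res.eigenvalues[0] == pytest.approx(3.0)
    assert np.allclose(res.eigenvalues[1:], 0.0, atol=1e-12)
    # sign convention: largest-magnitude loading entry negative
    for j in range(4):
        k = np.argmax(np.abs(res.loadings[:, j]))
        assert res.loadings[k, j] <= 0


def test_pca_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        ab.pca(np.array([[1.0, 0.2], [0.1, 1.0]]), "correlation")


def test_pca_two_by_two_eigenvectors_are_sum_and_difference():
    res = ab.pca(np.array([[1.0, 0.8], [0.8, 1.0]]), "correlation")
    inv_sqrt2 = 1 / np.sqrt(2)
    assert np.abs(res.loadings[:, 0]) == pytest.approx([inv_sqrt2] * 2)
    assert np.abs(res.loadings[:, 1]) == pytest.approx([inv_sqrt2] * 2)
    assert res.eigenvalues == pytest.approx([1.8, 0.2])


def test_pca_reconstruction_from_scores():
    rng = np.random.default_rng(1)
    m = _matrix_from_array(rng.normal(size=(40, 5)))
    res = ab.pca_from_data(m, "covariance")
    x = m.centered()
    assert np.allclose(res.scores @ res.loadings.T, x, atol=1e-8)


def test_pca_recovers_planted_two_factor_structure():
    loadings = np.array(
        [[1.0, 0.1], [0.9, 0.2], [1.1, -0.1], [1.0, 0.15], [0.7, -0.9]]
    )
    table, cov_true = make_planted_factor_table(
        PlantedFactorSpec(n_obs=5000, loadings=loadings, noise_sd=0.05, seed=42)
    )
    m = ab.assemble(table, [f"m{i}" for i in range(5)])
    res = ab.pca_from_data(m, "covariance")
    ev_true = np.linalg.eigvalsh(cov_true)[::-1]
    planted_ratio = ev_true[:2].sum() / ev_true.sum()
    got_ratio = res.explained_variance_ratio()[:2].sum()
    assert got_ratio == pytest.approx(planted_ratio, abs=0.02)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def test_backward_elimination_removes_duplicated_variable_first():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(60, 4))
    x[:, 1] = x[:, 0]  # perfect duplicate
    m = _matrix_from_array(x, names=["a", "a_copy", "b", "c"])
    order = backward_eliminate(correlation(m), 1)
    assert order[0] in ("a", "a_copy")


def test_backward_elimination_respects_dimension():
    m = _matrix_from_array(np.random.default_rng(0).normal(size=(10, 3)))
    with pytest.raises(ValueError, match="smaller"):
        backward_eliminate(correlation(m), 3)


# ---------------------------------------------------------------------------
# GCD and subset selection
# ---------------------------------------------------------------------------

def _orthogonal_design(n=48, p=4, scales=(4.0, 3.0, 2.0, 1.0), seed=3):
    """Centered data whose columns are exactly orthogonal with decreasing
    variance, so the top-k PCs are the first k columns."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    q -= q.mean(axis=0)
    q, _ = np.linalg.qr(q)          # re-orthonormalize after centering
    x = q * np.asarray(scales)
    return _matrix_from_array(x, names=["v1", "v2", "v3", "v4"])


def test_gcd_is_one_for_pc_generating_subset():
    m = _orthogonal_design()
    assert gcd_score(m, ["v1", "v2"]) == pytest.approx(1.0, abs=1e-10)


def test_gcd_is_zero_for_orthogonal_subset():
    m = _orthogonal_design()
    assert gcd_score(m, ["v3", "v4"]) == pytest.approx(0.0, abs=1e-10)


def test_gcd_of_full_set_is_one():
    rng = np.random.default_rng(5)
    m = _matrix_from_array(rng.normal(size=(30, 4)))
    assert gcd_score(m, m.methods) == pytest.approx(1.0, abs=1e-10)


def test_gcd_matches_brute_force_projectors():
    """Independent oracle: explicit n x n projector matrices."""
    from itertools import combinations

    rng = np.random.default_rng(7)
    x = rng.normal(size=(25, 6)) @ rng.normal(size=(6, 6))
    m = _matrix_from_array(x)
    xc = x - x.mean(axis=0)
    cov = np.cov(xc, rowvar=False)
    ev, vec = np.linalg.eigh(cov)
    order = np.argsort(ev)[::-1]
    scores = xc @ vec[:, order]
    for subset in combinations(range(6), 2):
        xs = xc[:, list(subset)]
        p_s = xs @ np.linalg.pinv(xs)
        t = scores[:, :2]
        p_k = t @ np.linalg.pinv(t)
        oracle = np.trace(p_s @ p_k) / 2
        got = gcd_score(m, [m.methods[i] for i in subset])
        assert got == pytest.approx(oracle, abs=1e-9)


def test_gcd_rank_deficient_subset_errors():
    x = np.random.default_rng(1).normal(size=(20, 3))
    x = np.column_stack([x, x[:, 0]])
    m = _matrix_from_array(x, names=["a", "b", "c", "a_copy"])
    with pytest.raises(ValueError, match="rank"):
        gcd_score(m, ["a", "a_copy"])


def _planted_representative_matrix(seed=0, n=800):
    """Three orthogonal factors; methods 0..2 are pure (noise-free)
    representatives, the rest are noisy mixtures."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, 3)) * np.array([3.0, 2.0, 1.5])
    pure = f
    mixtures = np.column_stack([
        0.5 * f[:, 0] + 0.5 * f[:, 1] + 0.2 * rng.standard_normal(n),
        0.5 * f[:, 1] + 0.5 * f[:, 2] + 0.2 * rng.standard_normal(n),
        0.5 * f[:, 0] + 0.5 * f[:, 2] + 0.2 * rng.standard_normal(n),
        0.4 * f[:, 0] + 0.3 * f[:, 1] + 0.3 * f[:, 2]
        + 0.2 * rng.standard_normal(n),
    ])
    x = np.column_stack([pure, mixtures])
    names = ["rep1", "rep2", "rep3", "mix12", "mix23", "mix13", "mix123"]
    return _matrix_from_array(x, names=names)


def test_exhaustive_selection_recovers_planted_representatives():
    m = _planted_representative_matrix()
    res = ab.select_subset(m, 3, method="exhaustive")
    assert res.subset == ("rep1", "rep2", "rep3")
    assert res.criterion > 0.99


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_annealing_matches_exhaustive(seed):
    m = _planted_representative_matrix()
    ex = ab.select_subset(m, 3, method="exhaustive")
    an = ab.select_subset(m, 3, method="anneal", seed=seed)
    assert an.subset == ex.subset
    assert an.criterion == pytest.approx(ex.criterion, abs=1e-12)


def test_select_subset_k_too_large():
    m = _orthogonal_design()
    with pytest.raises(ValueError, match="smaller"):
        ab.select_subset(m, 4)


# ---------------------------------------------------------------------------
# regression and PC fits
# ---------------------------------------------------------------------------

def test_regress_exact_linear_combination():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(200, 3))
    y = 0.3 * x[:, 0] - 1.2 * x[:, 1] + 0.5 * x[:, 2] + 2.0
    m = _matrix_from_array(np.column_stack([y, x]),
                           names=["t", "p1", "p2", "p3"])
    coef, intercept, r2 = ab.regress(m, "t", ["p1", "p2", "p3"])
    assert r2 == pytest.approx(1.0, abs=1e-12)
    assert coef == pytest.approx([0.3, -1.2, 0.5], abs=1e-10)
    assert intercept == pytest.approx(2.0, abs=1e-10)


def test_regress_independent_noise_has_low_r2():
    rng = np.random.default_rng(10)
    x = rng.normal(size=(1000, 3))
    y = rng.normal(size=1000)
    m = _matrix_from_array(np.column_stack([y, x]),
                           names=["t", "p1", "p2", "p3"])
    _, _, r2 = ab.regress(m, "t", ["p1", "p2", "p3"])
    assert r2 < 0.05


def test_regress_collinear_predictors_error():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(50, 2))
    m = _matrix_from_array(np.column_stack([x[:, 0], x, x[:, 1]]),
                           names=["t", "p1", "p2", "p2_copy"])
    with pytest.raises(np.linalg.LinAlgError, match="condition"):
        ab.regress(m, "t", ["p1", "p2", "p2_copy"])


def test_pc_fit_rank_one_data_saturates_at_first_component():
    rng = np.random.default_rng(12)
    f = rng.normal(size=100)
    x = np.outer(f, [1.0, 0.5, -2.0])
    m = _matrix_from_array(x)
    table = pc_fit_table(m, 2)
    assert np.allclose(table.iloc[:, 0], 1.0, atol=1e-10)


def test_pc_fit_monotone_in_components():
    rng = np.random.default_rng(13)
    m = _matrix_from_array(rng.normal(size=(80, 5)))
    table = pc_fit_table(m, 5)
    diffs = np.diff(table.to_numpy(), axis=1)
    assert np.all(diffs >= -1e-12)
    assert np.allclose(table.iloc[:, -1], 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# noise robustness
# ---------------------------------------------------------------------------

def _two_factor_matrix(seed=21):
    loadings = np.array(
        [[1.0, 0.1], [0.9, 0.2], [1.1, -0.1], [1.0, 0.15],
         [0.95, 0.05], [0.7, -0.9]]
    )
    table, _ = make_planted_factor_table(
        PlantedFactorSpec(n_obs=2500, loadings=loadings, noise_sd=0.05,
                          seed=seed)
    )
    return ab.assemble(table, [f"m{i}" for i in range(6)])


def test_noise_robustness_deterministic_under_seed():
    m = _two_factor_matrix()
    r1 = noise_robustness(m, 0.10, seed=5, n_rep=2)
    r2 = noise_robustness(m, 0.10, seed=5, n_rep=2)
    for a, b in zip(r1.eigenvalues_perturbed, r2.eigenvalues_perturbed):
        assert np.array_equal(a, b)
    for a, b in zip(r1.principal_angles_deg, r2.principal_angles_deg):
        assert np.array_equal(a, b)


def test_noise_robustness_small_fraction_small_shifts():
    m = _two_factor_matrix()
    r = noise_robustness(m, 0.01, seed=6, n_rep=2)
    for shift in r.eigenvalue_shifts:
        assert np.abs(shift[:2]).max() < 0.1 * r.eigenvalues_original[0]


def test_noise_robustness_leading_pcs_stable_higher_unstable():
    """Adulterating the sample leaves the two planted components in place
    while deeper components can reorient drastically."""
    m = _two_factor_matrix()
    r = noise_robustness(m, 0.10, seed=7, n_rep=3, n_components=4)
    angles = np.stack(r.principal_angles_deg)
    assert angles[:, 0].max() < 10.0
    assert angles[:, 1].max() < 10.0
    assert angles[:, 2:].max() > 45.0


def test_noise_robustness_fraction_validated():
    m = _two_factor_matrix()
    with pytest.raises(ValueError, match="fraction"):
        noise_robustness(m, 0.0)
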