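"""Stockholder schemes: identities, planted-parameter recovery, determinism.

The Hirshfeld oracle here is an independent brute-force integration: for a
diatomic scene the integrand is axially symmetric, so q_A = Z_A - int w_A
rho reduces to a 2-D integral in cylindrical coordinates evaluated with
scipy's adaptive quadrature — no code shared with the implementation
under test.
"""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad

import arboretum as ab
from arboretum.stockholder_charges import hirshfeld, hirshfeld_iterative, isa, mbis
from arboretum.synthetic_fixtures import SlaterAtom, SlaterSceneSpec, make_slater_scene


def _slater(n, zeta, r):
    return n * zeta**3 / (8 * math.pi) * np.exp(-zeta * r)


# ---------------------------------------------------------------------------
# Hirshfeld
# ---------------------------------------------------------------------------

def test_hirshfeld_zero_on_promolecule(symmetric_scene, symmetric_grid):
    """When the molecular density IS the neutral promolecule, every
    stockholder charge vanishes."""
    cv = hirshfeld(
        symmetric_scene.density, symmetric_scene.geometry,
        symmetric_scene.database, symmetric_grid,
    )
    assert np.allclose(cv.charges, 0.0, atol=1e-6)


def test_hirshfeld_single_atom_total_charge():
    scene = make_slater_scene(
        SlaterSceneSpec(atoms=[SlaterAtom("O", np.zeros(3), 7.0, 2.25)],
                        spacing=0.3)
    )
    grid = ab.build_becke_grid(scene.geometry)
    cv = hirshfeld(scene.density, scene.geometry, scene.database, grid)
    assert cv.charges[0] == pytest.approx(1.0, abs=1e-5)


def test_hirshfeld_matches_cylindrical_quadrature_oracle():
    """Polar diatomic: Becke-grid Hirshfeld vs an independent adaptive 2-D
    integration of the same stockholder functional."""
    z_a, z_b = 8, 1
    n_a, n_b, zeta_a, zeta_b = 8.5, 0.5, 2.25, 1.0
    r_bond = 1.8
    scene = make_slater_scene(
        SlaterSceneSpec(
            atoms=[
                SlaterAtom("O", np.zeros(3), n_a, zeta_a),
                SlaterAtom("H", np.array([0.0, 0.0, r_bond]), n_b, zeta_b),
            ],
            spacing=0.3,
        )
    )
    grid = ab.build_becke_grid(scene.geometry)
    cv = hirshfeld(scene.density, scene.geometry, scene.database, grid)

    def integrand(s, z):
        r_a = math.hypot(s, z)
        r_b = math.hypot(s, z - r_bond)
        pro_a = _slater(z_a, zeta_a, r_a)     # neutral proatoms
        pro_b = _slater(z_b, zeta_b, r_b)
        rho = _slater(n_a, zeta_a, r_a) + _slater(n_b, zeta_b, r_b)
        w_a = pro_a / (pro_a + pro_b)
        return 2 * math.pi * s * w_a * rho

    pop_a, _ = dblquad(integrand, -25, 27, 0, 25, epsabs=1e-8, epsrel=1e-10)
    oracle = z_a - pop_a
    assert cv.charges[0] == pytest.approx(oracle, abs=1e-4)
    assert cv.charges[1] == pytest.approx(
        (z_a + z_b - n_a - n_b) - oracle, abs=1e-4
    )


# ---------------------------------------------------------------------------
# Hirshfeld-I
# ---------------------------------------------------------------------------

def test_hirshfeld_i_recovers_planted_fractional_populations(
    transfer_scene, transfer_grid
):
    """Density built as the database's own promolecule at fractional
    populations is a fixed point: the iteration must recover the planted
    populations."""
    g = transfer_scene.geometry
    db = transfer_scene.database
    planted = np.array([7.3, 6.7])
    density = ab.promolecule_density(g, db, populations=planted)
    cv, trace = hirshfeld_iterative(density, g, db, transfer_grid, tol=1e-8)
    assert trace.converged
    assert g.numbers - cv.charges == pytest.approx(planted, abs=1e-5)


def test_hirshfeld_i_symmetric_diatomic_equal_every_iteration(
    symmetric_scene, symmetric_grid
):
    cv, trace = hirshfeld_iterative(
        symmetric_scene.density, symmetric_scene.geometry,
        symmetric_scene.database, symmetric_grid,
    )
    for pops in trace.populations:
        assert pops[0] == pytest.approx(pops[1], abs=1e-10)
    assert np.allclose(cv.charges, 0.0, atol=1e-5)


def test_hirshfeld_i_iteration_zero_equals_hirshfeld(
    transfer_scene, transfer_grid
):
    g, db = transfer_scene.geometry, transfer_scene.database
    plain = hirshfeld(transfer_scene.density, g, db, transfer_grid)
    _, trace = hirshfeld_iterative(
        transfer_scene.density, g, db, transfer_grid, tol=1e-8
    )
    assert np.array_equal(trace.populations[0], g.numbers - plain.charges)


def test_hirshfeld_i_infinite_tol_returns_hirshfeld(
    transfer_scene, transfer_grid
):
    g, db = transfer_scene.geometry, transfer_scene.database
    plain = hirshfeld(transfer_scene.density, g, db, transfer_grid)
    cv, trace = hirshfeld_iterative(
        transfer_scene.density, g, db, transfer_grid, tol=math.inf
    )
    assert trace.n_iterations == 1
    assert np.array_equal(cv.charges, plain.charges)


def test_hirshfeld_i_bracket_exit_names_atom_and_state(
    transfer_scene, transfer_grid
):
    """A density holding more electrons than any available anion state must
    raise, naming the needed charge state, not extrapolate."""
    g = transfer_scene.geometry
    narrow = ab.ProatomDatabase.slater([7], charges=(0, 1, 2))
    density = ab.promolecule_density(
        g, transfer_scene.database, populations=np.array([7.4, 6.6])
    )
    with pytest.raises(ValueError, match="bracket"):
        hirshfeld_iterative(density, g, narrow, transfer_grid)


# ---------------------------------------------------------------------------
# ISA
# ---------------------------------------------------------------------------

def test_isa_single_atom():
    scene = make_slater_scene(
        SlaterSceneSpec(atoms=[SlaterAtom("C", np.zeros(3), 5.6, 1.57)],
                        spacing=0.3)
    )
    grid = ab.build_becke_grid(scene.geometry)
    cv, trace = isa(scene.density, scene.geometry, grid)
    assert trace.converged
    assert cv.charges[0] == pytest.approx(6 - 5.6, abs=1e-4)


def test_isa_recovers_planted_transfer(transfer_scene, transfer_grid):
    cv, _ = isa(transfer_scene.density, transfer_scene.geometry, transfer_grid)
    assert cv.charges == pytest.approx(
        transfer_scene.planted_charges.charges, abs=2e-3
    )


def test_isa_symmetric_diatomic(symmetric_scene, symmetric_grid):
    cv, _ = isa(symmetric_scene.density, symmetric_scene.geometry, symmetric_grid)
    assert cv.charges[0] == pytest.approx(cv.charges[1], abs=1e-8)


# ---------------------------------------------------------------------------
# MBIS
# ---------------------------------------------------------------------------

def test_mbis_recovers_single_slater_parameters():
    """A density that IS one Slater shell: one-shell MBIS must return its
    (N, sigma) to 1e-4."""
    n_true, zeta = 1.0, 1.0
    scene = make_slater_scene(
        SlaterSceneSpec(atoms=[SlaterAtom("H", np.zeros(3), n_true, zeta)],
                        spacing=0.25)
    )
    grid = ab.build_becke_grid(scene.geometry)
    cv, proatoms, trace = mbis(scene.density, scene.geometry, grid)
    assert trace.converged
    assert len(proatoms[0].shell_populations) == 1
    assert proatoms[0].shell_populations[0] == pytest.approx(n_true, abs=1e-4)
    assert proatoms[0].shell_widths[0] == pytest.approx(1.0 / zeta, abs=1e-4)


def test_mbis_symmetric_diatomic_equal_populations(
    symmetric_scene, symmetric_grid
):
    cv, proatoms, _ = mbis(
        symmetric_scene.density, symmetric_scene.geometry, symmetric_grid
    )
    n = [p.shell_populations.sum() for p in proatoms]
    assert n[0] == pytest.approx(n[1], abs=1e-8)


def test_mbis_three_atom_scene_conserves_charge():
    """H2O-like planted scene: total charge defect bounded by the grid
    normalization defect."""
    scene = make_slater_scene(
        SlaterSceneSpec(
            atoms=[
                SlaterAtom("O", np.zeros(3), 8.4, 2.25),
                SlaterAtom("H", np.array([0.0, 1.43, 1.11]), 0.8, 1.0),
                SlaterAtom("H", np.array([0.0, -1.43, 1.11]), 0.8, 1.0),
            ],
            spacing=0.3,
        )
    )
    grid = ab.build_becke_grid(scene.geometry)
    rho = scene.density(grid.points)
    norm_defect = abs(ab.integrate(rho, grid) - 10.0)
    # the single-zeta O proatom makes the two O shells nearly degenerate;
    # they coalesce and are merged, which takes a few hundred extra sweeps
    cv, _, _ = mbis(scene.density, scene.geometry, grid, max_iter=1500)
    assert abs(cv.total() - 0.0) <= max(norm_defect * 1.5, 1e-6)


# ---------------------------------------------------------------------------
# shared invariants
# ---------------------------------------------------------------------------

def test_stockholder_weights_partition_of_unity(transfer_scene, transfer_grid):
    from arboretum.stockholder_charges import (
        _atom_distances,
        _weights_from_proatoms,
    )

    g = transfer_scene.geometry
    dists = _atom_distances(g, transfer_grid.points)
    pro = np.stack(
        [transfer_scene.database.density(z, 0, dists[a])
         for a, z in enumerate(g.numbers)]
    )
    w, valid = _weights_from_proatoms(pro)
    assert np.allclose(w[:, valid].sum(axis=0), 1.0, atol=1e-12)
    assert w.min() >= 0.0


def test_charge_conservation_bound(transfer_scene, transfer_grid):
    """|sum q - Q_total| <= 1.5 |int rho - N_elec| for every scheme."""
    g, db = transfer_scene.geometry, transfer_scene.database
    rho = transfer_scene.density(transfer_grid.points)
    defect = abs(ab.integrate(rho, transfer_grid) - 14.0)
    bound = max(1.5 * defect, 1e-8)
    results = [
        hirshfeld(transfer_scene.density, g, db, transfer_grid),
        hirshfeld_iterative(transfer_scene.density, g, db, transfer_grid)[0],
        isa(transfer_scene.density, g, transfer_grid)[0],
        mbis(transfer_scene.density, g, transfer_grid)[0],
    ]
    for cv in results:
        assert abs(cv.total() - g.total_charge) <= bound, cv.method


def test_stockholder_determinism(transfer_scene, transfer_grid):
    """No randomness anywhere: two runs give bitwise-identical traces."""
    g, db = transfer_scene.geometry, transfer_scene.database
    cv1, tr1 = hirshfeld_iterative(transfer_scene.density, g, db, transfer_grid)
    cv2, tr2 = hirshfeld_iterative(transfer_scene.density, g, db, transfer_grid)
    assert np.array_equal(cv1.charges, cv2.charges)
    assert tr1.deltas == tr2.deltas
    m1 = mbis(transfer_scene.density, g, transfer_grid)
    m2 = mbis(transfer_scene.density, g, transfer_grid)
    assert np.array_equal(m1[0].charges, m2[0].charges)
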