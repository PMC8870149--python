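"""Scalar transport: IFP, oxygen, cell density; conservation structure."""

import numpy as np
import pytest
import scipy.sparse as sp

from gliomech.meshing import ball_mesh
from gliomech.transport import (TransportError, convection_matrix,
                                diffusion_matrix, lumped_mass, nodal_average,
                                scalar_quadrature, solve_ifp, steady_oxygen,
                                step_cells, step_oxygen)


@pytest.fixture(scope="module")
def mesh():
    return ball_mesh(5.0, 20.0, 2, 2, 1.6)


class TestAssembly:
    def test_diffusion_zero_row_col_sums(self, mesh):
        k = diffusion_matrix(mesh, mesh.nodes, 0.3)
        assert np.abs(np.asarray(k.sum(axis=1))).max() < 1e-10
        assert np.abs(np.asarray(k.sum(axis=0))).max() < 1e-10

    def test_diffusion_spd(self, mesh):
        k = diffusion_matrix(mesh, mesh.nodes, 1.0)
        x = np.random.default_rng(0).normal(size=mesh.n_nodes)
        assert x @ (k @ x) >= -1e-12

    def test_tensor_diffusion_matches_scalar(self, mesh):
        d = np.broadcast_to(0.4 * np.eye(3), (mesh.n_hexes, 3, 3))
        kt = diffusion_matrix(mesh, mesh.nodes, d)
        ks = diffusion_matrix(mesh, mesh.nodes, 0.4)
        assert abs(kt - ks).max() < 1e-12

    def test_tensor_validation(self, mesh):
        bad = np.broadcast_to(np.array([[1.0, 0.5, 0.0],
                                        [0.0, 1.0, 0.0],
                                        [0.0, 0.0, 1.0]]), (mesh.n_hexes, 3, 3))
        with pytest.raises(TransportError):
            diffusion_matrix(mesh, mesh.nodes, bad)
        indef = np.broadcast_to(np.diag([1.0, 1.0, -1.0]), (mesh.n_hexes, 3, 3))
        with pytest.raises(TransportError):
            diffusion_matrix(mesh, mesh.nodes, indef)

    def test_lumped_mass_total_volume(self, mesh):
        mv = lumped_mass(mesh, mesh.nodes)
        vol = scalar_quadrature(mesh, mesh.nodes)["volume"].sum()
        assert mv.sum() == pytest.approx(vol, rel=1e-12)
        assert np.all(mv > 0)

    def test_convection_zero_column_sums(self, mesh):
        v = np.random.default_rng(1).normal(size=(mesh.n_hexes, 3))
        c = convection_matrix(mesh, mesh.nodes, v)
        assert np.abs(np.asarray(c.sum(axis=0))).max() < 1e-10

    def test_nodal_average_constant(self, mesh):
        out = nodal_average(mesh, mesh.nodes, np.full(mesh.n_hexes, 3.7))
        assert np.allclose(out, 3.7, rtol=1e-12)


class TestSolveIfp:
    def test_zero_sources_pinned(self, mesh):
        st = solve_ifp(mesh, mesh.nodes, np.zeros(mesh.n_nodes), 0.0, 2000.0,
                       3.1e-8)
        assert np.abs(st.p_i).max() < 1e-9
        assert np.abs(st.v_f).max() < 1e-9

    def test_zero_sources_unpinned_singular(self, mesh):
        with pytest.raises(TransportError):
            solve_ifp(mesh, mesh.nodes, np.zeros(mesh.n_nodes), 0.0, 2000.0,
                      3.1e-8, pin_far_field=False)

    def test_strong_exchange_plateau(self, mesh):
        sv = np.where(mesh.region == 1, 0.7, 0.01)
        st = solve_ifp(mesh, mesh.nodes, sv, 1e-5, 2000.0, 3.1e-8)
        core = np.linalg.norm(mesh.nodes, axis=1) < 2.5
        assert np.abs(st.p_i[core] - 2000.0).max() < 0.01 * 2000.0
        assert np.all(st.p_i <= 2000.0 + 1e-9)

    def test_invalid_inputs(self, mesh):
        with pytest.raises(TransportError):
            solve_ifp(mesh, mesh.nodes, np.zeros(mesh.n_nodes), 0.0, 2000.0, 0.0)
        with pytest.raises(TransportError):
            solve_ifp(mesh, mesh.nodes, -np.ones(mesh.n_nodes), 1e-7, 2000.0,
                      3.1e-8)


class TestCellsAndOxygen:
    def test_cells_exact_reaction_no_diffusion(self, mesh):
        tn = mesh.tumor_node_mask()
        t0 = np.where(tn, 1.0, 0.0)
        out = step_cells(mesh, mesh.nodes, t0, 0, np.full(mesh.n_nodes, 0.1),
                         tn, 0.06, 0.1, 0.012, 2.0)
        grow_t = np.exp(0.06 * 0.1 / 0.2 * 2.0)
        assert np.allclose(out[tn], grow_t, rtol=1e-12)
        assert np.allclose(out[~tn], 0.0)

    def test_cells_conservation_diffusion_only(self, mesh):
        rng = np.random.default_rng(2)
        t0 = rng.uniform(0, 1, mesh.n_nodes)
        mv = lumped_mass(mesh, mesh.nodes)
        d = np.broadcast_to(0.05 * np.eye(3), (mesh.n_hexes, 3, 3))
        total0 = mv @ t0
        t = t0
        cache = {}
        for _ in range(100):
            t = step_cells(mesh, mesh.nodes, t, d, np.zeros(mesh.n_nodes),
                           np.zeros(mesh.n_nodes, dtype=bool), 0.06, 0.1, 0.0,
                           0.5, cache=cache)
        assert mv @ t == pytest.approx(total0, rel=1e-9)
        assert np.all(t >= 0)

    def test_oxygen_bounds_and_equilibrium(self, mesh):
        sv = np.full(mesh.n_nodes, 0.7)
        c = np.full(mesh.n_nodes, 0.3)
        out = step_oxygen(mesh, mesh.nodes, c, None, sv,
                          np.ones(mesh.n_nodes), 172.8, 30.0, 1.0, 40.0, 0.15,
                          0.01)
        assert np.all((0.0 <= out) & (out <= 1.0))
        # no cells: supply drives oxygen toward the vascular level
        out2 = step_oxygen(mesh, mesh.nodes, np.full(mesh.n_nodes, 1.0), None,
                           sv, np.zeros(mesh.n_nodes), 172.8, 30.0, 1.0, 40.0,
                           0.15, 0.01)
        assert np.allclose(out2, 1.0, atol=1e-9)

    def test_oxygen_conservation_closed(self, mesh):
        """No vessels, no cells: oxygen total drifts below 1e-6 over many steps."""
        rng = np.random.default_rng(3)
        c = rng.uniform(0.2, 0.8, mesh.n_nodes)
        mv = lumped_mass(mesh, mesh.nodes)
        total0 = mv @ c
        cache = {}
        for _ in range(200):
            c = step_oxygen(mesh, mesh.nodes, c, None, np.zeros(mesh.n_nodes),
                            np.zeros(mesh.n_nodes), 172.8, 30.0, 1.0, 40.0,
                            0.15, 0.01, cache=cache)
        assert abs(mv @ c - total0) < 1e-6 * total0

    def test_steady_oxygen_saturates_without_cells(self, mesh):
        c = steady_oxygen(mesh, mesh.nodes, np.full(mesh.n_nodes, 0.7),
                          np.zeros(mesh.n_nodes), 172.8, 30.0, 1.0, 40.0, 0.15)
        assert np.allclose(c, 1.0, atol=1e-8)

    def test_steady_oxygen_depressed_by_cells(self, mesh):
        tn = mesh.tumor_node_mask()
        c = steady_oxygen(mesh, mesh.nodes, np.full(mesh.n_nodes, 0.7),
                          np.where(tn, 1.0, 0.0), 172.8, 30.0, 1.0, 40.0, 0.15)
        assert np.all((0.0 <= c) & (c <= 1.0))
        assert c[tn].mean() < c[~tn].mean()

    def test_convection_cfl_guard(self, mesh):
        v = np.full((mesh.n_hexes, 3), 1e4)
        with pytest.raises(TransportError):
            step_oxygen(mesh, mesh.nodes, np.full(mesh.n_nodes, 0.5), v,
                        np.zeros(mesh.n_nodes), np.zeros(mesh.n_nodes),
                        172.8, 30.0, 1.0, 40.0, 0.15, 0.5)
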