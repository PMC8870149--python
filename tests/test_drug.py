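"""Pore hindrance, vessel-wall coefficients, bolus, Starling flux, drug fields."""

import numpy as np
import pytest

from gliomech.drug import (DrugState, hindrance_factors, starling_flux,
                           step_drug, vascular_concentration, wall_transport)
from gliomech.meshing import ball_mesh


class TestHindranceFactors:
    def test_unhindered_limit(self):
        f, kt, ks, h, w, sf = hindrance_factors(0.0)
        assert f == 1.0
        # published series coefficients are rounded to 4-5 significant digits,
        # so the lam -> 0 limits hold to ~1e-6 rather than machine precision
        assert h == pytest.approx(1.0, abs=1e-6)
        assert w == pytest.approx(1.0, abs=1e-6)
        assert sf == pytest.approx(0.0, abs=1e-6)

    def test_excluded_limit(self):
        f, kt, ks, h, w, sf = hindrance_factors(1.0)
        assert f == 0.0 and h == 0.0 and w == 0.0 and sf == 1.0
        assert np.isinf(kt) and np.isinf(ks)

    def test_monotone(self):
        lams = np.linspace(0.0, 0.999, 400)
        vals = np.array([hindrance_factors(l)[3:] for l in lams])
        h, w, sf = vals[:, 0], vals[:, 1], vals[:, 2]
        assert np.all(np.diff(h) < 0)
        assert np.all(np.diff(w) < 0)
        assert np.all(np.diff(sf) > 0)
        assert np.all((0 <= sf) & (sf <= 1))

    def test_extended_precision_oracle(self):
        from _oracles import hindrance_exact
        for lam in (0.01, 0.1, 0.35, 0.5, 0.7):
            _, _, _, h, w, sf = hindrance_factors(lam)
            h_o, w_o, sf_o = hindrance_exact(lam)
            assert h == pytest.approx(h_o, rel=1e-10)
            assert w == pytest.approx(w_o, rel=1e-10)
            assert sf == pytest.approx(sf_o, rel=1e-10, abs=1e-10)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            hindrance_factors(-0.1)
        with pytest.raises(ValueError):
            hindrance_factors(1.1)


class TestWallTransport:
    def test_hydraulic_conductivity_closed_form(self):
        # Lp = gamma r0^2 / (8 eta Lvw): 0.05 * (1e-4 mm)^2 / (8*3e-3*5e-3)
        l_p, _, _ = wall_transport(0.05, 100.0, 3e-3, 5.0, 1e-6, 0.5)
        assert l_p == pytest.approx(4.1666667e-6, rel=1e-6)
        l_p2, _, _ = wall_transport(0.05, 200.0, 3e-3, 5.0, 1e-6, 0.5)
        assert l_p2 == pytest.approx(4.0 * l_p, rel=1e-12)

    def test_permeability_scales_with_hindrance(self):
        d0 = 1e-6
        _, per_small, sf_small = wall_transport(0.05, 200.0, 3e-3, 5.0, d0, 0.1)
        _, per_large, sf_large = wall_transport(0.05, 200.0, 3e-3, 5.0, d0, 0.7)
        assert per_small > per_large        # bigger drug -> more hindered
        assert sf_small < sf_large          # and more reflected
        h = hindrance_factors(0.1)[3]
        assert per_small == pytest.approx(0.05 * h * d0 / 5e-3, rel=1e-12)

    def test_positivity_errors(self):
        with pytest.raises(ValueError):
            wall_transport(0.0, 200.0, 3e-3, 5.0, 1e-6, 0.5)
        with pytest.raises(ValueError):
            wall_transport(0.05, 200.0, 3e-3, -5.0, 1e-6, 0.5)


class TestVascularConcentration:
    def test_before_injection(self):
        assert vascular_concentration(0.5, 1.0, 1.0) == 0.0

    def test_decay(self):
        assert vascular_concentration(1.0, 1.0, 1.0) == pytest.approx(1.0)
        assert vascular_concentration(2.0, 1.0, 1.0) == pytest.approx(np.exp(-1.0))

    def test_kd_error(self):
        with pytest.raises(ValueError):
            vascular_concentration(1.0, 0.0, 0.0)


class TestStarlingFlux:
    def test_equilibrium_zero(self):
        q = starling_flux(1.0, np.array([0.7]), 0.3, np.array([0.3]),
                          1e-6, 2000.0, np.array([2000.0]), 0.2)
        assert q[0] == pytest.approx(0.0, abs=1e-15)

    def test_high_ifp_purely_diffusive(self):
        q = starling_flux(2.0, np.array([0.7]), 1.0, np.array([0.4]),
                          1e-6, 2000.0, np.array([2000.0]), 0.2)
        assert q[0] == pytest.approx(2.0 * 0.7 * 0.6, rel=1e-12)

    def test_negative_sv_error(self):
        with pytest.raises(ValueError):
            starling_flux(1.0, np.array([-0.1]), 1.0, np.array([0.0]),
                          1e-6, 2000.0, np.array([0.0]), 0.2)


@pytest.fixture(scope="module")
def mesh():
    return ball_mesh(5.0, 20.0, 2, 2, 1.6)


class TestStepDrug:
    def test_closed_system_conservation(self, mesh):
        rng = np.random.default_rng(0)
        state = DrugState(rng.uniform(0, 1, mesh.n_nodes),
                          rng.uniform(0, 1, mesh.n_nodes),
                          np.zeros(mesh.n_nodes))
        from gliomech.transport import lumped_mass
        mv = lumped_mass(mesh, mesh.nodes)
        total0 = float(mv @ state.total)
        cache = {}
        for _ in range(50):
            state = step_drug(mesh, mesh.nodes, state, None, None, 0.5,
                              100.0, 10.0, 10.0, 1.0 / (24 * 60), cache=cache)
        total1 = float(mv @ state.total)
        assert abs(total1 - total0) <= 1e-9 * total0
        assert np.all(state.c_f >= 0) and np.all(state.c_b >= 0)
        assert np.all(state.c_int >= 0)

    def test_internalized_monotone(self, mesh):
        state = DrugState(np.full(mesh.n_nodes, 0.5), np.zeros(mesh.n_nodes),
                          np.zeros(mesh.n_nodes))
        prev = 0.0
        cache = {}
        for _ in range(20):
            state = step_drug(mesh, mesh.nodes, state, None, None, 0.0,
                              100.0, 10.0, 10.0, 1e-3, cache=cache)
            cur = state.c_int.sum()
            assert cur >= prev
            prev = cur

    def test_binding_kinetics_closed_form(self, mesh):
        """With only internalization (k_on = k_off = 0), c_b decays as e^{-k t}."""
        n = mesh.n_nodes
        state = DrugState(np.zeros(n), np.ones(n), np.zeros(n))
        dt = 1e-4
        for _ in range(1000):
            state = step_drug(mesh, mesh.nodes, state, None, None, 0.0,
                              0.0, 0.0, 10.0, dt, cache={})
        assert state.c_b[0] == pytest.approx(np.exp(-1.0), rel=1e-3)
        assert state.c_int[0] == pytest.approx(1.0 - state.c_b[0], rel=1e-12)

    def test_errors(self, mesh):
        state = DrugState.zero(mesh.n_nodes)
        with pytest.raises(Exception):
            step_drug(mesh, mesh.nodes, state, None, None, 0.0,
                      -1.0, 0.0, 0.0, 0.1)
        with pytest.raises(Exception):
            step_drug(mesh, mesh.nodes, state, None, None, 0.0,
                      1.0, 0.0, 0.0, 0.0)
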