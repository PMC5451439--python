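"""2D level-set Stefan solver: state construction, interface speed,
front advection, boundary extraction, geometry updates, and fitting."""

import numpy as np
import pytest

from gliomafit.geometry import Params
from gliomafit.levelset2d import (
    BoundaryCurve,
    PlanarDomain,
    evolve,
    extract_boundary,
    init_state,
    interface_velocity,
    rasterize_tumor,
    reinitialize,
    simulate_planar_truth,
)
from gliomafit.units import um2h_to_mm2h


def disk_domain(n=100, h=0.1, wall=0.2):
    X = (np.arange(n)[:, None] + 0.5) * h
    Y = (np.arange(n)[None, :] + 0.5) * h
    c = (n * h / 2, n * h / 2)
    rr = np.hypot(X - c[0], Y - c[1])
    brain = rr < (n * h / 2 - wall)
    return PlanarDomain((n, n), (h, h), brain, np.zeros((n, n), bool)), rr, c


class TestInitState:
    def test_signed_distance_at_disk_center(self):
        dom, rr, c = disk_domain()
        state = init_state(rr < 2.0, dom, day=0)
        center = (50, 50)
        assert state.phi[center] == pytest.approx(-2.0, abs=np.hypot(0.1, 0.1))

    def test_contour_length_matches_circumference(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 2.0, dom, day=0)
        b = extract_boundary(state)
        assert b.perimeter() == pytest.approx(2 * np.pi * 2.0, rel=0.05)

    def test_values_exactly_from_construction(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 1.0, dom, u0=0.5, u_bar=0.16, day=0)
        assert set(np.unique(state.u)) <= {0.0, 0.16, 0.5}

    def test_empty_tumor_rejected(self):
        dom, rr, _ = disk_domain()
        with pytest.raises(ValueError):
            init_state(np.zeros(dom.shape, bool), dom)

    def test_signed_distance_property_after_reinit(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 1.5, dom, day=0)
        phi = reinitialize(state.phi, dom.spacing)
        gx, gy = np.gradient(phi, 0.1, 0.1)
        g = np.hypot(gx, gy)
        band = np.abs(phi) < 0.2
        interior = (np.abs(phi) < 1.0) & ~band
        assert np.median(np.abs(g[interior] - 1.0)) < 0.05


class TestInterfaceVelocity:
    def test_uniform_density_gives_zero_speed(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 1.5, dom, u0=0.16, u_bar=0.16, day=0)
        state.u[state.phi < 0] = 0.16
        v = interface_velocity(state, 463.09)
        assert np.abs(v).max() < 1e-10

    def test_exponential_profile_oracle(self):
        # u = u_bar * exp(-k phi): since phi is the signed distance,
        # du/dn = -k u_bar on the interface, so v = D k everywhere on it
        dom, rr, _ = disk_domain(n=120)
        R, k, u_bar = 2.5, 1.2, 0.16
        state = init_state(rr < R, dom, u0=0.5, u_bar=u_bar, day=0)
        state.u = np.where(state.phi < 0, u_bar * np.exp(-k * state.phi), 0.0)
        D = 463.09
        v = interface_velocity(state, D)
        inside = state.phi < 0
        front = inside & ~np.roll(inside, 1, axis=0)
        expected = um2h_to_mm2h(D) * k
        got = np.median(v[front])
        assert got == pytest.approx(expected, rel=0.1)

    def test_linearity_in_D(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 2.0, dom, day=0)
        v1 = interface_velocity(state, 400.0)
        v2 = interface_velocity(state, 800.0)
        np.testing.assert_allclose(v2, 2 * v1, atol=1e-14)

    def test_scalar_and_field_paths_identical(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 2.0, dom, day=0)
        D = 463.09
        field = (np.full(dom.shape, D), np.full(dom.shape, D))
        np.testing.assert_allclose(
            interface_velocity(state, D), interface_velocity(state, field), atol=1e-10
        )


class TestEvolve:
    def test_prescribed_speed_disk_growth(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 1.0, dom, day=0)
        v0 = 0.005  # mm/h
        hist = evolve(state, Params(1, 1), dom, 200.0, speed_override=v0,
                      output_times=[100.0, 200.0])
        for s in hist:
            R = np.sqrt(extract_boundary(s).area() / np.pi)
            assert R == pytest.approx(1.0 + v0 * s.time, rel=0.03)

    def test_zero_speed_area_drift_small(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 2.0, dom, day=0)
        a0 = extract_boundary(state).area()
        hist = evolve(state, Params(1, 1), dom, 100.0, speed_override=0.0,
                      max_dt=1.0)  # 100 advection steps
        a1 = extract_boundary(hist[-1]).area()
        assert abs(a1 - a0) / a0 < 0.005

    def test_scalar_equals_constant_field_evolution(self):
        dom, rr, _ = disk_domain(n=60)
        state = init_state(rr < 1.0, dom, day=0)
        p = Params(463.09, 0.027164)
        a = evolve(state, p, dom, 96.0)[-1]
        field = (np.full(dom.shape, p.D), np.full(dom.shape, p.D))
        b = evolve(state, p, dom, 96.0, D_field=field)[-1]
        np.testing.assert_allclose(a.phi, b.phi, atol=1e-10)
        np.testing.assert_allclose(a.u, b.u, atol=1e-10)

    def test_tumor_clipped_out_of_updated_ventricles(self):
        dom, rr, c = disk_domain()
        # a ventricle appears at day 15 inside the growing tumour's path
        X = (np.arange(100)[:, None] + 0.5) * 0.1
        Y = (np.arange(100)[None, :] + 0.5) * 0.1
        vent = (np.hypot(X - c[0] - 1.2, Y - c[1]) < 0.4)
        updated = PlanarDomain(
            dom.shape, dom.spacing, dom.brain_mask, vent,
        )
        dom2 = PlanarDomain(
            dom.shape, dom.spacing, dom.brain_mask, np.zeros(dom.shape, bool),
            updates=((15, updated.brain_mask, vent),),
        )
        state = init_state(rr < 1.0, dom2, day=11)
        hist = evolve(state, Params(1, 1), dom2, 24 * 20.0, speed_override=0.006)
        tumor = rasterize_tumor(hist[-1])
        assert not (tumor & vent).any()
        assert tumor.sum() > (rr < 1.0).sum()  # it did keep growing


class TestBoundaryCurve:
    def test_rectangle_perimeter(self):
        dom, rr, _ = disk_domain()
        mask = np.zeros(dom.shape, bool)
        mask[20:60, 30:70] = True  # 4.0 x 4.0 mm
        state = init_state(mask, dom, day=0)
        assert extract_boundary(state).perimeter() == pytest.approx(16.0, rel=0.05)

    def test_disk_area(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 2.0, dom, day=0)
        assert extract_boundary(state).area() == pytest.approx(np.pi * 4.0, rel=0.02)

    def test_translation_equivariance(self):
        dom, rr, _ = disk_domain()
        state = init_state(rr < 1.5, dom, day=0)
        b1 = extract_boundary(state)
        shifted = type(state)(
            phi=np.roll(state.phi, 1, axis=0), u=state.u, time=state.time,
            u_bar=state.u_bar, spacing=state.spacing,
        )
        b2 = extract_boundary(shifted)
        np.testing.assert_allclose(
            b2.vertices, b1.vertices + np.array([0.1, 0.0]), atol=1e-9
        )

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            BoundaryCurve(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestPlanarFit:
    def test_anisotropic_truth_beats_isotropic_fit(self):
        from gliomafit.levelset2d import levelset_objective
        from gliomafit.phantom import DFieldSpec2D, make_anisotropic_D_field

        dom, rr, _ = disk_domain(n=64)
        tumor0 = rr < 0.5
        spec = DFieldSpec2D(eta=2000.0, seed=3)
        field = make_anisotropic_D_field(dom.domain_mask, spec, mode="axiswise")
        truth = Params(463.09, 0.027164)
        series = simulate_planar_truth(dom, tumor0, truth, (11, 15, 18), D_field=field)
        e2_truth, _, _ = levelset_objective(truth, series, D_field=field)
        e2_iso, _, _ = levelset_objective(truth, series)  # isotropic model
        assert e2_truth == 0.0
        assert e2_iso > e2_truth
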