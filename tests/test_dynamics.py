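"""Dynamics oracles: closed-form reductions, numerical-Lagrangian checks,
impact/take-off contracts and energy behaviour."""

import numpy as np
import pytest

from toewalk.dynamics import (NQ, NU, Contact, ContactSet, GenCoords,
                              ModelValidationError, PlanarLinkage,
                              build_model, constrained_accel,
                              constraint_jacobian, evaluate_dynamics,
                              impact_map, mirror_state, takeoff_map,
                              total_energy, _kkt_solve)


def random_state(rng, scale=0.6):
    q = rng.normal(0.0, scale, NQ)
    q[1] = abs(q[1]) + 0.6
    qd = rng.normal(0.0, 1.0, NQ)
    return GenCoords(q, qd)


def project_velocity(model, state, contacts):
    """Return the state with velocity projected onto the contact manifold."""
    G, _ = constraint_jacobian(model, state, contacts)
    qd = state.qdot - G.T @ np.linalg.solve(G @ G.T, G @ state.qdot)
    return GenCoords(state.q, qd)


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

class TestBuildModel:
    def test_defaults_validate(self):
        m = build_model(mass=40.0, height=1.45)
        assert len(m.segments) == 8
        assert m.B.shape == (NQ, NU)
        assert np.linalg.matrix_rank(m.B) == NU
        assert m.L_leg_nominal > 0

    def test_segment_masses_sum_to_total(self):
        m = build_model(mass=40.0, height=1.45)
        assert abs(sum(s.mass for s in m.segments.values()) - 40.0) < 1e-9

    @pytest.mark.parametrize("override", [
        {"segments": {"l_thigh": {"length": 0.0}}},
        {"mass": -3.0},
        {"segments": {"torso": {"mass": -1.0}}},
        {"segments": {"l_foot": {"com_offset": 9.9}}},
    ])
    def test_invalid_parameters_rejected(self, override):
        with pytest.raises(ModelValidationError):
            build_model(**override)


# --------------------------------------------------------------------------
# Lagrangian term oracles
# --------------------------------------------------------------------------

class TestLagrangianTerms:
    def test_coriolis_vanishes_at_rest(self, model, rng):
        for _ in range(5):
            q = rng.normal(0, 1, NQ)
            Cqd, _ = model.linkage.bias_forces(q, np.zeros(NQ))
            assert np.all(Cqd == 0.0)

    def test_single_body_closed_form(self, rng):
        # one planar rigid body: M has the textbook 3x3 form
        m_, c_, I_, L_ = 3.0, 0.2, 0.05, 0.5
        link = PlanarLinkage([m_], [I_], [[c_]], [1.0])
        for _ in range(5):
            th = rng.uniform(-np.pi, np.pi)
            M = link.mass_matrix(np.array([0.1, 0.2, th]))
            expected = np.array([
                [m_, 0.0, m_ * c_ * np.cos(th)],
                [0.0, m_, m_ * c_ * np.sin(th)],
                [m_ * c_ * np.cos(th), m_ * c_ * np.sin(th), m_ * c_ ** 2 + I_],
            ])
            assert np.allclose(M, expected, atol=1e-12)

    def test_mass_matrix_matches_kinetic_energy_hessian(self, model, rng):
        h = 1e-5
        for _ in range(3):
            st = random_state(rng)
            M = model.linkage.mass_matrix(st.q)
            assert np.allclose(M, M.T, atol=1e-12)
            Mfd = np.zeros((NQ, NQ))
            for i in range(NQ):
                for j in range(NQ):
                    def T(di, dj):
                        v = np.zeros(NQ)
                        v[i] += di
                        v[j] += dj
                        return model.linkage.kinetic_energy(st.q, v)
                    Mfd[i, j] = (T(h, h) - T(h, -h) - T(-h, h) + T(-h, -h)) / (4 * h * h)
            assert np.allclose(M, Mfd, rtol=1e-6, atol=1e-6)

    def test_bias_forces_match_numerical_lagrangian(self, model, rng):
        # C qd = Mdot qd - dT/dq and G = dV/dq by central differences
        h = 1e-6
        for _ in range(3):
            st = random_state(rng)
            q, qd = st.q, st.qdot
            Cqd, G = model.linkage.bias_forces(q, qd)
            Md = (model.linkage.mass_matrix(q + h * qd)
                  - model.linkage.mass_matrix(q - h * qd)) / (2 * h)
            dTdq = np.zeros(NQ)
            dVdq = np.zeros(NQ)
            for i in range(NQ):
                e = np.zeros(NQ)
                e[i] = h
                dTdq[i] = (model.linkage.kinetic_energy(q + e, qd)
                           - model.linkage.kinetic_energy(q - e, qd)) / (2 * h)
                dVdq[i] = (model.linkage.potential_energy(q + e)
                           - model.linkage.potential_energy(q - e)) / (2 * h)
            assert np.allclose(Cqd, Md @ qd - dTdq, atol=1e-6)
            assert np.allclose(G, dVdq, atol=1e-6)

    def test_mass_matrix_positive_definite(self, model, rng):
        for _ in range(1000):
            q = rng.normal(0, 1.5, NQ)
            M = model.linkage.mass_matrix(q)
            assert np.all(np.linalg.eigvalsh(M) > 0)

    def test_mirror_symmetry_of_dynamics(self, model, rng):
        st = random_state(rng)
        mi = mirror_state(st)
        assert np.isclose(model.linkage.kinetic_energy(st.q, st.qdot),
                          model.linkage.kinetic_energy(mi.q, mi.qdot))
        assert np.isclose(model.linkage.potential_energy(st.q),
                          model.linkage.potential_energy(mi.q))


# --------------------------------------------------------------------------
# double-pendulum reduction (symbolic oracle)
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def double_pendulum_oracle():
    """Symbolically derived accelerations of a planar 2-link pendulum
    (distributed-mass rods, absolute angles, pinned base)."""
    import sympy as sp
    t = sp.symbols("t")
    th1, th2 = sp.Function("th1")(t), sp.Function("th2")(t)
    m1, m2, l1, c1, c2, I1, I2, g = sp.symbols("m1 m2 l1 c1 c2 I1 I2 g", positive=True)
    # e(theta) = (sin, -cos) convention, pinned base at origin
    p1 = sp.Matrix([c1 * sp.sin(th1), -c1 * sp.cos(th1)])
    p2 = sp.Matrix([l1 * sp.sin(th1) + c2 * sp.sin(th2),
                    -l1 * sp.cos(th1) - c2 * sp.cos(th2)])
    v1, v2 = p1.diff(t), p2.diff(t)
    T = (m1 * (v1.T @ v1)[0] + m2 * (v2.T @ v2)[0]) / 2 \
        + (I1 * th1.diff(t) ** 2 + I2 * th2.diff(t) ** 2) / 2
    V = g * (m1 * p1[1] + m2 * p2[1])
    L = T - V
    eqs = []
    for th in (th1, th2):
        eqs.append(sp.diff(sp.diff(L, th.diff(t)), t) - sp.diff(L, th))
    dd = sp.symbols("dd1 dd2")
    sub = {th1.diff(t, 2): dd[0], th2.diff(t, 2): dd[1]}
    sol = sp.solve([sp.Eq(e.subs(sub), 0) for e in eqs], dd, dict=True)[0]
    w1, w2 = sp.symbols("w1 w2")
    vals = {th1: sp.Symbol("q1"), th2: sp.Symbol("q2"),
            th1.diff(t): w1, th2.diff(t): w2}
    f = sp.lambdify(
        (sp.Symbol("q1"), sp.Symbol("q2"), w1, w2, m1, m2, l1, c1, c2, I1, I2, g),
        [sol[dd[0]].subs(vals), sol[dd[1]].subs(vals)], "numpy")
    return f


def test_double_pendulum_matches_symbolic_oracle(double_pendulum_oracle, rng):
    m1, m2, l1, l2 = 2.0, 1.5, 0.6, 0.5
    c1, c2, I1, I2, g = 0.25, 0.3, 0.03, 0.02, 9.81
    link = PlanarLinkage([m1, m2], [I1, I2],
                         [[c1, 0.0], [l1, c2]], [1.0, 1.0], gravity=g)
    pin = np.zeros(2)  # pin the reference point: Gamma = [I2 | 0]
    for _ in range(10):
        th = rng.uniform(-np.pi, np.pi, 2)
        w = rng.normal(0, 2, 2)
        q = np.array([0.0, 0.0, th[0], th[1]])
        qd = np.array([0.0, 0.0, w[0], w[1]])
        M = link.mass_matrix(q)
        Cqd, G = link.bias_forces(q, qd)
        Gamma = link.point_jacobian(q, pin)
        gdot = link.point_accel_bias(q, qd, pin)
        qdd, lam, _ = _kkt_solve(M, Gamma, -Cqd - G, -gdot)
        expected = double_pendulum_oracle(th[0], th[1], w[0], w[1],
                                          m1, m2, l1, c1, c2, I1, I2, g)
        assert np.allclose(qdd[2:], expected, rtol=1e-8, atol=1e-8)


# --------------------------------------------------------------------------
# constrained dynamics
# --------------------------------------------------------------------------

class TestConstrainedDynamics:
    def test_constraint_residual(self, model, rng):
        cs = ContactSet((Contact(leg="left"),))
        for _ in range(5):
            st = project_velocity(model, random_state(rng, 0.4), cs)
            u = rng.normal(0, 10, NU)
            qdd, lam = constrained_accel(model, st, cs, u)
            G, gd = constraint_jacobian(model, st, cs)
            assert np.linalg.norm(G @ qdd + gd) < 1e-8

    def test_eom_residual(self, model, rng):
        cs = ContactSet((Contact(leg="right"),))
        st = project_velocity(model, random_state(rng, 0.4), cs)
        u = rng.normal(0, 10, NU)
        qdd, lam = constrained_accel(model, st, cs, u)
        ev = evaluate_dynamics(model, st, cs)
        res = ev.M @ qdd + ev.Cqdot + ev.G - model.B @ u - ev.Gamma.T @ lam
        assert np.linalg.norm(res) < 1e-8

    def test_static_equilibrium_under_gravity_compensation(self, model):
        from toewalk.references import load_casting_schedule
        from toewalk.control import GainConfig, StepTarget
        from toewalk.hybrid_sim import static_start
        hs = static_start(model, load_casting_schedule()[0], StepTarget(),
                          GainConfig.from_omega())
        st = GenCoords(hs.gen.q, np.zeros(NQ))
        # double support: the second toe rests at ground level
        from toewalk.geometry import forward_kinematics
        toe = forward_kinematics(model, st).toe("right")
        cs = ContactSet((Contact(leg="left", anchor=(0.0, 0.0)),
                         Contact(leg="right", anchor=tuple(toe))))
        ev = evaluate_dynamics(model, st, cs)
        A = np.hstack([model.B, ev.Gamma.T])
        sol, *_ = np.linalg.lstsq(A, ev.G, rcond=None)
        u = sol[:NU]
        qdd, _ = constrained_accel(model, st, cs, u)
        assert np.linalg.norm(qdd) < 1e-6


# --------------------------------------------------------------------------
# impact and take-off maps
# --------------------------------------------------------------------------

class TestImpactMap:
    def test_nothing_to_absorb(self, model, rng):
        st = GenCoords(random_state(rng).q, np.zeros(NQ))
        cs = ContactSet((Contact(leg="left"), Contact(leg="right")))
        res = impact_map(model, st, cs)
        assert np.allclose(res.qdot_plus, 0.0, atol=1e-12)
        assert np.allclose(res.impulse, 0.0, atol=1e-12)

    def test_falling_rod_angular_momentum(self, rng):
        # single rod hitting the ground at its tip: angular momentum about
        # the tip is conserved through the plastic impact
        m_, L_, c_ = 1.7, 0.8, 0.4
        I_ = m_ * L_ ** 2 / 12.0
        link = PlanarLinkage([m_], [I_], [[c_]], [1.0])
        for _ in range(10):
            th = rng.uniform(-1.2, 1.2)
            qd_minus = rng.normal(0, 1, 3)
            q = np.array([0.0, 1.0, th])
            tip = np.array([L_])
            M = link.mass_matrix(q)
            Gamma = link.point_jacobian(q, tip)
            qd_plus, F, _ = _kkt_solve(M, Gamma, M @ qd_minus, np.zeros(2))
            # angular momentum about the tip point
            e, ep = link.unit_vectors(np.array([th]))
            r_com_tip = (c_ - L_) * e[0]          # tip -> COM
            def ang_mom(qd):
                v_com = qd[:2] + c_ * qd[2] * ep[0]
                return I_ * qd[2] + m_ * (r_com_tip[0] * v_com[1]
                                          - r_com_tip[1] * v_com[0])
            assert np.isclose(ang_mom(qd_minus), ang_mom(qd_plus), atol=1e-10)
            # tip velocity is zero afterwards
            assert np.linalg.norm(Gamma @ qd_plus) < 1e-9
            # omega+ equals the closed form L_tip / I_tip
            I_tip = I_ + m_ * (L_ - c_) ** 2
            assert np.isclose(qd_plus[2], ang_mom(qd_minus) / I_tip, atol=1e-10)

    def test_zero_contact_velocity_and_dissipativity(self, model, rng):
        cs = ContactSet((Contact(leg="left"), Contact(leg="right")))
        for _ in range(1000):
            st = random_state(rng)
            res = impact_map(model, st, cs)
            G, _ = constraint_jacobian(model, st, cs)
            assert np.linalg.norm(G @ res.qdot_plus) < 1e-9
            ke_minus = model.linkage.kinetic_energy(st.q, st.qdot)
            ke_plus = model.linkage.kinetic_energy(st.q, res.qdot_plus)
            assert ke_plus <= ke_minus + 1e-10


class TestTakeoffMap:
    def test_identity_on_continuous_state(self, model, rng):
        st = random_state(rng)
        cs = ContactSet((Contact(leg="left"), Contact(leg="right")))
        st2, cs2 = takeoff_map(st, cs, "left")
        assert st2 is st
        assert cs2.legs() == ("right",)

    def test_constraint_dimension_bookkeeping(self, model, rng):
        cs = ContactSet((Contact(leg="left"), Contact(leg="right")))
        st = project_velocity(model, random_state(rng, 0.4), cs)
        G2, _ = constraint_jacobian(model, st, cs)
        _, cs1 = takeoff_map(st, cs, "right")
        G1, _ = constraint_jacobian(model, st, cs1)
        assert G2.shape[0] - G1.shape[0] == 2

    def test_reattach_while_point_at_rest_gives_zero_impulse(self, model, rng):
        cs = ContactSet((Contact(leg="left"), Contact(leg="right")))
        st = project_velocity(model, random_state(rng, 0.4), cs)
        _, cs1 = takeoff_map(st, cs, "right")
        res = impact_map(model, st, cs)   # re-add while velocity still zero
        assert np.linalg.norm(res.impulse) < 1e-8
        assert np.allclose(res.qdot_plus, st.qdot, atol=1e-9)


# --------------------------------------------------------------------------
# energy behaviour along simulated motion
# --------------------------------------------------------------------------

def test_passive_energy_conservation_and_anchor_drift(model):
    """Unforced constrained motion conserves T + V; the contact anchor
    does not drift."""
    from scipy.integrate import solve_ivp

    cs = ContactSet((Contact(leg="left", anchor=(0.0, 0.0)),))
    rng = np.random.default_rng(7)
    q = np.zeros(NQ)
    q[1] = 0.8
    q[2:] = rng.normal(0, 0.3, 8)
    st0 = project_velocity(model, GenCoords(q, rng.normal(0, 0.5, NQ)), cs)
    toe0 = model.linkage.point_position(st0.q, model.point_coeffs("toe_left"))

    def rhs(t, x):
        s = GenCoords(x[:NQ], x[NQ:])
        qdd, _ = constrained_accel(model, s, cs, np.zeros(NU))
        return np.concatenate([x[NQ:], qdd])

    sol = solve_ivp(rhs, (0.0, 0.5), np.concatenate([st0.q, st0.qdot]),
                    rtol=1e-8, atol=1e-10, dense_output=False,
                    t_eval=np.linspace(0, 0.5, 26))
    E0 = total_energy(model, st0)
    for x in sol.y.T:
        s = GenCoords(x[:NQ], x[NQ:])
        assert abs(total_energy(model, s) - E0) < 1e-4
        toe = model.linkage.point_position(s.q, model.point_coeffs("toe_left"))
        assert np.linalg.norm(toe - toe0) < 1e-6
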