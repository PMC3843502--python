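"""Hybrid execution engine.

A step runs from the contact of one leg to the successive contact of the
opposite leg: a (short) double-support phase ending at take-off of the
trailing leg, then a single-support phase ending at touchdown of the swing
leg.  Touchdown applies the plastic impact map; take-off is velocity
continuous.  Between steps the adaptive push-off law updates the stance-leg
end-lengthening velocity from the measured gait velocity, and references
for the next single support are refitted from the take-off state.

Event primitives are geometric/kinetic zero crossings root-located by the
integrator: swing-toe height crossing zero downward (touchdown; the
controller's clearance construction makes this coincide with the phase
variable reaching its touchdown target) and the trailing-leg vertical
contact force crossing zero from above (take-off).

Gait stability is judged by the standard deviation of the gait velocity
over the last N steps: sigma_N(v_gait) < eps.  A schedule run walks through
an ordered list of control-parameter sets, optionally sub-dividing each
change into m equal increments, settling at every set before moving on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .dynamics import (NQ, NU, IDX_PEL, IDX_TOR, BipedModel, Contact,
                       ContactSet, GenCoords, impact_map,
                       input_affine_dynamics, takeoff_map)
from .geometry import forward_kinematics, virtual_leg
from .control import (BetweenStepState, DSStartSnapshot, GainConfig,
                      StepTarget, between_step_update, feedback_torques,
                      outputs_ds, outputs_ss, touchdown_target)
from .references import (ControlParams, ReferenceSet, TakeoffSnapshot,
                         WeightRates, make_reference_set)


class SimulationError(RuntimeError):
    """Integration failed in a way that is not a detected fall."""


class FallError(RuntimeError):
    """The model fell or stalled (hip too low, or no event within the
    maximum phase time)."""

    def __init__(self, message, step_index=None, phase=None, t=None):
        super().__init__(message)
        self.step_index = step_index
        self.phase = phase
        self.t = t


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Engine parameters.

    Integrator tolerances default to rtol 1e-7 / atol 1e-9 with the step
    size capped at 10 ms so phase-boundary events cannot be skipped;
    records are sampled at 1 kHz.  N and epsilon define the velocity-settle
    criterion; m_interp sub-divides every scheduled parameter change.
    """
    rtol: float = 1e-7
    atol: float = 1e-9
    method: str = "RK45"
    max_step: float = 0.01
    record_rate: float = 1000.0
    max_ss_time: float = 5.0
    max_ds_time: float = 1.0
    guard_s: float = 0.25
    fall_hip_frac: float = 0.45
    k1: float = 0.05
    rates: WeightRates = field(default_factory=WeightRates)
    N: int = 10
    epsilon: float = 0.01
    max_steps_per_zeta: int = 40
    m_interp: int = 5
    abort_on_no_settle: bool = False


# --------------------------------------------------------------------------
# state and records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HybridState:
    """Continuous state plus the discrete mode of the hybrid system.

    ``stance_side`` names the single-support stance leg; during double
    support it names the trailing leg (the stance leg of the single-support
    phase that just ended).
    """
    gen: GenCoords
    t: float
    phase: str                      # 'ss' | 'ds'
    stance_side: str                # 'left' | 'right'
    contacts: ContactSet
    step_index: int = 0
    refs: ReferenceSet | None = None
    between: BetweenStepState = field(default_factory=BetweenStepState)
    qd_stv_end_prev: float | None = None

    def __post_init__(self):
        expected = {"ss": 1, "ds": 2}[self.phase]
        if len(self.contacts) != expected:
            raise ValueError(
                f"phase '{self.phase}' requires {expected} contacts, "
                f"got {len(self.contacts)}")


@dataclass
class StepRecord:
    """Uniformly sampled time series of one step plus scalar descriptors.

    Torques and ground reactions are recomputed on demand from the stored
    control context (:meth:`compute_kinetics`); ``grf`` columns are
    (trailing_x, trailing_z, leading_x, leading_z) during double support
    and (stance_x, stance_z, 0, 0) during single support.
    """
    step_index: int
    stance_side: str                  # stance leg of the single-support phase
    t: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    phase_flags: np.ndarray           # 0 = ds, 1 = ss
    t_start: float
    t_takeoff: float
    t_contact: float
    v_gait: float
    step_length: float                # hip travel over the step [m]
    contact_separation: float         # distance between the two contact anchors [m]
    q_stv_d: float
    q_stv_at_contact: float
    z_sw_at_contact: float
    L_dot_stv_end: float
    # control context for kinetics recomputation
    _ds_ctx: dict | None = None
    _ss_ctx: dict | None = None
    u: np.ndarray | None = None
    grf: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.t_contact - self.t_start

    def drop_series(self) -> None:
        self.t = self.q = self.qdot = self.phase_flags = None
        self.u = self.grf = None
        self._ds_ctx = self._ss_ctx = None

    def compute_kinetics(self, model: BipedModel, gains: GainConfig) -> None:
        if self.u is not None or self.t is None:
            return
        n = self.t.size
        u = np.zeros((n, NU))
        grf = np.zeros((n, 4))
        for i in range(n):
            state = GenCoords(self.q[i], self.qdot[i])
            if self.phase_flags[i] == 0 and self._ds_ctx is not None:
                ctx = self._ds_ctx
                out = outputs_ds(model, state, ctx["zeta"], ctx["snapshot"],
                                 ctx["rates"], ctx["trailing_side"], self.t[i])
                contacts = ctx["contacts"]
            else:
                ctx = self._ss_ctx
                out = outputs_ss(model, state, ctx["refs"],
                                 ctx["stance_side"], self.t[i])
                contacts = ctx["contacts"]
            A, b, lamA, lamb = input_affine_dynamics(model, state, contacts)
            ui = feedback_torques(model, state, contacts, out, gains)
            lam = lamA @ ui + lamb
            u[i] = ui
            if self.phase_flags[i] == 0:
                grf[i] = lam[:4]
            else:
                grf[i, :2] = lam[:2]
        self.u = u
        self.grf = grf


@dataclass
class ScheduleEntry:
    zeta: ControlParams
    scheduled: bool                  # a schedule column (not an interpolant)
    settled: bool
    steps_taken: int
    sigma: float | None
    velocities: list
    records: tuple | None            # settled (StepRecord, StepRecord) pair


@dataclass
class ScheduleResult:
    entries: list
    total_steps: int
    velocity_log: list
    fall: dict | None = None
    final_state: "HybridState | None" = None

    @property
    def settled_scheduled(self):
        return [e for e in self.entries if e.scheduled]


# --------------------------------------------------------------------------
# small event utilities
# --------------------------------------------------------------------------

def find_crossing(fun: Callable[[float], float], lo: float, hi: float) -> float:
    """Root-locate a sign change of ``fun`` on [lo, hi] to ~1e-12."""
    return float(brentq(fun, lo, hi, xtol=1e-12, rtol=8.881784197001252e-16))


def detect_events(hs: HybridState, model: BipedModel, gains: GainConfig,
                  cfg: SimConfig = SimConfig(), zeta: ControlParams | None = None,
                  ds_snapshot: DSStartSnapshot | None = None):
    """Which phase-terminating condition holds at the current state.

    Returns 'touchdown' when (in single support) the swing toe is at or
    below the ground with the phase variable past the guard, 'takeoff' when
    (in double support) the trailing-leg vertical contact force is
    non-positive, else None.
    """
    if hs.phase == "ss":
        lm = forward_kinematics(model, hs.gen)
        z_sw = lm.toe(_other(hs.stance_side))[1]
        s = hs.refs.s_of(virtual_leg(model, hs.gen, hs.stance_side).q_v)
        if z_sw <= 0.0 and s > cfg.guard_s:
            return "touchdown"
        return None
    out = outputs_ds(model, hs.gen, zeta, ds_snapshot, cfg.rates,
                     hs.stance_side, hs.t)
    A, b, lamA, lamb = input_affine_dynamics(model, hs.gen, hs.contacts)
    u = feedback_torques(model, hs.gen, hs.contacts, out, gains)
    lam = lamA @ u + lamb
    i = 2 * list(hs.contacts.legs()).index(hs.stance_side) + 1
    if lam[i] <= 0.0:
        return "takeoff"
    return None


# --------------------------------------------------------------------------
# phase integration
# --------------------------------------------------------------------------

def _integrate(rhs, x0, t0, t_max, events, cfg: SimConfig):
    dt = 1.0 / cfg.record_rate
    t_eval = t0 + np.arange(0.0, t_max, dt)
    sol = solve_ivp(rhs, (t0, t0 + t_max), x0, method=cfg.method,
                    rtol=cfg.rtol, atol=cfg.atol, max_step=cfg.max_step,
                    events=events, t_eval=t_eval)
    if not sol.success and sol.status != 1:
        raise SimulationError(f"integration failed: {sol.message}")
    return sol


def _sol_samples(sol):
    """Sample times/states of a phase, with the terminal-event point
    appended (if any)."""
    ts = list(sol.t)
    xs = list(sol.y.T)
    t_end, x_end = None, None
    for te, xe in zip(sol.t_events, sol.y_events):
        if te.size:
            t_end, x_end = float(te[-1]), xe[-1]
    if t_end is not None:
        if not ts or t_end > ts[-1] + 1e-12:
            ts.append(t_end)
            xs.append(x_end)
        else:
            ts[-1], xs[-1] = t_end, x_end
    return np.array(ts), (np.stack(xs) if xs else np.zeros((0, 2 * NQ)))


def _fall_event(model, cfg):
    z_min = cfg.fall_hip_frac * model.L_leg_nominal

    def ev(t, x):
        return x[1] - z_min
    ev.terminal = True
    ev.direction = -1.0
    return ev


def _premise_snapshot(model, state, stance_side, t) -> TakeoffSnapshot:
    st = virtual_leg(model, state, stance_side)
    sw = virtual_leg(model, state, _other(stance_side))
    return TakeoffSnapshot(
        q_stv=st.q_v, qd_stv=st.qd_v, L_stv=st.L_v, Ld_stv=st.Ld_v,
        q_P=state.q[IDX_PEL], qd_P=state.qdot[IDX_PEL],
        q_T=state.q[IDX_TOR], qd_T=state.qdot[IDX_TOR],
        L_st_ankle=st.L_ankle, Ld_st_ankle=st.Ld_ankle,
        L_sw_ankle=sw.L_ankle, Ld_sw_ankle=sw.Ld_ankle,
        asymmetry=st.q_v + sw.q_v, t=t)


def _run_ds(model, hs: HybridState, zeta, gains, cfg):
    """Integrate double support until trailing-leg take-off.

    Returns (state, t, samples, snapshot, ds_ctx)."""
    trailing = hs.stance_side
    contacts = hs.contacts
    snapshot = DSStartSnapshot(
        asymmetry=(virtual_leg(model, hs.gen, trailing).q_v
                   + virtual_leg(model, hs.gen, _other(trailing)).q_v),
        t=hs.t)
    i_lam = 2 * list(contacts.legs()).index(trailing) + 1

    def control(t, state):
        out = outputs_ds(model, state, zeta, snapshot, cfg.rates, trailing, t)
        A, b, lamA, lamb = input_affine_dynamics(model, state, contacts)
        u = feedback_torques(model, state, contacts, out, gains)
        return A @ u + b, lamA @ u + lamb

    def rhs(t, x):
        state = GenCoords(x[:NQ], x[NQ:])
        qdd, _ = control(t, state)
        return np.concatenate([x[NQ:], qdd])

    def ev_takeoff(t, x):
        state = GenCoords(x[:NQ], x[NQ:])
        _, lam = control(t, state)
        return lam[i_lam]
    ev_takeoff.terminal = True
    ev_takeoff.direction = -1.0

    ctx = {"zeta": zeta, "snapshot": snapshot, "rates": cfg.rates,
           "trailing_side": trailing, "contacts": contacts}

    # immediate take-off: the impact already unloaded the trailing leg
    _, lam0 = control(hs.t, hs.gen)
    if lam0[i_lam] <= 0.0:
        return hs.gen, hs.t, (np.array([hs.t]),
                              np.concatenate([hs.gen.q, hs.gen.qdot])[None, :]), ctx

    sol = _integrate(rhs, np.concatenate([hs.gen.q, hs.gen.qdot]), hs.t,
                     cfg.max_ds_time, [ev_takeoff, _fall_event(model, cfg)], cfg)
    ts, xs = _sol_samples(sol)
    if sol.t_events[1].size:
        raise FallError("hip dropped below the fall threshold",
                        step_index=hs.step_index, phase="ds", t=float(sol.t_events[1][0]))
    if not sol.t_events[0].size:
        raise FallError("no take-off within the maximum double-support time",
                        step_index=hs.step_index, phase="ds", t=hs.t)
    x_end = xs[-1]
    return GenCoords(x_end[:NQ], x_end[NQ:]), float(ts[-1]), (ts, xs), ctx


def _run_ss(model, hs_gen, t0, stance_side, contacts, refs, gains, cfg,
            step_index):
    """Integrate single support until swing-toe touchdown.

    Returns (state, t, samples, ss_ctx)."""
    swing_coeffs = None

    def rhs(t, x):
        state = GenCoords(x[:NQ], x[NQ:])
        out = outputs_ss(model, state, refs, stance_side, t)
        A, b, _, _ = input_affine_dynamics(model, state, contacts)
        u = feedback_torques(model, state, contacts, out, gains)
        return np.concatenate([x[NQ:], A @ u + b])

    swing = _other(stance_side)
    toe_coeffs = model.point_coeffs(f"toe_{swing}")

    def z_sw_of(x):
        return model.linkage.point_position(x[:NQ], toe_coeffs)[1]

    def ev_guard(t, x):
        state_q = x[:NQ]
        # phase progress measured through the stance virtual-leg angle
        vl = virtual_leg(model, GenCoords(state_q, x[NQ:]), stance_side)
        return refs.s_of(vl.q_v) - cfg.guard_s
    ev_guard.terminal = True
    ev_guard.direction = 1.0

    def ev_backward(t, x):
        vl = virtual_leg(model, GenCoords(x[:NQ], x[NQ:]), stance_side)
        return refs.s_of(vl.q_v) + 0.15
    ev_backward.terminal = True
    ev_backward.direction = -1.0

    def ev_touchdown(t, x):
        return z_sw_of(x)
    ev_touchdown.terminal = True
    ev_touchdown.direction = -1.0

    fall = _fall_event(model, cfg)
    x0 = np.concatenate([hs_gen.q, hs_gen.qdot])

    # stage 1: up to the guard phase (touchdown event disabled so the
    # just-lifted toe at z ~ 0 cannot retrigger)
    sol1 = sol2 = None
    try:
        if ev_guard(t0, x0) < 0:
            sol1 = _integrate(rhs, x0, t0, cfg.max_ss_time,
                              [ev_guard, fall, ev_backward], cfg)
            if sol1.t_events[1].size:
                raise FallError("hip dropped below the fall threshold",
                                step_index=step_index, phase="ss",
                                t=float(sol1.t_events[1][0]))
            if sol1.t_events[2].size:
                raise FallError("phase variable reversed (fell backwards)",
                                step_index=step_index, phase="ss",
                                t=float(sol1.t_events[2][0]))
            if not sol1.t_events[0].size:
                raise FallError("phase variable stalled before the guard",
                                step_index=step_index, phase="ss", t=t0)
            t1, x1 = float(sol1.t_events[0][0]), sol1.y_events[0][0]
        else:
            t1, x1 = t0, x0

        budget = cfg.max_ss_time - (t1 - t0)
        sol2 = _integrate(rhs, x1, t1, budget,
                          [ev_touchdown, fall, ev_backward], cfg)
    except SimulationError as exc:
        # integrator collapse away from any detected event: the model lost
        # viability (typically a singular crumpled posture) — report as a
        # structured fall, never a raw crash
        raise FallError(f"integration collapsed mid-swing: {exc}",
                        step_index=step_index, phase="ss", t=t0) from exc
    if sol2.t_events[1].size:
        raise FallError("hip dropped below the fall threshold",
                        step_index=step_index, phase="ss",
                        t=float(sol2.t_events[1][0]))
    if sol2.t_events[2].size:
        raise FallError("phase variable reversed (fell backwards)",
                        step_index=step_index, phase="ss",
                        t=float(sol2.t_events[2][0]))
    if not sol2.t_events[0].size:
        raise FallError("no touchdown within the maximum single-support time",
                        step_index=step_index, phase="ss", t=t1)

    parts_t, parts_x = [], []
    if sol1 is not None:
        ts, xs = _sol_samples(sol1)
        parts_t.append(ts[:-1] if ts.size else ts)  # event point repeats in stage 2
        parts_x.append(xs[:-1] if ts.size else xs)
    ts2, xs2 = _sol_samples(sol2)
    parts_t.append(ts2)
    parts_x.append(xs2)
    ts = np.concatenate(parts_t)
    xs = np.vstack(parts_x)
    x_end = xs[-1]
    ctx = {"refs": refs, "stance_side": stance_side, "contacts": contacts}
    return GenCoords(x_end[:NQ], x_end[NQ:]), float(ts[-1]), (ts, xs), ctx


# --------------------------------------------------------------------------
# step driver
# --------------------------------------------------------------------------

def _build_references(model, state, t, stance_side, zeta, target, between,
                      cfg, qd_stv_end_prev, contacts):
    """Touchdown target (from the step-length relation evaluated at
    single-support start) and the refitted premise references."""
    lm = forward_kinematics(model, state)
    x_st = lm.toe(stance_side)[0]
    x_sw = lm.toe(_other(stance_side))[0]
    q_d = touchdown_target(x_st, x_sw, target, model)
    snap = _premise_snapshot(model, state, stance_side, t)
    refs = make_reference_set(zeta, snap, q_d, between.L_dot_stv_end,
                              model.L_leg_nominal, k1=cfg.k1, rates=cfg.rates,
                              qd_stv_end_prev=qd_stv_end_prev)
    return refs, q_d


def simulate_step(hs: HybridState, model: BipedModel, zeta: ControlParams,
                  target: StepTarget, gains: GainConfig,
                  cfg: SimConfig = SimConfig()) -> tuple[HybridState, StepRecord]:
    """Run one full step (double support then single support) from a state
    just after contact; apply the transition maps; update the between-step
    controller with the measured gait velocity."""
    if hs.phase != "ds":
        raise ValueError("simulate_step expects a state at a step boundary (double support)")
    t_start = hs.t
    hip_x_start = hs.gen.q[0]

    try:
        gen, t, ds_samples, ds_ctx = _run_ds(model, hs, zeta, gains, cfg)

        # take-off: trailing leg lifts, roles swap
        gen, contacts = takeoff_map(gen, hs.contacts, hs.stance_side)
        stance = _other(hs.stance_side)

        refs, q_d = _build_references(model, gen, t, stance, zeta, target,
                                      hs.between, cfg, hs.qd_stv_end_prev,
                                      contacts)
        gen, t, ss_samples, ss_ctx = _run_ss(model, gen, t, stance, contacts,
                                             refs, gains, cfg, hs.step_index)
    except FallError:
        raise
    except Exception as exc:
        raise SimulationError(
            f"step {hs.step_index} failed in flight: {exc}") from exc

    # touchdown: plastic impact with the union of contacts
    vl_end = virtual_leg(model, gen, stance)
    lm = forward_kinematics(model, gen)
    swing = _other(stance)
    toe = lm.toe(swing)
    new_contact = Contact(leg=swing, anchor=(float(toe[0]), float(toe[1])))
    union = contacts.with_contact(new_contact)
    imp = impact_map(model, gen, union)
    gen_plus = GenCoords(gen.q, imp.qdot_plus)

    duration = t - t_start
    hip_travel = gen.q[0] - hip_x_start
    v_gait = hip_travel / duration
    between = between_step_update(hs.between, v_gait, target, gains)

    stance_anchor = next(c for c in contacts.contacts if c.leg == stance).anchor

    ts = np.concatenate([ds_samples[0], ss_samples[0]])
    xs = np.vstack([ds_samples[1], ss_samples[1]])
    flags = np.concatenate([np.zeros(ds_samples[0].size, dtype=int),
                            np.ones(ss_samples[0].size, dtype=int)])

    record = StepRecord(
        step_index=hs.step_index, stance_side=stance,
        t=ts, q=xs[:, :NQ], qdot=xs[:, NQ:], phase_flags=flags,
        t_start=t_start, t_takeoff=float(ss_samples[0][0]), t_contact=t,
        v_gait=v_gait, step_length=hip_travel,
        contact_separation=float(new_contact.anchor[0] - stance_anchor[0]),
        q_stv_d=q_d, q_stv_at_contact=vl_end.q_v,
        z_sw_at_contact=float(toe[1]),
        L_dot_stv_end=hs.between.L_dot_stv_end,
        _ds_ctx=ds_ctx, _ss_ctx=ss_ctx)

    hs_next = HybridState(
        gen=gen_plus, t=t, phase="ds", stance_side=stance, contacts=union,
        step_index=hs.step_index + 1, refs=refs, between=between,
        qd_stv_end_prev=vl_end.qd_v)
    return hs_next, record


# --------------------------------------------------------------------------
# initial condition
# --------------------------------------------------------------------------

def _leg_angles(model, side, toe, hip, L_ankle):
    """Absolute segment angles placing the leg with the given toe/hip
    positions and ankle component (heel behind the virtual-leg axis, knee
    flexed forward)."""
    lth = model.segments[f"{side[0]}_thigh"].length
    lsh = model.segments[f"{side[0]}_shank"].length
    lft = model.segments[f"{side[0]}_foot"].length
    d = hip - toe
    L = float(np.hypot(*d))
    u = d / L
    n = np.array([-u[1], u[0]])                   # heel-side normal (backward)
    perp = math.sqrt(max(lft ** 2 - L_ankle ** 2, 0.0))
    ankle = toe + L_ankle * u + perp * n
    # knee: circles of radius lsh (about ankle) and lth (about hip)
    v = hip - ankle
    dah = float(np.hypot(*v))
    if dah > lth + lsh or dah < abs(lth - lsh):
        raise ValueError("requested posture outside the leg workspace")
    a = (lsh ** 2 - lth ** 2 + dah ** 2) / (2 * dah)
    h = math.sqrt(max(lsh ** 2 - a ** 2, 0.0))
    base = ankle + a * v / dah
    nperp = np.array([-v[1], v[0]]) / dah
    k1p = base + h * nperp
    k2p = base - h * nperp
    knee = k1p if k1p[0] >= k2p[0] else k2p       # knee flexes forward (+x)

    def ang_down(vec):
        # e = (sin, -cos) -> theta = atan2(x, -z)
        return math.atan2(vec[0], -vec[1])

    th = ang_down((knee - hip) / lth)
    sh = ang_down((ankle - knee) / lsh)
    ft = ang_down((toe - ankle) / lft)
    return th, sh, ft


def static_start(model: BipedModel, zeta: ControlParams, target: StepTarget,
                 gains: GainConfig, cfg: SimConfig = SimConfig(),
                 v0: float | None = None, side: str = "left") -> HybridState:
    """Documented start routine: the model is posed at a single-support
    start (stance toe planted, swing toe on the ground behind, both legs at
    the nominal splay), with joint rates solved so the stance toe is
    stationary and the hip advances at the configured forward speed.  The
    first steps are transient and excluded from settle checks."""
    from .dynamics import (IDX_LFT, IDX_LSH, IDX_LTH, IDX_RFT, IDX_RSH,
                           IDX_RTH)
    v0 = target.v_gait_d if v0 is None else v0
    L_step = target.L_step_d / 2.0               # steady-state toe separation
    q_d0 = math.asin(L_step / (2.0 * model.L_leg_nominal))
    L0 = zeta.L_stv_mid
    toe_st = np.array([0.0, 0.0])
    hip = toe_st + L0 * np.array([math.sin(-q_d0), math.cos(-q_d0)])
    toe_sw = hip - L0 * np.array([math.sin(q_d0), math.cos(q_d0)])

    swing = _other(side)
    idx = {"left": (IDX_LTH, IDX_LSH, IDX_LFT),
           "right": (IDX_RTH, IDX_RSH, IDX_RFT)}
    q = np.zeros(NQ)
    q[0], q[1] = hip
    q[list(idx[side])] = _leg_angles(model, side, toe_st, hip, zeta.L_st_ankle_mid)
    q[list(idx[swing])] = _leg_angles(model, swing, toe_sw, hip, zeta.L_sw_ankle_mid)
    q[IDX_PEL] = zeta.q_P_mid
    q[IDX_TOR] = zeta.q_T_mid

    # rates: stance toe pinned, hip at (v0, 0), swing toe level, symmetric
    # virtual-leg rates (the symmetry output starts at rest); minimal
    # squared joint rates otherwise
    from .geometry import virtual_leg_quants
    Jst = model.linkage.point_jacobian(q, model.point_coeffs(f"toe_{side}"))
    Jsw = model.linkage.point_jacobian(q, model.point_coeffs(f"toe_{swing}"))
    Jhip = np.zeros((2, NQ))
    Jhip[0, 0] = Jhip[1, 1] = 1.0
    _, qv_st, _ = virtual_leg_quants(model, q, np.zeros(NQ), side)
    _, qv_sw, _ = virtual_leg_quants(model, q, np.zeros(NQ), swing)
    E = np.vstack([Jst, Jhip, Jsw[1:2], (qv_st.g + qv_sw.g)[None, :]])
    e = np.array([0.0, 0.0, v0, 0.0, 0.0, 0.0])
    W = np.eye(NQ)
    W[0, 0] = W[1, 1] = 0.0                       # hip rates are pinned anyway
    K = np.block([[W, E.T], [E, np.zeros((E.shape[0], E.shape[0]))]])
    rhs = np.concatenate([np.zeros(NQ), e])
    sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    qdot = sol[:NQ]
    gen = GenCoords(q, qdot)

    contacts = ContactSet((Contact(leg=side, anchor=(0.0, 0.0)),))
    hs = HybridState(gen=gen, t=0.0, phase="ss", stance_side=side,
                     contacts=contacts, step_index=0)
    refs, q_d = _build_references(model, gen, 0.0, side, zeta, target,
                                  hs.between, cfg, None, contacts)
    return replace(hs, refs=refs)


def _first_partial_step(hs, model, zeta, target, gains, cfg):
    """Single-support-only segment from the static start to first contact."""
    gen, t, ss_samples, ss_ctx = _run_ss(model, hs.gen, hs.t, hs.stance_side,
                                         hs.contacts, hs.refs, gains, cfg,
                                         hs.step_index)
    vl_end = virtual_leg(model, gen, hs.stance_side)
    lm = forward_kinematics(model, gen)
    swing = _other(hs.stance_side)
    toe = lm.toe(swing)
    new_contact = Contact(leg=swing, anchor=(float(toe[0]), float(toe[1])))
    union = hs.contacts.with_contact(new_contact)
    imp = impact_map(model, gen, union)
    gen_plus = GenCoords(gen.q, imp.qdot_plus)
    duration = t - hs.t
    v_gait = (gen.q[0] - hs.gen.q[0]) / duration
    between = between_step_update(hs.between, v_gait, target, gains)
    record = StepRecord(
        step_index=hs.step_index, stance_side=hs.stance_side,
        t=ss_samples[0], q=ss_samples[1][:, :NQ], qdot=ss_samples[1][:, NQ:],
        phase_flags=np.ones(ss_samples[0].size, dtype=int),
        t_start=hs.t, t_takeoff=hs.t, t_contact=t, v_gait=v_gait,
        step_length=gen.q[0] - hs.gen.q[0],
        contact_separation=float(new_contact.anchor[0]
                                 - hs.contacts.contacts[0].anchor[0]),
        q_stv_d=hs.refs.q_end, q_stv_at_contact=vl_end.q_v,
        z_sw_at_contact=float(toe[1]),
        L_dot_stv_end=hs.between.L_dot_stv_end,
        _ds_ctx=None, _ss_ctx=ss_ctx)
    hs_next = HybridState(
        gen=gen_plus, t=t, phase="ds", stance_side=hs.stance_side,
        contacts=union, step_index=hs.step_index + 1, refs=hs.refs,
        between=between, qd_stv_end_prev=vl_end.qd_v)
    return hs_next, record


# --------------------------------------------------------------------------
# walking drivers
# --------------------------------------------------------------------------

def stability_stat(velocities: Sequence[float], N: int) -> float | None:
    """Sample standard deviation (divisor N-1) of the last N step
    velocities; None while fewer than N steps are available."""
    if len(velocities) < N:
        return None
    return float(np.std(np.asarray(velocities, dtype=float)[-N:], ddof=1))


def walk(model: BipedModel, zeta: ControlParams, target: StepTarget,
         gains: GainConfig, cfg: SimConfig = SimConfig(),
         n_steps: int = 10, initial: HybridState | None = None,
         keep_last: int | None = None):
    """Walk ``n_steps`` steps under a fixed parameter set.

    Returns (final HybridState, [StepRecord...]).  ``keep_last`` limits how
    many records retain their full time series (older series are dropped to
    bound memory)."""
    records = []
    if initial is None:
        hs = static_start(model, zeta, target, gains, cfg)
        hs, rec = _first_partial_step(hs, model, zeta, target, gains, cfg)
        records.append(rec)
    else:
        hs = initial
    while len(records) < n_steps:
        hs, rec = simulate_step(hs, model, zeta, target, gains, cfg)
        records.append(rec)
        if keep_last is not None and len(records) > keep_last:
            records[-keep_last - 1].drop_series()
    return hs, records


def _walk_until_settled(hs, model, zeta, target, gains, cfg, velocity_log):
    """Walk under ``zeta`` until sigma_N < eps or the step budget runs out.

    Returns (hs, settled, sigma, records ring of last 3, velocities)."""
    vels = []
    ring = []
    settled, sigma = False, None
    for _ in range(cfg.max_steps_per_zeta):
        hs, rec = simulate_step(hs, model, zeta, target, gains, cfg)
        vels.append(rec.v_gait)
        velocity_log.append(rec.v_gait)
        ring.append(rec)
        if len(ring) > 3:
            ring.pop(0).drop_series()
        sigma = stability_stat(vels, cfg.N)
        if sigma is not None and sigma < cfg.epsilon:
            settled = True
            break
    return hs, settled, sigma, ring, vels


def run_schedule(model: BipedModel, schedule: Sequence[ControlParams],
                 target: StepTarget, gains: GainConfig,
                 cfg: SimConfig = SimConfig(),
                 initial: HybridState | None = None) -> ScheduleResult:
    """Execute an ordered zeta schedule.

    Every change between consecutive scheduled sets is split into
    ``cfg.m_interp`` equal increments; the model walks to the velocity-
    settle criterion at every intermediate and scheduled set (the gradual,
    destabilization-free transition regime).  For each *scheduled* set the
    settled two-step gait is captured with full time series.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    velocity_log: list = []
    entries: list = []
    total = 0

    if initial is None:
        hs = static_start(model, schedule[0], target, gains, cfg)
        hs, rec0 = _first_partial_step(hs, model, schedule[0], target, gains, cfg)
        rec0.drop_series()
        total += 1
    else:
        hs = initial

    # expand the schedule into (zeta, scheduled?) stops
    stops: list = [(schedule[0], True)]
    for prev, nxt in zip(schedule[:-1], schedule[1:]):
        for j in range(1, cfg.m_interp + 1):
            alpha = j / cfg.m_interp
            stops.append((prev.interpolate(nxt, alpha), j == cfg.m_interp))

    for zeta, scheduled in stops:
        try:
            hs, settled, sigma, ring, vels = _walk_until_settled(
                hs, model, zeta, target, gains, cfg, velocity_log)
        except FallError as exc:
            entries.append(ScheduleEntry(zeta=zeta, scheduled=scheduled,
                                         settled=False, steps_taken=0,
                                         sigma=None, velocities=[], records=None))
            return ScheduleResult(entries=entries, total_steps=total,
                                  velocity_log=velocity_log,
                                  fall={"step_index": exc.step_index,
                                        "phase": exc.phase, "t": exc.t,
                                        "message": str(exc)},
                                  final_state=hs)
        total += len(vels)
        records = tuple(ring[-2:]) if settled and len(ring) >= 2 else None
        if not scheduled and records:
            for r in records:
                r.drop_series()
            records = None
        entries.append(ScheduleEntry(zeta=zeta, scheduled=scheduled,
                                     settled=settled, steps_taken=len(vels),
                                     sigma=sigma, velocities=vels,
                                     records=records))
        if not settled and cfg.abort_on_no_settle:
            break
    return ScheduleResult(entries=entries, total_steps=total,
                          velocity_log=velocity_log, final_state=hs)
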