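"""Two-level control: within-step feedback linearization and the
between-step adaptive push-off law.

Within a step the walking premises are encoded as output vectors — seven
rows in single support (symmetry, swing-foot clearance, stance-leg length,
pelvis, torso, and the two ankle components), six in double support (the
clearance row is dropped; both feet are on the ground) — and driven to zero
by input-output feedback linearization:

    u_ss = -(Lg Lf h)^-1 (Lf^2 h + K_D Lf h + K_P h)        (7x7 inverse)
    u_ds = -(Lg Lf h)^+  (Lf^2 h + K_D Lf h + K_P h)        (6x7 pseudoinverse)

so the closed loop satisfies ydd = -K_D yd - K_P y.  The Lie-derivative
terms are assembled exactly from the output Jacobian J, the velocity-product
bias c (ydd = J qdd + c) and the input-affine constrained dynamics
qdd = A u + b:  Lg Lf h = J A and Lf^2 h = J b + c.

Between steps, the stance-leg lengthening velocity at single-support end
(the push-off proxy) is adapted once per step from the measured gait
velocity: walking slower than desired strengthens the next push-off.

The touchdown target couples desired gait velocity and cadence to the
virtual stance-leg angle at single-support end: the desired swing-toe
travel (stride) 2 v_d / cad_d must equal the current toe separation plus
2 L_leg,nominal sin(q_st,v,d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import (IDX_PEL, IDX_TOR, BipedModel, ContactSet, GenCoords,
                       input_affine_dynamics)
from .geometry import KinQuants, Quant, virtual_leg_quants
from .references import (ControlParams, ReferenceSet, WeightRates,
                         clearance_bump)


class ControllabilityError(RuntimeError):
    """The decoupling matrix is ill-conditioned: the outputs cannot be
    decoupled at this posture."""


class InfeasibleStepError(ValueError):
    """The requested step length is outside the reachable arcsin range."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GainConfig:
    """Within-step PD gains (diagonal, positive) and between-step gains.

    Defaults follow a critically damped second-order error dynamics with
    natural frequency omega: K_P = omega^2 I, K_D = 2 omega I.
    """
    K_P_ss: np.ndarray
    K_D_ss: np.ndarray
    K_P_ds: np.ndarray
    K_D_ds: np.ndarray
    k_p: float = 0.2
    k_d: float = 0.05
    cond_limit: float = 1e10

    def __post_init__(self):
        for name in ("K_P_ss", "K_D_ss", "K_P_ds", "K_D_ds"):
            K = getattr(self, name)
            if np.any(np.diag(K) <= 0):
                raise ValueError(f"{name} diagonal entries must be > 0")
        if self.k_p <= 0 or self.k_d < 0:
            raise ValueError("between-step gains must be positive")

    @classmethod
    def from_omega(cls, omega_ss: float = 20.0, omega_ds: float = 0.5,
                   k_p: float = 0.2, k_d: float = 0.05) -> "GainConfig":
        """Critically damped error dynamics per phase.  The double-support
        bandwidth defaults softer than single support: the velocity jump of
        the plastic impact leaves the double-support outputs with a rate
        error, and correcting it on a time scale shorter than the
        double-support phase itself would rip the trailing foot off the
        ground instantly."""
        return cls(K_P_ss=omega_ss ** 2 * np.eye(7),
                   K_D_ss=2 * omega_ss * np.eye(7),
                   K_P_ds=omega_ds ** 2 * np.eye(6),
                   K_D_ds=2 * omega_ds * np.eye(6),
                   k_p=k_p, k_d=k_d)


@dataclass(frozen=True)
class StepTarget:
    """Desired gait velocity [m/s], cadence [steps/s] and the derived
    stride (swing-toe travel) and per-step touchdown target."""
    v_gait_d: float = 1.0
    cad_gait_d: float = 2.2
    q_stv_d: float | None = None

    @property
    def L_step_d(self) -> float:
        """Desired swing-toe travel per swing: 2 v_d / cad_d [m]."""
        return 2.0 * self.v_gait_d / self.cad_gait_d


@dataclass(frozen=True)
class BetweenStepState:
    """Adaptive push-off state: current stance-leg end-lengthening velocity
    [m/s] and the last two measured step velocities."""
    L_dot_stv_end: float = 0.0
    v_hist: tuple = ()


@dataclass(frozen=True)
class OutputVector:
    """Premise outputs with the exact terms the linearizing law needs:
    ydd = J qdd + c along the constrained flow."""
    y: np.ndarray
    ydot: np.ndarray
    J: np.ndarray
    c: np.ndarray
    phase: str

    def __post_init__(self):
        n = {"ss": 7, "ds": 6}[self.phase]
        assert self.y.shape == (n,)


@dataclass(frozen=True)
class DSStartSnapshot:
    """Values anchored at the double-support start."""
    asymmetry: float
    t: float


# --------------------------------------------------------------------------
# output construction
# --------------------------------------------------------------------------

def _weight_quant(rate: float, dt: float) -> Quant:
    w = math.exp(-rate * dt)
    return Quant(w, -rate * w, None, rate * rate * w)


def _bump(s: Quant) -> Quant:
    """Clearance bump with a transversal descent at s = 1."""
    b, bp, bpp = clearance_bump(s.v)
    return s.apply(b, bp, bpp)


def _poly_quant(poly, s: Quant) -> Quant:
    return s.apply(poly.eval(s.v), poly.deriv(s.v), poly.second(s.v))


def _stack(rows: list[Quant], phase: str) -> OutputVector:
    return OutputVector(
        y=np.array([r.v for r in rows]),
        ydot=np.array([r.d for r in rows]),
        J=np.stack([r.g for r in rows]),
        c=np.array([r.c for r in rows]),
        phase=phase,
    )


def outputs_ss(model: BipedModel, state: GenCoords, refs: ReferenceSet,
               stance_side: str, t: float) -> OutputVector:
    """Single-support output vector (row order fixed):

    0. symmetry        q_st,v + q_sw,v - (q_st,v + q_sw,v)|takeoff * w_ss,1
    1. clearance       z_sw - k1 L_leg,nominal b(s)
    2. stance length   L_st,v - L_st,v,d(q_st,v)
    3. pelvis          q_P - q_P,d(q_st,v)
    4. torso           q_T - q_T,d(q_st,v)
    5. stance ankle    L_st,ankle - L_st,ankle,d(q_st,v)
    6. swing ankle     L_sw,ankle - L_sw,ankle,d(q_st,v)
    """
    swing_side = "right" if stance_side == "left" else "left"
    kin = KinQuants(model, state.q, state.qdot)
    L_st, qv_st, La_st = virtual_leg_quants(model, state.q, state.qdot,
                                            stance_side, kin)
    L_sw, qv_sw, La_sw = virtual_leg_quants(model, state.q, state.qdot,
                                            swing_side, kin)
    _, z_sw = kin.landmark(f"toe_{swing_side}")

    dt = max(t - refs.t_ss_start, 0.0)
    w1 = _weight_quant(refs.rates.w_ss[0], dt)
    s = (qv_st - refs.q_start) * (1.0 / (refs.q_end - refs.q_start))

    rows = [
        qv_st + qv_sw - refs.asymmetry0 * w1,
        z_sw - refs.k1 * refs.L_leg_nominal * _bump(s),
        L_st - _poly_quant(refs.L_stv, s),
        kin.angle(IDX_PEL) - _poly_quant(refs.q_P, s),
        kin.angle(IDX_TOR) - _poly_quant(refs.q_T, s),
        La_st - _poly_quant(refs.L_st_ankle, s),
        La_sw - _poly_quant(refs.L_sw_ankle, s),
    ]
    return _stack(rows, "ss")


def outputs_ds(model: BipedModel, state: GenCoords, zeta: ControlParams,
               snapshot: DSStartSnapshot, rates: WeightRates,
               trailing_side: str, t: float) -> OutputVector:
    """Double-support output vector: each premise relaxes exponentially
    from its double-support-start anchor (row order fixed):

    0. symmetry        q_st,v + q_sw,v - (q_st,v + q_sw,v)|ds,start * w_ds,1
    1. stance length   L_st,v - L_st,v,end * w_ds,2
    2. pelvis          q_P - q_P,end * w_ds,3
    3. torso           q_T - q_T,end * w_ds,4
    4. stance ankle    L_st,ankle - L_st,ankle,end * w_ds,5
    5. swing ankle     L_sw,ankle - L_sw,ankle,end * w_ds,6

    In double support the "stance" leg is the trailing leg (the stance leg
    of the single-support phase that just ended); the "swing" leg is the
    leading leg that has just touched down.
    """
    leading_side = "right" if trailing_side == "left" else "left"
    kin = KinQuants(model, state.q, state.qdot)
    L_st, qv_st, La_st = virtual_leg_quants(model, state.q, state.qdot,
                                            trailing_side, kin)
    L_sw, qv_sw, La_sw = virtual_leg_quants(model, state.q, state.qdot,
                                            leading_side, kin)
    dt = max(t - snapshot.t, 0.0)
    w = [_weight_quant(r, dt) for r in rates.w_ds]
    rows = [
        qv_st + qv_sw - snapshot.asymmetry * w[0],
        L_st - zeta.L_stv_end * w[1],
        kin.angle(IDX_PEL) - zeta.q_P_end * w[2],
        kin.angle(IDX_TOR) - zeta.q_T_end * w[3],
        La_st - zeta.L_st_ankle_end * w[4],
        La_sw - zeta.L_sw_ankle_end * w[5],
    ]
    return _stack(rows, "ds")


# --------------------------------------------------------------------------
# feedback linearization
# --------------------------------------------------------------------------

def feedback_torques(model: BipedModel, state: GenCoords, contacts: ContactSet,
                     outputs: OutputVector, gains: GainConfig) -> np.ndarray:
    """Joint torques imposing ydd = -K_D yd - K_P y on the premise outputs.

    Single support: the 7x7 decoupling matrix is inverted exactly.  Double
    support: only six outputs constrain seven torques; the Moore-Penrose
    pseudoinverse picks the minimum-norm torque vector.
    """
    A, b, _, _ = input_affine_dynamics(model, state, contacts)
    D = outputs.J @ A
    if outputs.phase == "ss":
        KP, KD = gains.K_P_ss, gains.K_D_ss
    else:
        KP, KD = gains.K_P_ds, gains.K_D_ds
    rhs = -(outputs.J @ b + outputs.c + KD @ outputs.ydot + KP @ outputs.y)
    sv = np.linalg.svd(D, compute_uv=False)
    if sv[0] / max(sv[-1], 1e-300) > gains.cond_limit:
        raise ControllabilityError(
            f"decoupling matrix ill-conditioned in {outputs.phase} "
            f"(cond ~ {sv[0] / max(sv[-1], 1e-300):.2e})")
    if outputs.phase == "ss":
        return np.linalg.solve(D, rhs)
    u, *_ = np.linalg.lstsq(D, rhs, rcond=None)
    return u


# --------------------------------------------------------------------------
# touchdown target and between-step law
# --------------------------------------------------------------------------

def touchdown_target(x_st: float, x_sw: float, target: StepTarget,
                     model: BipedModel) -> float:
    """Desired virtual stance-leg angle at single-support end.

    Solves  L_step,d = (x_st - x_sw) + 2 L_leg,nominal sin(q_st,v,d)
    for q_st,v,d, where x_st, x_sw are the toe positions at single-support
    start and L_step,d = 2 v_d / cad_d is the desired swing-toe travel.
    """
    ratio = (target.L_step_d - (x_st - x_sw)) / (2.0 * model.L_leg_nominal)
    if abs(ratio) > 1.0:
        raise InfeasibleStepError(
            f"step-length residual ratio {ratio:.3f} outside [-1, 1]")
    return math.asin(ratio)


def between_step_update(bss: BetweenStepState, v_measured: float,
                        target: StepTarget, gains: GainConfig) -> BetweenStepState:
    """Once-per-step adaptation of the push-off proxy.

    L_dot^k = L_dot^{k-1} + k_p (v_d - v^{k-1}) + k_d (v^{k-2} - v^{k-1}):
    walking slower than desired raises the stance-leg end-lengthening
    velocity (stronger push-off); the derivative term damps step-to-step
    velocity oscillation.  On the first completed step the derivative term
    is inactive.
    """
    v_prev = bss.v_hist[-1] if bss.v_hist else v_measured
    L_dot = (bss.L_dot_stv_end
             + gains.k_p * (target.v_gait_d - v_measured)
             + gains.k_d * (v_prev - v_measured))
    hist = (bss.v_hist + (v_measured,))[-2:]
    return BetweenStepState(L_dot_stv_end=L_dot, v_hist=hist)
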