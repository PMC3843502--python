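"""Virtual-leg kinematics and landmark forward kinematics.

The *virtual leg* is the line from a foot's toe tip to the hip joint.  Its
length ``L_v`` decomposes into an ankle component (scalar projection of the
toe->ankle vector onto the virtual-leg axis) and a knee component
(``L_knee = L_v - L_ankle``); the two sum to ``L_v`` by construction.

Sign convention (used consistently everywhere): the virtual-leg angle is

    q_v = atan2(x_hip - x_toe, z_hip - z_toe)

i.e. the signed angle of the toe->hip vector from the world vertical,
POSITIVE when the hip is ahead of (in front of) the toe.  During a nominal
stance phase q_st,v therefore increases monotonically from a negative value
at touchdown (toe ahead of the hip) through zero to the positive touchdown
target at single-support end — which is what qualifies it as the phase
variable.

This module also provides :class:`Quant`, a small second-order forward-mode
differential type: each quantity carries its value, time-derivative,
gradient w.r.t. q, and the velocity-product acceleration bias ``c`` such
that ``ydd = grad . qdd + c`` along the flow.  The within-step controller
builds its outputs from Quants, so output Jacobians and L_f^2-type bias
terms are exact (no numerical differentiation in the loop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import NQ, BipedModel, GenCoords


class DegeneratePostureError(ValueError):
    """The toe coincides with the hip: the virtual leg is undefined."""


# --------------------------------------------------------------------------
# second-order forward-mode differentials
# --------------------------------------------------------------------------

class Quant:
    """Scalar quantity with value ``v``, time-derivative ``d``, gradient
    ``g`` (w.r.t. q) and acceleration bias ``c``: ydd = g @ qdd + c.

    Explicitly time-dependent scalars (e.g. exponential weights) are
    represented with g = 0 and c = their full second time-derivative.
    """

    __slots__ = ("v", "d", "g", "c")

    def __init__(self, v, d=0.0, g=None, c=0.0):
        self.v = float(v)
        self.d = float(d)
        self.g = np.zeros(NQ) if g is None else g
        self.c = float(c)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, o):
        if isinstance(o, Quant):
            return Quant(self.v + o.v, self.d + o.d, self.g + o.g, self.c + o.c)
        return Quant(self.v + o, self.d, self.g, self.c)

    __radd__ = __add__

    def __neg__(self):
        return Quant(-self.v, -self.d, -self.g, -self.c)

    def __sub__(self, o):
        if isinstance(o, Quant):
            return Quant(self.v - o.v, self.d - o.d, self.g - o.g, self.c - o.c)
        return Quant(self.v - o, self.d, self.g, self.c)

    def __rsub__(self, o):
        return (-self) + o

    def __mul__(self, o):
        if isinstance(o, Quant):
            return Quant(self.v * o.v,
                         self.d * o.v + self.v * o.d,
                         self.g * o.v + o.g * self.v,
                         self.c * o.v + o.c * self.v + 2.0 * self.d * o.d)
        return Quant(self.v * o, self.d * o, self.g * o, self.c * o)

    __rmul__ = __mul__

    def __truediv__(self, o):
        if isinstance(o, Quant):
            return self * o.reciprocal()
        return self * (1.0 / o)

    def reciprocal(self):
        inv = 1.0 / self.v
        return self.apply(inv, -inv * inv, 2.0 * inv ** 3)

    def apply(self, f, fp, fpp):
        """Chain rule for y = f(self) given f, f', f'' at self.v."""
        return Quant(f, fp * self.d, fp * self.g, fp * self.c + fpp * self.d ** 2)

    def sqrt(self):
        r = math.sqrt(self.v)
        return self.apply(r, 0.5 / r, -0.25 / r ** 3)

    def sin(self):
        s, c = math.sin(self.v), math.cos(self.v)
        return self.apply(s, c, -s)

    def cos(self):
        s, c = math.sin(self.v), math.cos(self.v)
        return self.apply(c, -s, -c)


def quant_atan2(a: Quant, b: Quant) -> Quant:
    """atan2(a, b) of two Quants (angle of the vector (b, a) from the b-axis)."""
    r2 = a.v * a.v + b.v * b.v
    if r2 == 0.0:
        raise DegeneratePostureError("atan2 of zero vector")
    val = math.atan2(a.v, b.v)
    N = b.v * a.d - a.v * b.d
    d = N / r2
    g = (b.v * a.g - a.v * b.g) / r2
    r2dot = 2.0 * (a.v * a.d + b.v * b.d)
    c = (b.v * a.c - a.v * b.c) / r2 - N * r2dot / r2 ** 2
    return Quant(val, d, g, c)


def coordinate_quant(q: np.ndarray, qdot: np.ndarray, idx: int) -> Quant:
    g = np.zeros(NQ)
    g[idx] = 1.0
    return Quant(q[idx], qdot[idx], g, 0.0)


class KinQuants:
    """Per-state cache of the trigonometric Quants of every segment angle,
    from which landmark-point Quants are cheap linear combinations."""

    def __init__(self, model: BipedModel, q: np.ndarray, qdot: np.ndarray):
        self.model = model
        self.q = q
        self.qdot = qdot
        sigma = model.sigma
        theta = q[2:]
        thetad = qdot[2:]
        n = theta.size
        # e_j = sigma (sin, -cos); build x/z component quants per angle
        self._ex = []
        self._ez = []
        for j in range(n):
            s, c = math.sin(theta[j]), math.cos(theta[j])
            td = thetad[j]
            g = np.zeros(NQ)
            g[2 + j] = 1.0
            sg = sigma[j]
            # x = sg*sin(theta_j)
            self._ex.append(Quant(sg * s, sg * c * td, sg * c * g, -sg * s * td * td))
            # z = -sg*cos(theta_j)
            self._ez.append(Quant(-sg * c, sg * s * td, sg * s * g, sg * c * td * td))
        self.rx = coordinate_quant(q, qdot, 0)
        self.rz = coordinate_quant(q, qdot, 1)

    def point(self, coeffs: np.ndarray) -> tuple[Quant, Quant]:
        """World position (x, z) of the point with chain coefficients."""
        nz = np.nonzero(coeffs)[0]
        x, z = self.rx, self.rz
        for j in nz:
            x = x + coeffs[j] * self._ex[j]
            z = z + coeffs[j] * self._ez[j]
        return x, z

    def landmark(self, name: str) -> tuple[Quant, Quant]:
        return self.point(self.model.point_coeffs(name))

    def angle(self, idx: int) -> Quant:
        return coordinate_quant(self.q, self.qdot, idx)


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

_LANDMARK_NAMES = ("hip", "knee_left", "ankle_left", "toe_left",
                   "knee_right", "ankle_right", "toe_right",
                   "pelvis_com", "torso_com")


@dataclass(frozen=True)
class Landmarks:
    """World positions [m] of the biped landmarks."""
    positions: dict

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]

    def toe(self, side: str) -> np.ndarray:
        return self.positions[f"toe_{side}"]

    def ankle(self, side: str) -> np.ndarray:
        return self.positions[f"ankle_{side}"]

    def knee(self, side: str) -> np.ndarray:
        return self.positions[f"knee_{side}"]

    @property
    def hip(self) -> np.ndarray:
        return self.positions["hip"]


def forward_kinematics(model: BipedModel, state: GenCoords) -> Landmarks:
    """Exact chain composition of every landmark position."""
    pos = {name: model.linkage.point_position(state.q, model.point_coeffs(name))
           for name in _LANDMARK_NAMES}
    return Landmarks(positions=pos)


# --------------------------------------------------------------------------
# virtual leg
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualLeg:
    """Virtual leg of one side with analytic time-derivatives."""
    side: str
    L_v: float
    q_v: float
    L_ankle: float
    L_knee: float
    Ld_v: float
    qd_v: float
    Ld_ankle: float


def virtual_leg_quants(model: BipedModel, q: np.ndarray, qdot: np.ndarray,
                       side: str, kin: KinQuants | None = None):
    """Quants (L_v, q_v, L_ankle) of one side's virtual leg."""
    kin = kin or KinQuants(model, q, qdot)
    tx, tz = kin.landmark(f"toe_{side}")
    ax, az = kin.landmark(f"ankle_{side}")
    hx, hz = kin.rx, kin.rz
    dx = hx - tx
    dz = hz - tz
    L2 = dx * dx + dz * dz
    if L2.v < 1e-16:
        raise DegeneratePostureError(f"virtual {side} leg has zero length")
    L = L2.sqrt()
    qv = quant_atan2(dx, dz)
    # ankle component: projection of toe->ankle onto the unit toe->hip axis
    fx = ax - tx
    fz = az - tz
    L_ankle = (fx * dx + fz * dz) / L
    return L, qv, L_ankle


def virtual_leg(model: BipedModel, state: GenCoords, side: str) -> VirtualLeg:
    """Virtual-leg length, angle and ankle/knee components with their
    analytic time-derivatives."""
    L, qv, La = virtual_leg_quants(model, state.q, state.qdot, side)
    return VirtualLeg(side=side, L_v=L.v, q_v=qv.v, L_ankle=La.v,
                      L_knee=L.v - La.v, Ld_v=L.d, qd_v=qv.d, Ld_ankle=La.d)
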