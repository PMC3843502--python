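"""Walking-premise reference generator.

During single support the five premise references — virtual stance-leg
length, pelvis angle, torso angle, and the ankle components of the stance
and swing virtual legs — are fourth-order polynomials indexed by the phase
variable q_st,v (not by time).  A quartic is pinned by five conditions:
value and slope at the phase start (taken from the state at the preceding
take-off, so position and velocity are continuous), a user value at
mid-phase (s = 0.5), and a user value and slope at the phase end.  The 14
user parameters form the control-parameter set zeta; the end slope of the
stance-leg length polynomial is NOT user-set — the between-step controller
adapts it to regulate gait velocity.

Swing-foot clearance is prescribed as z_sw,d(s) = k1 * L_leg,nominal * b(s)
with b(s) = 16 s^2 (1-s)^2 + gamma s^2 (1-s): a unit-order bump that is
zero with zero slope at s = 0 (the toe leaves the ground smoothly), zero
at s = 1, and has slope -gamma at s = 1 so the swing toe crosses the
ground *transversally* exactly when the phase variable reaches its
touchdown target.  A pure symmetric bump would graze the ground with zero
vertical velocity, which neither a crossing detector nor a plastic impact
can handle robustly; the small descent rate (default gamma = 1, i.e. a
touchdown speed of k1 L_leg,nominal times the phase rate) makes touchdown
well-posed.

Exponential weights w(t) = exp(-rate * t) relax the remaining outputs:
fast ones remove the post-take-off asymmetry in single support, slow ones
let the double-support posture creep away from its anchors during the
(short) double-support phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml


class PhaseRateError(ValueError):
    """Phase rate too small to convert time-slopes to phase-slopes."""


# --------------------------------------------------------------------------
# quartic polynomials over normalized phase
# --------------------------------------------------------------------------

# condition matrix for [p(0), p'(0), p(0.5), p(1), p'(1)] on monomial coeffs
_COND = np.array([
    [1, 0, 0, 0, 0],
    [0, 1, 0, 0, 0],
    [1, 0.5, 0.25, 0.125, 0.0625],
    [1, 1, 1, 1, 1],
    [0, 1, 2, 3, 4],
], dtype=float)
_COND_INV = np.linalg.inv(_COND)


@dataclass(frozen=True)
class QuarticPoly:
    """Degree-4 polynomial over normalized phase s in [0, 1] with an affine
    map from the phase variable q in [q_start, q_end] to s."""

    coeffs: np.ndarray              # monomial coefficients, ascending
    q_start: float = 0.0
    q_end: float = 1.0

    def s_of(self, q: float) -> float:
        return (q - self.q_start) / (self.q_end - self.q_start)

    @property
    def ds_dq(self) -> float:
        return 1.0 / (self.q_end - self.q_start)

    def eval(self, s: float) -> float:
        return float(np.polyval(self.coeffs[::-1], s))

    def deriv(self, s: float) -> float:
        c = self.coeffs
        return float(c[1] + 2 * c[2] * s + 3 * c[3] * s ** 2 + 4 * c[4] * s ** 3)

    def second(self, s: float) -> float:
        c = self.coeffs
        return float(2 * c[2] + 6 * c[3] * s + 12 * c[4] * s ** 2)

    def eval_q(self, q: float) -> float:
        return self.eval(self.s_of(q))


def fit_quartic(start_pos: float, start_slope: float, mid_pos: float,
                end_pos: float, end_slope: float,
                q_start: float = 0.0, q_end: float = 1.0) -> QuarticPoly:
    """Unique quartic with p(0)=start_pos, p'(0)=start_slope, p(0.5)=mid_pos,
    p(1)=end_pos, p'(1)=end_slope (slopes in normalized-phase units)."""
    b = np.array([start_pos, start_slope, mid_pos, end_pos, end_slope], dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("quartic conditions must be finite")
    coeffs = _COND_INV @ b
    return QuarticPoly(coeffs=coeffs, q_start=q_start, q_end=q_end)


CLEARANCE_GAMMA = 1.0


def clearance_bump(s: float, gamma: float = CLEARANCE_GAMMA):
    """Clearance profile b(s) = 16 s^2 (1-s)^2 + gamma s^2 (1-s) and its
    first two derivatives w.r.t. s."""
    b = 16.0 * s * s * (1.0 - s) ** 2 + gamma * s * s * (1.0 - s)
    bp = 32.0 * s * (1.0 - s) * (1.0 - 2.0 * s) + gamma * s * (2.0 - 3.0 * s)
    bpp = 32.0 * (1.0 - 6.0 * s + 6.0 * s * s) + gamma * (2.0 - 6.0 * s)
    return b, bp, bpp


def exp_weight(rate: float, t: float) -> float:
    """w(t) = exp(-rate * t); w(0) = 1, strictly decreasing for rate > 0."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return math.exp(-rate * t)


# --------------------------------------------------------------------------
# control parameters (zeta)
# --------------------------------------------------------------------------

_ZETA_FIELDS = (
    "L_stv_mid", "L_stv_end",
    "q_P_mid", "q_P_end", "qd_P_end",
    "q_T_mid", "q_T_end", "qd_T_end",
    "L_st_ankle_mid", "L_st_ankle_end", "Ld_st_ankle_end",
    "L_sw_ankle_mid", "L_sw_ankle_end", "Ld_sw_ankle_end",
)

# fields printed in cm / cm/s in parameter tables
_CM_FIELDS = {"L_stv_mid", "L_stv_end", "L_st_ankle_mid", "L_st_ankle_end",
              "Ld_st_ankle_end", "L_sw_ankle_mid", "L_sw_ankle_end",
              "Ld_sw_ankle_end"}


@dataclass(frozen=True)
class ControlParams:
    """The 14 user-settable premise parameters (SI units: m, rad, rad/s, m/s).

    The adaptive stance-leg end-lengthening velocity Ld_stv_end is owned by
    the between-step controller and is deliberately not a field here.
    """

    L_stv_mid: float
    L_stv_end: float
    q_P_mid: float
    q_P_end: float
    qd_P_end: float
    q_T_mid: float
    q_T_end: float
    qd_T_end: float
    L_st_ankle_mid: float
    L_st_ankle_end: float
    Ld_st_ankle_end: float
    L_sw_ankle_mid: float
    L_sw_ankle_end: float
    Ld_sw_ankle_end: float

    def __post_init__(self):
        for name in ("L_stv_mid", "L_stv_end", "L_st_ankle_mid",
                     "L_st_ankle_end", "L_sw_ankle_mid", "L_sw_ankle_end"):
            if not getattr(self, name) > 0:
                raise ValueError(f"zeta.{name} must be > 0")

    @classmethod
    def from_table_units(cls, values: dict) -> "ControlParams":
        """Build from a mapping in the printed units (cm, rad, rad/s, cm/s)."""
        kw = {}
        for name in _ZETA_FIELDS:
            v = float(values[name])
            kw[name] = v / 100.0 if name in _CM_FIELDS else v
        return cls(**kw)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _ZETA_FIELDS])

    @classmethod
    def from_array(cls, arr) -> "ControlParams":
        return cls(**dict(zip(_ZETA_FIELDS, map(float, arr))))

    def interpolate(self, other: "ControlParams", alpha: float) -> "ControlParams":
        """Affine interpolation (1-alpha)*self + alpha*other."""
        return ControlParams.from_array(
            (1.0 - alpha) * self.as_array() + alpha * other.as_array())


def zeta_field_names() -> tuple[str, ...]:
    return _ZETA_FIELDS


def load_schedule(path) -> list[ControlParams]:
    """Load an ordered zeta schedule from a YAML file with a ``values``
    mapping of the 14 parameters to per-column lists (printed units)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _schedule_from_doc(doc)


def _schedule_from_doc(doc: dict) -> list[ControlParams]:
    values = doc["values"]
    ncol = len(next(iter(values.values())))
    out = []
    for i in range(ncol):
        out.append(ControlParams.from_table_units(
            {name: values[name][i] for name in _ZETA_FIELDS}))
    return out


def load_casting_schedule() -> list[ControlParams]:
    """The packaged five-column schedule pi1..pi5 (SI units)."""
    text = resources.files("toewalk").joinpath("data/casting_schedule.yaml").read_text()
    return _schedule_from_doc(yaml.safe_load(text))


def load_casting_schedule_raw() -> dict:
    """The packaged schedule in its printed units, as a plain mapping."""
    text = resources.files("toewalk").joinpath("data/casting_schedule.yaml").read_text()
    return yaml.safe_load(text)


# --------------------------------------------------------------------------
# weight rates and reference sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightRates:
    """Exponential decay rates [1/s] for the transition weights.

    Single-support weights remove the post-take-off asymmetry quickly
    (time constant 0.05 s); double-support weights are slow relative to the
    double-support duration (time constant 10 s), so the double-support
    references barely creep during the few tens of milliseconds both feet
    are planted and weight transfer unloads the trailing leg dynamically.
    """
    w_ss: tuple = (20.0, 20.0, 20.0)
    w_ds: tuple = (0.1, 0.1, 0.1, 0.1, 0.1, 0.1)


@dataclass(frozen=True)
class TakeoffSnapshot:
    """State of the premises at the single-support start (take-off), used
    to pin the continuity conditions of the reference polynomials."""
    q_stv: float
    qd_stv: float
    L_stv: float
    Ld_stv: float
    q_P: float
    qd_P: float
    q_T: float
    qd_T: float
    L_st_ankle: float
    Ld_st_ankle: float
    L_sw_ankle: float
    Ld_sw_ankle: float
    asymmetry: float          # q_st,v + q_sw,v at take-off
    t: float


@dataclass(frozen=True)
class ReferenceSet:
    """Phase-indexed references for one single-support phase plus the
    anchors and rates of the exponential transition weights."""

    L_stv: QuarticPoly
    q_P: QuarticPoly
    q_T: QuarticPoly
    L_st_ankle: QuarticPoly
    L_sw_ankle: QuarticPoly
    k1: float
    L_leg_nominal: float
    q_start: float
    q_end: float                  # touchdown target q_st,v,d
    asymmetry0: float
    t_ss_start: float
    rates: WeightRates

    def s_of(self, q_stv: float) -> float:
        return (q_stv - self.q_start) / (self.q_end - self.q_start)

    def clearance(self, s: float) -> float:
        """Desired swing-toe height z_sw,d at normalized phase s."""
        return self.k1 * self.L_leg_nominal * clearance_bump(s)[0]

    def polys(self) -> dict[str, QuarticPoly]:
        return {"L_stv": self.L_stv, "q_P": self.q_P, "q_T": self.q_T,
                "L_st_ankle": self.L_st_ankle, "L_sw_ankle": self.L_sw_ankle}


MIN_PHASE_RATE = 1e-4  # rad/s; below this the slope conversion is singular


def make_reference_set(zeta: ControlParams, takeoff: TakeoffSnapshot,
                       q_stv_target: float, L_dot_stv_end: float,
                       L_leg_nominal: float, k1: float = 0.05,
                       rates: WeightRates = WeightRates(),
                       qd_stv_end_prev: float | None = None) -> ReferenceSet:
    """Fit the five premise quartics for one single-support phase.

    Start values and slopes come from the take-off snapshot (position and
    velocity continuity); mid and end conditions come from zeta; the
    stance-leg end slope is the adaptive ``L_dot_stv_end``.  Time-slopes
    [m/s, rad/s] are converted to phase-slopes through the phase rate
    ds/dt = qd_st,v / (q_end - q_start): start slopes use the take-off
    phase rate, end slopes use the phase rate measured at the previous
    step's single-support end (falling back to the take-off rate on the
    first step).
    """
    dq = q_stv_target - takeoff.q_stv
    if abs(dq) < 1e-9:
        raise PhaseRateError("take-off q_st,v equals the touchdown target")
    sdot0 = takeoff.qd_stv / dq
    if abs(sdot0) < MIN_PHASE_RATE:
        raise PhaseRateError(
            f"phase rate at take-off too small ({takeoff.qd_stv:.2e} rad/s)")
    qd_end = qd_stv_end_prev if qd_stv_end_prev is not None else takeoff.qd_stv
    sdot1 = qd_end / dq
    if abs(sdot1) < MIN_PHASE_RATE:
        sdot1 = sdot0

    def fit(p0, pd0, pmid, pend, pdend):
        return fit_quartic(p0, pd0 / sdot0, pmid, pend, pdend / sdot1,
                           q_start=takeoff.q_stv, q_end=q_stv_target)

    return ReferenceSet(
        L_stv=fit(takeoff.L_stv, takeoff.Ld_stv, zeta.L_stv_mid,
                  zeta.L_stv_end, L_dot_stv_end),
        q_P=fit(takeoff.q_P, takeoff.qd_P, zeta.q_P_mid, zeta.q_P_end,
                zeta.qd_P_end),
        q_T=fit(takeoff.q_T, takeoff.qd_T, zeta.q_T_mid, zeta.q_T_end,
                zeta.qd_T_end),
        L_st_ankle=fit(takeoff.L_st_ankle, takeoff.Ld_st_ankle,
                       zeta.L_st_ankle_mid, zeta.L_st_ankle_end,
                       zeta.Ld_st_ankle_end),
        L_sw_ankle=fit(takeoff.L_sw_ankle, takeoff.Ld_sw_ankle,
                       zeta.L_sw_ankle_mid, zeta.L_sw_ankle_end,
                       zeta.Ld_sw_ankle_end),
        k1=k1, L_leg_nominal=L_leg_nominal,
        q_start=takeoff.q_stv, q_end=q_stv_target,
        asymmetry0=takeoff.asymmetry, t_ss_start=takeoff.t, rates=rates,
    )
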