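"""Constrained rigid-body dynamics of the planar eight-segment biped.

The model is a sagittal-plane linkage: left/right foot, shank and thigh,
plus pelvis and torso, all hinged at the common hip point.  Generalized
coordinates are ``q = (x, z, theta_1 .. theta_8)`` — the planar position of
the hip reference point followed by the *absolute* orientation of every
segment (counter-clockwise positive, measured from the world vertical).
With absolute angles every centre of mass is an affine combination of the
reference point and per-segment unit vectors ``e_j(theta_j)``, which gives
the Lagrangian terms a closed form:

    M_rr        = m_tot * I_2
    M_r,theta_j = w_j * e'_j
    M_jk        = S_jk * cos(theta_j - theta_k) * s_j s_k + delta_jk I_j

where ``w`` and ``S`` are constant mass-weighted first and second moments of
the chain coefficients.  The equations of motion are assembled from this
closed form and verified against numerical-Lagrangian and symbolic oracles
in the test-suite.

Ground contact is a toe-point contact: each active contact pins the toe of
one foot to a fixed world anchor (two holonomic constraints per contact).
Contact forces ``lambda`` are returned as the force exerted ON the biped BY
the ground, so the vertical component is >= 0 during valid contact.

Support-phase dynamics (single and double support):

    M qdd + C(q,qd) qd + G(q) = B u + Gamma^T lambda,   Gamma qd = 0

Touchdown is a rigid perfectly-plastic impact: positions are unchanged and
the post-impact velocity solves

    [ M  -Gamma^T ] [ qd+ ]   [ M qd- ]
    [ Gamma   0   ] [  F  ] = [   0   ]

Take-off is impulse-free removal of a constraint (velocities continuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import lu_factor, lu_solve


class ModelValidationError(ValueError):
    """A model parameter violates its physical invariant."""


class SingularityError(RuntimeError):
    """A constraint Jacobian or KKT system lost rank (singular posture)."""


# --------------------------------------------------------------------------
# segment parameters and anthropometric defaults
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment: mass [kg], length [m], COM offset from the
    proximal joint along the segment axis [m], inertia about the COM
    (out-of-plane axis) [kg m^2]."""

    name: str
    mass: float
    length: float
    com_offset: float
    inertia_com: float

    def validate(self) -> None:
        if not self.mass > 0:
            raise ModelValidationError(f"segment '{self.name}': mass must be > 0, got {self.mass}")
        if not self.length > 0:
            raise ModelValidationError(f"segment '{self.name}': length must be > 0, got {self.length}")
        if not 0.0 <= self.com_offset <= self.length:
            raise ModelValidationError(
                f"segment '{self.name}': com_offset must lie in [0, length], got {self.com_offset}")
        if self.inertia_com < 0:
            raise ModelValidationError(
                f"segment '{self.name}': inertia_com must be >= 0, got {self.inertia_com}")


# Default anthropometric table (gait-analysis convention): per-segment mass
# fraction of body mass, length fraction of stature, COM offset fraction of
# segment length (from the proximal joint) and radius of gyration about the
# COM as a fraction of segment length.  Thigh/shank length fractions are set
# slightly above the adult values (child-like leg proportions).  The foot
# segment runs from the ankle to the toe contact point.
#
# The default stature (see build_model) is chosen so the leg workspace
# comfortably covers toe-walking virtual-leg lengths up to ~0.84 m: shorter
# legs would push the swing knee through its straight-knee singularity when
# reaching the touchdown leg length.
_DEFAULT_ANTHRO = {
    #            m_frac   l_frac  com_frac  rgyr_frac
    "thigh":   (0.1000,   0.260,  0.433,    0.323),
    "shank":   (0.0465,   0.260,  0.433,    0.302),
    "foot":    (0.0145,   0.070,  0.500,    0.475),
    "pelvis":  (0.1420,   0.100,  0.500,    0.310),
    "torso":   (0.5360,   0.350,  0.450,    0.450),
}

SEGMENT_NAMES = (
    "l_thigh", "l_shank", "l_foot",
    "r_thigh", "r_shank", "r_foot",
    "pelvis", "torso",
)

# angle-coordinate indices within q (q[0:2] is the hip reference point)
IDX_X, IDX_Z = 0, 1
IDX_LTH, IDX_LSH, IDX_LFT = 2, 3, 4
IDX_RTH, IDX_RSH, IDX_RFT = 5, 6, 7
IDX_PEL, IDX_TOR = 8, 9
NQ = 10
NU = 7

# orientation of the reference direction per angle: +1 -> segment axis points
# straight down at theta = 0 (legs), -1 -> straight up (pelvis, torso)
_BIPED_SIGMA = np.array([1, 1, 1, 1, 1, 1, -1, -1], dtype=float)


# --------------------------------------------------------------------------
# generic planar linkage (also used by the 1-2 link oracle fixtures)
# --------------------------------------------------------------------------

class PlanarLinkage:
    """A planar linkage with coordinates (x, z, theta_1..theta_n).

    ``com_coeffs[i, j]`` is the coefficient of ``e_j(theta_j)`` in the world
    position of the i-th segment COM (positions are
    ``r + sum_j coeffs[i, j] * e_j``), with ``e_j = sigma_j (sin, -cos)``.
    """

    def __init__(self, masses, inertias, com_coeffs, sigma, gravity=9.81):
        self.masses = np.asarray(masses, dtype=float)
        self.inertias = np.asarray(inertias, dtype=float)
        self.com_coeffs = np.asarray(com_coeffs, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.gravity = float(gravity)
        self.n_ang = self.com_coeffs.shape[1]
        self.nq = 2 + self.n_ang
        self.m_tot = float(self.masses.sum())
        # constant mass moments of the chain coefficients
        self.w = self.masses @ self.com_coeffs                      # (n_ang,)
        self.S = self.com_coeffs.T @ (self.masses[:, None] * self.com_coeffs)

    # -- kinematic primitives ------------------------------------------------

    def unit_vectors(self, theta):
        """e_j and their derivatives e'_j, shape (n_ang, 2) each."""
        s, c = np.sin(theta), np.cos(theta)
        e = np.stack([self.sigma * s, -self.sigma * c], axis=1)
        ep = np.stack([self.sigma * c, self.sigma * s], axis=1)
        return e, ep

    def point_position(self, q, coeffs):
        theta = q[2:]
        e, _ = self.unit_vectors(theta)
        return q[:2] + coeffs @ e

    def point_jacobian(self, q, coeffs):
        theta = q[2:]
        _, ep = self.unit_vectors(theta)
        J = np.zeros((2, self.nq))
        J[0, 0] = J[1, 1] = 1.0
        J[:, 2:] = (coeffs[:, None] * ep).T
        return J

    def point_accel_bias(self, q, qdot, coeffs):
        """Jdot @ qdot for the point: the velocity-product acceleration."""
        theta, thetad = q[2:], qdot[2:]
        e, _ = self.unit_vectors(theta)
        return -(coeffs * thetad ** 2) @ e

    # -- Lagrangian terms ----------------------------------------------------

    def mass_matrix(self, q):
        theta = q[2:]
        _, ep = self.unit_vectors(theta)
        M = np.zeros((self.nq, self.nq))
        M[0, 0] = M[1, 1] = self.m_tot
        Mrt = (self.w[:, None] * ep).T                   # (2, n_ang)
        M[:2, 2:] = Mrt
        M[2:, :2] = Mrt.T
        ss = np.outer(self.sigma, self.sigma)
        cdiff = np.cos(theta[:, None] - theta[None, :])
        M[2:, 2:] = self.S * ss * cdiff + np.diag(self.inertias)
        return M

    def bias_forces(self, q, qdot):
        """Returns (C(q,qd) qd, G(q)) as generalized-force vectors."""
        theta, thetad = q[2:], qdot[2:]
        e, ep = self.unit_vectors(theta)
        td2 = thetad ** 2
        Cqd = np.zeros(self.nq)
        Cqd[:2] = -(self.w * td2) @ e
        ss = np.outer(self.sigma, self.sigma)
        sdiff = np.sin(theta[None, :] - theta[:, None])   # sin(theta_k - theta_j)
        Cqd[2:] = -(self.S * ss * sdiff) @ td2
        G = np.zeros(self.nq)
        G[1] = self.m_tot * self.gravity
        G[2:] = self.gravity * self.w * ep[:, 1]
        return Cqd, G

    def kinetic_energy(self, q, qdot):
        return 0.5 * qdot @ self.mass_matrix(q) @ qdot

    def potential_energy(self, q):
        theta = q[2:]
        e, _ = self.unit_vectors(theta)
        z_com = q[1] + self.com_coeffs @ e[:, 1]
        return self.gravity * float(self.masses @ z_com)


# --------------------------------------------------------------------------
# the biped model
# --------------------------------------------------------------------------

@dataclass
class BipedModel:
    """Planar eight-segment biped (Figure-1 topology).

    Segments attach at the common hip reference point: each leg is a
    thigh-shank-foot chain (hip, knee, ankle joints); pelvis and torso hinge
    at the hip.  Seven joint torques (hip, knee, ankle x2, pelvis-torso)
    enter through the constant actuation map ``B``.
    """

    segments: dict[str, SegmentSpec]
    gravity: float
    L_leg_nominal: float
    total_mass: float
    height: float

    linkage: PlanarLinkage = field(init=False, repr=False)
    B: np.ndarray = field(init=False, repr=False)
    _points: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self):
        for name in SEGMENT_NAMES:
            if name not in self.segments:
                raise ModelValidationError(f"missing segment '{name}'")
            self.segments[name].validate()
        if not self.L_leg_nominal > 0:
            raise ModelValidationError(f"L_leg_nominal must be > 0, got {self.L_leg_nominal}")
        segs = [self.segments[n] for n in SEGMENT_NAMES]
        masses = np.array([s.mass for s in segs])
        inertias = np.array([s.inertia_com for s in segs])

        lth = self.segments["l_thigh"].length
        lsh = self.segments["l_shank"].length
        lft = self.segments["l_foot"].length
        rth = self.segments["r_thigh"].length
        rsh = self.segments["r_shank"].length
        rft = self.segments["r_foot"].length

        n_ang = 8
        C = np.zeros((8, n_ang))

        def ang(i):
            return i - 2  # coordinate index -> angle index

        # COM chain coefficients
        C[0, ang(IDX_LTH)] = self.segments["l_thigh"].com_offset
        C[1, ang(IDX_LTH)] = lth
        C[1, ang(IDX_LSH)] = self.segments["l_shank"].com_offset
        C[2, ang(IDX_LTH)] = lth
        C[2, ang(IDX_LSH)] = lsh
        C[2, ang(IDX_LFT)] = self.segments["l_foot"].com_offset
        C[3, ang(IDX_RTH)] = self.segments["r_thigh"].com_offset
        C[4, ang(IDX_RTH)] = rth
        C[4, ang(IDX_RSH)] = self.segments["r_shank"].com_offset
        C[5, ang(IDX_RTH)] = rth
        C[5, ang(IDX_RSH)] = rsh
        C[5, ang(IDX_RFT)] = self.segments["r_foot"].com_offset
        C[6, ang(IDX_PEL)] = self.segments["pelvis"].com_offset
        C[7, ang(IDX_TOR)] = self.segments["torso"].com_offset

        self.linkage = PlanarLinkage(masses, inertias, C, _BIPED_SIGMA, self.gravity)

        # landmark coefficient rows
        P: dict[str, np.ndarray] = {}

        def row(**kw):
            r = np.zeros(n_ang)
            for idx, val in kw.items():
                r[ang(getattr_idx[idx])] = val
            return r

        getattr_idx = {
            "lth": IDX_LTH, "lsh": IDX_LSH, "lft": IDX_LFT,
            "rth": IDX_RTH, "rsh": IDX_RSH, "rft": IDX_RFT,
            "pel": IDX_PEL, "tor": IDX_TOR,
        }
        P["hip"] = np.zeros(n_ang)
        P["knee_left"] = row(lth=lth)
        P["ankle_left"] = row(lth=lth, lsh=lsh)
        P["toe_left"] = row(lth=lth, lsh=lsh, lft=lft)
        P["knee_right"] = row(rth=rth)
        P["ankle_right"] = row(rth=rth, rsh=rsh)
        P["toe_right"] = row(rth=rth, rsh=rsh, rft=rft)
        P["pelvis_com"] = row(pel=self.segments["pelvis"].com_offset)
        P["torso_com"] = row(tor=self.segments["torso"].com_offset)
        self._points = P

        # actuation map: joint torque on (theta_child - theta_parent)
        B = np.zeros((NQ, NU))
        joints = [
            (IDX_LTH, IDX_PEL),   # left hip
            (IDX_LSH, IDX_LTH),   # left knee
            (IDX_LFT, IDX_LSH),   # left ankle
            (IDX_RTH, IDX_PEL),   # right hip
            (IDX_RSH, IDX_RTH),   # right knee
            (IDX_RFT, IDX_RSH),   # right ankle
            (IDX_TOR, IDX_PEL),   # pelvis-torso
        ]
        for col, (child, parent) in enumerate(joints):
            B[child, col] = 1.0
            B[parent, col] = -1.0
        self.B = B

    # joint torque column order of ``B`` / ``u``
    TORQUE_LABELS = ("hip_l", "knee_l", "ankle_l", "hip_r", "knee_r", "ankle_r", "trunk")

    def point_coeffs(self, name: str) -> np.ndarray:
        return self._points[name]

    def toe_point(self, side: str) -> str:
        return f"toe_{side}"

    @property
    def sigma(self):
        return self.linkage.sigma


@dataclass(frozen=True)
class GenCoords:
    """Generalized coordinates and rates of the biped (10-vectors)."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "qdot", np.asarray(self.qdot, dtype=float))
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ModelValidationError("GenCoords entries must be finite")
        if self.q.shape != self.qdot.shape:
            raise ModelValidationError("q and qdot must have matching shapes")


@dataclass(frozen=True)
class Contact:
    """One active toe-point contact with its fixed world anchor."""
    leg: str                      # 'left' | 'right'
    point: str = "toe"
    anchor: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class ContactSet:
    contacts: tuple[Contact, ...]

    def __post_init__(self):
        if not 0 <= len(self.contacts) <= 2:
            raise ModelValidationError("0, 1 or 2 point contacts supported")
        for c in self.contacts:
            if c.leg not in ("left", "right"):
                raise ModelValidationError(f"unknown leg '{c.leg}'")

    def __len__(self):
        return len(self.contacts)

    def legs(self):
        return tuple(c.leg for c in self.contacts)

    def without(self, leg: str) -> "ContactSet":
        return ContactSet(tuple(c for c in self.contacts if c.leg != leg))

    def with_contact(self, contact: Contact) -> "ContactSet":
        return ContactSet(self.contacts + (contact,))


@dataclass(frozen=True)
class DynamicsEval:
    M: np.ndarray
    Cqdot: np.ndarray
    G: np.ndarray
    Gamma: np.ndarray
    lam: np.ndarray


@dataclass(frozen=True)
class ImpactResult:
    qdot_plus: np.ndarray
    impulse: np.ndarray


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------

def build_model(config: dict | None = None, **kwargs) -> BipedModel:
    """Build a validated :class:`BipedModel`.

    ``config`` (a mapping, e.g. parsed from YAML) supplies total body
    ``mass`` [kg] and ``height`` [m]; per-segment values default to the
    anthropometric table scaled to mass/height and can be overridden via
    ``segments: {name: {mass: .., length: .., com_offset: .., inertia_com: ..}}``.
    Left/right leg segments share the same defaults.

    ``L_leg_nominal`` defaults to thigh + shank + ``foot_axis_fraction``
    (default 0.45) of the foot length: the toe-to-hip distance with the leg
    extended and the ankle at its reference toe-walking posture.
    """
    cfg = dict(config or {})
    cfg.update(kwargs)
    mass = float(cfg.get("mass", 40.0))
    height = float(cfg.get("height", 1.60))
    gravity = float(cfg.get("gravity", 9.81))
    foot_axis_fraction = float(cfg.get("foot_axis_fraction", 0.45))
    if mass <= 0:
        raise ModelValidationError(f"mass must be > 0, got {mass}")
    if height <= 0:
        raise ModelValidationError(f"height must be > 0, got {height}")

    overrides = cfg.get("segments", {}) or {}
    segments: dict[str, SegmentSpec] = {}
    # distribute any rounding residue into the torso so segment masses sum
    # to the configured total exactly
    base = {}
    for key, (mf, lf, cf, rf) in _DEFAULT_ANTHRO.items():
        m = mf * mass
        L = lf * height
        base[key] = dict(mass=m, length=L, com_offset=cf * L,
                         inertia_com=m * (rf * L) ** 2)
    leg_keys = {"thigh": ("l_thigh", "r_thigh"), "shank": ("l_shank", "r_shank"),
                "foot": ("l_foot", "r_foot")}
    for generic, names in leg_keys.items():
        for n in names:
            segments[n] = SegmentSpec(name=n, **base[generic])
    segments["pelvis"] = SegmentSpec(name="pelvis", **base["pelvis"])
    segments["torso"] = SegmentSpec(name="torso", **base["torso"])

    for name, over in overrides.items():
        if name not in segments:
            raise ModelValidationError(f"unknown segment override '{name}'")
        segments[name] = replace(segments[name], **over)

    if not overrides:
        residue = mass - sum(s.mass for s in segments.values())
        segments["torso"] = replace(segments["torso"],
                                    mass=segments["torso"].mass + residue)

    if "L_leg_nominal" in cfg:
        L_nom = float(cfg["L_leg_nominal"])
    else:
        L_nom = (segments["l_thigh"].length + segments["l_shank"].length
                 + foot_axis_fraction * segments["l_foot"].length)

    return BipedModel(segments=segments, gravity=gravity,
                      L_leg_nominal=L_nom, total_mass=mass, height=height)


# --------------------------------------------------------------------------
# dynamics operations
# --------------------------------------------------------------------------

def contact_rows(model: BipedModel, contacts: ContactSet) -> list[np.ndarray]:
    return [model.point_coeffs(model.toe_point(c.leg)) for c in contacts.contacts]


def constraint_jacobian(model: BipedModel, state: GenCoords, contacts: ContactSet):
    """Gamma (k x 10) and the velocity-product term Gammadot @ qdot (k,)."""
    rows = contact_rows(model, contacts)
    k = 2 * len(rows)
    Gamma = np.zeros((k, NQ))
    gdot = np.zeros(k)
    for i, coeffs in enumerate(rows):
        Gamma[2 * i:2 * i + 2] = model.linkage.point_jacobian(state.q, coeffs)
        gdot[2 * i:2 * i + 2] = model.linkage.point_accel_bias(state.q, state.qdot, coeffs)
    return Gamma, gdot


def evaluate_dynamics(model: BipedModel, state: GenCoords,
                      contacts: ContactSet) -> DynamicsEval:
    """Mass matrix, bias forces, constraint Jacobian and the unforced
    (u = 0) contact force consistent with the active constraints."""
    M = model.linkage.mass_matrix(state.q)
    Cqd, G = model.linkage.bias_forces(state.q, state.qdot)
    Gamma, _ = constraint_jacobian(model, state, contacts)
    if len(contacts):
        _, lam = constrained_accel(model, state, contacts, np.zeros(NU))
    else:
        lam = np.zeros(0)
    return DynamicsEval(M=M, Cqdot=Cqd, G=G, Gamma=Gamma, lam=lam)


def _kkt_solve(M, Gamma, rhs_top, rhs_bot):
    nq, k = M.shape[0], Gamma.shape[0]
    K = np.zeros((nq + k, nq + k))
    K[:nq, :nq] = M
    K[:nq, nq:] = -Gamma.T
    K[nq:, :nq] = Gamma
    try:
        lu = lu_factor(K)
    except Exception as exc:  # pragma: no cover - defensive
        raise SingularityError(f"singular KKT system: {exc}") from exc
    rhs = np.concatenate([rhs_top, rhs_bot])
    sol = lu_solve(lu, rhs)
    if not np.all(np.isfinite(sol)):
        raise SingularityError("singular KKT system (non-finite solution)")
    return sol[:nq], sol[nq:], lu


def constrained_accel(model: BipedModel, state: GenCoords, contacts: ContactSet,
                      u: np.ndarray):
    """Solve the support-phase dynamics for (qddot, lambda) under torques u."""
    M = model.linkage.mass_matrix(state.q)
    Cqd, G = model.linkage.bias_forces(state.q, state.qdot)
    Gamma, gdot = constraint_jacobian(model, state, contacts)
    if len(contacts) and np.linalg.matrix_rank(Gamma, tol=1e-8) < Gamma.shape[0]:
        raise SingularityError("rank-deficient contact Jacobian (singular posture)")
    tau = model.B @ np.asarray(u, dtype=float) - Cqd - G
    if not len(contacts):
        return np.linalg.solve(M, tau), np.zeros(0)
    qdd, lam, _ = _kkt_solve(M, Gamma, tau, -gdot)
    return qdd, lam


def input_affine_dynamics(model: BipedModel, state: GenCoords, contacts: ContactSet):
    """Constrained dynamics in input-affine form qddot = A u + b.

    Returns (A, b, lamA, lamb) so that lambda = lamA @ u + lamb as well.
    """
    M = model.linkage.mass_matrix(state.q)
    Cqd, G = model.linkage.bias_forces(state.q, state.qdot)
    Gamma, gdot = constraint_jacobian(model, state, contacts)
    k = Gamma.shape[0]
    nq = NQ
    K = np.zeros((nq + k, nq + k))
    K[:nq, :nq] = M
    if k:
        K[:nq, nq:] = -Gamma.T
        K[nq:, :nq] = Gamma
    try:
        lu = lu_factor(K)
    except Exception as exc:  # pragma: no cover
        raise SingularityError(f"singular KKT system: {exc}") from exc
    rhs = np.zeros((nq + k, 1 + NU))
    rhs[:nq, 0] = -Cqd - G
    rhs[nq:, 0] = -gdot
    rhs[:nq, 1:] = model.B
    sol = lu_solve(lu, rhs)
    if not np.all(np.isfinite(sol)):
        raise SingularityError("singular KKT system (non-finite solution)")
    b = sol[:nq, 0]
    A = sol[:nq, 1:]
    lamb = sol[nq:, 0]
    lamA = sol[nq:, 1:]
    return A, b, lamA, lamb


def impact_map(model: BipedModel, state: GenCoords,
               new_contacts: ContactSet) -> ImpactResult:
    """Rigid perfectly-plastic impact: instantaneous velocity reset that
    zeroes the velocity of every point in ``new_contacts`` (the union of
    persisting and freshly-touching contacts).  Positions are unchanged."""
    M = model.linkage.mass_matrix(state.q)
    Gamma, _ = constraint_jacobian(model, state, new_contacts)
    qd_plus, F, _ = _kkt_solve(M, Gamma, M @ state.qdot, np.zeros(Gamma.shape[0]))
    return ImpactResult(qdot_plus=qd_plus, impulse=F)


def takeoff_map(state: GenCoords, contacts: ContactSet,
                removed_leg: str) -> tuple[GenCoords, ContactSet]:
    """Impulse-free constraint removal: the continuous state is unchanged,
    the lifted leg leaves the active contact set."""
    return state, contacts.without(removed_leg)


# --------------------------------------------------------------------------
# energy and mirror helpers
# --------------------------------------------------------------------------

def total_energy(model: BipedModel, state: GenCoords) -> float:
    return (model.linkage.kinetic_energy(state.q, state.qdot)
            + model.linkage.potential_energy(state.q))


_MIRROR_PERM = np.array([IDX_X, IDX_Z, IDX_RTH, IDX_RSH, IDX_RFT,
                         IDX_LTH, IDX_LSH, IDX_LFT, IDX_PEL, IDX_TOR])


def mirror_state(state: GenCoords) -> GenCoords:
    """Reflect the state about the sagittal vertical plane x -> -x
    (left and right legs swap, all angles negate)."""
    sgn = np.ones(NQ)
    sgn[IDX_X] = -1.0
    q = sgn * state.q[_MIRROR_PERM]
    q[2:] = -state.q[_MIRROR_PERM][2:]
    qd = sgn * state.qdot[_MIRROR_PERM]
    qd[2:] = -state.qdot[_MIRROR_PERM][2:]
    return GenCoords(q=q, qdot=qd)
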