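"""Planar two-link arm in the vertical plane driven by eight Hill-type muscles.

The skeleton is a rigid two-link pendulum (shoulder, elbow) moving in the
vertical plane, with the zero configuration hanging straight down and flexion
counted positive.  Eight muscles actuate it through constant moment arms:

==========  ==================  =========================
muscle      shoulder role       elbow role
==========  ==================  =========================
DELTant     flexor              --
DELTpost    extensor            --
BIClong     flexor              flexor   (biarticular)
BICshort    --                  flexor
BRA         --                  flexor
TRIlong     extensor            extensor (biarticular)
TRIlat      --                  extensor
TRImed      --                  extensor
==========  ==================  =========================

Each muscle produces ``f_m = F_max (a f_lv(l, ldot) + f_p(l)) cos(theta)``
where ``a`` follows first-order activation dynamics ``da/dt = (u - a)/tau``
with a fast activation and a slow deactivation time constant.  The active
curve ``f_lv`` is a Gaussian force-length factor times a Hill force-velocity
factor, both normalised so that ``f_lv(l0, 0) = 1``; the passive curve is an
exponential that is zero at or below the optimal length ``l0``.

Muscle-tendon length is linear in joint angle with constant moment arms,
``l = l_ref - sum_j r_j (q_j - q_ref_j)``, so joint torque ``tau_j = sum_m
r_mj f_m`` is exactly virtual-work consistent with the kinematics.

External hand forces (perturbations) map to joint torques through the hand
Jacobian transpose.  Integration is semi-implicit Euler; joint limits are
enforced by clamping with the post-clamp velocity zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .trajectory import JointState, N_JOINTS

MUSCLE_NAMES = (
    "DELTant", "DELTpost", "BIClong", "BICshort",
    "BRA", "TRIlong", "TRIlat", "TRImed",
)
N_MUSCLES = 8

# Default signed moment arms (m): columns (shoulder, elbow), flexion positive.
_DEFAULT_MOMENT_ARMS = {
    "DELTant": (0.035, 0.0),
    "DELTpost": (-0.035, 0.0),
    "BIClong": (0.025, 0.035),
    "BICshort": (0.0, 0.035),
    "BRA": (0.0, 0.025),
    "TRIlong": (-0.025, -0.025),
    "TRIlat": (0.0, -0.025),
    "TRImed": (0.0, -0.025),
}
# Peak isometric forces (N) and optimal fibre lengths (m): conventional adult
# upper-limb values, placeholders overridable in config -- not ground truth.
_DEFAULT_FMAX = {
    "DELTant": 1100.0, "DELTpost": 1100.0, "BIClong": 625.0, "BICshort": 435.0,
    "BRA": 990.0, "TRIlong": 800.0, "TRIlat": 625.0, "TRImed": 620.0,
}
_DEFAULT_L0 = {
    "DELTant": 0.10, "DELTpost": 0.14, "BIClong": 0.12, "BICshort": 0.13,
    "BRA": 0.086, "TRIlong": 0.13, "TRIlat": 0.11, "TRImed": 0.11,
}

FL_WIDTH = 0.40        # Gaussian force-length width (normalised length units)
VMAX_REL = 10.0        # max shortening velocity, optimal lengths per second
KP_PASSIVE = 5.0       # passive curve exponent; f_p(1.6 l0) = 1
_PASSIVE_NORM = 1.0 / (np.exp(KP_PASSIVE * 0.6) - 1.0)


class NumericalDivergenceError(RuntimeError):
    """Raised when the plant state stops being finite."""


@dataclass(frozen=True)
class MuscleParams:
    name: str
    F_max: float
    l0: float
    moment_arms: tuple  # (shoulder, elbow), signed, m
    pennation: float = 0.0
    l_ref: float = None  # muscle-tendon length at the reference posture
    tau_act: float = 0.010
    tau_deact: float = 0.040

    def __post_init__(self):
        if self.F_max <= 0 or self.l0 <= 0:
            raise ValueError(f"{self.name}: F_max and l0 must be positive")
        if abs(self.pennation) >= np.pi / 2:
            raise ValueError(f"{self.name}: |pennation| must be < pi/2")
        if self.l_ref is None:
            object.__setattr__(self, "l_ref", self.l0)


def default_muscles() -> tuple:
    return tuple(
        MuscleParams(
            name=n,
            F_max=_DEFAULT_FMAX[n],
            l0=_DEFAULT_L0[n],
            moment_arms=_DEFAULT_MOMENT_ARMS[n],
        )
        for n in MUSCLE_NAMES
    )


@dataclass(frozen=True)
class ArmConfig:
    """Segment and simulation parameters for the planar arm."""

    l1: float = 0.31          # upper-arm length, m
    l2: float = 0.34          # forearm+hand length, m
    m1: float = 2.10          # upper-arm mass, kg
    m2: float = 1.65          # forearm+hand mass, kg
    lc1: float = 0.15         # shoulder-to-CoM distance, m
    lc2: float = 0.19
    I1: float = 0.025         # link inertia about its CoM, kg m^2
    I2: float = 0.045
    gravity: float = 9.81     # magnitude; acts along -y in the plane
    damping: float = 0.5      # viscous joint damping, N m s / rad
    joint_limits: tuple = ((-1.0, 3.0), (0.0, 2.8))
    q_ref: tuple = (0.6, 1.0)  # posture at which every muscle is at l_ref
    dt: float = 0.001

    def __post_init__(self):
        if min(self.l1, self.l2, self.m1, self.m2) <= 0:
            raise ValueError("segment lengths and masses must be positive")
        for lo, hi in self.joint_limits:
            if lo >= hi:
                raise ValueError("joint limits must be ordered (lo < hi)")


@dataclass(frozen=True)
class Perturbation:
    """A brief external force applied at the hand (default 50 N for 30 ms)."""

    magnitude: float = 50.0
    direction: tuple = (1.0, 0.0)
    onset: float = 0.0
    duration: float = 0.030

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("perturbation duration must be positive")
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ValueError("perturbation direction must be nonzero")
        object.__setattr__(self, "direction", tuple(d / n))

    def force_at(self, t: float) -> np.ndarray:
        if self.onset <= t < self.onset + self.duration:
            return self.magnitude * np.asarray(self.direction)
        return np.zeros(2)


@dataclass
class ArmState:
    joint: JointState
    l_m: np.ndarray
    ldot_m: np.ndarray
    activation: np.ndarray
    excitation: np.ndarray
    force: np.ndarray


# ---------------------------------------------------------------------------
# Jitted kernels.  These operate on flat arrays and are shared by the public
# wrappers below and by the closed-loop runner's hot path.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _activation_kernel(a, u, dt, tau_act, tau_deact, out):
    for m in range(a.shape[0]):
        am = min(max(a[m], 0.0), 1.0)
        um = min(max(u[m], 0.0), 1.0)
        tau = tau_act[m] if um > am else tau_deact[m]
        am = am + dt * (um - am) / tau
        out[m] = min(max(am, 0.0), 1.0)


@njit(cache=True)
def _force_kernel(a, l, ldot, Fmax, l0, cospenn, fl_width, vmax_rel, kp, cnorm, out):
    for m in range(a.shape[0]):
        ln = l[m] / l0[m]
        fl = np.exp(-((ln - 1.0) / fl_width) ** 2)
        w = ldot[m] / (vmax_rel * l0[m])  # >0 lengthening
        if w < 0.0:
            fv = (1.0 + w) / (1.0 - 4.0 * w)
            if fv < 0.0:
                fv = 0.0
        else:
            fv = (1.0 + 15.0 * w) / (1.0 + 10.0 * w)
        if ln > 1.0:
            fp = (np.exp(kp * (ln - 1.0)) - 1.0) * cnorm
        else:
            fp = 0.0
        out[m] = Fmax[m] * (a[m] * fl * fv + fp) * cospenn[m]


@njit(cache=True)
def _muscle_kin_kernel(q, qd, q_ref, R, lref, l_out, ldot_out):
    for m in range(R.shape[0]):
        lm = lref[m]
        ld = 0.0
        for j in range(R.shape[1]):
            lm -= R[m, j] * (q[j] - q_ref[j])
            ld -= R[m, j] * qd[j]
        l_out[m] = lm
        ldot_out[m] = ld


@njit(cache=True)
def _dynamics_kernel(q, qd, tau_muscle, fx, fy,
                     l1, l2, m1, m2, lc1, lc2, I1, I2, g, b,
                     lim_lo, lim_hi, dt):
    """Semi-implicit Euler step of the two-link dynamics; mutates q, qd."""
    c2 = np.cos(q[1])
    s2 = np.sin(q[1])
    M11 = I1 + I2 + m1 * lc1 * lc1 + m2 * (l1 * l1 + lc2 * lc2 + 2.0 * l1 * lc2 * c2)
    M12 = I2 + m2 * (lc2 * lc2 + l1 * lc2 * c2)
    M22 = I2 + m2 * lc2 * lc2
    h = m2 * l1 * lc2 * s2
    C1 = -h * qd[1] * (2.0 * qd[0] + qd[1])
    C2 = h * qd[0] * qd[0]
    s1 = np.sin(q[0])
    s12 = np.sin(q[0] + q[1])
    G1 = (m1 * lc1 + m2 * l1) * g * s1 + m2 * lc2 * g * s12
    G2 = m2 * lc2 * g * s12
    c1 = np.cos(q[0])
    c12 = np.cos(q[0] + q[1])
    # hand Jacobian transpose times external force
    tx1 = (l1 * c1 + l2 * c12) * fx + (l1 * s1 + l2 * s12) * fy
    tx2 = l2 * c12 * fx + l2 * s12 * fy
    t1 = tau_muscle[0] + tx1 - C1 - G1 - b * qd[0]
    t2 = tau_muscle[1] + tx2 - C2 - G2 - b * qd[1]
    det = M11 * M22 - M12 * M12
    qdd0 = (M22 * t1 - M12 * t2) / det
    qdd1 = (M11 * t2 - M12 * t1) / det
    qd[0] += dt * qdd0
    qd[1] += dt * qdd1
    q[0] += dt * qd[0]
    q[1] += dt * qd[1]
    for j in range(2):
        if q[j] < lim_lo[j]:
            q[j] = lim_lo[j]
            if qd[j] < 0.0:
                qd[j] = 0.0
        elif q[j] > lim_hi[j]:
            q[j] = lim_hi[j]
            if qd[j] > 0.0:
                qd[j] = 0.0


@njit(cache=True)
def _arm_step_kernel(q, qd, a, l, ldot, f, u,
                     Fmax, l0, lref, cospenn, tau_act, tau_deact, R, q_ref,
                     fl_width, vmax_rel, kp, cnorm,
                     fx, fy, l1, l2, m1, m2, lc1, lc2, I1, I2, g, b,
                     lim_lo, lim_hi, dt):
    _activation_kernel(a, u, dt, tau_act, tau_deact, a)
    _muscle_kin_kernel(q, qd, q_ref, R, lref, l, ldot)
    _force_kernel(a, l, ldot, Fmax, l0, cospenn, fl_width, vmax_rel, kp, cnorm, f)
    tau = np.zeros(2)
    for m in range(R.shape[0]):
        tau[0] += R[m, 0] * f[m]
        tau[1] += R[m, 1] * f[m]
    _dynamics_kernel(q, qd, tau, fx, fy, l1, l2, m1, m2, lc1, lc2, I1, I2,
                     g, b, lim_lo, lim_hi, dt)


# ---------------------------------------------------------------------------
# Public wrappers
# ---------------------------------------------------------------------------

def activation_step(a: float, u: float, dt: float, params: MuscleParams) -> float:
    """One Euler step of the excitation->activation first-order dynamics."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a_arr = np.array([a], dtype=float)
    out = np.empty(1)
    _activation_kernel(a_arr, np.array([u], dtype=float), dt,
                       np.array([params.tau_act]), np.array([params.tau_deact]), out)
    return float(out[0])


def muscle_force(a: float, l_m: float, ldot_m: float, params: MuscleParams) -> float:
    """Hill-type muscle force: F_max (a f_lv + f_p) cos(pennation)."""
    if l_m <= 0:
        raise ValueError(f"{params.name}: non-positive muscle length {l_m}")
    out = np.empty(1)
    _force_kernel(np.array([np.clip(a, 0.0, 1.0)]), np.array([float(l_m)]),
                  np.array([float(ldot_m)]), np.array([params.F_max]),
                  np.array([params.l0]), np.array([np.cos(params.pennation)]),
                  FL_WIDTH, VMAX_REL, KP_PASSIVE, _PASSIVE_NORM, out)
    return float(out[0])


class ArmModel:
    """Packs muscle/segment parameters into arrays and advances the plant."""

    def __init__(self, config: ArmConfig = None, muscles=None):
        self.config = config or ArmConfig()
        self.muscles = tuple(muscles) if muscles is not None else default_muscles()
        if len(self.muscles) != N_MUSCLES:
            raise ValueError(f"expected {N_MUSCLES} muscles, got {len(self.muscles)}")
        ms = self.muscles
        self.Fmax = np.array([m.F_max for m in ms])
        self.l0 = np.array([m.l0 for m in ms])
        self.lref = np.array([m.l_ref for m in ms])
        self.cospenn = np.cos(np.array([m.pennation for m in ms]))
        self.tau_act = np.array([m.tau_act for m in ms])
        self.tau_deact = np.array([m.tau_deact for m in ms])
        self.R = np.array([m.moment_arms for m in ms], dtype=float)
        self.q_ref = np.asarray(self.config.q_ref, dtype=float)
        self.lim_lo = np.array([lim[0] for lim in self.config.joint_limits])
        self.lim_hi = np.array([lim[1] for lim in self.config.joint_limits])
        # flexor/extensor index sets per joint (sign of the moment arm)
        self.flexors = {j: np.where(self.R[:, j] > 0)[0] for j in range(N_JOINTS)}
        self.extensors = {j: np.where(self.R[:, j] < 0)[0] for j in range(N_JOINTS)}

    def muscle_kinematics(self, joint: JointState):
        """Muscle-tendon lengths and velocities at a joint state (m, m/s)."""
        l = np.empty(N_MUSCLES)
        ld = np.empty(N_MUSCLES)
        _muscle_kin_kernel(joint.q, joint.qdot, self.q_ref, self.R, self.lref, l, ld)
        return l, ld

    def initial_state(self, q=None, qdot=None) -> ArmState:
        q = np.array(self.q_ref if q is None else q, dtype=float)
        qd = np.zeros(N_JOINTS) if qdot is None else np.array(qdot, dtype=float)
        joint = JointState(q, qd)
        l, ld = self.muscle_kinematics(joint)
        return ArmState(joint=joint, l_m=l, ldot_m=ld,
                        activation=np.zeros(N_MUSCLES),
                        excitation=np.zeros(N_MUSCLES),
                        force=np.zeros(N_MUSCLES))

    def step(self, state: ArmState, excitations, force=None,
             dt: float = None) -> ArmState:
        """Advance the plant by one timestep under muscle excitations.

        ``force`` is an optional external (fx, fy) hand force in N.
        """
        dt = self.config.dt if dt is None else dt
        if dt <= 0:
            raise ValueError("dt must be positive")
        u = np.clip(np.asarray(excitations, dtype=float), 0.0, 1.0)
        if u.shape != (N_MUSCLES,):
            raise ValueError(f"need {N_MUSCLES} excitations, got shape {u.shape}")
        fx, fy = (0.0, 0.0) if force is None else (float(force[0]), float(force[1]))
        q = state.joint.q.copy()
        qd = state.joint.qdot.copy()
        a = state.activation.copy()
        l = np.empty(N_MUSCLES)
        ld = np.empty(N_MUSCLES)
        f = np.empty(N_MUSCLES)
        c = self.config
        _arm_step_kernel(q, qd, a, l, ld, f, u,
                         self.Fmax, self.l0, self.lref, self.cospenn,
                         self.tau_act, self.tau_deact, self.R, self.q_ref,
                         FL_WIDTH, VMAX_REL, KP_PASSIVE, _PASSIVE_NORM,
                         fx, fy, c.l1, c.l2, c.m1, c.m2, c.lc1, c.lc2,
                         c.I1, c.I2, c.gravity, c.damping,
                         self.lim_lo, self.lim_hi, dt)
        for name, arr in (("q", q), ("qd", qd), ("activation", a), ("force", f)):
            if not np.all(np.isfinite(arr)):
                raise NumericalDivergenceError(f"non-finite {name} after arm step")
        return ArmState(joint=JointState(q, qd), l_m=l, ldot_m=ld,
                        activation=a, excitation=u, force=f)

    def hand_jacobian(self, joint: JointState) -> np.ndarray:
        q1, q2 = joint.q
        c = self.config
        return np.array([
            [c.l1 * np.cos(q1) + c.l2 * np.cos(q1 + q2), c.l2 * np.cos(q1 + q2)],
            [c.l1 * np.sin(q1) + c.l2 * np.sin(q1 + q2), c.l2 * np.sin(q1 + q2)],
        ])

    def mechanical_energy(self, state: ArmState) -> float:
        """Kinetic + gravitational + muscle elastic potential energy (J).

        The elastic term integrates the passive force-length curve, so with
        zero activation and non-negative joint damping this quantity is
        non-increasing along trajectories.
        """
        c = self.config
        q1, q2 = state.joint.q
        qd = state.joint.qdot
        c2 = np.cos(q2)
        M11 = c.I1 + c.I2 + c.m1 * c.lc1**2 + c.m2 * (
            c.l1**2 + c.lc2**2 + 2 * c.l1 * c.lc2 * c2)
        M12 = c.I2 + c.m2 * (c.lc2**2 + c.l1 * c.lc2 * c2)
        M22 = c.I2 + c.m2 * c.lc2**2
        ke = 0.5 * (M11 * qd[0]**2 + 2 * M12 * qd[0] * qd[1] + M22 * qd[1]**2)
        pe = -(c.m1 * c.lc1 + c.m2 * c.l1) * c.gravity * np.cos(q1) \
             - c.m2 * c.lc2 * c.gravity * np.cos(q1 + q2)
        ln = state.l_m / self.l0
        x = np.maximum(ln - 1.0, 0.0)
        elastic = np.sum(self.Fmax * self.cospenn * self.l0 * _PASSIVE_NORM *
                         ((np.exp(KP_PASSIVE * x) - 1.0) / KP_PASSIVE - x))
        return float(ke + pe + elastic)
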