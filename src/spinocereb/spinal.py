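"""Rate-based spinal circuit: stretch reflex and reciprocal inhibition.

One motoneuron (MN) per muscle integrates three inputs: the descending
cerebellar drive (M_f or M_e for its joint), a monosynaptic excitatory input
from its own muscle's Ia afferent (stretch reflex, SR), and a disynaptic
inhibitory input from the Ia interneuron (Ia IN) driven by the antagonist
muscle's Ia afferent (reciprocal inhibition, RI).  Antagonist Ia INs also
inhibit each other.  Every neuron follows the leaky rate equation

    tau dr/dt = -r + sigma(sum_i w_i r_i(t - tau_i)),

with sigma a steep sigmoid centred at 0.5 (on-off behaviour), excitatory
weights 1.0, inhibitory weights 0.5, and a stretch-reflex feedback delay
tau_i of 30 ms.  The muscle excitation handed to the plant is u = sigma(r_MN).

Ia afferent firing follows Prochazka's spindle model (lengths in mm,
velocities in mm/s):

    r_Ia = sgn(ldot) * 4.3 * max(|ldot|, 0.01)^0.6 + 2 (l - l0) + 10

giving the physiological 10 Hz baseline at rest; rates are normalised by a
per-task maximum r_Ia,max before entering the circuit.

Variants: ``full`` (SR + RI), ``sr`` (stretch reflex only), ``ri``
(reciprocal inhibition only) and ``bypass`` (descending commands applied
directly as muscle excitations, no spinal dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .arm import N_MUSCLES

VARIANTS = ("full", "sr", "ri", "bypass")

# Antagonist pairing over the eight muscles (index into MUSCLE_NAMES):
# DELTant<->DELTpost, BIClong<->TRIlong, BICshort<->TRIlat, BRA<->TRImed.
ANTAGONIST = np.array([1, 0, 5, 6, 7, 2, 3, 4], dtype=np.int64)


@dataclass(frozen=True)
class SpinalParams:
    tau: float = 0.001        # neuron time constant, s
    D: float = 8.0            # sigmoid steepness
    w_exc: float = 1.0
    w_inh: float = 0.5
    tau_i: float = 0.030      # stretch-reflex feedback delay, s
    ia_gain_vel: float = 4.3  # Prochazka velocity gain (mm/s domain)
    ia_exp_vel: float = 0.6
    ia_gain_len: float = 2.0  # per mm of stretch
    ia_baseline: float = 10.0  # Hz at rest
    ia_vel_floor: float = 0.01  # mm/s floor inside the power law
    r_ia_max: float = 60.0    # normalising maximum, Hz (per-task, see helpers)

    def __post_init__(self):
        if self.tau <= 0 or self.D <= 0 or self.r_ia_max <= 0:
            raise ValueError("tau, D and r_ia_max must be positive")
        if self.w_inh > self.w_exc:
            raise ValueError("w_inh must not exceed w_exc")


def sigmoid(x, D: float = 8.0):
    """On-off neuron nonlinearity sigma(x) = 1 / (1 + exp(-D (x - 0.5)))."""
    return 1.0 / (1.0 + np.exp(-D * (np.asarray(x, dtype=float) - 0.5)))


def ia_rate(l_mm, ldot_mms, l0_mm, params: SpinalParams = None):
    """Prochazka Ia afferent rate (Hz) and its normalised value in [0, 1].

    Lengths in mm, velocities in mm/s.  At the reference length with zero
    velocity the model returns its 10 Hz baseline.
    """
    p = params or SpinalParams()
    l_mm = np.asarray(l_mm, dtype=float)
    ldot = np.asarray(ldot_mms, dtype=float)
    vel_term = np.sign(ldot) * p.ia_gain_vel * np.maximum(
        np.abs(ldot), p.ia_vel_floor) ** p.ia_exp_vel
    rate = vel_term + p.ia_gain_len * (l_mm - np.asarray(l0_mm, dtype=float)) \
        + p.ia_baseline
    norm = np.clip(rate / p.r_ia_max, 0.0, 1.0)
    return rate, norm


def neuron_rate_step(r, x, params: SpinalParams, dt: float):
    """One step of tau dr/dt = -r + sigma(x) for the already-summed input x.

    Uses the exponential-integrator update (exact for input held constant
    over the step), so stepping reproduces the closed-form relaxation
    r(t) = s + (r0 - s) exp(-t/tau) to machine precision.
    """
    if dt > params.tau:
        raise ValueError(f"dt={dt} must not exceed tau={params.tau}")
    s = sigmoid(x, params.D)
    return s + (r - s) * np.exp(-dt / params.tau)


@njit(cache=True)
def _ia_norm_kernel(l_mm, ldot, l0_mm, gain_v, exp_v, gain_l, base, floor,
                    r_max, out):
    for m in range(l_mm.shape[0]):
        v = ldot[m]
        av = abs(v)
        if av < floor:
            av = floor
        rate = np.sign(v) * gain_v * av ** exp_v \
            + gain_l * (l_mm[m] - l0_mm[m]) + base
        x = rate / r_max
        out[m] = min(max(x, 0.0), 1.0)


@njit(cache=True)
def _spinal_kernel(r_mn, r_iain, m_desc, ia_del, antag,
                   w_exc, w_inh, D, tau, dt, sr_on, ri_on, u_out):
    n = r_mn.shape[0]
    decay = np.exp(-dt / tau)
    iain_prev = r_iain.copy()
    for m in range(n):
        x_in = w_exc * ia_del[m] - w_inh * iain_prev[antag[m]]
        s_in = 1.0 / (1.0 + np.exp(-D * (x_in - 0.5)))
        r_iain[m] = s_in + (r_iain[m] - s_in) * decay
        x_mn = w_exc * m_desc[m]
        if sr_on:
            x_mn += w_exc * ia_del[m]
        if ri_on:
            x_mn -= w_inh * iain_prev[antag[m]]
        s_mn = 1.0 / (1.0 + np.exp(-D * (x_mn - 0.5)))
        r_mn[m] = s_mn + (r_mn[m] - s_mn) * decay
        u_out[m] = 1.0 / (1.0 + np.exp(-D * (r_mn[m] - 0.5)))


class SpinalCircuit:
    """Stateful spinal circuit with an internal Ia feedback delay line."""

    def __init__(self, params: SpinalParams = None, variant: str = "full",
                 dt: float = 0.001, l0_mm=None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.params = params or SpinalParams()
        self.variant = variant
        self.dt = dt
        self.l0_mm = (np.full(N_MUSCLES, 100.0) if l0_mm is None
                      else np.asarray(l0_mm, dtype=float))
        self.r_mn = np.zeros(N_MUSCLES)
        self.r_iain = np.zeros(N_MUSCLES)
        self.delay_steps = max(int(round(self.params.tau_i / dt)), 0)
        # ring buffer of normalised Ia rates; primed with the resting value
        _, rest = ia_rate(self.l0_mm, np.zeros(N_MUSCLES), self.l0_mm, self.params)
        self._buf = np.tile(rest, (self.delay_steps + 1, 1))
        self._head = 0

    def prime(self, l_mm, ldot_mms):
        """Fill the whole delay line with the Ia rates of one feedback sample."""
        _, norm = ia_rate(l_mm, ldot_mms, self.l0_mm, self.params)
        self._buf[:] = norm
        self._head = 0

    def _push_feedback(self, l_mm, ldot_mms) -> np.ndarray:
        """Insert current feedback, return the tau_i-delayed normalised rates."""
        p = self.params
        _ia_norm_kernel(l_mm, ldot_mms, self.l0_mm, p.ia_gain_vel,
                        p.ia_exp_vel, p.ia_gain_len, p.ia_baseline,
                        p.ia_vel_floor, p.r_ia_max, self._buf[self._head])
        self._head = (self._head + 1) % (self.delay_steps + 1)
        return self._buf[self._head]

    def step(self, m_desc, l_mm, ldot_mms, dt: float = None) -> np.ndarray:
        """Advance the circuit one timestep and return muscle excitations.

        ``m_desc`` is the per-muscle descending command (already mapped from
        the per-joint M_f/M_e pair); ``l_mm``/``ldot_mms`` is the *current*
        muscle feedback, delayed internally by tau_i.
        """
        dt = self.dt if dt is None else dt
        m_desc = np.asarray(m_desc, dtype=float)
        if m_desc.shape != (N_MUSCLES,):
            raise ValueError(f"need {N_MUSCLES} descending commands")
        if self.variant == "bypass":
            return np.clip(m_desc, 0.0, 1.0)
        ia_del = self._push_feedback(l_mm, ldot_mms)
        p = self.params
        u = np.empty(N_MUSCLES)
        _spinal_kernel(self.r_mn, self.r_iain, m_desc, ia_del, ANTAGONIST,
                       p.w_exc, p.w_inh, p.D, p.tau, dt,
                       self.variant in ("full", "sr"),
                       self.variant in ("full", "ri"), u)
        return u


def descending_commands(m_flex, m_ext, moment_arms) -> np.ndarray:
    """Map per-joint (M_f, M_e) pairs to per-muscle descending drives.

    Single-joint flexors get their joint's M_f, extensors M_e; biarticular
    muscles receive the mean of their two joints' commands.
    """
    m_flex = np.asarray(m_flex, dtype=float)
    m_ext = np.asarray(m_ext, dtype=float)
    out = np.zeros(moment_arms.shape[0])
    for m in range(moment_arms.shape[0]):
        acc, cnt = 0.0, 0
        for j in range(moment_arms.shape[1]):
            r = moment_arms[m, j]
            if r > 0:
                acc += m_flex[j]
                cnt += 1
            elif r < 0:
                acc += m_ext[j]
                cnt += 1
        out[m] = acc / cnt if cnt else 0.0
    return out


def compute_r_ia_max(arm_model, traj, params: SpinalParams = None,
                     pad: float = 0.10, vel_scale: float = 3.0) -> float:
    """Per-task Ia normalising maximum: max Prochazka rate over the
    trajectory's muscle-kinematics envelope, padded by ``pad``.

    ``vel_scale`` inflates the velocity envelope, since actual movements
    overshoot the desired profile before learning converges; normalising
    against the inflated envelope keeps the stretch-reflex loop gain below
    the oscillation threshold of the delayed feedback loop.
    """
    p = params or SpinalParams()
    rates = []
    for i in range(len(traj)):
        l, ld = arm_model.muscle_kinematics(traj.sample(i))
        r, _ = ia_rate(l * 1e3, ld * 1e3 * vel_scale, arm_model.l0 * 1e3, p)
        rates.append(np.max(r))
    return float(max(rates) * (1.0 + pad))
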