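"""Clock-driven spiking cerebellar network with CF-gated GC-PC plasticity.

Architecture (MF -> GC -> PC -> DCN, with CF teaching input):

* Mossy fibres (MFs) carry four sensorimotor signals per controlled joint
  (desired position/velocity, actual position/velocity).  Each signal is
  place-coded over ``n_mf_per_signal`` fibres covering its working range, so
  exactly one MF per signal -- four per microcomplex -- is active at each
  timestep.
* Granule cells (GCs) each receive a unique combination of one MF per input
  signal within their microcomplex, recoding the sensory state univocally:
  a single GC matches the full active-MF combination at any instant.
* Purkinje cells (PCs) receive excitatory parallel-fibre (PF) input from all
  GCs through the plastic weight matrix W, and one climbing fibre (CF) each.
* Deep cerebellar nuclei (DCN) neurons receive one-to-one PC inhibition,
  baseline MF excitation and one-to-one CF excitation (AMPA + NMDA); their
  region-averaged firing rate is decoded into the motor commands M_f / M_e.

The network is organised in one microcomplex per joint, each split into an
agonist (flexor) and an antagonist (extensor) region of the PC-CF-DCN loop.

Plasticity at GC-PC synapses: every PF spike potentiates its synapses by a
fixed ``alpha`` (LTP); every CF spike at PC j depresses w[:, j] by ``|beta|``
times an eligibility trace -- a delayed-peak (difference-of-exponentials)
kernel applied to each GC's recent spikes -- so the instructive signal
credits the PF activity that caused the error one sensorimotor loop delay
earlier.  Weights are clipped to [0, 15] nS.

All neurons are conductance-based leaky integrate-and-fire, stepped at 1 ms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from numba import njit

from .trajectory import JointState, N_JOINTS

SIGNALS_PER_MICROCOMPLEX = 4  # Q_d, Qdot_d, Q_a, Qdot_a
AGONIST, ANTAGONIST = 0, 1

# Fixed (non-plastic) synaptic weights, nS
W_MF_GC = 0.18
W_MF_DCN = 0.3
W_PC_DCN = 1.0
W_CF_PC = 0.0     # CF acts on PCs through plasticity gating, not conductance
W_CF_DCN_AMPA = 0.5
W_CF_DCN_NMDA = 0.25


class TopologyError(ValueError):
    pass


class CheckpointError(RuntimeError):
    pass


@dataclass(frozen=True)
class Topology:
    """Network sizes; defaults give the full two-joint configuration
    (80 MFs, 20000 GCs, 200 PCs/CFs/DCN)."""

    n_mf_per_signal: int = 10
    n_microcomplexes: int = N_JOINTS
    n_pc: int = 200

    @property
    def n_signals_per_microcomplex(self) -> int:
        return SIGNALS_PER_MICROCOMPLEX

    @property
    def n_mf(self) -> int:
        return self.n_microcomplexes * SIGNALS_PER_MICROCOMPLEX * self.n_mf_per_signal

    @property
    def n_gc(self) -> int:
        return self.n_microcomplexes * self.n_mf_per_signal ** SIGNALS_PER_MICROCOMPLEX

    @property
    def n_cf(self) -> int:
        return self.n_pc

    @property
    def n_dcn(self) -> int:
        return self.n_pc

    @property
    def n_regions(self) -> int:
        return self.n_microcomplexes * 2

    @property
    def pc_per_region(self) -> int:
        return self.n_pc // self.n_regions

    def validate(self) -> None:
        if self.n_mf_per_signal < 1:
            raise TopologyError("n_mf_per_signal must be >= 1")
        if self.n_pc % self.n_regions != 0:
            raise TopologyError(
                f"n_pc={self.n_pc} must divide evenly into "
                f"{self.n_regions} agonist/antagonist regions")

    def synapse_counts(self) -> dict:
        return {
            "mf_gc": SIGNALS_PER_MICROCOMPLEX * self.n_gc,
            "mf_dcn": self.n_mf * self.n_dcn,
            "gc_pc": self.n_gc * self.n_pc,
            "pc_dcn": self.n_pc,
            "cf_pc": self.n_pc,
            "cf_dcn_ampa": self.n_pc,
            "cf_dcn_nmda": self.n_pc,
        }

    def hash(self) -> str:
        s = f"{self.n_mf_per_signal},{self.n_microcomplexes},{self.n_pc}"
        return hashlib.md5(s.encode()).hexdigest()


@dataclass(frozen=True)
class LIFParams:
    """Conductance-based LIF constants (mV, nS, s).  The published neuron
    table was not available, so these are conventional values chosen to make
    each stage functional; every field is overridable."""

    tau_m: float = 0.010
    g_leak: float = 4.0       # nS; membrane capacitance is g_leak * tau_m
    E_L: float = -70.0
    V_th: float = -50.0
    V_reset: float = -70.0
    t_ref: float = 0.002
    E_exc: float = 0.0
    E_inh: float = -85.0
    tau_ampa: float = 0.002
    tau_gaba: float = 0.010
    tau_nmda: float = 0.030

    def __post_init__(self):
        if self.V_th <= self.E_L:
            raise ValueError("threshold must exceed resting potential")
        if min(self.tau_m, self.tau_ampa, self.tau_gaba, self.tau_nmda,
               self.g_leak) <= 0:
            raise ValueError("time constants and g_leak must be positive")

    def pack(self, dt: float) -> np.ndarray:
        """Flatten into the kernel parameter vector."""
        C = self.g_leak * self.tau_m * 1e3  # pF (nS * ms)
        return np.array([
            self.g_leak, self.E_L, self.V_th, self.V_reset,
            round(self.t_ref / dt), self.E_exc, self.E_inh, C,
            np.exp(-dt / self.tau_ampa), np.exp(-dt / self.tau_gaba),
            np.exp(-dt / self.tau_nmda),
        ])


def default_lif_params() -> dict:
    return {
        # GCs: small, fast; tuned so 4 coincident active MF afferents are
        # suprathreshold but 3 are not (combinatorial selectivity).
        "gc": LIFParams(tau_m=0.005, g_leak=4.0, V_th=-50.0, t_ref=0.002,
                        tau_ampa=0.002),
        # PCs: graded firing over the plastic weight range, near-silent
        # when their PF synapses are fully depressed.
        "pc": LIFParams(tau_m=0.010, g_leak=4.5, V_th=-52.0, t_ref=0.002,
                        tau_ampa=0.005),
        # DCN: tonically driven by MFs, slow strong PC inhibition so that
        # Purkinje firing gates the output range (disinhibition control).
        "dcn": LIFParams(tau_m=0.010, g_leak=2.0, V_th=-50.0, t_ref=0.003,
                         tau_ampa=0.002, tau_gaba=0.050, tau_nmda=0.030),
    }


@dataclass(frozen=True)
class PlasticityParams:
    alpha: float = 0.006      # LTP increment per PF spike, nS
    beta: float = -0.003      # LTD scale per CF spike, nS (negative)
    kernel_tau_rise: float = 0.050   # eligibility kernel rise, s
    kernel_tau_decay: float = 0.250  # eligibility kernel decay, s
    kernel_gain: float = 2.5  # kernel peak value (eligibility per past spike)
    w_min: float = 0.0
    w_max: float = 15.0
    init_low: float = 4.3
    init_high: float = 5.2
    init_homogeneous: float = 4.8

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta >= 0:
            raise ValueError("beta must be negative")
        if self.kernel_tau_decay <= self.kernel_tau_rise:
            raise ValueError("kernel decay must exceed rise time constant")

    @property
    def kernel_peak_time(self) -> float:
        t1, t2 = self.kernel_tau_decay, self.kernel_tau_rise
        return np.log(t1 / t2) * t1 * t2 / (t1 - t2)

    @property
    def kernel_peak_norm(self) -> float:
        """Scale making the kernel peak equal ``kernel_gain``.

        The gain sets the LTD/LTP balance: larger values let a CF spike
        cancel more accumulated LTP, lowering the residual teaching-signal
        rate at the learning equilibrium.
        """
        tp = self.kernel_peak_time
        return self.kernel_gain / (np.exp(-tp / self.kernel_tau_decay)
                                   - np.exp(-tp / self.kernel_tau_rise))


@dataclass(frozen=True)
class ClimbingFiberParams:
    max_rate: float = 10.0   # Hz, complex-spike ceiling
    eps_sat: float = 1.0     # |instructive signal| at which the rate saturates


@dataclass(frozen=True)
class DecoderParams:
    tau_smooth: float = 0.250  # s, exponential smoothing of region rates
    max_rate: float = 250.0    # Hz, region mean rate mapping to M = 1


@dataclass
class WorkingRanges:
    """Per-joint position/velocity ranges the MF place code covers."""

    pos_lo: np.ndarray
    pos_hi: np.ndarray
    vel_lo: np.ndarray
    vel_hi: np.ndarray

    @classmethod
    def from_trajectory(cls, traj, pad: float = 0.10) -> "WorkingRanges":
        def padded(lo, hi):
            span = np.maximum(hi - lo, 1e-6)
            return lo - pad * span, hi + pad * span
        plo, phi = padded(traj.q.min(axis=0), traj.q.max(axis=0))
        vlo, vhi = padded(traj.qd.min(axis=0), traj.qd.max(axis=0))
        return cls(pos_lo=plo, pos_hi=phi, vel_lo=vlo, vel_hi=vhi)


def instructive_signal(desired: JointState, actual: JointState,
                       k_p: float = 3.0, k_v: float = 1.0) -> np.ndarray:
    """Per-joint teaching signal eps = K_p (Q_d - Q_a) + K_v (Qd_d - Qd_a)."""
    return k_p * (desired.q - actual.q) + k_v * (desired.qdot - actual.qdot)


@njit(cache=True)
def _lif_pop_step(v, g_a, g_g, g_n, ref, drive_a, drive_g, drive_n,
                  par, dt, spikes):
    """One LIF step for a population; ``drive_*`` are conductance increments
    (weight sums of presynaptic spikes) applied before integration."""
    gL, EL, Vth, Vres = par[0], par[1], par[2], par[3]
    ref_steps = int(par[4])
    Eex, Einh, C = par[5], par[6], par[7]
    da, dg, dn = par[8], par[9], par[10]
    dt_ms = dt * 1e3
    for i in range(v.shape[0]):
        g_a[i] = g_a[i] * da + drive_a[i]
        g_g[i] = g_g[i] * dg + drive_g[i]
        g_n[i] = g_n[i] * dn + drive_n[i]
        if ref[i] > 0:
            ref[i] -= 1
            v[i] = Vres
            spikes[i] = False
            continue
        I = (gL * (EL - v[i]) + g_a[i] * (Eex - v[i])
             + g_g[i] * (Einh - v[i]) + g_n[i] * (Eex - v[i]))
        v[i] += dt_ms * I / C
        if v[i] >= Vth:
            v[i] = Vres
            ref[i] = ref_steps
            spikes[i] = True
        else:
            spikes[i] = False


@njit(cache=True)
def _gc_drive(gc_mf, active_mf, gc_per_mc, w, out):
    """AMPA increment per GC: w times the number of its four afferent MFs
    present in the active set (one active MF per signal, so only the
    matching signal slot of the GC's own microcomplex needs checking)."""
    n_sig = SIGNALS_PER_MICROCOMPLEX
    for i in range(gc_mf.shape[0]):
        mc = i // gc_per_mc
        cnt = 0
        for k in range(n_sig):
            if gc_mf[i, k] == active_mf[mc * n_sig + k]:
                cnt += 1
        out[i] = w * cnt


@njit(cache=True)
def _encode_mossy_kernel(qdes, qddes, qact, qdact, pos_lo, pos_hi,
                         vel_lo, vel_hi, per, out):
    n_mc = qdes.shape[0]
    for mc in range(n_mc):
        base = mc * SIGNALS_PER_MICROCOMPLEX * per
        for s in range(SIGNALS_PER_MICROCOMPLEX):
            if s == 0:
                v, lo, hi = qdes[mc], pos_lo[mc], pos_hi[mc]
            elif s == 1:
                v, lo, hi = qddes[mc], vel_lo[mc], vel_hi[mc]
            elif s == 2:
                v, lo, hi = qact[mc], pos_lo[mc], pos_hi[mc]
            else:
                v, lo, hi = qdact[mc], vel_lo[mc], vel_hi[mc]
            width = (hi - lo) / per
            b = int(np.floor((v - lo) / width))
            if b < 0:
                b = 0
            elif b > per - 1:
                b = per - 1
            out[mc * SIGNALS_PER_MICROCOMPLEX + s] = base + s * per + b


@njit(cache=True)
def _pc_drive(W, gc_spikes, out):
    out[:] = 0.0
    for i in range(gc_spikes.shape[0]):
        if gc_spikes[i]:
            for j in range(W.shape[1]):
                out[j] += W[i, j]


def build_network(topology: Topology = None, lif: dict = None,
                  plasticity: PlasticityParams = None, seed: int = 0,
                  weight_init: str = "random", cf: ClimbingFiberParams = None,
                  decoder: DecoderParams = None) -> "CerebellarNetwork":
    """Construct a wired cerebellar network (deterministic given ``seed``)."""
    return CerebellarNetwork(topology=topology, lif=lif, plasticity=plasticity,
                             seed=seed, weight_init=weight_init, cf=cf,
                             decoder=decoder)


class CerebellarNetwork:
    """Stateful spiking cerebellar model for the two-joint control loop."""

    def __init__(self, topology: Topology = None, lif: dict = None,
                 plasticity: PlasticityParams = None, seed: int = 0,
                 weight_init: str = "random", cf: ClimbingFiberParams = None,
                 decoder: DecoderParams = None, dt: float = 0.001):
        self.top = topology or Topology()
        self.top.validate()
        self.lif = dict(default_lif_params())
        if lif:
            self.lif.update(lif)
        self.plast = plasticity or PlasticityParams()
        self.cf_params = cf or ClimbingFiberParams()
        self.dec = decoder or DecoderParams()
        self.seed = int(seed)
        self.dt = float(dt)
        self.rng = np.random.default_rng(self.seed)

        t = self.top
        # --- wiring ------------------------------------------------------
        # GC afferents: within each microcomplex, one MF per signal, all
        # combinations enumerated (unique by construction).
        per = t.n_mf_per_signal
        combos = np.stack(np.meshgrid(*([np.arange(per)] * SIGNALS_PER_MICROCOMPLEX),
                                      indexing="ij"), axis=-1).reshape(-1, 4)
        gc_mf = np.empty((t.n_gc, SIGNALS_PER_MICROCOMPLEX), dtype=np.int64)
        for mc in range(t.n_microcomplexes):
            base = mc * SIGNALS_PER_MICROCOMPLEX * per
            rows = slice(mc * per**4, (mc + 1) * per**4)
            gc_mf[rows] = combos + base + np.arange(4) * per
        self.gc_mf = gc_mf
        # PC/CF/DCN regions: contiguous blocks, region id = mc*2 + side
        self.region_of = np.repeat(np.arange(t.n_regions), t.pc_per_region)
        self.region_slices = [
            slice(r * t.pc_per_region, (r + 1) * t.pc_per_region)
            for r in range(t.n_regions)
        ]
        # --- plastic weights --------------------------------------------
        if weight_init == "random":
            self.W = self.rng.uniform(self.plast.init_low, self.plast.init_high,
                                      size=(t.n_gc, t.n_pc))
        elif weight_init == "homogeneous":
            self.W = np.full((t.n_gc, t.n_pc), self.plast.init_homogeneous)
        else:
            raise ValueError("weight_init must be 'random' or 'homogeneous'")
        self.W_init = self.W.copy()
        # --- packed LIF params ------------------------------------------
        self._par = {k: p.pack(self.dt) for k, p in self.lif.items()}
        self.ranges: WorkingRanges = None
        self._d1 = np.exp(-self.dt / self.plast.kernel_tau_decay)
        self._d2 = np.exp(-self.dt / self.plast.kernel_tau_rise)
        self._elig_norm = self.plast.kernel_peak_norm
        self.reset_state()

    # ------------------------------------------------------------------
    def reset_state(self) -> None:
        t = self.top
        lif = self.lif
        init_rng = np.random.default_rng(self.seed + 1)

        def pop(n, p):
            # membrane potentials start spread over the subthreshold range:
            # desynchronises otherwise phase-locked spike volleys, so
            # population rates vary smoothly with synaptic weight
            v0 = p.E_L + 0.95 * (p.V_th - p.E_L) * init_rng.random(n)
            return {
                "v": v0, "ga": np.zeros(n), "gg": np.zeros(n),
                "gn": np.zeros(n), "ref": np.zeros(n, dtype=np.int64),
                "spk": np.zeros(n, dtype=np.bool_),
            }

        self._gc = pop(t.n_gc, lif["gc"])
        self._pc = pop(t.n_pc, lif["pc"])
        self._dcn = pop(t.n_dcn, lif["dcn"])
        self._e1 = np.zeros(t.n_gc)
        self._e2 = np.zeros(t.n_gc)
        self._m_smooth = np.zeros(t.n_regions)
        self._step_count = 0
        self._zeros_pc = np.zeros(t.n_pc)
        self._zeros_gc = np.zeros(t.n_gc)
        self._gc_drive_buf = np.zeros(t.n_gc)
        self._pc_drive_buf = np.zeros(t.n_pc)
        self._active_buf = np.empty(t.n_microcomplexes *
                                    SIGNALS_PER_MICROCOMPLEX, dtype=np.int64)
        self._cf_buf = np.zeros(t.n_cf, dtype=np.bool_)
        self._dcn_a_buf = np.empty(t.n_dcn)
        self._dcn_g_buf = np.empty(t.n_dcn)
        self._dcn_n_buf = np.empty(t.n_dcn)
        # flat (M_f joints..., M_e joints...) ordering for the motor buffer
        self._m_order = np.array(
            [mc * 2 + AGONIST for mc in range(t.n_microcomplexes)]
            + [mc * 2 + ANTAGONIST for mc in range(t.n_microcomplexes)])

    def set_working_ranges(self, ranges: WorkingRanges) -> None:
        self.ranges = ranges

    # ------------------------------------------------------------------
    def encode_mossy(self, desired: JointState, actual: JointState) -> np.ndarray:
        """Active MF global indices: one per signal per microcomplex.

        Each signal is discretised into ``n_mf_per_signal`` half-open uniform
        bins [lo, hi) over its working range; out-of-range values clamp to
        the edge bins.
        """
        if self.ranges is None:
            raise RuntimeError("working ranges not set; call set_working_ranges")
        r = self.ranges
        active = np.empty(self.top.n_microcomplexes * SIGNALS_PER_MICROCOMPLEX,
                          dtype=np.int64)
        _encode_mossy_kernel(desired.q, desired.qdot, actual.q, actual.qdot,
                             r.pos_lo, r.pos_hi, r.vel_lo, r.vel_hi,
                             self.top.n_mf_per_signal, active)
        return active

    def encode_climbing(self, eps: np.ndarray, rng=None) -> np.ndarray:
        """Sample CF spikes for the current timestep from the teaching signal.

        |eps| maps through a saturating ramp to a per-step spike probability
        (ceiling ``max_rate``); the sign routes spikes to the agonist
        (eps > 0) or antagonist (eps < 0) region of the joint's microcomplex.
        """
        rng = rng or self.rng
        t = self.top
        spikes = np.zeros(t.n_cf, dtype=np.bool_)
        p_max = self.cf_params.max_rate * self.dt
        for mc in range(t.n_microcomplexes):
            e = eps[mc]
            if e == 0.0:
                continue
            p = p_max * min(abs(e) / self.cf_params.eps_sat, 1.0)
            side = AGONIST if e > 0 else ANTAGONIST
            sl = self.region_slices[mc * 2 + side]
            n = sl.stop - sl.start
            spikes[sl] = rng.random(n) < p
        return spikes

    # ------------------------------------------------------------------
    def lif_step(self, active_mf: np.ndarray, cf_spikes: np.ndarray,
                 dt: float = None):
        """Advance GC, PC and DCN populations one step; returns spike masks."""
        dt = self.dt if dt is None else dt
        if dt > 0.001 + 1e-12:
            raise ValueError("neural stepping requires dt <= 1 ms")
        t = self.top
        gc, pc, dcn = self._gc, self._pc, self._dcn
        _gc_drive(self.gc_mf, active_mf, t.n_mf_per_signal ** 4, W_MF_GC,
                  self._gc_drive_buf)
        _lif_pop_step(gc["v"], gc["ga"], gc["gg"], gc["gn"], gc["ref"],
                      self._gc_drive_buf, self._zeros_gc, self._zeros_gc,
                      self._par["gc"], dt, gc["spk"])
        _pc_drive(self.W, gc["spk"], self._pc_drive_buf)
        # CF->PC synapses exist but carry zero conductance weight
        if W_CF_PC != 0.0:
            self._pc_drive_buf += W_CF_PC * cf_spikes
        _lif_pop_step(pc["v"], pc["ga"], pc["gg"], pc["gn"], pc["ref"],
                      self._pc_drive_buf, self._zeros_pc, self._zeros_pc,
                      self._par["pc"], dt, pc["spk"])
        n_active = int((active_mf >= 0).sum())  # all MF->DCN, all-to-all
        np.multiply(cf_spikes, W_CF_DCN_AMPA, out=self._dcn_a_buf,
                    casting="unsafe")
        self._dcn_a_buf += W_MF_DCN * n_active
        np.multiply(pc["spk"], W_PC_DCN, out=self._dcn_g_buf,
                    casting="unsafe")
        np.multiply(cf_spikes, W_CF_DCN_NMDA, out=self._dcn_n_buf,
                    casting="unsafe")
        _lif_pop_step(dcn["v"], dcn["ga"], dcn["gg"], dcn["gn"], dcn["ref"],
                      self._dcn_a_buf, self._dcn_g_buf, self._dcn_n_buf,
                      self._par["dcn"], dt, dcn["spk"])
        # conductance-based LIF keeps v between the reversal potentials, so
        # divergence is pathological; audit periodically rather than per step
        self._step_count += 1
        if self._step_count % 50 == 0:
            for name, p in (("gc", gc), ("pc", pc), ("dcn", dcn)):
                if not np.isfinite(p["v"]).all():
                    raise FloatingPointError(
                        f"non-finite membrane state in {name}")
        return gc["spk"], pc["spk"], dcn["spk"]

    def stdp_update(self, gc_spikes: np.ndarray, cf_spikes: np.ndarray) -> None:
        """Apply LTP for this step's PF spikes and CF-gated LTD.

        Must be called every step (also with plasticity conceptually "on")
        so the eligibility traces track PF history; use
        :meth:`eligibility_step` alone to advance traces without learning.
        """
        idx = np.nonzero(gc_spikes)[0]
        self._e1 *= self._d1
        self._e2 *= self._d2
        if idx.size:
            self._e1[idx] += 1.0
            self._e2[idx] += 1.0
            rows = self.W[idx, :]
            rows += self.plast.alpha
            np.minimum(rows, self.plast.w_max, out=rows)
            self.W[idx, :] = rows
        cf_idx = np.nonzero(cf_spikes)[0]
        if cf_idx.size:
            elig = self._elig_norm * (self._e1 - self._e2)
            cols = self.W[:, cf_idx]
            cols += self.plast.beta * elig[:, None]
            np.clip(cols, self.plast.w_min, self.plast.w_max, out=cols)
            self.W[:, cf_idx] = cols

    def eligibility_step(self, gc_spikes: np.ndarray) -> None:
        self._e1 *= self._d1
        self._e2 *= self._d2
        idx = np.nonzero(gc_spikes)[0]
        if idx.size:
            self._e1[idx] += 1.0
            self._e2[idx] += 1.0

    def eligibility(self) -> np.ndarray:
        """Current kernel-weighted PF spike history per GC."""
        return self._elig_norm * (self._e1 - self._e2)

    def decode_dcn(self, dcn_spikes: np.ndarray, dt: float = None):
        """Exponentially smoothed region rates normalised to [0, 1].

        Returns ``(M_f, M_e)`` arrays over joints (agonist region -> M_f,
        antagonist -> M_e).
        """
        dt = self.dt if dt is None else dt
        t = self.top
        counts = np.bincount(self.region_of[dcn_spikes], minlength=t.n_regions)
        inst = counts / (t.pc_per_region * dt)  # Hz, region mean
        k = dt / self.dec.tau_smooth
        self._m_smooth += k * (inst - self._m_smooth)
        m = np.clip(self._m_smooth / self.dec.max_rate, 0.0, 1.0)
        m2 = m.reshape(t.n_microcomplexes, 2)
        return m2[:, AGONIST].copy(), m2[:, ANTAGONIST].copy()

    def step(self, desired: JointState, actual: JointState,
             eps: np.ndarray = None, plasticity_on: bool = True):
        """Full per-timestep update: encode -> LIF -> plasticity -> decode."""
        if eps is None:
            eps = instructive_signal(desired, actual)
        m = self.step_arrays(desired.q, desired.qdot, actual.q, actual.qdot,
                             eps, plasticity_on)
        n = self.top.n_microcomplexes
        return m[:n].copy(), m[n:].copy()

    def step_arrays(self, qdes, qddes, qact, qdact, eps,
                    plasticity_on: bool = True) -> np.ndarray:
        """Array-level fast path of :meth:`step`.

        Returns the flat motor command vector ordered
        ``(M_f per joint..., M_e per joint...)``; the returned array is a
        reused buffer, valid until the next call.
        """
        r = self.ranges
        if r is None:
            raise RuntimeError("working ranges not set; call set_working_ranges")
        active = self._active_buf
        _encode_mossy_kernel(qdes, qddes, qact, qdact, r.pos_lo, r.pos_hi,
                             r.vel_lo, r.vel_hi, self.top.n_mf_per_signal,
                             active)
        cf = self._cf_buf
        cf[:] = False
        p_max = self.cf_params.max_rate * self.dt
        for mc in range(self.top.n_microcomplexes):
            e = eps[mc]
            if e == 0.0:
                continue
            p = p_max * min(abs(e) / self.cf_params.eps_sat, 1.0)
            sl = self.region_slices[mc * 2 + (AGONIST if e > 0 else ANTAGONIST)]
            cf[sl] = self.rng.random(sl.stop - sl.start) < p
        gc_spk, pc_spk, dcn_spk = self.lif_step(active, cf)
        if plasticity_on:
            self.stdp_update(gc_spk, cf)
        else:
            self.eligibility_step(gc_spk)
        t = self.top
        counts = np.bincount(self.region_of[dcn_spk], minlength=t.n_regions)
        inst = counts * (1.0 / (t.pc_per_region * self.dt))
        self._m_smooth += (self.dt / self.dec.tau_smooth) * (inst - self._m_smooth)
        m = self._m_smooth[self._m_order]
        m *= 1.0 / self.dec.max_rate
        np.clip(m, 0.0, 1.0, out=m)
        return m

    # ------------------------------------------------------------------
    def save_checkpoint(self, path, trial: int = 0) -> None:
        np.savez(path, W=self.W, trial=trial, topology_hash=self.top.hash(),
                 seed=self.seed)

    def load_checkpoint(self, path) -> int:
        with np.load(path, allow_pickle=False) as z:
            if str(z["topology_hash"]) != self.top.hash():
                raise CheckpointError(
                    f"checkpoint topology hash {z['topology_hash']} does not "
                    f"match network topology {self.top.hash()}")
            self.W[:] = z["W"]
            return int(z["trial"])
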