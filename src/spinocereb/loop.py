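"""Closed-loop sensorimotor simulation with biological delays.

The loop couples the spiking cerebellum, the rate-based spinal circuit and
the Hill-muscle planar arm with the pathway latencies of the upper limb:
a 50 ms sensory delay on the state the cerebellum receives, 30 ms from
cerebellum to spinal cord, and 30 ms from spinal cord to muscles (total
motor delay 60 ms).  The stretch-reflex feedback delay (30 ms) lives inside
the spinal circuit itself.

Model variants:

* ``full``   -- spino-cerebellar: cerebellum + complete spinal circuit
* ``sr``     -- spinal circuit with the stretch reflex only
* ``ri``     -- spinal circuit with reciprocal inhibition only
* ``bypass`` -- cerebellar-only: cerebellar commands applied directly as
  muscle excitations (no spinal dynamics)

Trial protocol: a trial is one pass over the desired trajectory.  Between
trials the arm is reset to the trajectory start pose while neural membrane
states, synaptic weights and delay lines persist.  Motor adaptation runs
``n_trials`` consecutive trials with plasticity on; the perturbation
protocol freezes plasticity and interleaves perturbed and clean trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import arm as arm_mod
from . import cerebellum as cb
from . import spinal as sp
from .arm import ArmModel, ArmConfig, Perturbation, N_MUSCLES
from .cerebellum import CerebellarNetwork, Topology, WorkingRanges
from .metrics import CCI_GROUPS
from .spinal import SpinalCircuit, SpinalParams
from .trajectory import JointState, Trajectory, N_JOINTS

VARIANTS = ("full", "sr", "ri", "bypass")


@dataclass(frozen=True)
class LoopConfig:
    sensory_delay: float = 0.050
    cereb_to_sc_delay: float = 0.030
    sc_to_muscle_delay: float = 0.030
    dt: float = 0.001
    n_trials: int = 2000
    n_repetitions: int = 3
    seed: int = 0
    variant: str = "full"
    plasticity: bool = True
    weight_init: str = "random"
    snapshot_every: int = 200

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("sensory_delay", "cereb_to_sc_delay", "sc_to_muscle_delay"):
            d = getattr(self, name)
            if d < 0:
                raise ValueError(f"{name} must be >= 0")
            steps = d / self.dt
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(f"{name}={d} must be a multiple of dt={self.dt}")

    def delay_steps(self):
        return (round(self.sensory_delay / self.dt),
                round(self.cereb_to_sc_delay / self.dt),
                round(self.sc_to_muscle_delay / self.dt))


@dataclass
class TrialResult:
    """Per-step traces and per-trial summaries of one closed-loop trial."""

    t: np.ndarray = None
    q_d: np.ndarray = None
    qd_d: np.ndarray = None
    q_a: np.ndarray = None
    qd_a: np.ndarray = None
    eps: np.ndarray = None
    m_f: np.ndarray = None
    m_e: np.ndarray = None
    u: np.ndarray = None
    activation: np.ndarray = None
    mae_pos: float = 0.0
    mae_vel: float = 0.0
    cci_mean: np.ndarray = None  # per-joint trial-mean cocontraction index


@dataclass
class AdaptationResult:
    mae_pos: np.ndarray
    mae_vel: np.ndarray
    cci: np.ndarray              # (n_trials, n_joints) trial-mean CCI
    snapshots: list              # [(trial_index, W copy), ...]
    last_trial: TrialResult


@dataclass(frozen=True)
class PerturbationProtocol:
    perturbations: tuple
    trials_per_perturbation: int = 50
    clean_between: int = 3
    baseline_trials: int = 10

    def __post_init__(self):
        if self.trials_per_perturbation < 1 or self.baseline_trials < 1:
            raise ValueError("protocol counts must be >= 1")

    @classmethod
    def default_grid(cls, T: float, magnitude: float = 50.0,
                     duration: float = 0.030, **kw) -> "PerturbationProtocol":
        """4 in-plane directions x 3 onset phases (extended, mid, flexed)."""
        dirs = [(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0), (0.0, -1.0)]
        phases = [0.05, 0.25, 0.5]
        perts = tuple(
            Perturbation(magnitude=magnitude, direction=d,
                         onset=ph * T, duration=duration)
            for d in dirs for ph in phases
        )
        return cls(perturbations=perts, **kw)


class LoopModels:
    """Assembled cerebellum + spinal circuit + arm, ready to run trials."""

    def __init__(self, network: CerebellarNetwork, spinal_circuit: SpinalCircuit,
                 arm_model: ArmModel, config: LoopConfig, traj: Trajectory):
        self.network = network
        self.spinal = spinal_circuit
        self.arm = arm_model
        self.config = config
        self.traj = traj
        d_sens, d_desc, d_mot = config.delay_steps()
        q0, qd0 = traj.q[0], traj.qd[0]
        # delay lines, primed with the trial-start state
        self._sens_q = np.tile(q0, (d_sens + 1, 1))
        self._sens_qd = np.tile(qd0, (d_sens + 1, 1))
        self._sens_head = 0
        self._m_buf = np.zeros((d_desc + 1, 2 * N_JOINTS))
        self._m_head = 0
        self._u_buf = np.zeros((d_mot + 1, N_MUSCLES))
        self._u_head = 0
        # descending-command mixing matrix: u_desc = Wd @ [M_f; M_e]
        R = arm_model.R
        Wd = np.zeros((N_MUSCLES, 2 * N_JOINTS))
        for m in range(N_MUSCLES):
            cnt = np.count_nonzero(R[m])
            for j in range(N_JOINTS):
                if R[m, j] > 0:
                    Wd[m, j] = 1.0 / cnt
                elif R[m, j] < 0:
                    Wd[m, N_JOINTS + j] = 1.0 / cnt
        self._Wd = Wd
        # group-mean matrix for per-step CCI accumulation
        G = np.zeros((2 * N_JOINTS, N_MUSCLES))
        for j in range(N_JOINTS):
            fl, ex = CCI_GROUPS[j]
            G[2 * j, fl] = 1.0 / len(fl)
            G[2 * j + 1, ex] = 1.0 / len(ex)
        self._cci_G = G
        self.arm_state = arm_model.initial_state(q=q0, qdot=qd0)

    def reset_arm(self) -> None:
        self.arm_state = self.arm.initial_state(q=self.traj.q[0],
                                                qdot=self.traj.qd[0])


def build_models(traj: Trajectory, config: LoopConfig,
                 topology: Topology = None, arm_config: ArmConfig = None,
                 muscles=None, spinal_params: SpinalParams = None,
                 lif: dict = None, plasticity_params=None) -> LoopModels:
    """Wire up all components for a task: working ranges for the MF code and
    the Ia normalising maximum are derived from the task trajectory."""
    arm_model = ArmModel(arm_config, muscles)
    network = cb.build_network(topology=topology, lif=lif,
                               plasticity=plasticity_params,
                               seed=config.seed, weight_init=config.weight_init)
    network.dt = config.dt
    network.set_working_ranges(WorkingRanges.from_trajectory(traj))
    params = spinal_params or SpinalParams()
    r_max = sp.compute_r_ia_max(arm_model, traj, params)
    params = replace(params, r_ia_max=r_max)
    variant = config.variant if config.variant != "full" else "full"
    circuit = SpinalCircuit(params=params, variant=variant, dt=config.dt,
                            l0_mm=arm_model.l0 * 1e3)
    return LoopModels(network, circuit, arm_model, config, traj)


def _push(buf, head, value):
    buf[head] = value
    head = (head + 1) % buf.shape[0]
    return head, buf[head]


def run_trial(models: LoopModels, perturbation: Perturbation = None,
              plasticity_on: bool = None, record: bool = True) -> TrialResult:
    """Run one pass over the task trajectory and return its traces.

    The arm is reset to the trajectory start pose first; neural states and
    delay lines carry over from any previous trial.
    """
    cfg = models.config
    traj = models.traj
    net = models.network
    arm_model = models.arm
    if plasticity_on is None:
        plasticity_on = cfg.plasticity
    n = len(traj)
    dt = cfg.dt
    d_sens = cfg.delay_steps()[0]

    models.reset_arm()
    st = models.arm_state
    q = st.joint.q.copy()
    qd = st.joint.qdot.copy()
    a = st.activation.copy()
    l = st.l_m.copy()
    ld = st.ldot_m.copy()
    f = st.force.copy()

    res = TrialResult()
    if record:
        res.t = traj.t.copy()
        res.q_d, res.qd_d = traj.q.copy(), traj.qd.copy()
        res.q_a = np.empty((n, N_JOINTS))
        res.qd_a = np.empty((n, N_JOINTS))
        res.eps = np.empty((n, N_JOINTS))
        res.m_f = np.empty((n, N_JOINTS))
        res.m_e = np.empty((n, N_JOINTS))
        res.u = np.empty((n, N_MUSCLES))
        res.activation = np.empty((n, N_MUSCLES))

    ac = arm_model.config
    err_pos_sum = 0.0
    err_vel_sum = 0.0
    # trial-mean CCI accumulators per joint (activation-based groupings)
    cci_sum = np.zeros(N_JOINTS)
    l_mm = np.empty(N_MUSCLES)
    ld_mm = np.empty(N_MUSCLES)
    kp, kv = 3.0, 1.0
    # hoisted hot-loop locals
    sens_q, sens_qd = models._sens_q, models._sens_qd
    sens_len = sens_q.shape[0]
    sens_head = models._sens_head
    m_buf, u_buf = models._m_buf, models._u_buf
    m_len, u_len = m_buf.shape[0], u_buf.shape[0]
    m_head, u_head = models._m_head, models._u_head
    Wd, cci_G = models._Wd, models._cci_G
    traj_q, traj_qd = traj.q, traj.qd
    step_arrays = net.step_arrays
    spinal_step = models.spinal.step

    for i in range(n):
        # --- sensing (50 ms delayed actual state; reference time-aligned)
        sens_q[sens_head] = q
        sens_qd[sens_head] = qd
        sens_head = (sens_head + 1) % sens_len
        sq = sens_q[sens_head]
        sqd = sens_qd[sens_head]
        j_ref = i - d_sens if i >= d_sens else 0
        dq, dqd = traj_q[j_ref], traj_qd[j_ref]

        eps = kp * (dq - sq) + kv * (dqd - sqd)
        m_flat = step_arrays(dq, dqd, sq, sqd, eps,
                             plasticity_on=plasticity_on)
        m_f, m_e = m_flat[:N_JOINTS], m_flat[N_JOINTS:]

        # --- descending delay (cerebellum -> spinal cord)
        m_buf[m_head] = m_flat
        m_head = (m_head + 1) % m_len
        m_desc = Wd @ m_buf[m_head]

        # --- spinal circuit (internal 30 ms Ia feedback delay)
        np.multiply(l, 1e3, out=l_mm)
        np.multiply(ld, 1e3, out=ld_mm)
        u = spinal_step(m_desc, l_mm, ld_mm)

        # --- motor delay (spinal cord -> muscles)
        u_buf[u_head] = u
        u_head = (u_head + 1) % u_len
        u_del = u_buf[u_head]

        # record the state the controls were computed from (sample i)
        tq, tqd = traj_q[i], traj_qd[i]
        err_pos_sum += (abs(tq[0] - q[0]) + abs(tq[1] - q[1])) * 0.5
        err_vel_sum += (abs(tqd[0] - qd[0]) + abs(tqd[1] - qd[1])) * 0.5
        gvals = models._cci_G @ a
        for j in range(N_JOINTS):
            flex, ext = gvals[2 * j], gvals[2 * j + 1]
            lo, hi = (flex, ext) if flex <= ext else (ext, flex)
            cci_sum[j] += 0.0 if hi == 0.0 else (lo / hi) * (lo + hi)
        if record:
            res.q_a[i] = q
            res.qd_a[i] = qd
            res.eps[i] = eps
            res.m_f[i] = m_f
            res.m_e[i] = m_e
            res.u[i] = u_del
            res.activation[i] = a

        force = perturbation.force_at(i * dt) if perturbation is not None \
            else None
        fx, fy = (0.0, 0.0) if force is None else (force[0], force[1])
        arm_mod._arm_step_kernel(
            q, qd, a, l, ld, f, u_del,
            arm_model.Fmax, arm_model.l0, arm_model.lref, arm_model.cospenn,
            arm_model.tau_act, arm_model.tau_deact, arm_model.R,
            arm_model.q_ref, arm_mod.FL_WIDTH, arm_mod.VMAX_REL,
            arm_mod.KP_PASSIVE, arm_mod._PASSIVE_NORM,
            fx, fy, ac.l1, ac.l2, ac.m1, ac.m2, ac.lc1, ac.lc2,
            ac.I1, ac.I2, ac.gravity, ac.damping,
            arm_model.lim_lo, arm_model.lim_hi, dt)

    models._sens_head = sens_head
    models._m_head = m_head
    models._u_head = u_head
    if not (np.isfinite(q).all() and np.isfinite(qd).all()):
        raise arm_mod.NumericalDivergenceError("non-finite arm state at trial end")
    models.arm_state = arm_mod.ArmState(
        joint=JointState(q, qd), l_m=l, ldot_m=ld, activation=a,
        excitation=np.clip(u, 0, 1), force=f)
    res.mae_pos = err_pos_sum / n
    res.mae_vel = err_vel_sum / n
    res.cci_mean = cci_sum / n
    return res


def run_adaptation(models: LoopModels, n_trials: int = None,
                   snapshot_every: int = None,
                   record_last: bool = True) -> AdaptationResult:
    """Run consecutive learning trials with persistent weights and buffers.

    Weight snapshots are taken at trial 0 (pre-learning) and every
    ``snapshot_every`` trials thereafter.
    """
    cfg = models.config
    n_trials = cfg.n_trials if n_trials is None else n_trials
    snapshot_every = cfg.snapshot_every if snapshot_every is None \
        else snapshot_every
    mae_pos = np.empty(n_trials)
    mae_vel = np.empty(n_trials)
    cci = np.empty((n_trials, N_JOINTS))
    snapshots = [(0, models.network.W.copy())]
    last = None
    for k in range(n_trials):
        rec = record_last and (k == n_trials - 1)
        tr = run_trial(models, record=rec)
        mae_pos[k] = tr.mae_pos
        mae_vel[k] = tr.mae_vel
        cci[k] = tr.cci_mean
        if rec:
            last = tr
        if (k + 1) % snapshot_every == 0:
            snapshots.append((k + 1, models.network.W.copy()))
    return AdaptationResult(mae_pos=mae_pos, mae_vel=mae_vel, cci=cci,
                            snapshots=snapshots, last_trial=last)


def run_perturbation_protocol(models: LoopModels, protocol: PerturbationProtocol,
                              checkpoint=None) -> dict:
    """Frozen-plasticity robustness protocol.

    Optionally loads a weight checkpoint (topology-hash checked) -- e.g.
    weights developed by the spino-cerebellar model, evaluated under the
    SR-only / RI-only / bypass variants.  For each perturbation spec,
    ``trials_per_perturbation`` perturbed trials are run with
    ``clean_between`` unperturbed trials interleaved.  Returns per-spec
    per-trial MAE arrays plus the unperturbed baseline means.
    """
    if checkpoint is not None:
        models.network.load_checkpoint(checkpoint)
    W_before = models.network.W.copy()
    base_pos = np.empty(protocol.baseline_trials)
    base_vel = np.empty(protocol.baseline_trials)
    for k in range(protocol.baseline_trials):
        tr = run_trial(models, plasticity_on=False, record=False)
        base_pos[k] = tr.mae_pos
        base_vel[k] = tr.mae_vel
    results = []
    for pert in protocol.perturbations:
        mp = np.empty(protocol.trials_per_perturbation)
        mv = np.empty(protocol.trials_per_perturbation)
        for k in range(protocol.trials_per_perturbation):
            tr = run_trial(models, perturbation=pert, plasticity_on=False,
                           record=False)
            mp[k] = tr.mae_pos
            mv[k] = tr.mae_vel
            if k < protocol.trials_per_perturbation - 1:
                for _ in range(protocol.clean_between):
                    run_trial(models, plasticity_on=False, record=False)
        results.append({"perturbation": pert, "mae_pos": mp, "mae_vel": mv})
    assert np.array_equal(W_before, models.network.W), \
        "plasticity must stay frozen during the perturbation protocol"
    return {
        "baseline_mae_pos": float(base_pos.mean()),
        "baseline_mae_vel": float(base_vel.mean()),
        "perturbed": results,
    }
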