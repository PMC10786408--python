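"""Deterministic synthetic data generators.

Everything here is synthetic stand-in data for testing and offline use: no
human recordings ship with the package.  Provided generators:

* :func:`synth_emg` -- multichannel surface-EMG-like signals: a band-limited
  noise carrier amplitude-modulated by bursts locked to movement phases,
  returned together with the ground-truth modulation envelope so envelope
  extraction can be checked against a known answer.
* :func:`passive_baseline` -- a zero-excitation drop of the arm recorded as
  a regression fixture, stamped with a hash of the arm configuration so
  stale fixtures fail loudly.
* :func:`toy_checkpoint` -- a short reduced-scale adaptation run saved as a
  loadable GC-PC weight checkpoint (enables the frozen-weight perturbation
  protocols in tests).

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .arm import ArmConfig, ArmModel, default_muscles, N_MUSCLES
from .cerebellum import Topology
from .trajectory import generate_flexion_extension


class StaleFixtureError(RuntimeError):
    """A stored fixture was generated under a different configuration."""


@dataclass(frozen=True)
class SyntheticEMGSpec:
    fs: float = 1259.3           # acquisition rate, Hz
    duration: float = 4.6        # s
    period: float = 2.3          # movement cycle, s
    n_channels: int = 4
    burst_phases: tuple = (0.1, 0.35, 0.6, 0.85)  # cycle fraction per channel
    burst_width: float = 0.08    # cycle fraction (Gaussian sigma)
    burst_amplitude: float = 1.0
    carrier_band: tuple = (20.0, 450.0)  # Hz
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 2 * self.carrier_band[1]:
            raise ValueError("fs must exceed twice the carrier band top")
        if self.burst_amplitude < 0 or self.noise_floor < 0:
            raise ValueError("amplitudes must be non-negative")
        if len(self.burst_phases) != self.n_channels:
            raise ValueError("need one burst phase per channel")


def synth_emg(spec: SyntheticEMGSpec = None):
    """Generate raw synthetic EMG and its ground-truth modulation envelope.

    Returns ``(raw, envelope)`` arrays of shape (n_samples, n_channels).
    """
    spec = spec or SyntheticEMGSpec()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    phase = (t / spec.period) % 1.0
    env = np.empty((n, spec.n_channels))
    for ch, ph in enumerate(spec.burst_phases):
        # circular distance to the burst centre, in cycle fractions
        d = np.abs(phase - ph)
        d = np.minimum(d, 1.0 - d)
        env[:, ch] = spec.noise_floor + spec.burst_amplitude * np.exp(
            -0.5 * (d / spec.burst_width) ** 2)
    white = rng.standard_normal((n, spec.n_channels))
    sos = sps.butter(4, spec.carrier_band, btype="band", fs=spec.fs,
                     output="sos")
    carrier = sps.sosfiltfilt(sos, white, axis=0)
    carrier /= carrier.std(axis=0)
    return env * carrier, env


def _config_hash(config: ArmConfig, muscles) -> str:
    payload = {
        "config": asdict(config),
        "muscles": [asdict(m) for m in muscles],
    }
    return hashlib.md5(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def passive_baseline(config: ArmConfig = None, duration: float = 1.0,
                     muscles=None, start_q=None) -> dict:
    """Record a zero-excitation arm drop as a regression fixture.

    Returns a dict with time, joint kinematics, mechanical energy and the
    arm-configuration hash.
    """
    config = config or ArmConfig()
    muscles = tuple(muscles) if muscles is not None else default_muscles()
    model = ArmModel(config, muscles)
    state = model.initial_state(q=start_q)
    n = int(round(duration / config.dt))
    q = np.empty((n + 1, 2))
    qd = np.empty((n + 1, 2))
    energy = np.empty(n + 1)
    q[0], qd[0] = state.joint.q, state.joint.qdot
    energy[0] = model.mechanical_energy(state)
    u = np.zeros(N_MUSCLES)
    for i in range(n):
        state = model.step(state, u)
        q[i + 1], qd[i + 1] = state.joint.q, state.joint.qdot
        energy[i + 1] = model.mechanical_energy(state)
    return {
        "t": np.arange(n + 1) * config.dt,
        "q": q, "qd": qd, "energy": energy,
        "config_hash": _config_hash(config, muscles),
    }


def save_passive_baseline(fixture: dict, path) -> None:
    np.savez(path, **fixture)


def load_passive_baseline(path, config: ArmConfig = None,
                          muscles=None) -> dict:
    """Load a stored drop fixture, verifying it matches the configuration."""
    config = config or ArmConfig()
    muscles = tuple(muscles) if muscles is not None else default_muscles()
    with np.load(path, allow_pickle=False) as z:
        data = {k: z[k] for k in z.files}
    if str(data["config_hash"]) != _config_hash(config, muscles):
        raise StaleFixtureError(
            "passive baseline fixture was generated under a different arm "
            "configuration; regenerate it")
    return data


def toy_checkpoint(topology: Topology, seed: int, path, n_trials: int = 30,
                   T: float = 2.3, dt: float = 0.001,
                   q_extended=(0.3, 0.4), q_flexed=(1.1, 1.6)):
    """Run a short reduced-scale adaptation and save the weights.

    Returns the :class:`~spinocereb.loop.LoopModels` used, with the
    checkpoint written to ``path``.
    """
    from .loop import LoopConfig, build_models, run_adaptation

    cfg = LoopConfig(n_trials=n_trials, seed=seed, variant="full",
                     dt=dt, snapshot_every=max(n_trials, 1))
    traj = generate_flexion_extension(np.asarray(q_flexed),
                                      np.asarray(q_extended), T, dt)
    models = build_models(traj, cfg, topology=topology)
    run_adaptation(models, n_trials=n_trials, record_last=False)
    models.network.save_checkpoint(path, trial=n_trials)
    return models
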