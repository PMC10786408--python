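"""Desired joint-space motor tasks for the two-joint arm.

The benchmark movements are flexion-extension cycles with bell-shaped joint
velocity profiles, the canonical kinematic signature of multi-joint reaching.
The bell shape is realised as a fifth-order minimum-jerk polynomial, and a
cyclic task is two back-to-back minimum-jerk segments (extend->flex,
flex->extend).  Recorded kinematics can be loaded from CSV with the dialect
documented in :func:`read_kinematics_csv`.

Joint ordering is fixed everywhere in the package: index 0 is the shoulder,
index 1 is the elbow; positions in rad, velocities in rad/s, time in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_JOINTS = 2
SHOULDER, ELBOW = 0, 1

CSV_COLUMNS = ["time", "q_shoulder", "q_elbow", "qd_shoulder", "qd_elbow"]


class TrajectoryFormatError(ValueError):
    """Raised when a kinematics CSV does not match the expected dialect."""


@dataclass(frozen=True)
class JointState:
    """Joint positions and velocities at one instant (shoulder, elbow)."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "qdot", np.asarray(self.qdot, dtype=float))
        if self.q.shape != (N_JOINTS,) or self.qdot.shape != (N_JOINTS,):
            raise ValueError(f"joint state must have {N_JOINTS} entries per field")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("joint state must be finite")


@dataclass
class Trajectory:
    """Uniformly sampled desired trajectory over one task period ``T``.

    ``q`` and ``qd`` are ``(n_samples, 2)`` arrays with
    ``n_samples == round(T / dt) + 1`` (both endpoints included).
    """

    dt: float
    T: float
    q: np.ndarray
    qd: np.ndarray
    t: np.ndarray = field(default=None)

    def __post_init__(self):
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.qd = np.atleast_2d(np.asarray(self.qd, dtype=float))
        n = round(self.T / self.dt) + 1
        if self.q.shape != (n, N_JOINTS) or self.qd.shape != (n, N_JOINTS):
            raise ValueError(
                f"expected {(n, N_JOINTS)} samples for T={self.T}, dt={self.dt}; "
                f"got q{self.q.shape}, qd{self.qd.shape}"
            )
        if self.t is None:
            self.t = np.arange(n) * self.dt

    @property
    def n_samples(self) -> int:
        return self.q.shape[0]

    def sample(self, i: int) -> JointState:
        return JointState(self.q[i], self.qd[i])

    def __len__(self) -> int:
        return self.n_samples


def _check_timing(T: float, dt: float) -> None:
    if not (T > 0 and dt > 0):
        raise ValueError(f"T and dt must be positive (got T={T}, dt={dt})")
    if dt > T / 10:
        raise ValueError(f"dt={dt} too coarse for T={T} (need dt <= T/10)")


def generate_min_jerk(q_start, q_end, T: float, dt: float) -> Trajectory:
    """Point-to-point minimum-jerk reach between two joint configurations.

    Positions follow ``q(t) = q0 + (q1-q0) * s(t/T)`` with
    ``s(x) = 10x^3 - 15x^4 + 6x^5``, which has zero velocity and acceleration
    at both endpoints and a single, bell-shaped velocity peak of
    ``1.875 |dq| / T`` at the midpoint.
    """
    _check_timing(T, dt)
    q_start = np.asarray(q_start, dtype=float)
    q_end = np.asarray(q_end, dtype=float)
    n = round(T / dt) + 1
    x = np.arange(n) * dt / T
    s = 10 * x**3 - 15 * x**4 + 6 * x**5
    sdot = (30 * x**2 - 60 * x**3 + 30 * x**4) / T
    dq = q_end - q_start
    q = q_start[None, :] + s[:, None] * dq[None, :]
    qd = sdot[:, None] * dq[None, :]
    return Trajectory(dt=dt, T=T, q=q, qd=qd)


def generate_flexion_extension(q_flexed, q_extended, T: float, dt: float) -> Trajectory:
    """Cyclic flexion-extension: extend->flex over T/2 then flex->extend.

    The full out-and-back period is ``T`` (benchmark speeds 3 s, 2.3 s and
    1.5 s); the trajectory starts and ends in the extended pose with zero
    velocity at t = 0, T/2 and T.
    """
    _check_timing(T, dt)
    half = generate_min_jerk(q_extended, q_flexed, T / 2, dt)
    back = generate_min_jerk(q_flexed, q_extended, T / 2, dt)
    q = np.vstack([half.q, back.q[1:]])
    qd = np.vstack([half.qd, back.qd[1:]])
    return Trajectory(dt=dt, T=T, q=q, qd=qd)


def write_kinematics_csv(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV (time, q_shoulder, q_elbow, qd_shoulder, qd_elbow)."""
    df = pd.DataFrame(
        {
            "time": traj.t,
            "q_shoulder": traj.q[:, SHOULDER],
            "q_elbow": traj.q[:, ELBOW],
            "qd_shoulder": traj.qd[:, SHOULDER],
            "qd_elbow": traj.qd[:, ELBOW],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_kinematics_csv(path, dt_rtol: float = 1e-6) -> Trajectory:
    """Load a kinematics CSV written in the dialect of :func:`write_kinematics_csv`.

    Raises :class:`TrajectoryFormatError` on missing columns, non-monotone
    time, or non-uniform sampling beyond ``dt_rtol``.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TrajectoryFormatError(f"{path}: need at least 2 rows, got {len(t)}")
    steps = np.diff(t)
    if np.any(steps <= 0):
        row = int(np.argmax(steps <= 0)) + 1
        raise TrajectoryFormatError(f"{path}: time not strictly increasing at row {row}")
    dt = float(np.median(steps))
    if np.any(np.abs(steps - dt) > dt_rtol * dt + 1e-12):
        row = int(np.argmax(np.abs(steps - dt) > dt_rtol * dt + 1e-12)) + 1
        raise TrajectoryFormatError(f"{path}: non-uniform sampling at row {row}")
    q = df[["q_shoulder", "q_elbow"]].to_numpy(dtype=float)
    qd = df[["qd_shoulder", "qd_elbow"]].to_numpy(dtype=float)
    T = float(t[-1] - t[0])
    return Trajectory(dt=dt, T=T, q=q, qd=qd, t=t - t[0])
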