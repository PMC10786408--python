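"""Evaluation statistics for motor learning, synaptic adaptation and EMG.

Covers: trial MAE between desired and actual joint kinematics; control-chart
learning convergence (sliding 200-trial window with sigma-band occupancy
criteria); learning speed (reciprocal of trials to a target MAE); Shannon
entropy of the GC-PC weight matrix treated as a quantised image; fraction of
modified synapses; the cocontraction index CCI = (min/max)(min+max) over
agonist/antagonist group activity; MAE deviation under perturbations; EMG
envelope extraction (rectification + zero-phase low-pass Butterworth) with
MVC normalisation; lagged cross-correlation; and the significance tests used
to compare model variants (two-sample t-test, Kruskal-Wallis with a Dunn
post-hoc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

# Agonist/antagonist muscle groups per joint for the cocontraction index,
# indices into arm.MUSCLE_NAMES; biarticular muscles (BIClong, TRIlong)
# appear in both joints' groups.
CCI_GROUPS = {
    0: (np.array([0, 2]), np.array([1, 5])),       # shoulder: flex, ext
    1: (np.array([2, 3, 4]), np.array([5, 6])),    # elbow: flex, ext
}


@dataclass
class MAESeries:
    """Per-trial position (rad) and velocity (rad/s) mean absolute errors."""

    pos: np.ndarray
    vel: np.ndarray


@dataclass(frozen=True)
class ConvergenceCriteria:
    """Control-chart stability thresholds over a sliding trial window."""

    window: int = 200
    l1_min_pos: float = 0.75   # fraction of window inside mu +/- sigma
    l1_min_vel: float = 0.73
    l2_max: float = 0.03       # fraction inside the 2-3 sigma band
    l3_max: float = 0.02       # fraction beyond 3 sigma
    sigma_cap_pos: float = 0.012   # rad
    sigma_cap_vel: float = 0.055   # rad/s
    speed_target_pos: float = 0.1  # rad
    speed_target_vel: float = 0.5  # rad/s


def mae(desired, actual):
    """Trial MAE: joint-averaged then time-averaged |desired - actual|.

    Accepts two trajectories or two (n, n_joints) position arrays; returns
    a scalar per array pair.  Use :func:`mae_pair` for position+velocity.
    """
    d = np.asarray(desired.q if hasattr(desired, "q") else desired, dtype=float)
    a = np.asarray(actual.q if hasattr(actual, "q") else actual, dtype=float)
    if d.shape != a.shape:
        raise ValueError(f"shape mismatch {d.shape} vs {a.shape}")
    return float(np.mean(np.abs(d - a)))


def mae_pair(desired, actual):
    """(MAE_pos, MAE_vel) between two trajectories with equal sampling."""
    if len(desired) != len(actual):
        raise ValueError("trajectories must have equal sampling")
    return mae(desired.q, actual.q), mae(desired.qd, actual.qd)


def _window_stable(w, l1_min, l2_max, l3_max, sigma_cap):
    mu = w.mean()
    sd = w.std()
    if sd == 0.0:
        # degenerate constant window: every trial sits at mu, inside L1
        return sd <= sigma_cap
    dev = np.abs(w - mu)
    n = len(w)
    f1 = np.count_nonzero(dev <= sd) / n
    f2 = np.count_nonzero((dev >= 2 * sd) & (dev <= 3 * sd)) / n
    f3 = np.count_nonzero(dev >= 3 * sd) / n
    return (f1 >= l1_min) and (f2 <= l2_max) and (f3 <= l3_max) \
        and (sd <= sigma_cap)


def convergence_trial(series, criteria: ConvergenceCriteria = None,
                      kind: str = "pos"):
    """First trial at which the trailing window satisfies the control chart.

    Returns the 1-based trial count (so the earliest possible value equals
    the window length), or ``None`` if the series never stabilises.
    """
    c = criteria or ConvergenceCriteria()
    x = np.asarray(series, dtype=float)
    if len(x) < c.window:
        raise ValueError(f"series shorter than window ({len(x)} < {c.window})")
    l1 = c.l1_min_pos if kind == "pos" else c.l1_min_vel
    cap = c.sigma_cap_pos if kind == "pos" else c.sigma_cap_vel
    for end in range(c.window, len(x) + 1):
        if _window_stable(x[end - c.window:end], l1, c.l2_max, c.l3_max, cap):
            return end
    return None


def learning_speed(series, target: float, window: int = 20):
    """1 / (trials to reach the target MAE).

    The target is considered reached at the first trial whose trailing
    ``window``-trial mean is at or below ``target``; the short default
    window only suppresses single-trial noise.  Returns 0.0 if the target
    is never reached (or the series is shorter than one window).
    """
    x = np.asarray(series, dtype=float)
    for end in range(window, len(x) + 1):
        if x[end - window:end].mean() <= target:
            return 1.0 / end
    return 0.0


def weight_entropy(W, bins: int = 256, w_max: float = 15.0) -> float:
    """Shannon entropy (bits) of the weight matrix quantised as an image.

    Weights are normalised to [0, 1] by the weight-range bound and binned;
    the entropy is taken over the empirical bin distribution of all
    synapses.  Homogeneous weights give 0 bits; a uniform spread over all
    bins gives log2(bins).
    """
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("weights must be finite")
    q = np.clip(W / w_max, 0.0, 1.0)
    idx = np.minimum((q * bins).astype(np.int64), bins - 1)
    counts = np.bincount(idx.ravel(), minlength=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def pct_modified_synapses(W, w_init, tol: float = 0.003) -> float:
    """Percent of synapses whose weight moved more than ``tol`` from init.

    The default tolerance is half one LTP step (alpha/2), the smallest
    meaningful change.
    """
    W = np.asarray(W, dtype=float)
    w_init = np.asarray(w_init, dtype=float)
    if np.ndim(w_init) and W.shape != w_init.shape:
        raise ValueError("shape mismatch between W and w_init")
    return float(100.0 * np.count_nonzero(np.abs(W - w_init) > tol) / W.size)


def cci(flexor_activity, extensor_activity):
    """Cocontraction index series: (min/max) * (min + max) per sample.

    Defined as 0 where the larger group activity is exactly 0.  Returns the
    per-sample series; take ``.mean()`` for the trial-mean index.
    """
    fl = np.asarray(flexor_activity, dtype=float)
    ex = np.asarray(extensor_activity, dtype=float)
    if fl.shape != ex.shape:
        raise ValueError("group series must have equal length")
    lo = np.minimum(fl, ex)
    hi = np.maximum(fl, ex)
    out = np.zeros_like(lo)
    nz = hi > 0
    out[nz] = (lo[nz] / hi[nz]) * (lo[nz] + hi[nz])
    return out


def delta_mae(perturbed_maes, baseline: float):
    """Mean and std of |MAE_i - baseline| over the perturbed trials."""
    x = np.abs(np.asarray(perturbed_maes, dtype=float) - baseline)
    if x.size < 1:
        raise ValueError("need at least one perturbed trial")
    return float(x.mean()), float(x.std())


def emg_envelope(raw, fs: float, mvc=None, cutoff: float = 5.0,
                 order: int = 5):
    """EMG envelope: remove mean, rectify, zero-phase low-pass Butterworth.

    ``mvc`` is an optional maximal-voluntary-contraction recording processed
    identically; its maximum normalises the envelope to [0, 1].
    """
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the {cutoff} Hz cutoff")
    x = np.asarray(raw, dtype=float)
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(x - x.mean(axis=0)), axis=0)
    env = np.clip(env, 0.0, None)
    if mvc is not None:
        m = np.asarray(mvc, dtype=float)
        mvc_env = sps.sosfiltfilt(sos, np.abs(m - m.mean(axis=0)), axis=0)
        env = env / mvc_env.max(axis=0)
    return env


def lagged_max_correlation(x, y, max_lag: int = None, duration: float = None,
                           dt: float = None):
    """Pearson correlation maximised over integer lags within a window.

    The lag window is ``+/- max_lag`` samples, or ``+/- duration/4`` when
    given a movement duration and sampling step (the standard one-fourth of
    the movement duration).  Returns ``(r_max, lag)`` with positive lag
    meaning y is delayed relative to x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if max_lag is None:
        if duration is None or dt is None:
            raise ValueError("give max_lag, or duration and dt")
        max_lag = int(round(duration / 4.0 / dt))
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    best_r, best_lag = -np.inf, 0
    n = len(x)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        if len(xs) < 2 or xs.std() == 0 or ys.std() == 0:
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag


def dunn_posthoc(*samples, p_adjust: str = None):
    """Dunn's rank-based pairwise post-hoc test with tie correction.

    Returns a (k, k) matrix of two-sided p-values.  ``p_adjust='holm'``
    applies a Holm step-down correction across the pairs.
    """
    k = len(samples)
    groups = [np.asarray(s, dtype=float) for s in samples]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    i0 = 0
    for g in groups:
        mean_ranks.append(ranks[i0:i0 + len(g)].mean())
        i0 += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    P = np.ones((k, k))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            pairs.append((i, j, p))
    if p_adjust == "holm":
        order = np.argsort([p for _, _, p in pairs])
        m = len(pairs)
        prev = 0.0
        adj = [0.0] * m
        for rank, oi in enumerate(order):
            p = pairs[oi][2]
            val = min(1.0, max(prev, (m - rank) * p))
            adj[oi] = val
            prev = val
        pairs = [(i, j, adj[idx]) for idx, (i, j, _) in enumerate(pairs)]
    elif p_adjust is not None:
        raise ValueError("p_adjust must be None or 'holm'")
    for i, j, p in pairs:
        P[i, j] = P[j, i] = min(p, 1.0)
    return P


def group_tests(*samples):
    """Model-comparison tests: t-test for two samples, Kruskal-Wallis plus
    Dunn post-hoc for three or more.  Returns a result dict."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    groups = [np.asarray(s, dtype=float) for s in samples]
    for g in groups:
        if len(g) < 2:
            raise ValueError("each sample needs at least two values")
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1])
        return {"test": "t-test", "statistic": float(t), "p_value": float(p)}
    if all(np.ptp(g) == 0 for g in groups) and \
            np.ptp(np.concatenate(groups)) == 0:
        # Kruskal-Wallis is undefined when every value is identical; the
        # location hypothesis trivially holds.
        return {"test": "kruskal-dunn", "statistic": 0.0, "p_value": 1.0,
                "posthoc_p": np.ones((len(groups), len(groups)))}
    h, p = stats.kruskal(*groups)
    return {"test": "kruskal-dunn", "statistic": float(h), "p_value": float(p),
            "posthoc_p": dunn_posthoc(*groups)}
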