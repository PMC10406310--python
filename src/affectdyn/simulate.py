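"""Closed-loop simulation of affect trajectories and surrogate testing.

From each valid resting volume the decoded state and first derivative seed
a forward-difference (Euler) integration with one-volume steps:

    x[t+1]     = x[t] + dx/dt[t]
    dx/dt[t+1] = dx/dt[t] + d2x/dt2[t]

Position and velocity are integrated closed-loop; the acceleration at each
step is the derivative decoded from the brain state at the corresponding
real volume time.  The surrogate null uses the identical integrator but
draws (d1, d2) pairs uniformly with replacement from the subject's observed
set, destroying temporal order while preserving the marginal distribution.
If the neurally decoded derivative sequence carries real temporal
information, true-sequence simulation error should undercut the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._seeds import rng_for
from .dynamics import central_first_derivative

__all__ = [
    "euler_step",
    "simulate_closed_loop",
    "surrogate_trajectory",
    "SimulationErrorProfile",
    "error_profile",
    "rmse_growth",
]


def euler_step(
    position: float, velocity: float, acceleration: float
) -> tuple[float, float]:
    """One forward-difference step: position += velocity, then velocity += acc."""
    if not (np.isfinite(position) and np.isfinite(velocity) and np.isfinite(acceleration)):
        raise ValueError("euler_step requires finite inputs")
    return position + velocity, velocity + acceleration


def simulate_closed_loop(
    value: np.ndarray,
    d1_decoded: np.ndarray,
    d2_decoded: np.ndarray,
    start_volume: int,
    k_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate forward from ``start_volume`` for up to ``k_steps`` steps.

    Returns (positions, velocities): entry k-1 is the simulated state at
    volume ``start_volume + k``.  The trajectory truncates early when the
    decoded acceleration at a needed volume is NaN.
    """
    value = np.asarray(value, dtype=float)
    d1_decoded = np.asarray(d1_decoded, dtype=float)
    d2_decoded = np.asarray(d2_decoded, dtype=float)
    x = value[start_volume]
    dx = d1_decoded[start_volume]
    if not (np.isfinite(x) and np.isfinite(dx)):
        raise ValueError(
            f"start volume {start_volume} has undefined state or derivative "
            "(trimmed or outlier region)"
        )
    xs, dxs = [], []
    for j in range(k_steps):
        t = start_volume + j
        if t >= d2_decoded.shape[0] or not np.isfinite(d2_decoded[t]):
            break
        x, dx = euler_step(x, dx, d2_decoded[t])
        xs.append(x)
        dxs.append(dx)
    return np.asarray(xs), np.asarray(dxs)


def surrogate_trajectory(
    value: np.ndarray,
    d1_decoded: np.ndarray,
    d2_decoded: np.ndarray,
    start_volume: int,
    k_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Surrogate integration with temporally scrambled derivative pairs.

    At each step a (d1, d2) pair is drawn uniformly with replacement from
    the subject's non-NaN decoded pairs; the first draw also replaces the
    initial velocity.
    """
    value = np.asarray(value, dtype=float)
    d1_decoded = np.asarray(d1_decoded, dtype=float)
    d2_decoded = np.asarray(d2_decoded, dtype=float)
    x = value[start_volume]
    if not np.isfinite(x):
        raise ValueError(f"start volume {start_volume} has undefined state")
    pool = np.flatnonzero(np.isfinite(d1_decoded) & np.isfinite(d2_decoded))
    if pool.size == 0:
        raise ValueError("no finite decoded derivative pairs to sample from")
    draws = pool[rng.integers(0, pool.size, size=k_steps)]
    dx = d1_decoded[draws[0]]
    xs, dxs = [], []
    for j in range(k_steps):
        x, dx = euler_step(x, dx, d2_decoded[draws[j]])
        xs.append(x)
        dxs.append(dx)
    return np.asarray(xs), np.asarray(dxs)


@dataclass
class SimulationErrorProfile:
    """Per-subject and group simulation errors, true vs surrogate sequence."""

    per_subject: pd.DataFrame  # subject, dimension, step, err_true, err_surr, rmse_d1_true
    group: pd.DataFrame  # dimension, step, mean_true, mean_surr, t, p, n, degenerate
    n_iterations: int


def _per_start_errors(value, d1_dec, d2_dec, k_max, trajectory_fn):
    """Accumulate |simulated - decoded| per step over all valid starts."""
    n_vol = value.shape[0]
    d1_true = central_first_derivative(value)
    pos_err = [[] for _ in range(k_max)]
    vel_err = [[] for _ in range(k_max)]
    for start in range(n_vol - 1):
        if not (np.isfinite(value[start]) and np.isfinite(d1_dec[start])):
            continue
        try:
            xs, dxs = trajectory_fn(start)
        except ValueError:
            continue
        for k in range(1, len(xs) + 1):
            t = start + k
            if t < n_vol and np.isfinite(value[t]):
                pos_err[k - 1].append(abs(xs[k - 1] - value[t]))
            if t < n_vol and np.isfinite(d1_true[t]):
                vel_err[k - 1].append(abs(dxs[k - 1] - d1_true[t]))
    return pos_err, vel_err


def error_profile(
    subject_series: dict[str, dict[str, dict[str, np.ndarray]]],
    k_max: int = 6,
    n_iterations: int = 30,
    seed: int = 0,
) -> SimulationErrorProfile:
    """Simulation error profile, true vs surrogate sequence, with t-tests.

    ``subject_series[sid][dim]`` must map to arrays ``value`` (decoded
    state), ``d1`` and ``d2`` (decoded derivatives), all per volume.  The
    true-sequence simulation is deterministic; the surrogate is averaged
    over ``n_iterations`` resamples.  Group comparison is a two-sided
    paired t-test per (dimension, step); a degenerate comparison (all
    paired differences zero) reports NaN with a flag.
    """
    sids = sorted(subject_series)
    rows = []
    for sid in sids:
        for dim, arrs in sorted(subject_series[sid].items()):
            value, d1_dec, d2_dec = arrs["value"], arrs["d1"], arrs["d2"]
            pos_true, vel_true = _per_start_errors(
                value, d1_dec, d2_dec, k_max,
                lambda s: simulate_closed_loop(value, d1_dec, d2_dec, s, k_max),
            )
            surr_means = np.full((n_iterations, k_max), np.nan)
            for it in range(n_iterations):
                rng = rng_for(seed, "surrogate", sid, dim, it)
                pos_surr, _ = _per_start_errors(
                    value, d1_dec, d2_dec, k_max,
                    lambda s: surrogate_trajectory(value, d1_dec, d2_dec, s, k_max, rng),
                )
                surr_means[it] = [
                    np.mean(e) if e else np.nan for e in pos_surr
                ]
            for k in range(1, k_max + 1):
                e_true = pos_true[k - 1]
                rows.append(
                    (
                        sid,
                        dim,
                        k,
                        float(np.mean(e_true)) if e_true else np.nan,
                        float(np.nanmean(surr_means[:, k - 1]))
                        if np.isfinite(surr_means[:, k - 1]).any()
                        else np.nan,
                        float(np.sqrt(np.mean(np.square(vel_err))))
                        if (vel_err := vel_true[k - 1])
                        else np.nan,
                        len(e_true),
                    )
                )
    per_subject = pd.DataFrame(
        rows,
        columns=[
            "subject", "dimension", "step",
            "err_true", "err_surr", "rmse_d1_true", "n_starts",
        ],
    )

    grp_rows = []
    for (dim, k), sub in per_subject.groupby(["dimension", "step"]):
        ok = sub.dropna(subset=["err_true", "err_surr"])
        n = len(ok)
        mean_true = float(ok["err_true"].mean()) if n else np.nan
        mean_surr = float(ok["err_surr"].mean()) if n else np.nan
        diffs = ok["err_true"].to_numpy() - ok["err_surr"].to_numpy()
        degenerate = bool(n < 3 or np.allclose(diffs, 0.0))
        if degenerate:
            t_val, p_val = np.nan, np.nan
        else:
            t_val, p_val = stats.ttest_rel(ok["err_true"], ok["err_surr"])
        grp_rows.append((dim, int(k), mean_true, mean_surr, float(t_val), float(p_val), n, degenerate))
    group = pd.DataFrame(
        grp_rows,
        columns=["dimension", "step", "mean_true", "mean_surr", "t", "p", "n", "degenerate"],
    )
    return SimulationErrorProfile(per_subject, group, n_iterations)


def rmse_growth(rmse_table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Robust per-subject RMSE growth rate and its group-level summary.

    ``rmse_table`` needs columns subject, step, rmse.  Each subject's RMSE
    is regressed on step count by iteratively reweighted least squares with
    bisquare weights (tuning constant 4.685); the group summary is the mean
    slope with a t-based 95% CI and a one-sample t-test against 0.
    """
    slopes = []
    for sid, sub in rmse_table.groupby("subject"):
        sub = sub.dropna(subset=["rmse"])
        steps = sub["step"].to_numpy(dtype=float)
        if np.unique(steps).size < 2:
            raise ValueError(f"subject {sid}: fewer than 2 distinct steps")
        if np.unique(steps).size < 3:
            raise ValueError(f"subject {sid}: need >= 3 step levels")
        X = sm.add_constant(steps)
        fit = sm.RLM(
            sub["rmse"].to_numpy(dtype=float),
            X,
            M=sm.robust.norms.TukeyBiweight(c=4.685),
        ).fit()
        slopes.append((sid, float(fit.params[1])))
    per_subject = pd.DataFrame(slopes, columns=["subject", "slope"])
    vals = per_subject["slope"].to_numpy()
    mean = float(vals.mean())
    if vals.size >= 2 and vals.std(ddof=1) > 0:
        sem = vals.std(ddof=1) / np.sqrt(vals.size)
        tcrit = stats.t.ppf(0.975, vals.size - 1)
        t_val, p_val = stats.ttest_1samp(vals, 0.0)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
        summary = {
            "mean_slope": mean,
            "ci95": (float(ci[0]), float(ci[1])),
            "t": float(t_val),
            "p": float(p_val),
            "n": int(vals.size),
        }
    else:
        summary = {"mean_slope": mean, "ci95": (mean, mean), "t": np.nan, "p": np.nan, "n": int(vals.size)}
    return per_subject, summary
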