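"""Maximum-likelihood fitting of the kinetic model to culture observations.

Under independent Gaussian measurement errors with per-channel variances
1/w_c, minimizing the weighted SSE is maximum likelihood; the fit is a
multi-start bound-constrained nonlinear least-squares problem.  Two residual
modes are available: free forward simulation from t0, and teacher forcing,
where each measured state channel is re-initialized to its observed value at
every observation time so residuals are per-segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import Channel, CultureTable, logger
from .kinetics import (FeedSchedule, KineticParams, ModelState, Trajectory,
                       simulate_fedbatch)

__all__ = ["FitResult", "weighted_sse", "default_channel_weights",
           "teacher_forcing_residuals", "fit", "DEFAULT_FIT_PARAMS"]

# channel -> ModelState attribute used when re-initializing under teacher forcing
CHANNEL_STATE = {
    Channel.VCD: "Xv", Channel.TITER: "mAb", Channel.GLC: "Glc",
    Channel.GLN: "Gln", Channel.GLU: "Glu", Channel.LAC: "Lac",
    Channel.NH4: "NH4", Channel.GAL: "Gal",
    Channel.UDP_GLC: "UDP_Glc", Channel.UDP_GAL: "UDP_Gal",
    Channel.UDP_GLCNAC: "UDP_GlcNAc", Channel.UDP_GALNAC: "UDP_GalNAc",
}

#: parameters fitted by default: growth, uptake, production and NSD Vmax
#: values.  K-constants stay fixed by default to curb an under-constrained
#: problem (typically more parameters than informative observations).
DEFAULT_FIT_PARAMS = [
    "mu_max", "K_glc", "Y_xglc", "alpha_mab", "beta_mab",
    "V_gal", "Vmax_udpglc", "Vmax_udpgal_epi", "Vmax_udpgal_sal",
    "Vmax_udpglcnac", "Vmax_udpgalnac",
]


class EstimationError(RuntimeError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class FitResult:
    params: KineticParams
    sse: float
    per_channel_sse: dict
    n_function_evals: int
    converged: bool
    seed: int
    best_start: int
    fitted_names: list
    bounds: dict
    init_state: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "init_state": self.init_state,
            "params": self.params.to_dict(),
            "sse": self.sse,
            "per_channel_sse": self.per_channel_sse,
            "n_function_evals": self.n_function_evals,
            "converged": self.converged,
            "seed": self.seed,
            "best_start": self.best_start,
            "fitted": self.fitted_names,
            "fixed": [k for k in self.params.to_dict()
                      if k not in self.fitted_names],
            "bounds": self.bounds,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        return cls(params=KineticParams.from_dict(d["params"]), sse=d["sse"],
                   per_channel_sse=d["per_channel_sse"],
                   n_function_evals=d["n_function_evals"],
                   converged=d["converged"], seed=d["seed"],
                   best_start=d["best_start"], fitted_names=d["fitted"],
                   bounds=d["bounds"], init_state=d.get("init_state"))


def default_channel_weights(data: CultureTable) -> dict:
    """w_c = 1 / mean(|value|)^2 per channel: a scale-invariant objective.

    Rescaling a channel's units rescales its residuals and its weight
    inversely, leaving the optimum unchanged.
    """
    weights = {}
    for name, grp in data.df.groupby("channel"):
        m = np.nanmean(np.abs(grp["value"].to_numpy(dtype=float)))
        weights[name] = 1.0 / m**2 if np.isfinite(m) and m > 0 else 1.0
    return weights


def _interp_prediction(traj: Trajectory, ch: Channel, t: np.ndarray) -> np.ndarray:
    if t.min() < traj.time_h[0] - 1e-9 or t.max() > traj.time_h[-1] + 1e-9:
        raise AlignmentError(
            f"observation times outside trajectory span "
            f"[{traj.time_h[0]}, {traj.time_h[-1]}] h")
    return np.interp(t, traj.time_h, traj.channel_series(ch))


def weighted_sse(traj: Trajectory, data: CultureTable,
                 weights: Mapping[str, float] | None = None) -> float:
    """Sum over non-missing observations of w_c * (obs - pred)^2."""
    if weights is None:
        weights = default_channel_weights(data)
    total = 0.0
    for name, grp in data.df.groupby("channel"):
        vals = grp["value"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        ch = Channel[name]
        pred = _interp_prediction(traj, ch, grp["time_h"].to_numpy(dtype=float)[ok])
        w = weights.get(name, 1.0)
        resid = vals[ok] - pred
        resid = resid[np.isfinite(pred)]  # undefined glycan fractions skipped
        total += float(w * np.sum(resid**2))
    return total


def _relative_floors(data: CultureTable, frac: float = 0.05) -> dict:
    """Per-channel denominators floor for observation-relative residuals:
    a small fraction of the channel's mean magnitude, so observations at or
    near zero (e.g. post-depletion glucose) cannot blow up the objective."""
    floors = {}
    for name, grp in data.df.groupby("channel"):
        m = np.nanmean(np.abs(grp["value"].to_numpy(dtype=float)))
        floors[name] = frac * m if np.isfinite(m) and m > 0 else 1.0
    return floors


def _observed_wide(data: CultureTable):
    """(times, {channel_name: values-with-NaN}) sorted by time."""
    wide = data.df.pivot_table(index="time_h", columns="channel",
                               values="value", aggfunc="mean", dropna=False)
    wide = wide.sort_index()
    return wide.index.to_numpy(dtype=float), wide


def teacher_forcing_residuals(p: KineticParams, data: CultureTable,
                              schedule: FeedSchedule,
                              init: ModelState | None = None,
                              weights: Mapping[str, float] | None = None,
                              rtol: float = 1e-6, atol: float = 1e-8,
                              return_channels: bool = False,
                              residual_scale: str = "channel") -> np.ndarray:
    """Per-segment residuals under teacher forcing.

    Between consecutive observation times (t_k, t_k+1) every *observed*
    state channel is reset to its measured value at t_k (unobserved channels
    carry the simulated value over), the model is integrated to t_k+1, and
    residuals obs - pred are emitted there.  Glycan fraction channels are
    compared but not reset (fractions are not a single state variable).

    ``residual_scale="channel"`` scales residuals by the per-channel weight
    (sqrt); ``"observation"`` divides each residual by the observation
    magnitude (floored), the maximum-likelihood scaling under constant-CV
    measurement error.
    """
    times, wide = _observed_wide(data)
    if len(times) < 2:
        raise AlignmentError("teacher forcing needs at least 2 time points")
    if weights is None:
        weights = default_channel_weights(data)
    floors = _relative_floors(data) if residual_scale == "observation" else None
    state = init if init is not None else ModelState()
    residuals = []
    labels = []
    for k in range(len(times) - 1):
        t0, t1 = times[k], times[k + 1]
        # force measured state channels at t0
        forced = {}
        for name in wide.columns:
            v = wide.at[t0, name]
            ch = Channel[name]
            if np.isfinite(v) and ch in CHANNEL_STATE:
                forced[CHANNEL_STATE[ch]] = float(v)
        if forced:
            state = state.__class__(**{**state.__dict__, **forced})
        grid = np.unique(np.concatenate(
            [[t0, t1], schedule.event_times()[(schedule.event_times() > t0)
                                              & (schedule.event_times() <= t1)]]))
        traj = simulate_fedbatch(p, state, schedule, grid, rtol=rtol, atol=atol)
        state = traj.state_at(len(grid) - 1)
        for name in wide.columns:
            v = wide.at[t1, name]
            if not np.isfinite(v):
                continue
            pred = traj.channel_series(Channel[name])[-1]
            if not np.isfinite(pred):
                continue
            if floors is not None:
                residuals.append((v - pred) / max(abs(v), floors[name]))
            else:
                residuals.append(np.sqrt(weights.get(name, 1.0)) * (v - pred))
            labels.append(name)
    res = np.asarray(residuals, dtype=float)
    if return_channels:
        return res, labels
    return res


def _free_residuals(p: KineticParams, data: CultureTable,
                    schedule: FeedSchedule, init: ModelState,
                    weights: Mapping[str, float],
                    rtol: float = 1e-6, atol: float = 1e-8,
                    return_channels: bool = False,
                    residual_scale: str = "channel") -> np.ndarray:
    floors = _relative_floors(data) if residual_scale == "observation" else None
    times, wide = _observed_wide(data)
    grid = np.unique(np.concatenate([times, schedule.event_times(),
                                     [0.0]]))
    grid = grid[(grid >= 0)]
    traj = simulate_fedbatch(p, init, schedule, grid, rtol=rtol, atol=atol)
    residuals = []
    labels = []
    for name in wide.columns:
        vals = wide[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        pred = _interp_prediction(traj, Channel[name], times[ok])
        if floors is not None:
            r = (vals[ok] - pred) / np.maximum(np.abs(vals[ok]), floors[name])
        else:
            r = np.sqrt(weights.get(name, 1.0)) * (vals[ok] - pred)
        r = r[np.isfinite(r)]
        residuals.append(r)
        labels.extend([name] * len(r))
    res = np.concatenate(residuals) if residuals else np.zeros(0)
    if return_channels:
        return res, labels
    return res


def fit(p0: KineticParams, bounds: Mapping[str, tuple],
        data: CultureTable, schedule: FeedSchedule,
        init: ModelState | None = None,
        mode: str = "free", n_starts: int = 8, seed: int = 0,
        tolerance: float = 1e-8, weights: Mapping[str, float] | None = None,
        sim_rtol: float = 1e-6, residual_scale: str = "channel") -> FitResult:
    """Multi-start bound-constrained least-squares fit.

    Only parameters named in ``bounds`` are fitted; the rest stay at ``p0``.
    Bounds keys of the form ``init.<field>`` (e.g. ``init.Xv``) estimate the
    corresponding initial-state component jointly with the kinetic
    parameters, which avoids anchoring the simulation to a noisy t = 0
    measurement.  Starts beyond the first are drawn log-uniform within the
    bounds from the given seed, so results are deterministic given
    (seed, data, options).
    ``residual_scale`` selects per-channel weighting ("channel", default) or
    observation-relative residuals ("observation", MLE under constant-CV
    noise).
    """
    if data.df["value"].notna().sum() == 0:
        raise EstimationError("no non-missing observations to fit")
    names = list(bounds.keys())
    init = init if init is not None else ModelState()
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)

    def start_value(n):
        if n.startswith("init."):
            return getattr(init, n[5:])
        return getattr(p0, n)

    x0 = np.array([start_value(n) for n in names], dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise EstimationError("p0 outside bounds")
    if weights is None:
        weights = default_channel_weights(data)

    def split(x):
        pkw, ikw = {}, {}
        for n, v in zip(names, x):
            (ikw if n.startswith("init.") else pkw)[
                n[5:] if n.startswith("init.") else n] = float(v)
        p = p0.replace(**pkw)
        st = (init.__class__(**{**init.__dict__, **ikw}) if ikw else init)
        return p, st

    def residual_fn(x):
        p, init_x = split(x)
        try:
            if mode == "teacher_forcing":
                return teacher_forcing_residuals(p, data, schedule, init=init_x,
                                                 weights=weights, rtol=sim_rtol,
                                                 residual_scale=residual_scale)
            return _free_residuals(p, data, schedule, init_x, weights,
                                   rtol=sim_rtol, residual_scale=residual_scale)
        except Exception:
            return np.full(1, 1e6)

    rng = np.random.default_rng(seed)
    # log-uniform starts need strictly positive bounds; fall back to uniform
    safe_lo = np.where(lo > 0, lo, 1e-12)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        u = rng.uniform(size=len(names))
        starts.append(np.exp(np.log(safe_lo) + u * (np.log(hi) - np.log(safe_lo))))

    best = None
    best_idx = -1
    n_evals = 0
    failures = []
    for i, s in enumerate(starts):
        try:
            # parameters span many orders of magnitude; scale steps per-parameter.
            # diff_step must stay well above the adaptive integrator's noise
            # floor or finite-difference Jacobians are dominated by it.
            x_scale = np.maximum(np.abs(s), 1e-12)
            res = least_squares(residual_fn, s, bounds=(lo, hi), method="trf",
                                x_scale=x_scale, diff_step=1e-4,
                                ftol=tolerance, xtol=tolerance, gtol=tolerance)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        n_evals += res.nfev
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
            best_idx = i
    if best is None:
        raise EstimationError(f"all {len(starts)} starts failed: {failures}")
    sse, res = best
    p_fit, init_fit = split(res.x)

    # per-channel SSE at the optimum: decompose one labeled residual vector
    # so the per-channel values sum to the total exactly
    if mode == "teacher_forcing":
        r, labels = teacher_forcing_residuals(p_fit, data, schedule,
                                              init=init_fit,
                                              weights=weights, rtol=sim_rtol,
                                              return_channels=True,
                                              residual_scale=residual_scale)
    else:
        r, labels = _free_residuals(p_fit, data, schedule, init_fit, weights,
                                    rtol=sim_rtol, return_channels=True,
                                    residual_scale=residual_scale)
    per_channel: dict = {}
    for ri, name in zip(r, labels):
        per_channel[name] = per_channel.get(name, 0.0) + float(ri**2)
    sse = float(np.sum(r**2))

    return FitResult(params=p_fit, sse=sse, per_channel_sse=per_channel,
                     n_function_evals=n_evals, converged=bool(res.success),
                     seed=seed, best_start=best_idx, fitted_names=names,
                     bounds={n: list(bounds[n]) for n in names},
                     init_state=init_fit.__dict__.copy())
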