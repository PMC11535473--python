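"""Small tanh feed-forward soft sensor with penalized-likelihood training.

Architecture: 6 factor inputs -> 3 tanh hidden units -> 8 linear outputs,
53 trainable parameters in total (6*3 weights + 3 biases + 3*8 weights + 8
biases).  Inputs and outputs are autoscaled; predictions are de-scaled and
remain unconstrained reals, so negative concentration predictions are
possible and deliberately preserved.

Training minimizes a Gaussian negative log-likelihood (sum of squared errors
over the *observed* scaled responses — rows missing a response contribute
only their observed channels, which is what lets a mostly-missing response
be carried without poisoning the rest) plus a ridge penalty lambda times the
sum of squared weights (biases unpenalized).  The fitting algorithm is an
outer line search on the penalty parameter around an inner BFGS with
analytic gradient; the per-iteration validation likelihood is monitored and
the inner optimization stops when it no longer improves.  Among the
line-search candidates the model with the best training likelihood is
reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .core import logger

__all__ = ["NNModel", "count_parameters", "forward", "penalized_objective",
           "objective_and_grad", "fit_nn", "profiler", "rase", "r_squared"]


class ConfigurationError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


def count_parameters(n_in: int, n_hidden: int, n_out: int) -> int:
    """Trainable parameter count of the one-hidden-layer network."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ConfigurationError("layer sizes must be positive")
    return n_in * n_hidden + n_hidden + n_hidden * n_out + n_out


@dataclass
class NNModel:
    W1: np.ndarray               # n_in x n_hidden
    b1: np.ndarray               # n_hidden
    W2: np.ndarray               # n_hidden x n_out
    b2: np.ndarray               # n_out
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    lam: float = 0.0
    x_cols: list = field(default_factory=list)
    y_cols: list = field(default_factory=list)
    training_log: dict = field(default_factory=dict)

    @property
    def n_in(self) -> int:
        return self.W1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[1]

    @property
    def n_out(self) -> int:
        return self.W2.shape[1]

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.n_in, self.n_hidden, self.n_out)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1,
                               self.W2.ravel(), self.b2])

    def unpack(self, theta: np.ndarray) -> None:
        i, h, o = self.n_in, self.n_hidden, self.n_out
        k = 0
        self.W1 = theta[k:k + i * h].reshape(i, h).copy(); k += i * h
        self.b1 = theta[k:k + h].copy(); k += h
        self.W2 = theta[k:k + h * o].reshape(h, o).copy(); k += h * o
        self.b2 = theta[k:k + o].copy()

    def to_json(self, path: str | Path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "NNModel":
        d = json.loads(Path(path).read_text())
        for k in ("W1", "b1", "W2", "b2", "x_mean", "x_std", "y_mean", "y_std"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _scale_x(model: NNModel, X: np.ndarray) -> np.ndarray:
    """Autoscale inputs; missing factor cells are imputed to the training
    mean (0 on the scaled axis)."""
    Xs = (X - model.x_mean) / model.x_std
    return np.where(np.isfinite(Xs), Xs, 0.0)


def forward(model: NNModel, x: np.ndarray) -> np.ndarray:
    """Network output in original units for one input row or a matrix."""
    x = np.asarray(x, dtype=float)
    one = x.ndim == 1
    X = x[None, :] if one else x
    H = np.tanh(_scale_x(model, X) @ model.W1 + model.b1)
    Ys = H @ model.W2 + model.b2
    Y = Ys * model.y_std + model.y_mean
    return Y[0] if one else Y


def _sse_terms(model: NNModel, X: np.ndarray, Y: np.ndarray):
    """Scaled-response residual matrix with missing responses masked out."""
    Ys = (Y - model.y_mean) / model.y_std
    H = np.tanh(_scale_x(model, X) @ model.W1 + model.b1)
    R = H @ model.W2 + model.b2 - Ys
    mask = np.isfinite(Ys)
    return np.where(mask, R, 0.0), H, mask


def penalized_objective(model: NNModel, X: np.ndarray, Y: np.ndarray,
                        lam: float | None = None) -> float:
    """SSE over observed scaled responses + lambda * sum(weights^2)."""
    lam = model.lam if lam is None else lam
    R, _, _ = _sse_terms(model, X, Y)
    return float(np.sum(R**2) + lam * (np.sum(model.W1**2) + np.sum(model.W2**2)))


def objective_and_grad(theta: np.ndarray, model: NNModel, X: np.ndarray,
                       Y: np.ndarray, lam: float):
    """Penalized objective and its analytic gradient w.r.t. the packed
    parameter vector (backpropagation through the single tanh layer)."""
    model.unpack(theta)
    Xs = _scale_x(model, X)
    A = Xs @ model.W1 + model.b1
    H = np.tanh(A)
    Ys = (Y - model.y_mean) / model.y_std
    R = H @ model.W2 + model.b2 - Ys
    mask = np.isfinite(Ys)
    R = np.where(mask, R, 0.0)
    f = float(np.sum(R**2) + lam * (np.sum(model.W1**2) + np.sum(model.W2**2)))
    # gradients
    gW2 = 2.0 * H.T @ R + 2.0 * lam * model.W2
    gb2 = 2.0 * R.sum(axis=0)
    D = (R @ model.W2.T) * (1.0 - H**2)     # n x n_hidden
    gW1 = 2.0 * Xs.T @ D + 2.0 * lam * model.W1
    gb1 = 2.0 * D.sum(axis=0)
    g = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return f, g


def _nll(model: NNModel, X, Y) -> float:
    """Unpenalized training negative log-likelihood (up to a constant):
    the SSE over observed scaled responses."""
    R, _, _ = _sse_terms(model, X, Y)
    return float(np.sum(R**2))


def _bfgs_with_validation(model: NNModel, theta0, X, Y, lam,
                          Xv, Yv, patience: int, max_iter: int):
    """Inner BFGS; stops early when the validation likelihood stops
    improving for ``patience`` iterations."""
    state = {"best_v": math.inf, "since": 0, "best_theta": theta0.copy(),
             "history": []}
    have_valid = Xv is not None and len(Xv) > 0

    def cb(xk):
        if not have_valid:
            return
        model.unpack(xk)
        v = _nll(model, Xv, Yv)
        state["history"].append(v)
        if v < state["best_v"] - 1e-12:
            state["best_v"] = v
            state["best_theta"] = xk.copy()
            state["since"] = 0
        else:
            state["since"] += 1
            if state["since"] >= patience:
                raise StopIteration

    res = minimize(objective_and_grad, theta0, args=(model, X, Y, lam),
                   jac=True, method="BFGS", callback=cb,
                   options={"maxiter": max_iter, "gtol": 1e-8})
    theta = state["best_theta"] if (have_valid and state["history"]) else res.x
    # keep whichever of (validation-best, final) has the better valid NLL
    if have_valid and state["history"]:
        model.unpack(res.x)
        if _nll(model, Xv, Yv) < state["best_v"]:
            theta = res.x
    model.unpack(theta)
    return theta, state["history"]


def fit_nn(X: np.ndarray, Y: np.ndarray,
           X_valid: np.ndarray | None = None, Y_valid: np.ndarray | None = None,
           n_hidden: int = 3, n_starts: int = 16, seed: int = 1234,
           lambda_grid: tuple = (1e-4, 1e2), n_lambda: int = 8,
           max_iter: int = 400, patience: int = 10,
           x_cols=None, y_cols=None) -> NNModel:
    """Train the soft-sensor network.

    Starting parameter values are standard-normal draws from ``seed``.  The
    first fit uses lambda = 0; a golden-section line search over
    log10(lambda) in ``lambda_grid`` then proposes penalized candidates, and
    the candidate whose parameters give the best training likelihood is
    reported.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    y_cols = list(y_cols) if y_cols else [f"y{j}" for j in range(Y.shape[1])]
    # drop response columns with no observations at all (output layer is
    # re-sized; the remaining channels' fit is unaffected)
    col_keep = np.isfinite(Y).any(axis=0)
    if not col_keep.all():
        logger.warning("dropping all-missing response column(s): %s",
                       [y_cols[j] for j in np.where(~col_keep)[0]])
        Y = Y[:, col_keep]
        y_cols = [c for c, k in zip(y_cols, col_keep) if k]
        if X_valid is not None and Y_valid is not None:
            Y_valid = np.asarray(Y_valid, dtype=float)[:, col_keep]
    # drop rows with every response missing
    keep = np.isfinite(Y).any(axis=1)
    X, Y = X[keep], Y[keep]
    if len(X) == 0:
        raise TrainingError("no training rows with observed responses")
    n_in, n_out = X.shape[1], Y.shape[1]

    x_mean = np.nanmean(X, axis=0)
    x_std = np.nanstd(X, axis=0, ddof=1)
    y_mean = np.nanmean(Y, axis=0)
    y_std = np.nanstd(Y, axis=0, ddof=1)
    for arr, what in ((x_std, "factor"), (y_std, "response")):
        bad = ~np.isfinite(arr) | (arr <= 0)
        if bad.any():
            raise TrainingError(f"zero-variance {what} column(s) at {np.where(bad)[0]}")

    model = NNModel(W1=np.zeros((n_in, n_hidden)), b1=np.zeros(n_hidden),
                    W2=np.zeros((n_hidden, n_out)), b2=np.zeros(n_out),
                    x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
                    x_cols=list(x_cols or []), y_cols=y_cols)
    n_par = model.n_parameters
    rng = np.random.default_rng(seed)
    starts = rng.standard_normal((n_starts, n_par)) * 0.5

    def run(theta0, lam):
        theta, hist = _bfgs_with_validation(model, theta0, X, Y, lam,
                                            X_valid, Y_valid,
                                            patience=patience,
                                            max_iter=max_iter)
        return theta, _nll(model, X, Y), hist

    # initial fit at lambda = 0 from the best of the random starts
    best0 = None
    for i in range(n_starts):
        theta, train_nll, hist = run(starts[i], 0.0)
        if best0 is None or train_nll < best0[1]:
            best0 = (theta, train_nll, hist, i)
    if best0 is None:
        raise TrainingError("all starts diverged")
    candidates = [(0.0, best0[0], best0[1], best0[2])]

    # golden-section line search on log10(lambda), warm-started
    lo, hi = math.log10(lambda_grid[0]), math.log10(lambda_grid[1])
    invphi = (math.sqrt(5) - 1) / 2

    def _valid_score(theta):
        model.unpack(theta)
        if X_valid is not None and len(X_valid) > 0:
            return _nll(model, X_valid, Y_valid)
        return _nll(model, X, Y)

    def eval_lambda(loglam):
        lam = 10.0 ** loglam
        theta, train_nll, hist = run(candidates[0][1].copy(), lam)
        candidates.append((lam, theta, train_nll, hist))
        return _valid_score(theta)

    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = eval_lambda(c)
    fd = eval_lambda(d)
    for _ in range(max(0, n_lambda - 2)):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = eval_lambda(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = eval_lambda(d)

    # report the candidate with the best training likelihood
    lam_best, theta_best, nll_best, hist_best = min(candidates, key=lambda t: t[2])
    model.unpack(theta_best)
    model.lam = float(lam_best)
    model.training_log = {
        "seed": seed, "n_starts": n_starts, "best_start": int(best0[3]),
        "lambdas_tried": [float(c[0]) for c in candidates],
        "train_nll": [float(c[2]) for c in candidates],
        "validation_history_best": [float(v) for v in (hist_best or [])],
    }
    return model


def profiler(model: NNModel, reference: np.ndarray, factor_index: int,
             grid: np.ndarray, train_range: tuple | None = None):
    """One-at-a-time prediction profile.

    The chosen factor sweeps the grid while the others sit at the reference
    point.  Returns (responses matrix len(grid) x n_out, extrapolation
    flags); grid values outside +-20% of the training range are flagged.
    """
    reference = np.asarray(reference, dtype=float)
    if not 0 <= factor_index < model.n_in:
        raise ConfigurationError(f"invalid factor index {factor_index}")
    grid = np.asarray(grid, dtype=float)
    rows = np.tile(reference, (len(grid), 1))
    rows[:, factor_index] = grid
    out = forward(model, rows)
    if train_range is None:
        # reconstruct a +-2 sd proxy for the training range
        lo = model.x_mean[factor_index] - 2 * model.x_std[factor_index]
        hi = model.x_mean[factor_index] + 2 * model.x_std[factor_index]
    else:
        lo, hi = train_range
    span = hi - lo
    flags = (grid < lo - 0.2 * span) | (grid > hi + 0.2 * span)
    return out, flags


def rase(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Root average squared error over observed entries."""
    ok = np.isfinite(y_obs)
    return float(np.sqrt(np.mean((y_obs[ok] - y_pred[ok]) ** 2)))


def r_squared(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    ok = np.isfinite(y_obs)
    ss_res = np.sum((y_obs[ok] - y_pred[ok]) ** 2)
    ss_tot = np.sum((y_obs[ok] - np.mean(y_obs[ok])) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan")
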