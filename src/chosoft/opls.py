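"""Orthogonal partial least squares (OPLS) soft sensor.

OPLS decomposes the predictor block X into a part linearly related to the
response block Y and a part orthogonal to it.  Orthogonal components are
extracted (and removed from X) before the predictive components, so the
predictive scores carry only Y-correlated variation.

All inner products skip missing cells (NIPALS missing-data convention):
every score/loading regression uses only the entries present in both
vectors.  This matters because bioprocess channels are sampled on different
cadences, leaving 30-87% of cells empty per channel.

Columns are autoscaled (zero mean / unit variance) before fitting and
predictions are returned in original units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Channel, CultureTable, logger

__all__ = ["OPLSModel", "fit_opls", "predict", "q2_crossval", "vip",
           "correlation_matrix", "design_matrices"]


class ScalingError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def _masked_regress(M: np.ndarray, v: np.ndarray, axis: int) -> np.ndarray:
    """Regress the rows (axis=1) or columns (axis=0) of a masked matrix on v.

    Returns, per row/column, sum(m*v)/sum(v^2) over entries where m is
    present.  Entirely-missing rows/columns give 0.
    """
    mask = np.isfinite(M)
    Mz = np.where(mask, M, 0.0)
    if axis == 0:      # project columns on v (len n) -> p-vector
        num = Mz.T @ np.where(np.isfinite(v), v, 0.0)
        den = mask.T @ (v**2)
    else:              # project rows on v (len p) -> n-vector
        num = Mz @ np.where(np.isfinite(v), v, 0.0)
        den = mask @ (v**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _sign_fix(w: np.ndarray) -> int:
    """Sign convention: the largest-|w| element is made positive."""
    j = int(np.argmax(np.abs(w)))
    return -1 if w[j] < 0 else 1


def _xty_basis(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X'Y (skip-missing inner
    products).  Orthogonal components are orthogonalized against this basis
    so their scores are exactly uncorrelated with every response column on
    complete training data."""
    cols = []
    for j in range(Y.shape[1]):
        v = _masked_regress(X, Y[:, j], axis=0)
        if np.linalg.norm(v) > 0:
            cols.append(v)
    if not cols:
        return np.zeros((X.shape[1], 0))
    M = np.column_stack(cols)
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-12 * max(np.abs(np.diag(r)).max(), 1e-300)
    return q[:, keep]


def _svd_component(X: np.ndarray, Y: np.ndarray):
    """Deterministic fallback direction: dominant left singular vector of the
    mean-imputed (NaN -> 0 on the autoscaled blocks) cross-product X'Y.
    Scores/loadings still use skip-missing regressions."""
    Xz = np.where(np.isfinite(X), X, 0.0)
    Yz = np.where(np.isfinite(Y), Y, 0.0)
    U, s, Vt = np.linalg.svd(Xz.T @ Yz, full_matrices=False)
    w = U[:, 0]
    w = w * _sign_fix(w)
    t = _masked_regress(X, w, axis=1)
    c = _masked_regress(Y, t, axis=0)
    u = _masked_regress(Y, c, axis=1)
    p = _masked_regress(X, t, axis=0)
    return w, t, p, c, u


def _nipals_component(X: np.ndarray, Y: np.ndarray, tol: float = 1e-12,
                      max_sweeps: int = 1000, fallback: bool = True):
    """One predictive PLS2 component by NIPALS with skip-missing products.

    With heavy, structured missingness the masked alternating iteration can
    fail to settle (the masked operator is not a fixed linear map); in that
    case the deterministic SVD fallback direction is used instead.

    Returns (w, t, p, c, u) with ||w|| = 1.
    """
    # start u: Y column with largest variance (present cells)
    var = np.nanvar(Y, axis=0)
    u = Y[:, int(np.nanargmax(var))].copy()
    u = np.where(np.isfinite(u), u, 0.0)
    if not np.any(u != 0):
        u = np.ones(Y.shape[0])
    t_old = None
    for sweep in range(max_sweeps):
        w = _masked_regress(X, u, axis=0)
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ConvergenceError("degenerate X block (zero weights)")
        w /= nw
        t = _masked_regress(X, w, axis=1)
        c = _masked_regress(Y, t, axis=0)
        u = _masked_regress(Y, c, axis=1)
        if t_old is not None:
            d = np.linalg.norm(t - t_old) / max(np.linalg.norm(t), 1e-300)
            if d < tol:
                break
        t_old = t.copy()
    else:
        if not fallback:
            raise ConvergenceError(
                f"NIPALS did not converge in {max_sweeps} sweeps")
        logger.warning("skip-missing NIPALS did not converge in %d sweeps; "
                       "using mean-imputed SVD direction", max_sweeps)
        return _svd_component(X, Y)
    s = _sign_fix(w)
    w, t, c, u = s * w, s * t, s * c, s * u
    p = _masked_regress(X, t, axis=0)
    return w, t, p, c, u


@dataclass
class OPLSModel:
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    x_cols: list
    y_cols: list
    # predictive components
    W: np.ndarray   # p x A_pred weights, unit norm
    P: np.ndarray   # p x A_pred X-loadings
    C: np.ndarray   # q x A_pred Y-loadings
    T: np.ndarray   # n x A_pred training scores
    # orthogonal components
    Wo: np.ndarray  # p x A_orth
    Po: np.ndarray  # p x A_orth
    To: np.ndarray  # n x A_orth
    r2x_cum: list = field(default_factory=list)
    r2y_cum: list = field(default_factory=list)
    q2_cum: list = field(default_factory=list)

    @property
    def a_pred(self) -> int:
        return self.W.shape[1]

    @property
    def a_orth(self) -> int:
        return self.Wo.shape[1]

    def to_json(self, path: str | Path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "OPLSModel":
        d = json.loads(Path(path).read_text())
        for k, v in d.items():
            if isinstance(v, list) and k not in ("x_cols", "y_cols",
                                                 "r2x_cum", "r2y_cum", "q2_cum"):
                d[k] = np.asarray(v, dtype=float)
        return cls(**d)


def _autoscale(M: np.ndarray, cols):
    mean = np.nanmean(M, axis=0)
    std = np.nanstd(M, axis=0, ddof=1)
    bad = ~np.isfinite(std) | (std <= 0)
    if bad.any():
        names = [cols[j] for j in np.where(bad)[0]]
        raise ScalingError(f"zero-variance or empty column(s): {names}")
    return (M - mean) / std, mean, std


def fit_opls(X: np.ndarray, Y: np.ndarray, A_pred: int = 1, A_orth: int = 4,
             x_cols=None, y_cols=None) -> OPLSModel:
    """Fit an OPLS model with ``A_pred`` predictive and ``A_orth`` orthogonal
    components on (possibly incomplete) matrices.

    Orthogonal components are extracted first: for each, a provisional
    predictive component (w, t, p) is computed, the part of p orthogonal to w
    defines w_o, and the corresponding variation t_o p_o' is removed from X.
    Predictive components then follow by standard NIPALS PLS2 with deflation
    of both blocks.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    x_cols = list(x_cols) if x_cols is not None else [f"x{j}" for j in range(p)]
    y_cols = list(y_cols) if y_cols is not None else [f"y{j}" for j in range(q)]
    if n < A_pred + A_orth + 2:
        raise ValueError("too few rows for requested component counts")
    Xs, x_mean, x_std = _autoscale(X, x_cols)
    Ys, y_mean, y_std = _autoscale(Y, y_cols)

    ssx_total = np.nansum(Xs**2)
    ssy_total = np.nansum(Ys**2)
    Xd, Yd = Xs.copy(), Ys.copy()

    Wo, Po, To = [], [], []
    r2x_cum, r2y_cum = [], []

    def _r2x():
        return 1.0 - np.nansum(Xd**2) / ssx_total

    for _ in range(A_orth):
        try:
            # no imputation fallback here: orthogonal structure that the
            # skip-missing iteration cannot resolve is left in place rather
            # than deflated with an unreliable direction
            w, t, pl, c, u = _nipals_component(Xd, Yd, fallback=False)
        except ConvergenceError:
            logger.warning("orthogonal-component extraction stopped early "
                           "(inner iteration did not converge)")
            break
        # strip from p every direction predictive of any response column
        V = _xty_basis(Xd, Yd)
        w_o = pl - V @ (V.T @ pl)
        nw = np.linalg.norm(w_o)
        if nw < 1e-12:
            logger.warning("no orthogonal variation left; stopping early")
            break
        w_o /= nw
        s = _sign_fix(w_o)
        w_o *= s
        t_o = _masked_regress(Xd, w_o, axis=1)
        p_o = _masked_regress(Xd, t_o, axis=0)
        Xd_new = np.where(np.isfinite(Xd), Xd - np.outer(t_o, p_o), Xd)
        if (not np.isfinite(np.nansum(Xd_new**2))
                or np.nansum(Xd_new**2) > np.nansum(Xd**2) + 1e-12 * ssx_total):
            logger.warning("orthogonal-component extraction stopped early "
                           "(unstable deflation with missing data)")
            break
        Xd = Xd_new
        Wo.append(w_o)
        Po.append(p_o)
        To.append(t_o)
        r2x_cum.append(_r2x())
        r2y_cum.append(0.0)  # orthogonal components explain no Y by design

    W, P, C, T = [], [], [], []
    for _ in range(A_pred):
        try:
            w, t, pl, c, u = _nipals_component(Xd, Yd)
        except ConvergenceError:
            logger.warning("predictive-component extraction stopped early "
                           "(degenerate deflated block)")
            break
        Xd_new = np.where(np.isfinite(Xd), Xd - np.outer(t, pl), Xd)
        Yd_new = np.where(np.isfinite(Yd), Yd - np.outer(t, c), Yd)
        # with missing data, masked deflation is not an orthogonal projection
        # and can amplify the residual block; stop when it does
        if (not np.isfinite(np.nansum(Xd_new**2))
                or np.nansum(Xd_new**2) > np.nansum(Xd**2) + 1e-12 * ssx_total
                or np.nansum(Yd_new**2) > np.nansum(Yd**2) + 1e-12 * ssy_total):
            logger.warning("predictive-component extraction stopped early "
                           "(unstable deflation with missing data)")
            break
        Xd, Yd = Xd_new, Yd_new
        W.append(w)
        P.append(pl)
        C.append(c)
        T.append(t)
        r2x_cum.append(_r2x())
        r2y_cum.append(1.0 - np.nansum(Yd**2) / ssy_total)
    if not W:
        raise ConvergenceError("no predictive component could be extracted")

    def stack(vs, length):
        return (np.column_stack(vs) if vs
                else np.zeros((length, 0)))

    model = OPLSModel(
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        x_cols=x_cols, y_cols=y_cols,
        W=stack(W, p), P=stack(P, p), C=stack(C, q), T=stack(T, n),
        Wo=stack(Wo, p), Po=stack(Po, p), To=stack(To, n),
        r2x_cum=[float(v) for v in r2x_cum],
        r2y_cum=[float(max(v, 0.0)) for v in r2y_cum],
    )
    return model


def _project(model: OPLSModel, X_new: np.ndarray):
    """Scale, strip orthogonal variation, and compute predictive scores.

    Rows with missing cells use skip-missing regression projections.
    """
    Xs = (np.array(X_new, dtype=float) - model.x_mean) / model.x_std
    for a in range(model.a_orth):
        t_o = _masked_regress(Xs, model.Wo[:, a], axis=1)
        Xs = np.where(np.isfinite(Xs), Xs - np.outer(t_o, model.Po[:, a]), Xs)
    T = np.zeros((Xs.shape[0], model.a_pred))
    for a in range(model.a_pred):
        t = _masked_regress(Xs, model.W[:, a], axis=1)
        Xs = np.where(np.isfinite(Xs), Xs - np.outer(t, model.P[:, a]), Xs)
        T[:, a] = t
    return T


def predict(model: OPLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses (original units) for new factor rows.

    All-missing rows score 0 on every component and therefore predict the
    training Y mean.
    """
    X_new = np.array(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != len(model.x_cols):
        raise ValueError(
            f"expected {len(model.x_cols)} factor columns, got {X_new.shape[1]}")
    T = _project(model, X_new)
    Ys = T @ model.C.T
    return Ys * model.y_std + model.y_mean


def q2_crossval(X: np.ndarray, Y: np.ndarray, A_pred: int = 1, A_orth: int = 4,
                folds: int = 7, seed: int = 0) -> list:
    """Cross-validated Q2(cum) for 1..(A_pred+A_orth) total components.

    Rows are assigned to folds round-robin after a seeded shuffle; PRESS is
    accumulated over held-out rows and Q2 = 1 - PRESS/SS_Y with SS_Y the
    total sum of squares of autoscaled Y about its fold-training mean.
    Component counts are filled predictive-first (at least one predictive
    component is always used).
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < 2 * folds:
        raise ValueError("need at least 2 rows per fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    assign[order] = np.arange(n) % folds

    total = A_pred + A_orth
    q2 = []
    for a_total in range(1, total + 1):
        a_p = min(a_total, A_pred)
        a_o = a_total - a_p
        press = 0.0
        ss = 0.0
        for f in range(folds):
            tr, te = assign != f, assign == f
            model = fit_opls(X[tr], Y[tr], A_pred=a_p, A_orth=a_o)
            y_hat = predict(model, X[te])
            resid = (Y[te] - y_hat) / model.y_std
            base = (Y[te] - model.y_mean) / model.y_std
            press += np.nansum(resid**2)
            ss += np.nansum(base**2)
        q2.append(float(1.0 - press / ss))
    return q2


def vip(model: OPLSModel) -> np.ndarray:
    """Variable influence on projection over the predictive components.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ); the squared VIPs
    average to 1 (sum to p).
    """
    if model.a_pred < 1:
        raise ValueError("model has no predictive components")
    p = model.W.shape[0]
    # SSY explained per predictive component = increments of cumulative R2Y
    pred_r2 = model.r2y_cum[model.a_orth:]
    incr = np.diff(np.concatenate([[0.0], pred_r2]))
    incr = np.maximum(incr, 1e-300)
    w2 = model.W**2  # columns already unit norm
    num = p * (w2 @ incr)
    return np.sqrt(num / incr.sum())


def correlation_matrix(table: CultureTable, variables: list) -> pd.DataFrame:
    """Pearson correlations between channels over pairwise-complete rows.

    Rows are (batch, replicate, time) observations; pairs with fewer than 3
    pairwise-complete cases are reported as missing.
    """
    wide = table.wide()
    names = [ch.name for ch in variables]
    cols = [c for c in names if c in wide.columns]
    sub = wide[cols].astype(float)
    corr = sub.corr(method="pearson", min_periods=3)
    return corr.reindex(index=cols, columns=cols)


def design_matrices(table: CultureTable, factors=None, responses=None,
                    include_time: bool = True):
    """Unfold a CultureTable into (X, Y, x_cols, y_cols) observation-level
    matrices, one row per (batch, replicate, time).

    Time in hours is appended as an extra factor column by default, which is
    what lets the data-driven sensors track culture progression.
    """
    from .core import FACTOR_CHANNELS, RESPONSE_CHANNELS
    factors = factors if factors is not None else FACTOR_CHANNELS
    responses = responses if responses is not None else RESPONSE_CHANNELS
    wide = table.wide()
    x_cols = [c.name for c in factors]
    y_cols = [c.name for c in responses]
    for c in x_cols + y_cols:
        if c not in wide.columns:
            wide[c] = np.nan
    X = wide[x_cols].to_numpy(dtype=float)
    Y = wide[y_cols].to_numpy(dtype=float)
    if include_time:
        X = np.column_stack([X, wide["time_h"].to_numpy(dtype=float)])
        x_cols = x_cols + ["time_h"]
    # keep rows that carry information: at least one factor and one response
    keep = np.isfinite(X).any(axis=1) & np.isfinite(Y).any(axis=1)
    return X[keep], Y[keep], x_cols, y_cols
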