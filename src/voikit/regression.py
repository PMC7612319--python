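"""Flexible conditional-mean regression backends for VoI emulation.

EVPPI and EVSI are estimated by regressing sampled model outputs on
parameter draws (or simulated study summaries):

    y^(r) = h(x^(r)) + eps^(r),  eps^(r) ~ N(0, sigma^2)

where h is a sufficiently flexible regression function. The variance of
the fitted values estimates var_x[E(Y|x)], the variance "explained by" x,
and the residual variance estimates the uncertainty that would remain
after learning x. Three backends are provided:

``spline_gam``
    Additive penalized cubic regression splines. The B-spline basis and
    second-derivative penalty come from :mod:`statsmodels`; the Gaussian
    penalized least-squares solve and the smoothing-parameter search by
    generalized cross-validation are done directly for speed.
``adaptive_splines``
    Multivariate adaptive regression splines (forward hinge selection,
    backward GCV pruning; see :mod:`voikit._mars`).
``gaussian_process``
    Squared-exponential kernel with per-dimension lengthscales and a
    nugget, hyperparameters by marginal-likelihood maximization
    (scikit-learn), fitted to a random subset of the draws for
    tractability and evaluated at all of them.
``auto``
    Picks the backend with the smallest held-out mean squared error on a
    seeded 80/20 train/validation split, then refits on all draws.

No backend is universally reliable: sensitivity analysis across backends
is advised for joint-parameter calculations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg as sla
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from statsmodels.gam.api import BSplines

from ._mars import fit_mars

__all__ = ["FittedSurface", "fit_flexible_mean", "predict_surface"]

METHODS = ("spline_gam", "adaptive_splines", "gaussian_process", "auto")

#: predictors with at most this many unique values are fitted by saturated
#: group means (the exact flexible conditional mean for a discrete x, where
#: a spline basis would be rank-deficient)
_DISCRETE_MAX_UNIQUE = 25


class ExtrapolationWarning(UserWarning):
    pass


@dataclass
class FittedSurface:
    """A fitted emulator: values at the training draws plus residual variance.

    By the law of total variance, ``var(fitted) + resid_var`` should
    approximately reconstruct ``var(y)``; the discrepancy is a diagnostic
    for emulator misfit.
    """

    fitted: np.ndarray
    resid_var: float
    method: str
    diagnostics: dict = field(default_factory=dict)
    _predict: Callable[[np.ndarray], np.ndarray] | None = None
    _xmin: np.ndarray | None = None
    _xmax: np.ndarray | None = None

    @property
    def var_fitted(self) -> float:
        return float(np.var(self.fitted, ddof=1))


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError(f"x has {x.shape[0]} rows but y has {y.size} values")
    return x, y


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd, mu, sd


def _fit_discrete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, Callable]:
    """Saturated group-mean fit over the joint levels of discrete predictors."""
    keys = [tuple(row) for row in x]
    levels: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        levels.setdefault(k, []).append(i)
    means = {k: float(np.mean(y[idx])) for k, idx in levels.items()}
    fitted = np.array([means[k] for k in keys])
    grand = float(np.mean(y))
    lev_arr = np.array(list(means.keys()), dtype=float)
    lev_val = np.array(list(means.values()))

    def predict(xnew: np.ndarray) -> np.ndarray:
        out = np.empty(xnew.shape[0])
        for i, row in enumerate(xnew):
            k = tuple(row)
            if k in means:
                out[i] = means[k]
            else:  # nearest level in standardized space
                j = int(np.argmin(((lev_arr - row) ** 2).sum(axis=1)))
                out[i] = lev_val[j] if lev_arr.size else grand
        return out

    return fitted, predict


def _fit_gam(x, y, basis_dim=None, **_):
    r, p = x.shape
    uniq = [np.unique(x[:, j]).size for j in range(p)]
    if max(uniq) <= _DISCRETE_MAX_UNIQUE:
        fitted, predict = _fit_discrete(x, y)
        diag = {"saturated": True, "n_levels": int(np.prod(uniq))}
        return fitted, predict, diag
    if basis_dim is None:
        basis_dim = max(4, min(10, r // 50))
    df = [min(basis_dim, u - 1) for u in uniq]
    degree = [min(3, d - 1) for d in df]
    bs = BSplines(x, df=df, degree=degree)
    X = np.column_stack([np.ones(r), bs.basis])
    k = X.shape[1]
    S = np.zeros((k, k))
    off = 1
    for sm in bs.smoothers:
        kk = sm.basis.shape[1]
        S[off:off + kk, off:off + kk] = sm.cov_der2
        off += kk
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # scale-free lambda grid, then keep the GCV minimizer
    s_scale = np.trace(XtX) / max(np.trace(S), 1e-300)
    best = None
    for lam in s_scale * np.logspace(-8, 4, 31):
        A = XtX + lam * S
        A[np.diag_indices_from(A)] += 1e-10 * np.diag(XtX).mean()
        try:
            cf = sla.cho_factor(A)
        except np.linalg.LinAlgError:
            continue
        beta = sla.cho_solve(cf, Xty)
        edf = float(np.trace(sla.cho_solve(cf, XtX)))
        rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 0.0)
        gcv = r * rss / max(r - edf, 1.0) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf)
    if best is None:
        raise np.linalg.LinAlgError("penalized spline solve failed for all penalties")
    gcv, lam, beta, edf = best
    fitted = X @ beta
    x_lo, x_hi = x.min(axis=0), x.max(axis=0)

    def predict(xnew: np.ndarray) -> np.ndarray:
        # constant extrapolation: clamp queries to the training support,
        # where the basis is defined (the caller warns on extrapolation)
        xc = np.clip(np.asarray(xnew, dtype=float), x_lo, x_hi)
        basis = bs.transform(xc)
        return np.column_stack([np.ones(len(basis)), basis]) @ beta

    return fitted, predict, {"basis_dim": df, "edf": edf, "gcv": gcv, "penalty": lam}


def _fit_mars_backend(x, y, max_terms=21, max_degree=2, **_):
    model = fit_mars(x, y, max_terms=max_terms, max_degree=max_degree)
    fitted = model.predict(x)
    diag = {"n_terms": len(model.terms), "gcv": model.gcv}
    return fitted, model.predict, diag


def _fit_gp(x, y, gp_subset=1000, seed=0, **_):
    r, p = x.shape
    rng = np.random.default_rng(seed)
    idx = rng.permutation(r)[: min(r, gp_subset)]
    ymu, ysd = y.mean(), y.std()
    ysd = ysd if ysd > 0 else 1.0
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(np.ones(p), (1e-2, 1e2))
        + WhiteKernel(0.1, (1e-8, 1e2))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=False, n_restarts_optimizer=0,
        random_state=int(rng.integers(2**31)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(x[idx], (y[idx] - ymu) / ysd)

    def predict(xnew: np.ndarray) -> np.ndarray:
        return gp.predict(np.asarray(xnew, dtype=float)) * ysd + ymu

    fitted = predict(x)
    diag = {"kernel": str(gp.kernel_), "subset": int(idx.size)}
    return fitted, predict, diag


_BACKENDS = {
    "spline_gam": _fit_gam,
    "adaptive_splines": _fit_mars_backend,
    "gaussian_process": _fit_gp,
}


def fit_flexible_mean(x, y, method: str = "auto", **options) -> FittedSurface:
    """Fit a flexible emulator of E(Y | x) to a Monte Carlo sample.

    Parameters
    ----------
    x : array-like, shape (R, p) or (R,)
        Predictor draws (parameter values or study summaries).
    y : array-like, shape (R,)
        Output draws (model output or one action's net benefit).
    method : {"spline_gam", "adaptive_splines", "gaussian_process", "auto"}
    options :
        Backend options: ``basis_dim`` (GAM), ``max_terms``/``max_degree``
        (adaptive splines), ``gp_subset`` (GP training subset size),
        ``seed`` (GP subset and auto split).

    Notes
    -----
    Reliable identification of the regression shape needs a generous
    Monte Carlo sample; several thousand draws are typically required
    when there are several predictors.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    x, y = _as_xy(x, y)
    r, p = x.shape
    if r < 10 * p:
        raise ValueError(
            f"too few draws (R={r}) to fit a flexible surface on p={p} predictors"
        )
    xs, mu, sd = _standardize(x)

    if method == "auto":
        seed = options.get("seed", 0)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(r)
        n_val = max(1, r // 5)
        val, train = perm[:n_val], perm[n_val:]
        scores = {}
        for name, backend in _BACKENDS.items():
            try:
                _, pred, _ = backend(xs[train], y[train], **options)
                scores[name] = float(np.mean((y[val] - pred(xs[val])) ** 2))
            except Exception:
                continue
        if not scores:
            raise RuntimeError("all regression backends failed")
        method = min(scores, key=scores.get)
        options = {**options, "_auto_scores": scores}

    fitted, predict_std, diag = _BACKENDS[method](xs, y, **{
        k: v for k, v in options.items() if not k.startswith("_")
    })
    resid_var = float(np.var(y - fitted, ddof=1))
    if "_auto_scores" in options:
        diag["auto_validation_mse"] = options["_auto_scores"]
    surf = FittedSurface(
        fitted=np.asarray(fitted, dtype=float),
        resid_var=resid_var,
        method=method,
        diagnostics=diag,
        _predict=lambda xn: predict_std((np.asarray(xn, dtype=float) - mu) / sd),
        _xmin=x.min(axis=0),
        _xmax=x.max(axis=0),
    )
    return surf


def predict_surface(fit: FittedSurface, xnew) -> np.ndarray:
    """Evaluate a fitted surface at new predictor values.

    Warns when any query point lies outside the training support;
    emulator behaviour under extrapolation is not trustworthy.
    """
    if fit._predict is None:
        raise ValueError("this surface does not carry a predictor")
    xnew = np.asarray(xnew, dtype=float)
    if xnew.ndim == 1:
        xnew = xnew[:, None] if fit._xmin.size == 1 else xnew[None, :]
    if xnew.shape[1] != fit._xmin.size:
        raise ValueError(
            f"xnew has {xnew.shape[1]} columns; surface was trained on {fit._xmin.size}"
        )
    if (xnew < fit._xmin).any() or (xnew > fit._xmax).any():
        warnings.warn(
            "query points outside the training support; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return np.asarray(fit._predict(xnew), dtype=float)
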