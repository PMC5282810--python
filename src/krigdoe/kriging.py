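"""Ordinary Kriging (constant-trend Gaussian-process interpolation).

The trend constant and process variance are profiled out in closed form;
the anisotropic correlation lengths and the nugget maximize the concentrated
log-likelihood via seeded multistart L-BFGS-B. Inputs are standardized to
[-1, 1] per dimension and responses are centered and scaled internally; all
reported parameters (``sigma2``, ``tau2``, ``beta0``) are in natural response
units.

Predictive variance convention: ``s2(x) = sigma2 * (1 - r' C^-1 r) + tau2``
with ``C`` the nugget-augmented correlation matrix. This interpolates exactly
at tau2 = 0, tends to ``sigma2 + tau2`` far from all data, and never exceeds
that ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from ._flattext import dumps, loads, parse_floats, parse_list
from .effects import ObservationSet

__all__ = ["KrigingModel", "Prediction", "GridResult", "fit", "fit_arrays",
           "predict", "grid_evaluate", "model_to_text", "model_from_text"]

JITTER = 1e-10
_SQRT5 = np.sqrt(5.0)


def _correlation(kernel: str, A: np.ndarray, B: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Correlation matrix between row sets A (m,d) and B (n,d)."""
    D = A[:, None, :] - B[None, :, :]
    H = D / theta
    if kernel == "sq_exp":
        return np.exp(-0.5 * np.sum(H * H, axis=2))
    if kernel == "matern52":
        r = np.sqrt(np.maximum(np.sum(H * H, axis=2), 0.0))
        return (1.0 + _SQRT5 * r + 5.0 / 3.0 * r * r) * np.exp(-_SQRT5 * r)
    raise ValueError(f"unknown correlation family {kernel!r}")


@dataclass
class Prediction:
    """Kriging predictive mean and standard deviation."""

    mean: np.ndarray
    sd: np.ndarray
    extrapolated: np.ndarray

    def item(self) -> tuple[float, float]:
        return float(np.ravel(self.mean)[0]), float(np.ravel(self.sd)[0])


@dataclass
class KrigingModel:
    factor_names: tuple[str, ...]
    kernel: str
    X: np.ndarray                 # training inputs, natural units (n, d)
    y: np.ndarray                 # training responses, natural units (n,)
    theta: np.ndarray             # correlation lengths, scaled-input coords
    sigma2_s: float               # process variance, scaled-output units
    tau2_s: float                 # nugget, scaled-output units
    beta0_s: float                # trend constant, scaled-output units
    x_mid: np.ndarray
    x_half: np.ndarray
    y_mean: float
    y_sd: float
    box_lower: np.ndarray
    box_upper: np.ndarray
    loglik: float = np.nan
    cond: float = np.nan
    _L: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.sigma2_s <= 0:
            raise ValueError("process variance must be positive")
        if np.any(np.asarray(self.theta) <= 0):
            raise ValueError("correlation lengths must be positive")
        if self.tau2_s < 0:
            raise ValueError("nugget must be non-negative")
        if self._L is None:
            self._factorize()

    # -- natural-unit views --------------------------------------------------

    @property
    def sigma2(self) -> float:
        return self.sigma2_s * self.y_sd ** 2

    @property
    def tau2(self) -> float:
        return self.tau2_s * self.y_sd ** 2

    @property
    def beta0(self) -> float:
        return self.y_mean + self.y_sd * self.beta0_s

    @property
    def n(self) -> int:
        return len(self.y)

    # -- internals -----------------------------------------------------------

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mid) / self.x_half

    def _scale_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_sd

    def _factorize(self) -> None:
        Xs = self._scale_x(self.X)
        eta = self.tau2_s / self.sigma2_s
        C = _correlation(self.kernel, Xs, Xs, self.theta)
        C[np.diag_indices_from(C)] += eta + JITTER
        self._L = linalg.cholesky(C, lower=True)
        ys = self._scale_y(self.y)
        self._alpha = linalg.cho_solve((self._L, True), ys - self.beta0_s)
        if not np.isfinite(self.cond):
            d = np.diag(self._L)
            self.cond = float((d.max() / d.min()) ** 2)

    def predict(self, x) -> Prediction:
        """Ordinary-Kriging mean and standard deviation at query points."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != len(self.factor_names):
            raise ValueError(f"expected {len(self.factor_names)} input dimensions")
        Xs = self._scale_x(X)
        r = _correlation(self.kernel, Xs, self._scale_x(self.X), self.theta)
        mu_s = self.beta0_s + r @ self._alpha
        v = linalg.solve_triangular(self._L, r.T, lower=True)
        s2_s = self.sigma2_s * np.clip(1.0 - np.sum(v * v, axis=0), 0.0, None) + self.tau2_s
        mean = self.y_mean + self.y_sd * mu_s
        sd = self.y_sd * np.sqrt(s2_s)
        tol = 1e-9
        extra = np.any((X < self.box_lower - tol) | (X > self.box_upper + tol), axis=1)
        if single:
            return Prediction(mean[0], sd[0], extra[0])
        return Prediction(mean, sd, extra)

    def loo_standardized(self) -> np.ndarray:
        """Leave-one-out residuals standardized by the LOO Kriging SD."""
        Xs = self._scale_x(self.X)
        eta = self.tau2_s / self.sigma2_s
        C = _correlation(self.kernel, Xs, Xs, self.theta)
        C[np.diag_indices_from(C)] += eta + JITTER
        Cinv = linalg.inv(C)
        ys = self._scale_y(self.y) - self.beta0_s
        e = (Cinv @ ys) / np.diag(Cinv)
        var = self.sigma2_s / np.diag(Cinv)
        return e / np.sqrt(var)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _profiled(C: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """Profiled trend constant, process variance and neg log likelihood."""
    n = len(ys)
    L = linalg.cholesky(C, lower=True)
    ones = np.ones(n)
    Ci_y = linalg.cho_solve((L, True), ys)
    Ci_1 = linalg.cho_solve((L, True), ones)
    beta0 = float(ones @ Ci_y) / float(ones @ Ci_1)
    resid = ys - beta0
    sigma2 = float(resid @ linalg.cho_solve((L, True), resid)) / n
    sigma2 = max(sigma2, 1e-12)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    nll = 0.5 * (n * np.log(sigma2) + logdet + n)
    return beta0, sigma2, nll


def _nll(params: np.ndarray, Xs: np.ndarray, ys: np.ndarray, kernel: str,
         estimate_nugget: bool, eta_fixed: float) -> float:
    d = Xs.shape[1]
    theta = np.exp(params[:d])
    eta = np.exp(params[d]) if estimate_nugget else eta_fixed
    C = _correlation(kernel, Xs, Xs, theta)
    C[np.diag_indices_from(C)] += eta + JITTER
    try:
        _, _, nll = _profiled(C, ys)
    except linalg.LinAlgError:
        return 1e12
    return nll


def fit_arrays(X: np.ndarray, y: np.ndarray, factor_names=None, *, kernel: str = "sq_exp",
               estimate_nugget: bool = True, theta=None, tau2: float | None = None,
               sigma2: float | None = None, beta0: float | None = None,
               n_starts: int = 8, seed: int = 0, normalize_inputs: bool = True,
               normalize_output: bool = True, nugget_floor: float = 0.0,
               box=None) -> KrigingModel:
    """Fit an ordinary-Kriging model to raw arrays.

    When ``theta`` is supplied no hyperparameter search is run (``tau2``
    defaults to 0 in that case); otherwise ``(theta, tau2)`` maximize the
    concentrated log-likelihood from ``n_starts`` seeded starting points.
    ``nugget_floor`` is a lower bound for the nugget in natural response
    variance units (derived from reference replicates upstream).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite training data")
    factor_names = tuple(factor_names) if factor_names is not None else tuple(f"x{i}" for i in range(d))

    distinct = np.unique(np.round(X, 12), axis=0)
    optimizing = theta is None
    if optimizing and len(distinct) < 3:
        raise ValueError(f"need >= 3 distinct input points, got {len(distinct)}")

    has_dup_conflict = len(distinct) < n
    if has_dup_conflict and tau2 == 0.0:
        warnings.warn("duplicate inputs with tau2 forced to 0; forcing a positive nugget",
                      RuntimeWarning, stacklevel=2)
        tau2 = None
        nugget_floor = max(nugget_floor, 1e-8 * max(np.var(y), 1.0))

    if normalize_inputs:
        lo, hi = X.min(axis=0), X.max(axis=0)
        x_mid = (lo + hi) / 2.0
        x_half = np.where(hi > lo, (hi - lo) / 2.0, 1.0)
    else:
        x_mid, x_half = np.zeros(d), np.ones(d)
    if box is not None:
        box_lower, box_upper = np.asarray(box[0], float), np.asarray(box[1], float)
    else:
        box_lower, box_upper = X.min(axis=0), X.max(axis=0)

    y_sd_raw = float(np.std(y))
    if normalize_output and y_sd_raw > 0:
        y_mean, y_sd = float(np.mean(y)), y_sd_raw
    else:
        y_mean, y_sd = 0.0, 1.0

    Xs = (X - x_mid) / x_half
    ys = (y - y_mean) / y_sd

    if y_sd_raw == 0.0:
        # constant responses: degenerate but valid model
        return KrigingModel(factor_names, kernel, X, y, np.ones(d), 1e-12, 0.0,
                            float(y[0]), x_mid, x_half, 0.0, 1.0, box_lower, box_upper,
                            loglik=np.nan)

    floor_s = nugget_floor / y_sd ** 2  # nugget floor in scaled output units

    if not optimizing:
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.shape != (d,):
            raise ValueError(f"theta must have {d} entries")
        tau2_s = (0.0 if tau2 is None else float(tau2) / y_sd ** 2)
        C = _correlation(kernel, Xs, Xs, theta)
        if sigma2 is not None:
            # everything fixed except (optionally) the trend constant
            sigma2_s = float(sigma2) / y_sd ** 2
            eta = tau2_s / sigma2_s
            Ceta = C.copy()
            Ceta[np.diag_indices_from(Ceta)] += eta + JITTER
            beta0_prof, _, nll = _profiled(Ceta, ys)
            beta0_s = beta0_prof if beta0 is None else (float(beta0) - y_mean) / y_sd
        else:
            # profile beta0 and sigma2 at the given correlation parameters;
            # eta depends on sigma2 which depends on eta -> fixed point
            eta = 0.0
            if tau2_s > 0.0:
                eta = tau2_s  # initial guess with sigma2 ~ 1 on scaled outputs
                for _ in range(50):
                    Ceta = C.copy()
                    Ceta[np.diag_indices_from(Ceta)] += eta + JITTER
                    _, sigma2_fp, _ = _profiled(Ceta, ys)
                    eta_new = tau2_s / sigma2_fp
                    if abs(eta_new - eta) < 1e-14:
                        eta = eta_new
                        break
                    eta = eta_new
            Ceta = C.copy()
            Ceta[np.diag_indices_from(Ceta)] += eta + JITTER
            beta0_s, sigma2_s, nll = _profiled(Ceta, ys)
            if beta0 is not None:
                beta0_s = (float(beta0) - y_mean) / y_sd
            tau2_s = eta * sigma2_s
        return KrigingModel(factor_names, kernel, X, y, theta, sigma2_s, tau2_s, beta0_s,
                            x_mid, x_half, y_mean, y_sd, box_lower, box_upper, loglik=-nll)

    # -- maximum-likelihood search -------------------------------------------
    rng = np.random.default_rng(seed)
    log_theta_lo, log_theta_hi = np.log(5e-2), np.log(20.0)
    eta_lo = max(floor_s, 1e-8)
    log_eta_lo, log_eta_hi = np.log(eta_lo), np.log(10.0)
    if estimate_nugget:
        bounds = [(log_theta_lo, log_theta_hi)] * d + [(log_eta_lo, log_eta_hi)]
    else:
        bounds = [(log_theta_lo, log_theta_hi)] * d
    eta_fixed = max(floor_s, 0.0)

    starts = [np.concatenate([np.zeros(d), [np.log(max(1e-2, eta_lo * 2))]])[: len(bounds)]]
    for _ in range(max(0, n_starts - 1)):
        s = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        starts.append(s)

    best = None
    for s in starts:
        res = optimize.minimize(_nll, s, args=(Xs, ys, kernel, estimate_nugget, eta_fixed),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    theta = np.exp(best.x[:d])
    eta = np.exp(best.x[d]) if estimate_nugget else eta_fixed
    C = _correlation(kernel, Xs, Xs, theta)
    C[np.diag_indices_from(C)] += eta + JITTER
    beta0_s, sigma2_s, nll = _profiled(C, ys)
    tau2_s = eta * sigma2_s
    return KrigingModel(factor_names, kernel, X, y, theta, sigma2_s, tau2_s, beta0_s,
                        x_mid, x_half, y_mean, y_sd, box_lower, box_upper, loglik=-nll)


def fit(obs: ObservationSet, factor_names=None, *, space=None, **options) -> KrigingModel:
    """Fit a Kriging surrogate to an :class:`ObservationSet`.

    A nugget floor is derived from reference-replicate variance when at least
    two reference rows exist. ``space`` (a FactorSpace) supplies the factor
    box used for extrapolation flags and grid evaluation.
    """
    names = tuple(factor_names) if factor_names is not None else tuple(obs.factor_names)
    X = obs.inputs(names)
    y = obs.responses
    if "nugget_floor" not in options:
        refs = obs.references()
        if len(refs) >= 2:
            ss, df = 0.0, 0
            for _, sub in refs.groupby("plate_id"):
                if len(sub) >= 2:
                    r = sub["response"].to_numpy(dtype=float)
                    ss += float(np.sum((r - r.mean()) ** 2))
                    df += len(sub) - 1
            if df > 0:
                options["nugget_floor"] = ss / df
    if space is not None and "box" not in options:
        idx = [space.names.index(n) for n in names]
        options["box"] = (space.lower[idx], space.upper[idx])
    return fit_arrays(X, y, names, **options)


def predict(model: KrigingModel, x) -> Prediction:
    """Module-level alias of :meth:`KrigingModel.predict`."""
    return model.predict(x)


# ---------------------------------------------------------------------------
# grid evaluation
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    axes: tuple[str, ...]
    coords: tuple[np.ndarray, ...]
    mean: np.ndarray
    sd: np.ndarray
    fixed: dict[str, float]
    argmax: dict[str, float]
    argmax_mean: float

    def to_frame(self):
        import pandas as pd

        mesh = np.meshgrid(*self.coords, indexing="ij")
        data = {name: m.ravel() for name, m in zip(self.axes, mesh)}
        for name, level in self.fixed.items():
            data[name] = np.full(mesh[0].size, level)
        data["mean"] = self.mean.ravel()
        data["sd"] = self.sd.ravel()
        return pd.DataFrame(data)


def grid_evaluate(model: KrigingModel, axes, fixed: dict[str, float],
                  resolution: int = 41, box=None, chunk: int = 20000) -> GridResult:
    """Dense predictive mean/SD grids over 1-3 axes with the rest fixed."""
    axes = tuple(axes)
    names = list(model.factor_names)
    for a in axes:
        if a not in names:
            raise ValueError(f"axis {a!r} not a model factor")
        if a in fixed:
            raise ValueError(f"axis {a!r} also appears in fixed levels")
    rest = [n for n in names if n not in axes]
    missing = set(rest) - set(fixed)
    if missing:
        raise ValueError(f"fixed levels missing for {sorted(missing)}")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")

    if box is None:
        lo = {n: model.box_lower[i] for i, n in enumerate(names)}
        hi = {n: model.box_upper[i] for i, n in enumerate(names)}
    else:
        lo = {n: box[0][i] for i, n in enumerate(names)}
        hi = {n: box[1][i] for i, n in enumerate(names)}
    coords = tuple(np.linspace(lo[a], hi[a], resolution) if resolution > 1
                   else np.array([fixed.get(a, (lo[a] + hi[a]) / 2)]) for a in axes)
    mesh = np.meshgrid(*coords, indexing="ij")
    m = mesh[0].size
    Q = np.empty((m, len(names)))
    for i, n in enumerate(names):
        if n in axes:
            Q[:, i] = mesh[axes.index(n)].ravel()
        else:
            Q[:, i] = fixed[n]

    mean = np.empty(m)
    sd = np.empty(m)
    for start in range(0, m, chunk):
        pred = model.predict(Q[start:start + chunk])
        mean[start:start + chunk] = pred.mean
        sd[start:start + chunk] = pred.sd
    shape = tuple(len(c) for c in coords)
    imax = int(np.argmax(mean))
    argmax = {n: float(Q[imax, i]) for i, n in enumerate(names)}
    return GridResult(axes, coords, mean.reshape(shape), sd.reshape(shape),
                      dict(fixed), argmax, float(mean[imax]))


def argmax_mean(model: KrigingModel, box=None, resolution: int = 21,
                polish: bool = True, seed: int = 0, n_starts: int = 8) -> tuple[np.ndarray, float]:
    """Locate the maximizer of the predictive mean over the factor box.

    Dense grid argmax (dimensions <= 4) or seeded multistart local search,
    followed by an L-BFGS-B polish.
    """
    d = len(model.factor_names)
    if box is None:
        lower, upper = model.box_lower, model.box_upper
    else:
        lower, upper = np.asarray(box[0], float), np.asarray(box[1], float)

    if d <= 4:
        grids = [np.linspace(lower[i], upper[i], resolution) for i in range(d)]
        mesh = np.meshgrid(*grids, indexing="ij")
        Q = np.column_stack([m.ravel() for m in mesh])
    else:
        rng = np.random.default_rng(seed)
        Q = rng.uniform(lower, upper, size=(4096, d))
    mean = np.empty(len(Q))
    for start in range(0, len(Q), 20000):
        mean[start:start + 20000] = model.predict(Q[start:start + 20000]).mean
    x0 = Q[int(np.argmax(mean))]
    best_x, best_f = x0, float(mean.max())

    if polish:
        def neg_mean(x):
            return -float(model.predict(x).mean)

        res = optimize.minimize(neg_mean, x0, method="L-BFGS-B",
                                bounds=list(zip(lower, upper)))
        if -res.fun > best_f:
            best_x, best_f = res.x, float(-res.fun)
    return np.asarray(best_x, float), best_f


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_text(model: KrigingModel) -> str:
    scalars = {
        "type": "kriging_model",
        "kernel": model.kernel,
        "factor_names": ",".join(model.factor_names),
        "sigma2_s": model.sigma2_s,
        "tau2_s": model.tau2_s,
        "beta0_s": model.beta0_s,
        "y_mean": model.y_mean,
        "y_sd": model.y_sd,
        "loglik": model.loglik,
        "cond": model.cond,
    }
    arrays = {
        "theta": model.theta,
        "x_mid": model.x_mid,
        "x_half": model.x_half,
        "box_lower": model.box_lower,
        "box_upper": model.box_upper,
        "X": model.X,
        "y": model.y,
    }
    return dumps(scalars, arrays, header="krigdoe kriging model v1")


def model_from_text(text: str) -> KrigingModel:
    scalars, arrays = loads(text)
    if scalars.get("type") != "kriging_model":
        raise ValueError("not a serialized Kriging model")
    return KrigingModel(
        factor_names=tuple(parse_list(scalars["factor_names"])),
        kernel=scalars["kernel"],
        X=arrays["X"],
        y=arrays["y"].ravel(),
        theta=arrays["theta"].ravel(),
        sigma2_s=float(scalars["sigma2_s"]),
        tau2_s=float(scalars["tau2_s"]),
        beta0_s=float(scalars["beta0_s"]),
        x_mid=arrays["x_mid"].ravel(),
        x_half=arrays["x_half"].ravel(),
        y_mean=float(scalars["y_mean"]),
        y_sd=float(scalars["y_sd"]),
        box_lower=arrays["box_lower"].ravel(),
        box_upper=arrays["box_upper"].ravel(),
        loglik=float(scalars["loglik"]),
        cond=float(scalars["cond"]),
    )
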