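"""Gaussian-process surrogates with ARD, Thompson sampling, and LOO q².

One independent GP is fitted per objective (conversion, d.e.).  The kernel is
Matérn 5/2 with automatic relevance determination (one length scale per input
dimension); a squared-exponential variant is available by configuration.
Hyperparameters are set by maximising the log marginal likelihood with
multi-restart L-BFGS in log space.  Posterior *functions* are drawn for
Thompson sampling via random Fourier features combined with Matheron's
pathwise update, so each sample is a cheap deterministic function once drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from ._utils import as_seedseq
from .errors import (
    InvalidArgumentError,
    NumericalConditioningError,
    UndefinedQuantityError,
    UnsupportedConfigError,
)

SQRT5 = np.sqrt(5.0)


# --------------------------------------------------------------------------
# Kernels
# --------------------------------------------------------------------------

def _scaled_sq_dists(X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    A = X1 / ls
    B = X2 / ls
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


def kernel_matrix(
    X1: np.ndarray, X2: np.ndarray, kernel: str, ls: np.ndarray, sf2: float
) -> np.ndarray:
    """Covariance between two point sets under the stated kernel."""
    d2 = _scaled_sq_dists(X1, X2, ls)
    if kernel == "matern52":
        r = np.sqrt(d2)
        return sf2 * (1.0 + SQRT5 * r + (5.0 / 3.0) * d2) * np.exp(-SQRT5 * r)
    if kernel == "rbf":
        return sf2 * np.exp(-0.5 * d2)
    raise UnsupportedConfigError(f"unknown kernel {kernel!r}")


def _kernel_grads(X, kernel, ls, sf2):
    """K and its gradients w.r.t. log length scales and log signal variance."""
    d2 = _scaled_sq_dists(X, X, ls)
    n, d = X.shape
    diff2 = (X[:, None, :] - X[None, :, :]) ** 2 / ls**2  # (n, n, d)
    if kernel == "matern52":
        r = np.sqrt(d2)
        e = np.exp(-SQRT5 * r)
        K = sf2 * (1.0 + SQRT5 * r + (5.0 / 3.0) * d2) * e
        # dK/d(log ls_j) = (5/3)·sf2·(1+√5 r)·e^{−√5 r}·diff2_j
        base = (5.0 / 3.0) * sf2 * (1.0 + SQRT5 * r) * e
        grads_ls = base[:, :, None] * diff2
    elif kernel == "rbf":
        K = sf2 * np.exp(-0.5 * d2)
        grads_ls = K[:, :, None] * diff2
    else:
        raise UnsupportedConfigError(f"unknown kernel {kernel!r}")
    return K, grads_ls, K.copy()  # dK/d(log sf2) = K


# --------------------------------------------------------------------------
# Configuration and model containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GPConfig:
    """Fit settings for :func:`fit_gp`.

    ``optimize=False`` keeps the supplied hyperparameters fixed (useful for
    oracle comparisons); ``normalize=False`` fits in raw input/output units.
    ``noise_floor`` is a lower bound on the noise variance in *standardised*
    target units (variance fraction).
    """

    kernel: str = "matern52"
    ard: bool = True
    n_restarts: int = 10
    optimize: bool = True
    normalize: bool = True
    noise_floor: float = 1e-6
    jitter: float = 1e-8
    lengthscales: np.ndarray | float | None = None
    signal_variance: float = 1.0
    noise_variance: float = 1e-2


@dataclass
class GPSurrogate:
    """A fitted GP: kernel, ARD length scales, normalisation, training data.

    All public prediction APIs work in raw (unstandardised) units; internally
    the model stores standardised training data and a cached Cholesky factor.
    """

    kernel: str
    ard: bool
    lengthscales: np.ndarray      # per standardised input dim (shared if not ARD)
    signal_variance: float
    noise_variance: float          # in standardised target units
    X_train: np.ndarray            # raw inputs
    y_train: np.ndarray            # raw targets
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    log_marginal_likelihood: float
    seed: int | None = None
    _chol: np.ndarray = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    # -- internals ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.X_train.shape[0]

    @property
    def dim(self) -> int:
        return self.X_train.shape[1]

    def _zx(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale

    @property
    def Z(self) -> np.ndarray:
        return self._zx(self.X_train)

    @property
    def y_std(self) -> np.ndarray:
        return (self.y_train - self.y_mean) / self.y_scale

    def condition(self, X_new: np.ndarray, y_new: np.ndarray) -> "GPSurrogate":
        """New surrogate with extra observations, hyperparameters unchanged."""
        X = np.vstack([self.X_train, np.atleast_2d(X_new)])
        y = np.concatenate([self.y_train, np.atleast_1d(y_new)])
        m = replace(self, X_train=X, y_train=y, _chol=None, _alpha=None)
        m._factorize()
        return m

    def _factorize(self):
        Z = self.Z
        K = kernel_matrix(Z, Z, self.kernel, self.lengthscales, self.signal_variance)
        K[np.diag_indices_from(K)] += max(self.noise_variance, 0.0)
        self._chol = _chol_with_jitter(K)
        self._alpha = cho_solve((self._chol, True), self.y_std)


def _chol_with_jitter(K: np.ndarray, jitter: float = 1e-8, max_jitter: float = 1e-4):
    j = 0.0
    while True:
        try:
            return cholesky(K + j * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            j = jitter if j == 0.0 else j * 10.0
            if j > max_jitter:
                raise NumericalConditioningError(
                    "training covariance not positive definite even with jitter "
                    f"up to {max_jitter:g}; check for duplicated inputs with "
                    "conflicting targets, or raise the noise floor"
                )


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def _neg_lml_and_grad(theta, Z, y, kernel, d, ard, noise_floor):
    """Negative log marginal likelihood and gradient in log space.

    theta = [log ls (d or 1), log sf2, log noise].
    """
    n_ls = d if ard else 1
    ls = np.exp(theta[:n_ls]) * np.ones(d)
    sf2 = np.exp(theta[n_ls])
    noise = np.exp(theta[n_ls + 1]) + noise_floor
    n = Z.shape[0]
    K, grads_ls, grad_sf2 = _kernel_grads(Z, kernel, ls, sf2)
    Ky = K + noise * np.eye(n)
    try:
        L = cholesky(Ky + 1e-10 * np.eye(n), lower=True)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    alpha = cho_solve((L, True), y)
    lml = (
        -0.5 * y @ alpha
        - np.sum(np.log(np.diag(L)))
        - 0.5 * n * np.log(2 * np.pi)
    )
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # d lml / dK = 0.5 W
    grad = np.empty_like(theta)
    if ard:
        for j in range(d):
            grad[j] = 0.5 * np.sum(W * grads_ls[:, :, j])
    else:
        grad[0] = 0.5 * np.sum(W * grads_ls.sum(axis=2))
    grad[n_ls] = 0.5 * np.sum(W * grad_sf2)
    grad[n_ls + 1] = 0.5 * np.trace(W) * (noise - noise_floor)
    return -lml, -grad


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    config: GPConfig = GPConfig(),
    seed: int | None = 0,
) -> GPSurrogate:
    """Fit a GP by multi-restart type-II maximum likelihood.

    Inputs are z-scored per column and targets standardised (unless
    ``config.normalize`` is False).  With ``config.optimize`` False the
    hyperparameters in ``config`` are used verbatim.  Refitting with the same
    seed and data is bit-reproducible.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise InvalidArgumentError("X and y row counts differ")
    if X.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("X and y must be finite")
    n, d = X.shape

    if config.normalize:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale[x_scale == 0] = 1.0
        y_mean = float(y.mean())
        y_scale = float(y.std()) or 1.0
    else:
        x_mean, x_scale = np.zeros(d), np.ones(d)
        y_mean, y_scale = 0.0, 1.0
    Z = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    n_ls = d if config.ard else 1

    if not config.optimize:
        if config.lengthscales is None:
            raise InvalidArgumentError("optimize=False requires explicit lengthscales")
        ls = np.asarray(config.lengthscales, dtype=float) * np.ones(d)
        model = GPSurrogate(
            kernel=config.kernel,
            ard=config.ard,
            lengthscales=ls,
            signal_variance=float(config.signal_variance),
            noise_variance=float(config.noise_variance),
            X_train=X,
            y_train=y,
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=y_mean,
            y_scale=y_scale,
            log_marginal_likelihood=np.nan,
            seed=seed,
        )
        model._factorize()
        nll, _ = _neg_lml_and_grad(
            np.log(np.concatenate([ls[:n_ls], [model.signal_variance],
                                   [max(model.noise_variance, 1e-300)]])),
            Z, ys, config.kernel, d, config.ard, 0.0,
        )
        model.log_marginal_likelihood = -nll
        return model

    rng = np.random.default_rng(seed)
    starts = [np.concatenate([np.zeros(n_ls), [0.0], [np.log(1e-2)]])]
    for _ in range(max(config.n_restarts - 1, 0)):
        starts.append(
            np.concatenate(
                [
                    rng.uniform(np.log(0.1), np.log(10.0), size=n_ls),
                    [rng.uniform(np.log(0.1), np.log(2.0))],
                    [rng.uniform(np.log(1e-4), np.log(0.5))],
                ]
            )
        )
    bounds = (
        [(np.log(1e-2), np.log(1e3))] * n_ls
        + [(np.log(1e-4), np.log(1e3))]
        + [(np.log(1e-8), np.log(10.0))]
    )
    best = None
    for theta0 in starts:
        res = minimize(
            _neg_lml_and_grad,
            theta0,
            args=(Z, ys, config.kernel, d, config.ard, config.noise_floor),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ls = np.exp(theta[:n_ls]) * np.ones(d)
    model = GPSurrogate(
        kernel=config.kernel,
        ard=config.ard,
        lengthscales=ls,
        signal_variance=float(np.exp(theta[n_ls])),
        noise_variance=float(np.exp(theta[n_ls + 1]) + config.noise_floor),
        X_train=X,
        y_train=y,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        log_marginal_likelihood=float(-best.fun),
        seed=seed,
    )
    model._factorize()
    return model


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------

def predict(
    model: GPSurrogate, Xstar: np.ndarray, include_noise: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior means and variances at ``Xstar`` in raw target units.

    ``include_noise`` adds the observation-noise variance to the latent
    predictive variance (i.e. predicts a new *measurement* rather than the
    latent function value).
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != model.dim:
        raise InvalidArgumentError(
            f"Xstar has {Xstar.shape[1]} columns, model expects {model.dim}"
        )
    Zs = model._zx(Xstar)
    Z = model.Z
    Ks = kernel_matrix(Zs, Z, model.kernel, model.lengthscales, model.signal_variance)
    mean_std = Ks @ model._alpha
    V = solve_triangular(model._chol, Ks.T, lower=True)
    var_std = model.signal_variance - np.sum(V**2, axis=0)
    var_std = np.maximum(var_std, 0.0)
    if include_noise:
        var_std = var_std + model.noise_variance
    mean = model.y_mean + model.y_scale * mean_std
    var = model.y_scale**2 * var_std
    return mean, var


# --------------------------------------------------------------------------
# Thompson sampling (spectral posterior functions)
# --------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    """One posterior function draw, deterministic once constructed.

    The prior part is a random-Fourier-feature expansion
    f₀(x) = √(2σ²_f/M) Σ_i w_i cos(ω_iᵀ z + b_i); the posterior correction is
    Matheron's pathwise update f(x) = f₀(x) + k(x, X)(K+σ²I)⁻¹(y − f₀(X) − ε),
    so ensemble statistics over draws match the exact posterior up to the
    O(1/M) spectral approximation of the prior covariance.
    """

    model: GPSurrogate
    omega: np.ndarray   # (M, d) spectral frequencies (standardised space)
    phases: np.ndarray  # (M,)
    weights: np.ndarray  # (M,)
    resid_coef: np.ndarray  # (n,) pathwise-update coefficients
    seed: int | None

    def _prior(self, Zs: np.ndarray) -> np.ndarray:
        M = self.omega.shape[0]
        proj = Zs @ self.omega.T + self.phases
        return np.sqrt(2.0 * self.model.signal_variance / M) * (
            np.cos(proj) @ self.weights
        )

    def __call__(self, Xstar: np.ndarray) -> np.ndarray:
        """Evaluate the sampled function (raw target units) at raw inputs."""
        Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
        if Xstar.shape[1] != self.model.dim:
            raise InvalidArgumentError("dimension mismatch")
        Zs = self.model._zx(Xstar)
        Ks = kernel_matrix(
            Zs, self.model.Z, self.model.kernel,
            self.model.lengthscales, self.model.signal_variance,
        )
        f = self._prior(Zs) + Ks @ self.resid_coef
        return self.model.y_mean + self.model.y_scale * f


def sample_posterior_function(
    model: GPSurrogate,
    n_spectral_features: int = 512,
    seed: int | None = 0,
) -> PosteriorSample:
    """Draw one function from the GP posterior (latent, noise-free).

    Spectral frequencies follow the kernel's spectral density — Gaussian for
    the squared-exponential, multivariate Student-t with 5 degrees of freedom
    for Matérn 5/2 — scaled by the inverse ARD length scales.
    """
    if n_spectral_features < 1:
        raise InvalidArgumentError("n_spectral_features must be ≥ 1")
    if model.kernel not in ("matern52", "rbf"):
        raise UnsupportedConfigError(
            f"spectral sampling unsupported for kernel {model.kernel!r}"
        )
    rng = np.random.default_rng(seed)
    M, d = n_spectral_features, model.dim
    z = rng.standard_normal((M, d))
    if model.kernel == "matern52":
        g = rng.chisquare(5.0, size=(M, 1))
        z = z * np.sqrt(5.0 / g)
    omega = z / model.lengthscales
    phases = rng.uniform(0.0, 2.0 * np.pi, size=M)
    weights = rng.standard_normal(M)

    Z = model.Z
    proj = Z @ omega.T + phases
    f0_train = np.sqrt(2.0 * model.signal_variance / M) * (np.cos(proj) @ weights)
    eps = rng.standard_normal(model.n) * np.sqrt(max(model.noise_variance, 0.0))
    resid = model.y_std - f0_train - eps
    resid_coef = cho_solve((model._chol, True), resid)
    return PosteriorSample(
        model=model,
        omega=omega,
        phases=phases,
        weights=weights,
        resid_coef=resid_coef,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Leave-one-out cross-validation
# --------------------------------------------------------------------------

def loocv_q2(
    X: np.ndarray,
    y: np.ndarray,
    config: GPConfig = GPConfig(),
    seed: int | None = 0,
    formula: str = "press",
) -> tuple[float, np.ndarray]:
    """Honest leave-one-out q² with per-fold hyperparameter re-optimisation.

    ``formula="press"`` (default, the QSAR convention) computes
    q² = 1 − PRESS/TSS with TSS about the full-sample mean;
    ``formula="pearson"`` returns the squared Pearson correlation between
    held-out predictions and observations.  Also returns the per-point
    held-out predictions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise InvalidArgumentError("LOOCV needs at least 3 points")
    if np.var(y) == 0:
        raise UndefinedQuantityError("q² undefined for zero-variance targets")
    child_seeds = as_seedseq(seed).generate_state(n)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = fit_gp(X[mask], y[mask], config, seed=int(child_seeds[i] % (2**31)))
        preds[i] = predict(m, X[i : i + 1])[0][0]
        mask[i] = True
    if formula == "press":
        press = float(np.sum((y - preds) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        q2 = 1.0 - press / tss
    elif formula == "pearson":
        q2 = float(np.corrcoef(y, preds)[0, 1] ** 2)
    else:
        raise InvalidArgumentError(f"unknown q² formula {formula!r}")
    return q2, preds


def q2_score(y: np.ndarray, preds: np.ndarray, formula: str = "press") -> float:
    """q² from observations and held-out predictions (no refitting)."""
    y = np.asarray(y, dtype=float)
    preds = np.asarray(preds, dtype=float)
    if np.var(y) == 0:
        raise UndefinedQuantityError("q² undefined for zero-variance targets")
    if formula == "press":
        return 1.0 - float(np.sum((y - preds) ** 2)) / float(np.sum((y - y.mean()) ** 2))
    if formula == "pearson":
        return float(np.corrcoef(y, preds)[0, 1] ** 2)
    raise InvalidArgumentError(f"unknown q² formula {formula!r}")


# --------------------------------------------------------------------------
# Relevance and threshold classification
# --------------------------------------------------------------------------

def relevance_ranking(
    model: GPSurrogate, feature_names: Sequence[str]
) -> list[tuple[str, float]]:
    """Features ordered by increasing ARD length scale (most relevant first).

    Smaller length scale ⇒ the objective varies faster along that input ⇒
    greater relevance.  Ties keep input order (stable sort).
    """
    if not model.ard:
        raise UnsupportedConfigError("relevance ranking requires an ARD kernel")
    names = list(feature_names)
    if len(names) != model.dim:
        raise InvalidArgumentError("one name per input dimension required")
    order = np.argsort(model.lengthscales, kind="stable")
    return [(names[i], float(model.lengthscales[i])) for i in order]


def classify_by_threshold(
    conversion,
    de,
    thresholds: tuple[float, float] = (80.0, 65.0),
):
    """Per-objective and joint high/low labels under strict thresholds.

    A value is 'high' iff it strictly exceeds its threshold; the joint label
    is 'high' iff both objectives are.  Returns boolean arrays (or scalars)
    ``(conv_high, de_high, joint_high)``.
    """
    conv = np.asarray(conversion, dtype=float)
    de_ = np.asarray(de, dtype=float)
    t_conv, t_de = thresholds
    conv_high = conv > t_conv
    de_high = de_ > t_de
    joint = conv_high & de_high
    if conv.ndim == 0:
        return bool(conv_high), bool(de_high), bool(joint)
    return conv_high, de_high, joint
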