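"""Squared-exponential GP regression with hyperparameter priors and
CCD-based marginal-likelihood estimation.

The model for a single expression time course is

    x(t) = f(t) + eps,   f ~ GP(0, k_se),   eps ~ N(0, sigma_eps^2),

with the squared-exponential kernel

    k_se(t, t') = sigma_se^2 * exp(-(t - t')^2 / (2 * ell^2)).

Rather than optimising the three hyperparameters (type-II maximum
likelihood, which overfits badly on the short series typical of
longitudinal omics), the marginal likelihood p(X | M) is approximated by
numerically integrating the product likelihood x prior over a central
composite design (CCD) of hyperparameter points: the posterior mode, star
points along whitened axes, and a 2^d factorial, with a split-Gaussian
approximation supplying per-direction scales.  All hyperparameters are
handled on the natural-log scale internally; priors are stated on the
natural scale and the change-of-variables Jacobian is applied.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import minimize
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

PARAM_NAMES = ("lengthscale", "signal_variance", "noise_variance")


class InvalidParameterError(ValueError):
    """Raised when hyperparameters are non-positive or malformed."""


class GPLinalgError(RuntimeError):
    """Raised when a covariance factorisation fails even after jitter escalation."""


class OptimisationError(RuntimeError):
    """Raised when every MAP restart fails."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeries:
    """Observed expression values at (possibly duplicated) times in weeks."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size < 1:
            raise ValueError("a time series needs at least one observation")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def centred(self) -> tuple["TimeSeries", float]:
        """Return a mean-centred copy together with the subtracted mean."""
        mu = float(self.values.mean())
        return TimeSeries(self.times, self.values - mu), mu


@dataclass(frozen=True)
class Hyperparameters:
    """SE-kernel hyperparameters on the natural scale.

    lengthscale is in weeks; signal_variance and noise_variance are in
    squared (log-)expression units.
    """

    lengthscale: float
    signal_variance: float
    noise_variance: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v}")

    def to_log(self) -> np.ndarray:
        return np.log([self.lengthscale, self.signal_variance, self.noise_variance])

    @staticmethod
    def from_log(phi: np.ndarray) -> "Hyperparameters":
        ell, sv, nv = np.exp(np.asarray(phi, dtype=float))
        return Hyperparameters(ell, sv, nv)


@dataclass(frozen=True)
class HyperPriors:
    """Priors on the natural-scale hyperparameters.

    * lengthscale: Gaussian with mean 30 weeks, variance 6 — concentrates
      on smooth, months-scale dynamics and makes very short length-scales
      improbable.
    * signal standard deviation sigma_se: half-Student-t (nu=20, scale=1).
    * noise variance: scaled-inverse-chi-square (nu=1, scale^2=0.01),
      which keeps the noise floor small but heavy-tailed.
    """

    lengthscale_mean: float = 30.0
    lengthscale_var: float = 6.0
    signal_sd_scale: float = 1.0
    signal_sd_df: float = 20.0
    noise_scale_sq: float = 0.01
    noise_df: float = 1.0

    def log_density(self, hp: Hyperparameters) -> float:
        """Log prior density on the natural scale (no Jacobian).

        Closed forms (Gaussian, half-Student-t, scaled-inverse-chi-square
        == InvGamma(nu/2, nu*tau^2/2)) are written out directly; this is
        the hottest scalar in mode finding.
        """
        z = (hp.lengthscale - self.lengthscale_mean) / math.sqrt(self.lengthscale_var)
        lp = -0.5 * z * z - 0.5 * math.log(2 * math.pi * self.lengthscale_var)

        sd = math.sqrt(hp.signal_variance)
        nu, s = self.signal_sd_df, self.signal_sd_scale
        lp += (
            math.log(2.0)
            + math.lgamma((nu + 1) / 2)
            - math.lgamma(nu / 2)
            - 0.5 * math.log(nu * math.pi)
            - math.log(s)
            - 0.5 * (nu + 1) * math.log1p((sd / s) ** 2 / nu)
        )

        a = self.noise_df / 2.0
        b = self.noise_df * self.noise_scale_sq / 2.0
        v = hp.noise_variance
        lp += a * math.log(b) - math.lgamma(a) - (a + 1) * math.log(v) - b / v
        return float(lp)

    def log_density_log_scale(self, phi: np.ndarray) -> float:
        """Log prior density of phi = log(theta), Jacobians included.

        The signal prior is stated on sigma_se while phi parameterises
        log(sigma_se^2), so its Jacobian is d sigma / d phi = sigma / 2.
        """
        phi = np.asarray(phi, dtype=float)
        if not np.all(np.isfinite(phi)):
            return -np.inf
        hp = Hyperparameters.from_log(phi)
        jac = phi[0] + (0.5 * phi[1] - math.log(2.0)) + phi[2]
        return self.log_density(hp) + jac

    def log_density_log_scale_grad(self, phi: np.ndarray) -> np.ndarray:
        """Closed-form gradient of ``log_density_log_scale`` w.r.t. phi."""
        ell, sv, nv = np.exp(np.asarray(phi, dtype=float))
        g0 = -(ell - self.lengthscale_mean) * ell / self.lengthscale_var + 1.0
        nu, s = self.signal_sd_df, self.signal_sd_scale
        g1 = -(nu + 1) * sv / (2.0 * (s**2 * nu + sv)) + 0.5
        a = self.noise_df / 2.0
        b = self.noise_df * self.noise_scale_sq / 2.0
        g2 = -a + b / nv
        return np.array([g0, g1, g2])

    def initial_log_point(self) -> np.ndarray:
        """Optimiser starting point near the prior means."""
        return np.array(
            [math.log(self.lengthscale_mean), math.log(self.signal_sd_scale**2), math.log(self.noise_scale_sq)]
        )


@dataclass
class GPConfig:
    """Numerical knobs for fitting and CCD integration."""

    jitter_initial_rel: float = 1e-8
    jitter_max_rel: float = 1e-2
    jitter_factor: float = 10.0
    ccd_scale: float = 1.1  # radius multiplier f: design radius = f * sqrt(d)
    restarts: int = 5
    restart_sd: float = 0.5
    seed: int = 0
    phi_bounds: tuple[float, float] = (-12.0, 12.0)


@dataclass(frozen=True)
class GPPosterior:
    """Gaussian posterior over latent function values at test times."""

    mean: np.ndarray
    cov: np.ndarray
    test_times: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float)
        c = np.asarray(self.cov, dtype=float)
        t = np.asarray(self.test_times, dtype=float)
        if c.shape != (m.size, m.size) or t.size != m.size:
            raise ValueError("inconsistent posterior dimensions")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", 0.5 * (c + c.T))
        object.__setattr__(self, "test_times", t)


@dataclass
class CCDGrid:
    """Central-composite design over log-hyperparameters.

    points holds the design on the natural scale; posterior_values are the
    split-Gaussian q(theta_r | M) relative to the mode (q=1 there); weights
    are integration volumes Delta_r in log-hyperparameter space.
    """

    points: list[Hyperparameters]
    posterior_values: np.ndarray
    weights: np.ndarray
    mode: Hyperparameters
    hessian: np.ndarray
    log_joints: np.ndarray  # cached log p(X|theta_r) + log p(theta_r) (log scale)
    free: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if len(self.points) < 1:
            raise ValueError("CCD grid needs at least one point")
        if np.any(self.weights <= 0):
            raise ValueError("CCD weights must be positive")
        if not np.allclose(self.hessian, self.hessian.T, atol=1e-8):
            raise ValueError("hessian must be symmetric")


# ---------------------------------------------------------------------------
# kernel and posterior
# ---------------------------------------------------------------------------


def se_kernel(t1: np.ndarray, t2: np.ndarray, hp: Hyperparameters) -> np.ndarray:
    """Squared-exponential kernel matrix between two sets of times."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise InvalidParameterError("kernel inputs must be finite")
    d = t1[:, None] - t2[None, :]
    return hp.signal_variance * np.exp(-0.5 * (d / hp.lengthscale) ** 2)


def _chol_with_jitter(A: np.ndarray, cfg: GPConfig) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor with an escalating relative jitter ladder."""
    scale = float(np.mean(np.diag(A)))
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    jitter = 0.0
    rel = cfg.jitter_initial_rel
    n = A.shape[0]
    while True:
        try:
            L = linalg.cholesky(A + jitter * np.eye(n), lower=True)
            return L, jitter
        except linalg.LinAlgError:
            if rel > cfg.jitter_max_rel:
                raise GPLinalgError(
                    f"Cholesky failed after escalating jitter to {jitter:g}"
                ) from None
            jitter = rel * scale
            rel *= cfg.jitter_factor


def gp_posterior(
    data: TimeSeries,
    test_times: np.ndarray,
    hp: Hyperparameters,
    cfg: GPConfig | None = None,
) -> GPPosterior:
    """Exact GP posterior at ``test_times`` for fixed hyperparameters.

    mu* = K(T*,T) (K(T,T) + s_eps^2 I)^{-1} X
    Sigma* = K(T*,T*) - K(T*,T) (K(T,T) + s_eps^2 I)^{-1} K(T,T*)
    """
    cfg = cfg or GPConfig()
    test_times = np.atleast_1d(np.asarray(test_times, dtype=float))
    K = se_kernel(data.times, data.times, hp)
    Ky = K + hp.noise_variance * np.eye(len(data))
    L, _ = _chol_with_jitter(Ky, cfg)
    Ks = se_kernel(test_times, data.times, hp)
    Kss = se_kernel(test_times, test_times, hp)
    alpha = linalg.cho_solve((L, True), data.values)
    V = linalg.solve_triangular(L, Ks.T, lower=True)
    mean = Ks @ alpha
    cov = Kss - V.T @ V
    return GPPosterior(mean, cov, test_times)


# ---------------------------------------------------------------------------
# log joint (likelihood x prior) and its gradient on the log scale
# ---------------------------------------------------------------------------


def log_marginal_likelihood(data: TimeSeries, hp: Hyperparameters, cfg: GPConfig | None = None) -> float:
    """log N(X; 0, K + s_eps^2 I) for fixed hyperparameters."""
    cfg = cfg or GPConfig()
    n = len(data)
    Ky = se_kernel(data.times, data.times, hp) + hp.noise_variance * np.eye(n)
    L, _ = _chol_with_jitter(Ky, cfg)
    alpha = linalg.cho_solve((L, True), data.values)
    return float(
        -0.5 * data.values @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2 * math.pi)
    )


def log_joint(
    data: TimeSeries,
    hp: Hyperparameters,
    priors: HyperPriors,
    cfg: GPConfig | None = None,
) -> float:
    """log [ p(X | theta) p(theta) ] in the log-scale parameterisation.

    Degenerate hyperparameters (factorisation failure, overflow) yield
    -inf explicitly rather than an exception, so optimisers can step
    around them.
    """
    cfg = cfg or GPConfig()
    phi = hp.to_log()
    lp = priors.log_density_log_scale(phi)
    if not np.isfinite(lp):
        return -np.inf
    D2 = (data.times[:, None] - data.times[None, :]) ** 2
    ll = _lml_phi(phi, D2, data.values, cfg)
    out = ll + lp
    return out if np.isfinite(out) else -np.inf


def _chol_jitter_fast(Ky: np.ndarray, cfg: GPConfig) -> np.ndarray | None:
    """np.linalg Cholesky with the escalating jitter ladder; None on failure."""
    scale = float(Ky.trace()) / Ky.shape[0]
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    jitter = 0.0
    rel = cfg.jitter_initial_rel
    eye = np.eye(Ky.shape[0])
    while True:
        try:
            return np.linalg.cholesky(Ky + jitter * eye)
        except np.linalg.LinAlgError:
            if rel > cfg.jitter_max_rel:
                return None
            jitter = rel * scale
            rel *= cfg.jitter_factor


def _lml_phi(phi: np.ndarray, D2: np.ndarray, x: np.ndarray, cfg: GPConfig) -> float:
    """Gaussian log marginal likelihood at phi = log(theta); -inf if degenerate."""
    with np.errstate(over="ignore"):
        ell, sv, nv = np.exp(phi)
    if not np.all(np.isfinite([ell, sv, nv])):
        return -np.inf
    n = x.size
    Ky = sv * np.exp(-0.5 * D2 / (ell * ell))
    Ky.flat[:: n + 1] += nv
    L = _chol_jitter_fast(Ky, cfg)
    if L is None:
        return -np.inf
    alpha = linalg.cho_solve((L, True), x, check_finite=False)
    val = float(-0.5 * x @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2 * math.pi))
    return val if np.isfinite(val) else -np.inf


def _log_joint_and_grad(
    phi: np.ndarray, D2: np.ndarray, x: np.ndarray, priors: HyperPriors, cfg: GPConfig
) -> tuple[float, np.ndarray]:
    """Value and gradient of log_joint w.r.t. phi = log(theta).

    Likelihood gradient by the standard trace identities; prior gradient
    in closed form.  Degenerate hyperparameters yield (-inf, 0).
    """
    phi = np.asarray(phi, dtype=float)
    lp = priors.log_density_log_scale(phi)
    if not np.isfinite(lp):
        return -np.inf, np.zeros(3)
    with np.errstate(over="ignore"):
        ell, sv, nv = np.exp(phi)
    if not np.all(np.isfinite([ell, sv, nv])):
        return -np.inf, np.zeros(3)
    n = x.size
    B = D2 / (ell * ell)
    Kse = sv * np.exp(-0.5 * B)
    Ky = Kse.copy()
    Ky.flat[:: n + 1] += nv
    L = _chol_jitter_fast(Ky, cfg)
    if L is None:
        return -np.inf, np.zeros(3)
    alpha = linalg.cho_solve((L, True), x, check_finite=False)
    ll = float(-0.5 * x @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * math.log(2 * math.pi))
    val = ll + lp
    if not np.isfinite(val):
        return -np.inf, np.zeros(3)

    Kinv = linalg.cho_solve((L, True), np.eye(n), check_finite=False)
    W = np.outer(alpha, alpha) - Kinv  # d logN / dK = W / 2
    grad = np.array(
        [
            0.5 * np.sum(W * (Kse * B)),
            0.5 * np.sum(W * Kse),
            0.5 * nv * np.trace(W),
        ]
    )
    grad += priors.log_density_log_scale_grad(phi)
    return val, grad


# ---------------------------------------------------------------------------
# MAP mode and Hessian
# ---------------------------------------------------------------------------


def _embed(phi_free: np.ndarray, phi_base: np.ndarray, free: tuple[int, ...]) -> np.ndarray:
    phi = phi_base.copy()
    phi[list(free)] = phi_free
    return phi


def find_mode(
    data: TimeSeries,
    priors: HyperPriors,
    cfg: GPConfig | None = None,
    restarts: int | None = None,
    fixed: dict[str, float] | None = None,
) -> tuple[Hyperparameters, np.ndarray]:
    """MAP estimate of the log-hyperparameters by multi-start L-BFGS-B.

    Returns the mode (natural scale) and the negative Hessian of the log
    joint at the mode over the *free* dimensions (central differences).
    ``fixed`` clamps named hyperparameters at given natural-scale values.
    Deterministic for a given cfg.seed.
    """
    cfg = cfg or GPConfig()
    restarts = cfg.restarts if restarts is None else restarts
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    fixed = fixed or {}
    for k in fixed:
        if k not in PARAM_NAMES:
            raise ValueError(f"unknown hyperparameter {k!r}")
    free = tuple(i for i, name in enumerate(PARAM_NAMES) if name not in fixed)
    if not free:
        raise ValueError("at least one hyperparameter must be free")
    phi_base = priors.initial_log_point()
    for name, v in fixed.items():
        if v <= 0:
            raise InvalidParameterError(f"fixed {name} must be > 0")
        phi_base[PARAM_NAMES.index(name)] = math.log(v)

    D2 = (data.times[:, None] - data.times[None, :]) ** 2
    x = data.values
    free_list = list(free)

    def negobj(phi_free):
        val, grad = _log_joint_and_grad(_embed(phi_free, phi_base, free), D2, x, priors, cfg)
        if not np.isfinite(val):
            return 1e12, np.zeros(len(free))
        return -val, -grad[free_list]

    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.phi_bounds
    bounds = [(lo, hi)] * len(free)
    best = None
    for r in range(restarts):
        x0 = phi_base[list(free)].copy()
        if r > 0:
            x0 = x0 + rng.normal(0.0, cfg.restart_sd, size=len(free))
        x0 = np.clip(x0, lo, hi)
        try:
            res = minimize(negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        except (linalg.LinAlgError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise OptimisationError("all MAP restarts failed")

    phi_mode = _embed(best.x, phi_base, free)
    H = _neg_hessian_fd(phi_mode, free, data, priors, cfg)
    return Hyperparameters.from_log(phi_mode), H


def _neg_hessian_fd(
    phi: np.ndarray, free: tuple[int, ...], data: TimeSeries, priors: HyperPriors, cfg: GPConfig
) -> np.ndarray:
    """Negative Hessian of log_joint over the free dims, central differences."""
    D2 = (data.times[:, None] - data.times[None, :]) ** 2

    def f(phi_free):
        p = _embed(phi_free, phi.copy(), free)
        return _lml_phi(p, D2, data.values, cfg) + priors.log_density_log_scale(p)

    x = phi[list(free)]
    d = len(free)
    h = 1e-4
    H = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return -0.5 * (H + H.T)


def _nearest_pd(H: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix onto the PD cone by eigenvalue clipping."""
    w, V = linalg.eigh(H)
    if np.all(w > 0):
        return H
    logger.warning("non-PD Hessian at CCD mode; clipping eigenvalues (min %g)", w.min())
    w = np.maximum(w, floor * max(1.0, np.abs(w).max()))
    return V @ np.diag(w) @ V.T


# ---------------------------------------------------------------------------
# central composite design
# ---------------------------------------------------------------------------


def _ccd_directions(d: int) -> list[np.ndarray]:
    """Unit direction vectors: 2d star axes plus the 2^d factorial corners.

    Exact duplicates (d = 1, where corners coincide with the star axes)
    are merged.
    """
    dirs: list[np.ndarray] = []
    seen = set()
    for i in range(d):
        for s in (1.0, -1.0):
            u = np.zeros(d)
            u[i] = s
            key = tuple(np.round(u, 12))
            if key not in seen:
                seen.add(key)
                dirs.append(u)
    for signs in itertools.product((1.0, -1.0), repeat=d):
        u = np.array(signs) / math.sqrt(d)
        key = tuple(np.round(u, 12))
        if key not in seen:
            seen.add(key)
            dirs.append(u)
    return dirs


def build_ccd(
    mode: Hyperparameters,
    hessian: np.ndarray,
    data: TimeSeries,
    priors: HyperPriors,
    cfg: GPConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> CCDGrid:
    """CCD grid around the MAP mode in whitened log-hyperparameter space.

    Per-direction split-Gaussian scales are found by bisection on the log
    joint: along each whitened half-axis the design distance is stretched
    until the log joint has dropped by r0^2/2 below the mode, so every
    non-mode design point carries q(theta_r | M) = exp(-r0^2/2) exactly
    under the split-Gaussian approximation.

    Integration weights: in standardised coordinates all non-mode points
    share one weight chosen so the rule integrates a standard Gaussian and
    its second moment exactly; the mode takes the complement (positive for
    any radius multiplier f > 1).  Weights are then mapped to
    log-hyperparameter volumes via the whitening determinant and the local
    split scales.
    """
    cfg = cfg or GPConfig()
    fixed = fixed or {}
    free = tuple(i for i, name in enumerate(PARAM_NAMES) if name not in fixed)
    d = len(free)
    phi_mode = mode.to_log()

    H = np.asarray(hessian, dtype=float)
    H = 0.5 * (H + H.T)
    if H.shape != (d, d):
        raise ValueError(f"hessian must be {d}x{d} over the free dimensions")
    H = _nearest_pd(H)
    Lh = linalg.cholesky(H, lower=True)
    # whitening: phi = phi_mode + Wfull z, with z'z the Mahalanobis distance
    W = linalg.solve_triangular(Lh, np.eye(d), lower=True).T

    r0 = cfg.ccd_scale * math.sqrt(d)
    D2 = (data.times[:, None] - data.times[None, :]) ** 2
    free_list = list(free)

    def lj_phi(phi: np.ndarray) -> float:
        lp = priors.log_density_log_scale(phi)
        if not np.isfinite(lp):
            return -np.inf
        return _lml_phi(phi, D2, data.values, cfg) + lp

    lj_mode = lj_phi(phi_mode)
    if not np.isfinite(lj_mode):
        raise OptimisationError("log joint not finite at the mode")
    target = r0**2 / 2.0

    def lj_at(z: np.ndarray) -> float:
        phi = phi_mode.copy()
        phi[free_list] = phi_mode[free_list] + W @ z
        return lj_phi(phi)

    # split scales: sigma[i, 0] for +axis, sigma[i, 1] for -axis
    sigma = np.ones((d, 2))
    for i in range(d):
        for col, s in ((0, 1.0), (1, -1.0)):
            e = np.zeros(d)
            e[i] = s
            t_lo, t_hi = 0.0, r0
            drop = lj_mode - lj_at(t_hi * e)
            n_expand = 0
            while drop < target and n_expand < 60:
                t_lo, t_hi = t_hi, t_hi * 2.0
                drop = lj_mode - lj_at(t_hi * e)
                n_expand += 1
            if drop < target:  # posterior flat to the edge; keep unit scale
                sigma[i, col] = 1.0
                continue
            for _ in range(24):
                t_mid = 0.5 * (t_lo + t_hi)
                if lj_mode - lj_at(t_mid * e) < target:
                    t_lo = t_mid
                else:
                    t_hi = t_mid
            sigma[i, col] = 0.5 * (t_lo + t_hi) / r0

    dirs = _ccd_directions(d)
    n_p = len(dirs)
    # standardised design second moment per axis (symmetric across axes)
    a = sum(float(np.sum((r0 * u) ** 2)) for u in dirs) / d
    log_norm = 0.5 * d * math.log(2 * math.pi)
    delta_non = math.exp(log_norm + target) / a
    mass_mode = 1.0 - n_p / a
    if mass_mode <= 0:
        raise ValueError(
            f"ccd_scale {cfg.ccd_scale} leaves no mass at the mode; use f > 1"
        )
    delta_mode = math.exp(log_norm) * mass_mode

    det_W = float(np.prod(1.0 / np.diag(Lh)))  # |det W|
    sigma_avg = 0.5 * (sigma[:, 0] + sigma[:, 1])

    points = [mode]
    qs = [1.0]
    deltas = [delta_mode * det_W * float(np.prod(sigma_avg))]
    for u in dirs:
        stretch = np.where(u > 0, sigma[:, 0], np.where(u < 0, sigma[:, 1], sigma_avg))
        z = r0 * u * stretch
        phi = phi_mode.copy()
        phi[list(free)] = phi_mode[list(free)] + W @ z
        points.append(Hyperparameters.from_log(phi))
        qs.append(math.exp(-target))
        deltas.append(delta_non * det_W * float(np.prod(stretch)))

    ljs = np.array([lj_phi(p.to_log()) for p in points])
    hess_full = np.zeros((3, 3))
    for a_i, i in enumerate(free):
        for a_j, j in enumerate(free):
            hess_full[i, j] = H[a_i, a_j]
    return CCDGrid(
        points=points,
        posterior_values=np.array(qs),
        weights=np.array(deltas),
        mode=mode,
        hessian=hess_full,
        log_joints=ljs,
        free=free,
    )


def fit_ccd(
    data: TimeSeries,
    priors: HyperPriors,
    cfg: GPConfig | None = None,
    fixed: dict[str, float] | None = None,
) -> CCDGrid:
    """Find the MAP mode and build the CCD grid for one series."""
    cfg = cfg or GPConfig()
    mode, H = find_mode(data, priors, cfg, fixed=fixed)
    return build_ccd(mode, H, data, priors, cfg, fixed=fixed)


def estimate_log_ml(
    data: TimeSeries,
    priors: HyperPriors,
    cfg: GPConfig | None = None,
    fixed: dict[str, float] | None = None,
    grid: CCDGrid | None = None,
) -> float:
    """CCD estimate of log p(X | M) = log sum_r p(X|theta_r) p(theta_r) Delta_r."""
    if grid is None:
        grid = fit_ccd(data, priors, cfg, fixed=fixed)
    finite = np.isfinite(grid.log_joints)
    if not finite.any():
        return -np.inf
    return float(logsumexp(grid.log_joints[finite] + np.log(grid.weights[finite])))


def predictive_distribution(
    data: TimeSeries,
    test_times: np.ndarray,
    grid: CCDGrid,
    cfg: GPConfig | None = None,
) -> GPPosterior:
    """CCD-mixture predictive: q(theta_r|M) Delta_r-weighted posterior.

    Weights are renormalised to sum to one; the covariance is the weighted
    average of the per-point posterior covariances (no between-component
    mean-dispersion term).
    """
    cfg = cfg or GPConfig()
    test_times = np.atleast_1d(np.asarray(test_times, dtype=float))
    w = grid.posterior_values * grid.weights
    if w.sum() <= 0:
        raise ValueError("CCD mixture weights sum to zero")
    w = w / w.sum()
    mean = np.zeros(test_times.size)
    cov = np.zeros((test_times.size, test_times.size))
    for wi, hp in zip(w, grid.points):
        if wi == 0.0:
            continue
        post = gp_posterior(data, test_times, hp, cfg)
        mean += wi * post.mean
        cov += wi * post.cov
    return GPPosterior(mean, cov, test_times)
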