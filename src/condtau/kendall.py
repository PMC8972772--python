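"""Kernel weights and (conditional) multivariate Kendall's tau estimators.

The multivariate Kendall's tau of a p-variate copula C is

    tau = (2^(p-1) - 1)^(-1) * (2^p * int C dC - 1),

the normalization keeping the measure in [-1, 1] for every dimension p.  Its
empirical version counts strictly dominated observation pairs.  The
conditional version localizes the count around a covariate value z with
Nadaraya-Watson kernel weights w_i(z, h) and replaces the 1/(n(n-1))
pair-count normalization by the weighted analogue 1/(1 - sum_i w_i^2):

    tau_hat(z, h) = (2^(p-1)-1)^(-1) *
                    (2^p / (1 - sum w_i^2) * sum_{i,j} w_i w_j I{Y_i < Y_j} - 1).

With uniform weights w_i = 1/n the conditional estimator reduces exactly to
the unconditional one; as the bandwidth grows it tends to the unconditional
empirical tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .exceptions import DegenerateWeightsError, EmptyWindowError
from .sample import LabeledSample

__all__ = [
    "KernelSpec",
    "EPANECHNIKOV",
    "epanechnikov_kernel",
    "WeightVector",
    "nw_weights",
    "conditional_marginal_cdf",
    "conditional_quantile",
    "conditional_copula",
    "dominance_matrix",
    "empirical_kendall_tau",
    "ConditionalTauEstimate",
    "conditional_kendall_tau",
    "TauTestResult",
    "unconditional_tau_test",
]


def epanechnikov_kernel(u):
    """Epanechnikov kernel 0.75 * (1 - u^2) on [-1, 1], zero outside."""
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KernelSpec:
    """A symmetric second-order kernel with compact support [-1, 1].

    ``c_k = int u^2 k(u) du`` and ``d_k = int k(u)^2 du`` are the moment
    constants entering asymptotic bias/variance expressions; both must be
    nonzero.
    """

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    c_k: float
    d_k: float

    def __call__(self, u):
        return self.fn(u)


#: Default kernel (compact support makes estimation windows disjoint when
#: conditioning points are spaced more than 2h apart).
EPANECHNIKOV = KernelSpec("epanechnikov", epanechnikov_kernel, c_k=0.2, d_k=0.6)


@dataclass(frozen=True)
class WeightVector:
    """Nadaraya-Watson weights at a conditioning point; nonnegative, sum to one."""

    w: np.ndarray
    z: float
    h: float

    @property
    def n_eff(self) -> float:
        """Effective sample size 1 / sum w_i^2."""
        return 1.0 / float(self.w @ self.w)

    @property
    def active(self) -> np.ndarray:
        """Indices of observations with positive weight."""
        return np.flatnonzero(self.w > 0)


def nw_weights(
    z: float,
    Z: np.ndarray,
    h: float,
    kernel: Callable[[np.ndarray], np.ndarray] = EPANECHNIKOV,
) -> WeightVector:
    """Nadaraya-Watson weights w_i = k((z - Z_i)/h) / sum_j k((z - Z_j)/h).

    Raises
    ------
    EmptyWindowError
        If no observation lies within the kernel support around ``z``.
    """
    if h <= 0:
        raise ValueError(f"bandwidth must be positive, got h={h}")
    Z = np.asarray(Z, dtype=float)
    k = np.asarray(kernel((z - Z) / h), dtype=float)
    total = k.sum()
    if total <= 0.0:
        raise EmptyWindowError(f"no observation within bandwidth h={h} of z={z}")
    return WeightVector(w=k / total, z=float(z), h=float(h))


def conditional_marginal_cdf(
    y: float, j: int, sample: LabeledSample, weights: WeightVector
) -> float:
    """Weighted conditional marginal CDF  F_hat_{jz}(y) = sum_i w_i I{Y_ji <= y}."""
    return float(np.clip(weights.w @ (sample.Y[:, j] <= y), 0.0, 1.0))

def conditional_quantile(
    u: float, j: int, sample: LabeledSample, weights: WeightVector
) -> float:
    """Left-continuous generalized inverse inf{y : F_hat_{jz}(y) >= u} over observed values."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must lie in [0, 1], got {u}")
    order = np.argsort(sample.Y[:, j], kind="stable")
    yj = sample.Y[order, j]
    cdf = np.cumsum(weights.w[order])
    idx = int(np.searchsorted(cdf, u - 1e-12, side="left"))
    idx = min(idx, len(yj) - 1)
    return float(yj[idx])


def conditional_copula(
    u: np.ndarray, sample: LabeledSample, weights: WeightVector
) -> float:
    """Nonparametric conditional copula estimate at ``u`` in [0, 1]^p.

    C_hat_z(u) = sum_i w_i I{Y_1i <= F_hat^{-1}_{1z}(u_1), ..., Y_pi <= F_hat^{-1}_{pz}(u_p)}.
    With uniform weights this is the empirical copula.
    """
    u = np.asarray(u, dtype=float).ravel()
    if u.shape[0] != sample.p:
        raise ValueError(f"u has length {u.shape[0]}, expected p={sample.p}")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("all coordinates of u must lie in [0, 1]")
    thresholds = np.array(
        [conditional_quantile(u[j], j, sample, weights) for j in range(sample.p)]
    )
    inside = np.all(sample.Y <= thresholds, axis=1)
    # exactly 0/1 at the corners regardless of quantile conventions
    if np.all(u == 1.0):
        return 1.0
    if np.any(u == 0.0):
        return 0.0
    return float(weights.w @ inside)


def cv_margin_bandwidth(
    y: np.ndarray,
    Z: np.ndarray,
    kernel: Callable[[np.ndarray], np.ndarray] = EPANECHNIKOV,
    grid: Optional[np.ndarray] = None,
    n_thresholds: int = 50,
) -> float:
    """Least-squares leave-one-out CV bandwidth for a conditional marginal CDF.

    Scores each candidate g by the LOO Brier score of the kernel-weighted
    conditional CDF F_hat_{z,g}(y) against the indicators I{y_l <= t} on a
    grid of thresholds t.  Margins that move quickly with the covariate get
    a small bandwidth; margins unrelated to the covariate get a bandwidth of
    the order of the covariate range (global ranks).
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float).ravel()
    n = Z.shape[0]
    if grid is None:
        span = float(Z.max() - Z.min())
        if span <= 0:
            raise ValueError("covariate has zero spread")
        d = np.sort(np.abs(Z[:, None] - Z[None, :]), axis=1)
        lo = max(float(np.median(d[:, min(5, n - 1)])) * 1.1, 1e-3 * span)
        grid = np.geomspace(lo, span, 10)
    thr = np.quantile(y, np.linspace(0.02, 0.98, n_thresholds))
    A = (y[None, :] <= thr[:, None]).astype(float)
    best_score, best_g = np.inf, float(grid[-1])
    for g in grid:
        W = np.asarray(kernel((Z[:, None] - Z[None, :]) / g), dtype=float)
        np.fill_diagonal(W, 0.0)
        s = W.sum(axis=1)
        if np.any(s <= 0):
            continue
        F = (A @ W.T) / s[None, :]
        score = float(((A - F) ** 2).sum())
        if score < best_score:
            best_score, best_g = score, float(g)
    return best_g


def conditional_pseudo_observations(
    sample: LabeledSample,
    bandwidths: Optional[np.ndarray] = None,
    kernel: Callable[[np.ndarray], np.ndarray] = EPANECHNIKOV,
) -> np.ndarray:
    """Local-rank (conditional pseudo-)observations U_ji = F_hat_{j,Z_i,g_j}(Y_ji).

    Each response is transformed by the kernel-weighted conditional marginal
    CDF evaluated at the observation's own covariate value, removing the
    covariate effect from the margins.  Under a conditional copula that does
    not vary with z, the transformed p-tuples are (approximately)
    exchangeable, which is what permutation-based covariance estimation
    requires.

    Parameters
    ----------
    bandwidths : scalar, (p,) array, or None
        Margin bandwidth(s) g_j.  ``None`` (default) selects each g_j by
        :func:`cv_margin_bandwidth`, which adapts to how fast each margin
        moves with the covariate.
    """
    n, p = sample.n, sample.p
    if bandwidths is None:
        g = np.array(
            [cv_margin_bandwidth(sample.Y[:, j], sample.Z, kernel) for j in range(p)]
        )
    else:
        g = np.broadcast_to(np.asarray(bandwidths, dtype=float), (p,))
    U = np.empty((n, p))
    diff = sample.Z[:, None] - sample.Z[None, :]
    for j in range(p):
        K = np.asarray(kernel(diff / g[j]), dtype=float)
        tot = K.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise EmptyWindowError(
                f"empty kernel window in margin {j + 1} at bandwidth {g[j]:.4g}"
            )
        K = K / tot
        ind = sample.Y[None, :, j] <= sample.Y[:, None, j]
        U[:, j] = (K * ind).sum(axis=1)
    return U


def _local_poly_hat(Z: np.ndarray, g: float, kernel, degree: int = 2) -> np.ndarray:
    """Local-polynomial smoother (hat) matrix for regression on Z.

    Degree 2 by default: the leading detrending bias is then O(g^3 m''')
    instead of O(g^2 m''), which matters for links with strong curvature
    (sinusoidal marginal links leave visible covariate-correlated residual
    structure under a local-linear fit).
    """
    d = Z[None, :] - Z[:, None] if Z.ndim == 1 else Z
    W = np.asarray(kernel(d / g), dtype=float)
    Wd = W * d
    Wd2 = Wd * d
    if degree == 1:
        S1 = Wd.sum(axis=1, keepdims=True)
        S2 = Wd2.sum(axis=1, keepdims=True)
        Wstar = W * S2 - Wd * S1
    elif degree == 2:
        S1 = Wd.sum(axis=1, keepdims=True)
        S2 = Wd2.sum(axis=1, keepdims=True)
        S3 = (Wd2 * d).sum(axis=1, keepdims=True)
        S4 = (Wd2 * d * d).sum(axis=1, keepdims=True)
        # first row of (X'WX)^{-1} X'W via cofactors of the 3x3 moment matrix
        c0 = S2 * S4 - S3 * S3
        c1 = S1 * S4 - S2 * S3
        c2 = S1 * S3 - S2 * S2
        Wstar = W * c0 - Wd * c1 + Wd2 * c2
    else:
        raise ValueError(f"unsupported local polynomial degree {degree}")
    s = Wstar.sum(axis=1, keepdims=True)
    if np.any(np.abs(s) <= 1e-300):
        raise EmptyWindowError(
            f"local-polynomial window degenerates at bandwidth {g:.4g}"
        )
    return Wstar / s


def _link_grid(Z: np.ndarray) -> np.ndarray:
    n = Z.shape[0]
    span = float(Z.max() - Z.min())
    if span <= 0:
        raise ValueError("covariate has zero spread")
    d = np.sort(np.abs(Z[:, None] - Z[None, :]), axis=1)
    lo = max(float(np.median(d[:, min(7, n - 1)])) * 1.1, 1e-3 * span)
    return np.geomspace(lo, span, 10)


def cv_link_bandwidth(
    y: np.ndarray,
    Z: np.ndarray,
    kernel: Callable[[np.ndarray], np.ndarray] = EPANECHNIKOV,
    grid: Optional[np.ndarray] = None,
    _dmat: Optional[np.ndarray] = None,
) -> float:
    """Leave-one-out CV bandwidth for the local-polynomial fit of a margin link.

    A margin that moves quickly with the covariate gets a small bandwidth; a
    margin unrelated to the covariate gets a bandwidth of the order of the
    covariate range (the fit degenerates to a global line).
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float).ravel()
    if grid is None:
        grid = _link_grid(Z)
    dmat = Z[None, :] - Z[:, None] if _dmat is None else _dmat
    best_score, best_g = np.inf, float(grid[-1])
    for g in grid:
        try:
            H = _local_poly_hat(dmat, float(g), kernel)
        except EmptyWindowError:
            continue
        hii = np.diag(H)
        if np.any(hii >= 1.0):
            continue
        resid = (y - H @ y) / (1.0 - hii)
        score = float(resid @ resid)
        if score < best_score:
            best_score, best_g = score, float(g)
    return best_g


def margin_adjusted_ranks(
    sample: LabeledSample,
    kernel: Callable[[np.ndarray], np.ndarray] = EPANECHNIKOV,
    bandwidths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Covariate-free uniforms: local-quadratic detrend of each margin, then ranks.

    Each response column is detrended by a local-quadratic fit on the covariate
    (bandwidth per column by :func:`cv_link_bandwidth`) and replaced by the
    global ranks of the residuals, scaled to (0, 1).  For location-shift
    margins Y_j = m_j(Z) + e_j this removes the covariate effect exactly up
    to the fit error, so under a conditional copula that is constant in z
    the transformed p-tuples are (approximately) exchangeable — the
    requirement for permutation-based covariance estimation.  A margin that
    does not depend on the covariate reduces to its ordinary global ranks.
    """
    n, p = sample.n, sample.p
    if bandwidths is not None:
        g = np.broadcast_to(np.asarray(bandwidths, dtype=float), (p,))
        grid = None
    else:
        g = None
        grid = _link_grid(sample.Z)
    dmat = sample.Z[None, :] - sample.Z[:, None]
    U = np.empty((n, p))
    for j in range(p):
        y = sample.Y[:, j]
        if g is not None:
            gj = float(g[j])
        else:
            gj = cv_link_bandwidth(y, sample.Z, kernel, grid=grid, _dmat=dmat)
        H = _local_poly_hat(dmat, gj, kernel)
        resid = y - H @ y
        order = np.argsort(np.argsort(resid, kind="stable"), kind="stable")
        U[:, j] = (order + 1.0) / (n + 1.0)
    return U


def dominance_matrix(Y: np.ndarray) -> np.ndarray:
    """Boolean matrix with entry (i, j) true iff Y_i < Y_j strictly in every coordinate."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return np.all(Y[:, None, :] < Y[None, :, :], axis=2)


def _dominance_f(Y: np.ndarray) -> np.ndarray:
    """Float64 dominance matrix (internal: fast repeated quadratic forms)."""
    return dominance_matrix(Y).astype(np.float64)


def empirical_kendall_tau(Y: np.ndarray) -> float:
    """Empirical multivariate Kendall's tau via strict-dominance pair counts.

    tau_hat = (2^(p-1)-1)^(-1) * (2^p / (n(n-1)) * sum_{i,j} I{Y_i < Y_j} - 1).
    For p = 2 on tie-free data this is the classic empirical Kendall's tau.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    if n < 2:
        raise ValueError(f"need n >= 2 observations, got n={n}")
    count = float(dominance_matrix(Y).sum())
    return ((2.0**p) * count / (n * (n - 1)) - 1.0) / (2.0 ** (p - 1) - 1.0)


@dataclass(frozen=True)
class ConditionalTauEstimate:
    """A conditional tau value with its conditioning point and diagnostics.

    ``tau`` is clipped to [-1, 1]; ``tau_raw`` keeps the raw weighted value
    (the 1 - sum w^2 correction can push it marginally outside the range).
    ``n_eff = 1 / sum w_i^2`` is the effective number of observations in the
    window and ``denom = 1 - sum w_i^2`` the bias-correction denominator.
    """

    tau: float
    tau_raw: float
    z: float
    h: float
    p: int
    n_eff: float
    denom: float


def _tau_from_quadform(s: float, denom: float, p: int) -> float:
    return ((2.0**p) * s / denom - 1.0) / (2.0 ** (p - 1) - 1.0)


def conditional_kendall_tau(
    sample: LabeledSample,
    weights: WeightVector,
    dominance: Optional[np.ndarray] = None,
) -> ConditionalTauEstimate:
    """Kernel-weighted conditional multivariate Kendall's tau at ``weights.z``.

    Parameters
    ----------
    dominance : (n, n) float array, optional
        Precomputed ``_dominance_f(sample.Y)``; pass it when evaluating many
        conditioning points or resamples of the same data.

    Raises
    ------
    DegenerateWeightsError
        If fewer than two observations carry positive weight, or
        ``1 - sum w_i^2 <= 0``.
    """
    w = weights.w
    if w.shape[0] != sample.n:
        raise ValueError("weight vector length does not match the sample")
    act = np.flatnonzero(w > 0)
    if act.size < 2:
        raise DegenerateWeightsError(
            f"only {act.size} observation(s) carry weight at z={weights.z}"
        )
    ssq = float(w @ w)
    denom = 1.0 - ssq
    if denom <= 0.0:
        raise DegenerateWeightsError(
            f"degenerate weights at z={weights.z}: 1 - sum w^2 = {denom:.3g}"
        )
    wa = w[act]
    if dominance is None:
        D = _dominance_f(sample.Y[act])
    else:
        D = dominance[np.ix_(act, act)]
    s = float(wa @ D @ wa)
    raw = _tau_from_quadform(s, denom, sample.p)
    return ConditionalTauEstimate(
        tau=float(np.clip(raw, -1.0, 1.0)),
        tau_raw=raw,
        z=weights.z,
        h=weights.h,
        p=sample.p,
        n_eff=1.0 / ssq,
        denom=denom,
    )


@dataclass(frozen=True)
class TauTestResult:
    """Result of the unconditional no-concordance test (H0: tau = 0)."""

    tau: float
    statistic: float
    p_value: float
    method: str
    n: int
    B: int = 0


def unconditional_tau_test(
    Y: np.ndarray,
    B: int = 500,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TauTestResult:
    """Test H0: tau = 0 for the (multivariate) Kendall's tau.

    For p = 2 the classic normal approximation is used, with null variance
    ``2(2n+5) / (9n(n-1))``.  For p > 2 no standard null is available and a
    permutation test is run instead: each column of ``Y`` is permuted
    independently (destroying all cross-column dependence), the statistic is
    recomputed ``B`` times and a two-sided add-one p-value is reported.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    if n < 10:
        raise ValueError(f"need n >= 10 for the tau test, got n={n}")
    tau = empirical_kendall_tau(Y)
    if p == 2:
        var0 = 2.0 * (2 * n + 5) / (9.0 * n * (n - 1))
        stat = tau / math.sqrt(var0)
        pval = 2.0 * stats.norm.sf(abs(stat))
        return TauTestResult(tau, stat, float(pval), "normal", n)
    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        Yb = np.column_stack([Y[rng.permutation(n), j] for j in range(p)])
        if abs(empirical_kendall_tau(Yb)) >= abs(tau):
            exceed += 1
    pval = (1.0 + exceed) / (B + 1.0)
    return TauTestResult(tau, tau, pval, "permutation", n, B)
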