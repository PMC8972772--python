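"""Wald-type tests for linear restrictions on conditional Kendall's taus.

A null hypothesis H0: R tau_z = r constrains the vector
tau_z = (tau_{z_1}, ..., tau_{z_m})' of conditional taus at m deterministic
conditioning points.  The statistic is the quadratic form

    J = (R tau_hat - r)' (R V_hat R')^(-1) (R tau_hat - r),

chi-square with q = rank(R) degrees of freedom under H0.  V_hat is the
finite-sample covariance of the tau vector, estimated by resampling: a joint
row-permutation scheme for one-sample hypotheses (keep Z fixed, permute the
complete margin-adjusted p-tuples) and a delete-one jackknife or pairs
bootstrap for the two-sample equality hypothesis.  The full covariance
matrix is kept: when the conditioning points are spaced beyond twice the
bandwidth the kernel windows are disjoint and the off-diagonals vanish,
while overlapping windows contribute the positive correlation that the
quadratic form must account for.

The module also provides the variance-of-the-tau-curve comparator
V_n1 = n^(-1) sum_i (tau_hat_{Z_i} - mean)^2 with a permutation calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bandwidth import median_bandwidth
from .exceptions import (
    DegenerateWeightsError,
    DisjointWindowError,
    EmptyWindowError,
    SingularCovarianceError,
)
from .kendall import (
    EPANECHNIKOV,
    _dominance_f,
    _tau_from_quadform,
    conditional_kendall_tau,
    conditional_pseudo_observations,
    margin_adjusted_ranks,
    empirical_kendall_tau,
    nw_weights,
)
from .sample import LabeledSample

__all__ = [
    "RestrictionSystem",
    "CovarianceEstimate",
    "WaldTestResult",
    "choose_conditioning_points",
    "build_restriction",
    "permutation_covariance",
    "bootstrap_covariance_two_sample",
    "jackknife_covariance",
    "wald_statistic",
    "noncentrality",
    "wald_test",
    "vn1_statistic",
    "vn1_test",
]

HYPOTHESES = (
    "constant_dependence",
    "conditional_independence",
    "equal_to_unconditional",
    "two_sample_equality",
)


@dataclass(frozen=True)
class RestrictionSystem:
    """A linear null hypothesis R tau_z = r on conditional taus.

    ``R`` is q x d with full row rank, where d = m for one-sample hypotheses
    and d = 2m for the two-sample stacked vector; ``zpoints`` are the m
    strictly increasing conditioning values.
    """

    R: np.ndarray
    r: np.ndarray
    zpoints: np.ndarray
    label: str

    def __post_init__(self):
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        r = np.asarray(self.r, dtype=float).ravel()
        zp = np.asarray(self.zpoints, dtype=float).ravel()
        q, d = R.shape
        m = zp.shape[0]
        if d not in (m, 2 * m):
            raise ValueError(f"R has {d} columns; expected m={m} or 2m={2 * m}")
        if r.shape[0] != q:
            raise ValueError("r length must match the number of rows of R")
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(r))):
            raise ValueError("R and r must be finite")
        if np.linalg.matrix_rank(R) != q:
            raise ValueError("R must have full row rank q <= m")
        if m > 1 and np.any(np.diff(zp) <= 0):
            raise ValueError("conditioning points must be strictly increasing")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "zpoints", zp)

    @property
    def q(self) -> int:
        return self.R.shape[0]

    @property
    def m(self) -> int:
        return self.zpoints.shape[0]


@dataclass(frozen=True)
class CovarianceEstimate:
    """Covariance of the tau vector on the finite-sample scale.

    ``method`` records how it was obtained (permutation, two-sample
    bootstrap, jackknife, or a user-supplied plug-in); ``B`` is the
    resample count (0 for deterministic methods).
    """

    V: np.ndarray
    method: str
    B: int


@dataclass(frozen=True)
class WaldTestResult:
    statistic: float
    df: int
    p_value: float
    tau_hat: np.ndarray
    restriction: RestrictionSystem
    covariance: CovarianceEstimate
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row report (round-trips through CSV)."""
        m = self.restriction.m
        row = {
            "hypothesis": self.restriction.label,
            "m": m,
            "q": self.restriction.q,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "bandwidth": self.bandwidth,
            "B": self.covariance.B,
            "cov_method": self.covariance.method,
        }
        for ell, z in enumerate(self.restriction.zpoints):
            row[f"z{ell + 1}"] = z
        for ell, t in enumerate(np.asarray(self.tau_hat).ravel()):
            row[f"tau{ell + 1}"] = t
        return pd.DataFrame([row])

    def summary(self) -> str:
        taus = ", ".join(f"{t:+.4f}" for t in np.asarray(self.tau_hat).ravel())
        zs = ", ".join(f"{z:.4f}" for z in self.restriction.zpoints)
        return (
            f"Wald test [{self.restriction.label}]\n"
            f"  conditioning points ({self.restriction.m}): {zs}\n"
            f"  bandwidth: {self.bandwidth:.4f}\n"
            f"  tau estimates: {taus}\n"
            f"  J = {self.statistic:.4f} on {self.df} df "
            f"({self.covariance.method} covariance, B={self.covariance.B})\n"
            f"  p-value = {self.p_value:.4g}"
        )


def _target_points(
    Z: np.ndarray, fraction: float, n_basis: Optional[int] = None
) -> np.ndarray:
    """Equally spaced covariate quantiles; the count is ~fraction * n_basis
    (per-sample size in two-sample settings, where Z may be pooled)."""
    n = Z.shape[0] if n_basis is None else n_basis
    m = max(2, int(np.floor(fraction * n)))
    levels = (np.arange(1, m + 1) - 0.5) / m
    return np.quantile(Z, levels)


def choose_conditioning_points(
    Z: np.ndarray, fraction: float = 0.05, h: float = 0.0
) -> np.ndarray:
    """Conditioning points: ~``fraction * n`` covariate quantiles, thinned for
    disjoint kernel windows.

    ``max(2, floor(fraction * n))`` target points are placed at equally
    spaced quantiles of Z and thinned greedily left-to-right so consecutive
    points are more than ``2h`` apart (Epanechnikov windows of half-width h
    then share no observation).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if h <= 0.0:
        raise ValueError(f"bandwidth must be positive, got h={h}")
    Z = np.asarray(Z, dtype=float).ravel()
    targets = _target_points(Z, fraction)
    keep = [float(targets[0])]
    for pt in targets[1:]:
        if pt - keep[-1] > 2.0 * h:
            keep.append(float(pt))
    if len(keep) < 2:
        raise DisjointWindowError(
            f"bandwidth h={h} too large for two disjoint windows in the range of Z"
        )
    return np.asarray(keep)


def build_restriction(
    kind: str,
    m: int,
    zpoints: Optional[Sequence[float]] = None,
    tau: Optional[float] = None,
) -> RestrictionSystem:
    """Restriction matrices (R, r) for the canonical hypotheses.

    * ``constant_dependence``: tau_{z_1} = ... = tau_{z_m}; first-difference
      R of shape (m-1, m) (ones on the diagonal, -1 on the upper diagonal),
      r = 0.
    * ``conditional_independence``: tau_{z_l} = 0 for all l; R = I_m, r = 0.
    * ``equal_to_unconditional``: tau_{z_l} = tau for all l; R = I_m,
      r = tau * 1 (pass the unconditional estimate as ``tau``).
    * ``two_sample_equality``: tau_z^{s1} = tau_z^{s2}; R = (I_m, -I_m),
      r = 0, acting on the stacked 2m-vector.
    """
    if zpoints is None:
        zpoints = np.arange(m, dtype=float)
    if kind == "constant_dependence":
        if m < 2:
            raise ValueError("constant_dependence needs m >= 2 points")
        R = np.eye(m - 1, m) - np.eye(m - 1, m, k=1)
        r = np.zeros(m - 1)
    elif kind == "conditional_independence":
        R = np.eye(m)
        r = np.zeros(m)
    elif kind == "equal_to_unconditional":
        if tau is None:
            raise ValueError("equal_to_unconditional needs the unconditional tau")
        R = np.eye(m)
        r = float(tau) * np.ones(m)
    elif kind == "two_sample_equality":
        if m < 2:
            raise ValueError("two_sample_equality needs m >= 2 points")
        R = np.hstack([np.eye(m), -np.eye(m)])
        r = np.zeros(m)
    else:
        raise ValueError(f"unknown hypothesis kind: {kind!r} (choose from {HYPOTHESES})")
    return RestrictionSystem(R=R, r=r, zpoints=np.asarray(zpoints, float), label=kind)


def _window_data(sample, zpoints, h, kernel):
    """Per-point active indices and normalized weights (errors propagate)."""
    out = []
    for z in zpoints:
        wv = nw_weights(float(z), sample.Z, h, kernel)
        act = wv.active
        if act.size < 2 or 1.0 - float(wv.w @ wv.w) <= 0.0:
            raise DegenerateWeightsError(f"window at z={z} too small for tau")
        out.append((act, wv.w[act]))
    return out


def permutation_covariance(
    sample: LabeledSample,
    zpoints: Sequence[float],
    h: float,
    B: int = 500,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    kernel=EPANECHNIKOV,
    dominance: Optional[np.ndarray] = None,
    use_pseudo_obs: bool = True,
) -> CovarianceEstimate:
    """Permutation covariance of the tau vector under the one-sample null.

    Z is kept fixed and complete p-tuples of responses are jointly permuted
    B times; the per-point sample variances of the recomputed taus form a
    diagonal V_hat (off-diagonals are zero by the disjoint-window
    construction).

    By default the permuted tuples are the conditional pseudo-observations
    (local ranks) rather than the raw responses: when the marginal links
    m_j(Z) are strong, raw tuples are not exchangeable even under the
    constant-copula null (the Y-Z link manufactures spurious mixture
    dependence and the permutation variance can be badly off), while the
    local-rank tuples are free of the covariate effect in the margins.  Set
    ``use_pseudo_obs=False`` to permute raw rows of Y (also ignored when an
    explicit ``dominance`` matrix is supplied).

    The full m x m covariance of the permuted tau vector is returned.  When
    the kernel windows are disjoint the off-diagonal entries are near zero
    by construction; when the windows overlap they carry the (large)
    positive correlation between neighbouring estimates, which the Wald
    quadratic form needs in order to be correctly scaled.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 resamples, got B={B}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n, p = sample.n, sample.p
    if dominance is not None:
        D = dominance
    elif use_pseudo_obs:
        D = _dominance_f(margin_adjusted_ranks(sample, kernel=kernel))
    else:
        D = _dominance_f(sample.Y)
    windows = _window_data(sample, zpoints, h, kernel)
    m = len(windows)
    W = np.zeros((m, n))
    for ell, (act, wa) in enumerate(windows):
        W[ell, act] = wa
    denoms = 1.0 - (W * W).sum(axis=1)
    cp, norm = 2.0**p, 2.0 ** (p - 1) - 1.0
    draws = np.empty((B, m))
    U = np.empty_like(W)
    for b in range(B):
        perm = rng.permutation(n)
        U[:, perm] = W  # weight of permuted tuple perm[i] at position i
        s = np.einsum("ij,ij->i", U @ D, U)
        draws[b] = np.clip((cp * s / denoms - 1.0) / norm, -1.0, 1.0)
    V = np.atleast_2d(np.cov(draws, rowvar=False, ddof=1))
    return CovarianceEstimate(V=V, method="permutation", B=B)


def bootstrap_covariance_two_sample(
    sample1: LabeledSample,
    sample2: LabeledSample,
    zpoints: Sequence[float],
    h: float,
    B: int = 500,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    kernel=EPANECHNIKOV,
    max_retries: int = 100,
    use_pseudo_obs: bool = True,
    dominances: Optional[tuple] = None,
) -> CovarianceEstimate:
    """Pairs-bootstrap covariance for the stacked two-sample tau vector.

    For each sample the observation tuples are resampled with replacement B
    times and the taus at all points recomputed.  The per-sample bootstrap
    covariance matrices of the m-vector are pooled with the (2B)^(-1)
    convention (each sample centred at its own bootstrap mean) and the
    pooled m x m block is placed at both diagonal blocks of the 2m x 2m
    V_hat; the off-diagonal blocks are zero because the samples are
    independent.  A resample whose window at some point empties is redrawn,
    up to ``max_retries`` attempts.

    ``use_pseudo_obs`` bootstraps the conditional pseudo-observations
    (computed once per sample at bandwidth ``h``) instead of the raw
    responses, matching the margin-adjusted taus used by the test pipeline.
    """
    if B < 100:
        raise ValueError(f"need B >= 100 resamples, got B={B}")
    if rng is None:
        rng = np.random.default_rng(seed)
    zpoints = np.asarray(zpoints, dtype=float)
    m = zpoints.shape[0]
    taus = np.empty((2, B, m))
    for s_idx, smp in enumerate((sample1, sample2)):
        n, p = smp.n, smp.p
        if dominances is not None:
            D = dominances[s_idx]
        elif use_pseudo_obs:
            D = _dominance_f(margin_adjusted_ranks(smp, kernel=kernel))
        else:
            D = _dominance_f(smp.Y)
        cp, norm = 2.0**p, 2.0 ** (p - 1) - 1.0
        U = np.empty((m, n))
        for b in range(B):
            for attempt in range(max_retries):
                idx = rng.integers(0, n, n)
                Zb = smp.Z[idx]
                Wb = np.asarray(
                    kernel((np.asarray(zpoints)[:, None] - Zb[None, :]) / h), float
                )
                tot = Wb.sum(axis=1)
                if np.any(tot <= 0.0):
                    continue
                Wb /= tot[:, None]
                denoms = 1.0 - (Wb * Wb).sum(axis=1)
                if np.any((Wb > 0).sum(axis=1) < 2) or np.any(denoms <= 0.0):
                    continue
                # accumulate resample weights onto original rows: D is fixed
                U[:] = 0.0
                np.add.at(U, (slice(None), idx), Wb)
                s = np.einsum("ij,ij->i", U @ D, U)
                taus[s_idx, b] = np.clip((cp * s / denoms - 1.0) / norm, -1.0, 1.0)
                break
            else:
                raise EmptyWindowError(
                    f"bootstrap windows kept emptying at sample {s_idx + 1} "
                    f"after {max_retries} redraws"
                )
    centred = taus - taus.mean(axis=1, keepdims=True)
    flat = centred.reshape(2 * B, m)
    pooled = flat.T @ flat / (2.0 * B)
    V = np.zeros((2 * m, 2 * m))
    V[:m, :m] = pooled
    V[m:, m:] = pooled
    return CovarianceEstimate(V=V, method="bootstrap_two_sample", B=B)


def wald_statistic(
    tau_hat: Sequence[float],
    restriction: RestrictionSystem,
    covariance: CovarianceEstimate,
) -> float:
    """Quadratic form J = (R tau - r)' (R V R')^(-1) (R tau - r) >= 0."""
    tau = np.asarray(tau_hat, dtype=float).ravel()
    R, r, V = restriction.R, restriction.r, covariance.V
    if tau.shape[0] != R.shape[1] or V.shape != (tau.shape[0], tau.shape[0]):
        raise ValueError("dimensions of tau_hat, R and V do not conform")
    d = R @ tau - r
    M = R @ V @ R.T
    try:
        sol = np.linalg.solve(M, d)
    except np.linalg.LinAlgError as exc:
        zero_rows = np.flatnonzero(np.all(M == 0.0, axis=1)).tolist()
        raise SingularCovarianceError(
            f"R V R' is singular for hypothesis {restriction.label!r}"
            + (f" (degenerate restriction rows {zero_rows})" if zero_rows else "")
        ) from exc
    return max(float(d @ sol), 0.0)


def noncentrality(
    restriction: RestrictionSystem,
    covariance: CovarianceEstimate,
    varsigma: Sequence[float],
) -> float:
    """Local-power noncentrality delta = varsigma' (R V R')^(-1) varsigma."""
    s = np.asarray(varsigma, dtype=float).ravel()
    if s.shape[0] != restriction.q:
        raise ValueError("varsigma length must equal the number of restrictions q")
    if np.all(s == 0.0):
        raise ValueError("varsigma must be nonzero")
    M = restriction.R @ covariance.V @ restriction.R.T
    try:
        sol = np.linalg.solve(M, s)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("R V R' is singular") from exc
    return max(float(s @ sol), 0.0)


def jackknife_covariance(
    sample: LabeledSample,
    zpoints: Sequence[float],
    h: float,
    kernel=EPANECHNIKOV,
    dominance: Optional[np.ndarray] = None,
) -> CovarianceEstimate:
    """Delete-one jackknife covariance of the conditional tau vector.

    The leave-one-out values of every tau share the same deleted
    observation, so the full m x m covariance (including the cross-point
    terms induced by overlapping windows) follows from one pass:
    C = (n-1)/n * sum_i (tau_(-i) - tau_bar)(tau_(-i) - tau_bar)'.
    Deterministic given the sample.
    """
    from .bandwidth import conditional_tau_jackknife

    if dominance is None:
        dominance = _dominance_f(sample.Y)
    loos = np.array(
        [
            conditional_tau_jackknife(
                sample, float(z), h, kernel, dominance
            ).leave_one_out_values
            for z in zpoints
        ]
    )
    n = loos.shape[1]
    c = loos - loos.mean(axis=1, keepdims=True)
    V = (n - 1) / n * (c @ c.T)
    return CovarianceEstimate(V=np.atleast_2d(V), method="jackknife", B=0)


def wald_test(
    sample: LabeledSample,
    kind: str = "constant_dependence",
    sample2: Optional[LabeledSample] = None,
    fraction: float = 0.05,
    bandwidth: Optional[float] = None,
    B: int = 500,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    kernel=EPANECHNIKOV,
    tau_unconditional: Optional[float] = None,
    two_sample_covariance: str = "jackknife",
) -> WaldTestResult:
    """Full testing pipeline: points -> margins -> bandwidth -> taus -> covariance -> J.

    Conditioning points are ``max(2, floor(fraction * n))`` equally spaced
    covariate quantiles (per-sample n in the two-sample case).  The
    conditional taus entering the statistic are computed from the
    margin-adjusted ranks (local-quadratic detrend of each response, then
    global residual ranks; see
    :func:`~condtau.kendall.margin_adjusted_ranks`), which removes the
    covariate effect on the margins so that only the conditional copula can
    vary with z.  A single bandwidth is used: supplied, or the median of
    the pointwise plug-in selections run on the margin-adjusted sample with
    candidates up to a quarter of the covariate range (under a constant
    copula the adjusted taus have no smoothing bias, so wide overlapping
    windows are admissible and sharpen the test; beyond ~1/4 of the range
    the tau vector degenerates toward a single global value), floored so
    every window holds at least 5 observations.  The full covariance matrix
    of the tau vector is estimated by permutation of the adjusted tuples
    (one-sample hypotheses) and by the per-sample delete-one jackknife for
    ``two_sample_equality`` (``two_sample_covariance="bootstrap"`` selects
    the pairs bootstrap instead), so the quadratic form is correctly scaled
    even with overlapping windows.  Resampling-based covariances use a
    finite-resample Hotelling-type F reference that tends to the
    chi-square(q) tail as B grows; the jackknife path uses chi-square(q).
    """
    if kind not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis kind: {kind!r} (choose from {HYPOTHESES})")
    two_sample = kind == "two_sample_equality"
    if two_sample and sample2 is None:
        raise ValueError("two_sample_equality needs a second sample")
    if not two_sample and sample2 is not None:
        raise ValueError(f"hypothesis {kind!r} takes a single sample")
    if rng is None:
        rng = np.random.default_rng(seed)

    if two_sample:
        Zref = np.concatenate([sample.Z, sample2.Z])
        n_basis = min(sample.n, sample2.n)
    else:
        Zref = sample.Z
        n_basis = sample.n
    zpoints = _target_points(Zref, fraction, n_basis)
    m = zpoints.shape[0]

    samples = [sample] + ([sample2] if two_sample else [])
    pseudo = []
    doms = []
    for smp in samples:
        U = margin_adjusted_ranks(smp, kernel=kernel)
        pseudo.append(LabeledSample(U, smp.Z, validate=False))
        doms.append(_dominance_f(U))

    # every window must hold >= 5 observations of every involved sample
    floor = max(
        float(np.sort(np.abs(smp.Z - z))[4]) * 1.05 for smp in samples for z in zpoints
    )
    if bandwidth is None:
        if two_sample:
            # the per-sample jackknife covariance degenerates once windows
            # approach global coverage (all leave-one-out curves move
            # together); keep the windows at the conditioning-point spacing
            # scale, where the estimated covariance stays accurate
            h_max = 2.0 * float(np.median(np.diff(zpoints)))
        else:
            h_max = 0.25 * float(Zref.max() - Zref.min())
        hs = [
            median_bandwidth(ps, zpoints, dominance=D, h_max=max(h_max, floor))
            for ps, D in zip(pseudo, doms)
        ]
        h = max(float(np.median(hs)), floor)
    else:
        h = float(bandwidth)

    tau_vec = [
        conditional_kendall_tau(ps, nw_weights(z, ps.Z, h, kernel), D).tau
        for ps, D in zip(pseudo, doms)
        for z in zpoints
    ]
    if two_sample:
        if two_sample_covariance == "bootstrap":
            cov = bootstrap_covariance_two_sample(
                sample, sample2, zpoints, h, B=B, rng=rng, kernel=kernel,
                dominances=tuple(doms),
            )
        else:
            blocks = [
                jackknife_covariance(ps, zpoints, h, kernel, D).V
                for ps, D in zip(pseudo, doms)
            ]
            V = np.zeros((2 * m, 2 * m))
            V[:m, :m] = blocks[0]
            V[m:, m:] = blocks[1]
            cov = CovarianceEstimate(V=V, method="jackknife", B=0)
        restriction = build_restriction(kind, m, zpoints=zpoints)
    else:
        cov = permutation_covariance(
            sample, zpoints, h, B=B, rng=rng, kernel=kernel, dominance=doms[0]
        )
        if kind == "equal_to_unconditional" and tau_unconditional is None:
            tau_unconditional = empirical_kendall_tau(sample.Y)
        restriction = build_restriction(kind, m, zpoints=zpoints, tau=tau_unconditional)

    tau_vec = np.asarray(tau_vec)
    J = wald_statistic(tau_vec, restriction, cov)
    q = restriction.q
    # Finite-resample calibration: V_hat comes from a finite number of
    # resamples, so (R V_hat R')^{-1} is Wishart-noisy and the chi-square
    # reference is slightly anticonservative for q close to the number of
    # resamples.  The Hotelling-type F reference corrects this and tends to
    # chi-square(q)/q as the resample count grows.
    if cov.method == "jackknife":
        n_res = 0  # deterministic covariance -> chi-square reference
    elif cov.method == "bootstrap_two_sample":
        n_res = 2 * B
    else:
        n_res = B
    if n_res > q + 1:
        x = J * (n_res - q) / (q * (n_res - 1.0))
        p_value = float(stats.f.sf(x, q, n_res - q))
    else:
        p_value = float(stats.chi2.sf(J, q))
    return WaldTestResult(
        statistic=J,
        df=q,
        p_value=p_value,
        tau_hat=tau_vec,
        restriction=restriction,
        covariance=cov,
        bandwidth=h,
    )


def vn1_statistic(
    sample: LabeledSample,
    h: float,
    kernel=EPANECHNIKOV,
    dominance: Optional[np.ndarray] = None,
) -> float:
    """Variance of the conditional tau curve over the observed covariate values.

    V_n1 = n^(-1) sum_i (tau_hat_{Z_i, h} - mean_i tau_hat_{Z_i, h})^2; zero
    when the conditional tau is flat in Z.
    """
    D = _dominance_f(sample.Y) if dominance is None else dominance
    taus = np.array(
        [
            conditional_kendall_tau(sample, nw_weights(z, sample.Z, h, kernel), D).tau
            for z in sample.Z
        ]
    )
    return float(np.mean((taus - taus.mean()) ** 2))


def vn1_test(
    sample: LabeledSample,
    h: float,
    B: int = 500,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    kernel=EPANECHNIKOV,
) -> float:
    """Permutation p-value for V_n1 (joint row permutation, Z fixed).

    The permuted tuples are the conditional pseudo-observations, which are
    exchangeable under the constant-copula null (see
    :func:`permutation_covariance`).  p = (1 + #{V_n1^b >= V_n1}) / (B + 1).
    """
    if B < 100:
        raise ValueError(f"need B >= 100 permutations, got B={B}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n, p = sample.n, sample.p
    D = _dominance_f(margin_adjusted_ranks(sample, kernel=kernel))
    windows = _window_data(sample, sample.Z, h, kernel)
    W = np.zeros((n, n))
    for i, (act, wa) in enumerate(windows):
        W[i, act] = wa
    denoms = 1.0 - (W * W).sum(axis=1)
    cp, norm = 2.0**p, 2.0 ** (p - 1) - 1.0
    U = np.empty_like(W)

    def _vn1(perm):
        U[:, perm] = W
        s = np.einsum("ij,ij->i", U @ D, U)
        taus = np.clip((cp * s / denoms - 1.0) / norm, -1.0, 1.0)
        return float(np.mean((taus - taus.mean()) ** 2))

    observed = _vn1(np.arange(n))
    exceed = sum(_vn1(rng.permutation(n)) >= observed for _ in range(B))
    return (1.0 + exceed) / (B + 1.0)
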