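"""Data-generating processes: Archimedean/mixture copulas, simulation models,
two-sample scenarios, truth oracles, and the rejection-frequency driver.

Each model draws a uniform covariate Z, samples copula uniforms whose
dependence parameter is evaluated per observation at Z_i, maps them through
the coordinate error quantile functions, and adds a marginal link m_j(Z_i):

    Y_ji = m_j(Z_i) + F_j^{-1}(U_ji),   (U_1i, ..., U_pi) ~ C_{theta(Z_i)}.

Models with a constant dependence parameter satisfy the constant-conditional-
dependence null; models with a Z-dependent parameter are the alternatives.
Two special models (L, NL) use correlated Gaussian errors instead of an
explicit copula, giving the closed-form constant truth
tau = 2/pi * arcsin(rho).

Archimedean samplers use the frailty (Marshall-Olkin) construction, exact for
every dimension p >= 2: Gamma frailty for Clayton, positive-stable for
Gumbel, logarithmic-series for Frank (theta > 0); a bivariate
conditional-inversion sampler covers Frank with theta < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .sample import LabeledSample
from .wald import vn1_test, wald_test

__all__ = [
    "CopulaSpec",
    "MixtureCopulaSpec",
    "ModelSpec",
    "ScenarioSpec",
    "MODEL_IDS",
    "SCENARIOS",
    "model_spec",
    "scenario_spec",
    "sample_archimedean",
    "sample_mixture",
    "triangular_icdf",
    "generate_model",
    "generate_scenario",
    "true_pairwise_tau",
    "true_multivariate_tau_mc",
    "ExperimentResult",
    "rejection_frequency_experiment",
]

_FAMILIES = ("independence", "clayton", "gumbel", "frank")


@dataclass(frozen=True)
class CopulaSpec:
    """An Archimedean copula family with a covariate-dependent parameter."""

    family: str
    p: int
    theta_fn: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.p < 2:
            raise ValueError("copula dimension must be >= 2")


@dataclass(frozen=True)
class MixtureCopulaSpec:
    """Convex mixture w * C_a + (1 - w) * C_b of two copulas of equal dimension."""

    a: CopulaSpec
    b: CopulaSpec
    w: float

    def __post_init__(self):
        if self.a.p != self.b.p:
            raise ValueError("mixture components must share the dimension p")
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"mixture weight must be in (0, 1), got {self.w}")

    @property
    def p(self) -> int:
        return self.a.p


def _check_theta(family: str, theta: np.ndarray, z: np.ndarray, p: int) -> None:
    if family == "clayton" and np.any(theta <= 0):
        bad = int(np.argmax(theta <= 0))
    elif family == "gumbel" and np.any(theta < 1):
        bad = int(np.argmax(theta < 1))
    elif family == "frank" and (np.any(theta == 0) or (p > 2 and np.any(theta <= 0))):
        bad = int(np.argmax(theta <= 0 if p > 2 else theta == 0))
    else:
        return
    raise ValueError(
        f"{family} parameter out of range at z={z[bad]:.4g}: theta={theta[bad]:.4g}"
    )


def _positive_stable(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Positive alpha-stable draws (Laplace transform exp(-t^alpha)), alpha in (0, 1]."""
    n = alpha.shape[0]
    W = rng.uniform(0.0, np.pi, n)
    E = rng.exponential(size=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = (
            np.sin(alpha * W)
            / np.sin(W) ** (1.0 / alpha)
            * (np.sin((1.0 - alpha) * W) / E) ** ((1.0 - alpha) / alpha)
        )
    return np.where(alpha > 1.0 - 1e-12, 1.0, S)


def _frank_bivariate_inversion(theta, n, rng):
    u1 = rng.uniform(size=n)
    t = rng.uniform(size=n)
    em = np.exp(-theta)
    emu = np.exp(-theta * u1)
    u2 = -np.log1p(t * (1.0 - em) / (t * (emu - 1.0) - emu)) / theta
    return np.column_stack([u1, u2])


def sample_archimedean(
    spec: CopulaSpec,
    z: Union[float, np.ndarray],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n draws from the copula; row i uses parameter theta_fn(z_i).

    ``z`` may be a scalar (one conditioning value for all rows) or an
    n-vector of covariate values.  Marginals are uniform on [0, 1].
    """
    z = np.broadcast_to(np.asarray(z, dtype=float), (n,)).copy()
    p = spec.p
    if spec.family == "independence":
        return rng.uniform(size=(n, p))
    theta = np.broadcast_to(np.asarray(spec.theta_fn(z), dtype=float), (n,))
    _check_theta(spec.family, theta, z, p)
    E = rng.exponential(size=(n, p))
    if spec.family == "clayton":
        theta = np.maximum(theta, 1e-10)
        V = rng.gamma(shape=1.0 / theta)
        return (1.0 + E / V[:, None]) ** (-1.0 / theta[:, None])
    if spec.family == "gumbel":
        alpha = 1.0 / theta
        S = _positive_stable(alpha, rng)
        return np.exp(-((E / S[:, None]) ** alpha[:, None]))
    # frank
    if np.any(theta < 0):
        if p != 2:
            raise ValueError("frank with theta < 0 is only defined for p = 2")
        return _frank_bivariate_inversion(theta, n, rng)
    theta = np.maximum(theta, 1e-8)
    V = np.asarray(
        stats.logser.rvs(1.0 - np.exp(-theta), size=n, random_state=rng), dtype=float
    )
    U = -np.log1p(np.exp(-E / V[:, None]) * (np.exp(-theta[:, None]) - 1.0)) / theta[
        :, None
    ]
    # guard against floating-point overshoot at the u = 1 boundary
    return np.clip(U, 0.0, 1.0)


def sample_mixture(
    spec: MixtureCopulaSpec,
    z: Union[float, np.ndarray],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n mixture draws: each row comes from component a with probability w."""
    z = np.broadcast_to(np.asarray(z, dtype=float), (n,)).copy()
    from_a = rng.random(n) < spec.w
    U = np.empty((n, spec.p))
    n_a = int(from_a.sum())
    if n_a:
        U[from_a] = sample_archimedean(spec.a, z[from_a], n_a, rng)
    if n - n_a:
        U[~from_a] = sample_archimedean(spec.b, z[~from_a], n - n_a, rng)
    return U


def triangular_icdf(u):
    """Quantile function of the triangular density 1 - |x| on [-1, 1]."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u must lie in [0, 1]")
    out = np.where(u <= 0.5, -1.0 + np.sqrt(2.0 * u), 1.0 - np.sqrt(2.0 * (1.0 - u)))
    return out if out.ndim else float(out)


def _norm_icdf(u):
    return special.ndtri(np.clip(u, 1e-15, 1.0 - 1e-15))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a data-generating process.

    ``kind`` is ``"copula"`` (copula uniforms -> error quantiles + links) or
    ``"gaussian_errors"`` (models L/NL: correlated normal errors with
    correlation ``rho`` added to the links).
    """

    id: str
    p: int
    z_range: tuple[float, float]
    links: tuple[Callable[[np.ndarray], np.ndarray], ...]
    kind: str = "copula"
    error_icdfs: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()
    copula: Optional[Union[CopulaSpec, MixtureCopulaSpec]] = None
    rho: float = 0.0


MODEL_IDS = ("L", "NL", "1", "2", "3", "4", "5", "6", "7", "8", "9", "10")

_THETA3 = math.exp(0.5) + 1.0  # constant Gumbel/Clayton level in models 3 and 5


def _m1_sine(z):
    return 2.0 * np.sin(2.0 * np.pi / 3.0 * (z - 2.0) - 1.0)


def _zero(z):
    return np.zeros_like(np.asarray(z, dtype=float))


def model_spec(model_id: Union[str, int], rho: float = 0.75) -> ModelSpec:
    """Specification of one of the built-in models (L, NL, 1-10).

    ``rho`` only matters for models L and NL (error correlation; the constant
    truth is tau = 2/pi * arcsin(rho)).
    """
    mid = str(model_id)
    tri, norm_ = triangular_icdf, _norm_icdf
    if mid == "L":
        return ModelSpec("L", 2, (0.0, 1.0), (lambda z: 7.0 * z, lambda z: 9.0 * z),
                         kind="gaussian_errors", rho=rho)
    if mid == "NL":
        return ModelSpec("NL", 2, (0.0, 1.0),
                         (lambda z: 4.0 * np.exp(z), lambda z: 5.0 * np.exp(z)),
                         kind="gaussian_errors", rho=rho)
    if mid == "1":
        # independence case: model NL with rho = 0
        return ModelSpec("1", 2, (0.0, 1.0),
                         (lambda z: 4.0 * np.exp(z), lambda z: 5.0 * np.exp(z)),
                         kind="gaussian_errors", rho=0.0)
    if mid == "2":
        cop = CopulaSpec("clayton", 2, lambda z: z**2 / (z**2 + 1.0))
        return ModelSpec("2", 2, (0.0, 6.0), (_zero, _zero),
                         error_icdfs=(norm_, norm_), copula=cop)
    if mid == "3":
        cop = CopulaSpec("gumbel", 2, lambda z: np.full_like(z, _THETA3))
        return ModelSpec("3", 2, (2.0, 5.0), (_m1_sine, _zero),
                         error_icdfs=(tri, tri), copula=cop)
    if mid == "4":
        cop = CopulaSpec("gumbel", 2, lambda z: np.exp(1.5 - 0.4 * z) + 1.0)
        return ModelSpec("4", 2, (2.0, 5.0), (_m1_sine, _zero),
                         error_icdfs=(tri, tri), copula=cop)
    if mid == "5":
        cop = CopulaSpec("clayton", 3, lambda z: np.full_like(z, _THETA3))
        return ModelSpec(
            "5", 3, (2.0, 5.0),
            (_m1_sine, _zero,
             lambda z: 5.0 + 3.0 * np.cos(14.0 * np.pi / 3.0 * (z - 2.0) - 7.0)),
            error_icdfs=(tri, tri, norm_), copula=cop)
    if mid == "6":
        cop = CopulaSpec("clayton", 3, lambda z: np.exp(1.5 + 0.4 * z) + 1.0)
        return ModelSpec("6", 3, (2.0, 5.0), (_m1_sine, _zero, _zero),
                         error_icdfs=(tri, tri, norm_), copula=cop)
    if mid == "7":
        mix = MixtureCopulaSpec(
            CopulaSpec("clayton", 2, lambda z: np.full_like(z, math.exp(0.5))),
            CopulaSpec("gumbel", 2, lambda z: np.full_like(z, 1.2)),
            w=0.3)
        return ModelSpec("7", 2, (0.0, 6.0), (_zero, _zero),
                         error_icdfs=(norm_, norm_), copula=mix)
    if mid == "8":
        mix = MixtureCopulaSpec(
            CopulaSpec("frank", 2, lambda z: z**3 / (z**3 + 1.0)),
            CopulaSpec("frank", 2, lambda z: np.exp(1.5 + 0.4 * z) + 1.0),
            w=0.3)
        return ModelSpec("8", 2, (2.0, 5.0), (_m1_sine, _zero),
                         error_icdfs=(tri, tri), copula=mix)
    if mid == "9":
        mix = MixtureCopulaSpec(
            CopulaSpec("clayton", 3, lambda z: np.full_like(z, math.sin(4 * math.pi / 7) + 1.0)),
            CopulaSpec("gumbel", 3, lambda z: np.full_like(z, math.exp(2.5) + 1.0)),
            w=0.7)
        return ModelSpec(
            "9", 3, (0.0, 6.0),
            (lambda z: 2.0 * np.sin(np.pi * (z / 3.0 - 1.0)), _zero, _zero),
            error_icdfs=(norm_, norm_, norm_), copula=mix)
    if mid == "10":
        mix = MixtureCopulaSpec(
            CopulaSpec("frank", 3, lambda z: z**3 / (z**3 + 1.0)),
            CopulaSpec("frank", 3, lambda z: np.exp(1.5 + 0.4 * z) + 1.0),
            w=0.3)
        return ModelSpec("10", 3, (2.0, 5.0), (_m1_sine, _zero, _zero),
                         error_icdfs=(tri, tri, tri), copula=mix)
    raise ValueError(f"unknown model id {model_id!r}; choose from {MODEL_IDS}")


def generate_model(
    spec: Union[ModelSpec, str, int],
    n: int,
    rng: np.random.Generator,
    rho: float = 0.75,
) -> LabeledSample:
    """Draw a LabeledSample of size ``n`` from one of the built-in models."""
    if not isinstance(spec, ModelSpec):
        spec = model_spec(spec, rho=rho)
    lo, hi = spec.z_range
    Z = rng.uniform(lo, hi, n)
    if spec.kind == "gaussian_errors":
        e1 = rng.normal(size=n)
        eps = rng.normal(size=n)
        e2 = spec.rho * e1 + math.sqrt(1.0 - spec.rho**2) * eps
        Y = np.column_stack([spec.links[0](Z) + e1, spec.links[1](Z) + e2])
        return LabeledSample(Y, Z)
    if isinstance(spec.copula, MixtureCopulaSpec):
        U = sample_mixture(spec.copula, Z, n, rng)
    else:
        U = sample_archimedean(spec.copula, Z, n, rng)
    cols = [
        spec.links[j](Z) + spec.error_icdfs[j](U[:, j]) for j in range(spec.p)
    ]
    return LabeledSample(np.column_stack(cols), Z)


@dataclass(frozen=True)
class ScenarioSpec:
    """Two-sample scenario: which model generates each sample."""

    id: int
    model1: str
    model2: str
    n: int = 250


SCENARIOS = {1: ("2", "2"), 2: ("2", "4"), 3: ("8", "8"), 4: ("8", "4")}


def scenario_spec(scenario_id: int, n: int = 250) -> ScenarioSpec:
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}; choose from {sorted(SCENARIOS)}")
    m1, m2 = SCENARIOS[scenario_id]
    return ScenarioSpec(scenario_id, m1, m2, n)


def generate_scenario(
    spec: Union[ScenarioSpec, int],
    rng: np.random.Generator,
    n: Optional[int] = None,
) -> tuple[LabeledSample, LabeledSample]:
    """Draw the two independent samples of a scenario."""
    if not isinstance(spec, ScenarioSpec):
        spec = scenario_spec(spec)
    n = spec.n if n is None else n
    s1 = generate_model(spec.model1, n, rng)
    s2 = generate_model(spec.model2, n, rng)
    return s1, s2


def _debye1(theta: float) -> float:
    val, _ = integrate.quad(lambda t: t / math.expm1(t), 0.0, theta)
    return val / theta


def true_pairwise_tau(family: str, theta: float) -> float:
    """Closed-form pairwise Kendall's tau of an Archimedean family.

    clayton: theta/(theta+2); gumbel: 1 - 1/theta; frank:
    1 - 4/theta * (1 - D1(theta)) with D1 the first Debye function.
    """
    if family == "independence":
        return 0.0
    if family == "clayton":
        if theta <= 0:
            raise ValueError(f"clayton needs theta > 0, got {theta}")
        return theta / (theta + 2.0)
    if family == "gumbel":
        if theta < 1:
            raise ValueError(f"gumbel needs theta >= 1, got {theta}")
        return 1.0 - 1.0 / theta
    if family == "frank":
        if theta == 0:
            raise ValueError("frank needs theta != 0")
        if abs(theta) < 1e-6:
            return theta / 9.0  # small-theta expansion
        return 1.0 - 4.0 / theta * (1.0 - _debye1(theta))
    raise ValueError(f"unknown family {family!r}")


def true_multivariate_tau_mc(
    spec: Union[CopulaSpec, MixtureCopulaSpec],
    z: float,
    n_mc: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo truth (2^(p-1)-1)^(-1) (2^p P(U' < U) - 1) at fixed z.

    P(U' < U) for two independent copula draws equals int C dC; it is
    estimated from n_mc independent pairs.
    """
    if n_mc < 10_000:
        raise ValueError("use n_mc >= 10^4 for a usable oracle")
    if rng is None:
        rng = np.random.default_rng()
    sampler = sample_mixture if isinstance(spec, MixtureCopulaSpec) else sample_archimedean
    U = sampler(spec, z, n_mc, rng)
    V = sampler(spec, z, n_mc, rng)
    p = spec.p
    prob = float(np.mean(np.all(V < U, axis=1)))
    return ((2.0**p) * prob - 1.0) / (2.0 ** (p - 1) - 1.0)


@dataclass(frozen=True)
class ExperimentResult:
    """Rejection-frequency table with the underlying p-values and provenance."""

    table: pd.DataFrame  # columns: model, statistic, n, alpha, rejection_pct
    p_values: np.ndarray
    meta: dict


def rejection_frequency_experiment(
    model: Optional[Union[str, int]] = None,
    scenario: Optional[int] = None,
    n: int = 250,
    S: int = 200,
    alphas: Sequence[float] = (0.01, 0.05, 0.10),
    statistic: str = "Jn",
    kind: str = "constant_dependence",
    fraction: float = 0.05,
    B: int = 500,
    bandwidth: Optional[float] = None,
    seed: int = 0,
    rho: float = 0.75,
) -> ExperimentResult:
    """Empirical size/power: S replications of generate -> bandwidth -> test.

    One of ``model`` (one-sample test of ``kind``) or ``scenario``
    (two-sample equality) must be given.  ``statistic`` is ``"Jn"`` (the Wald
    test) or ``"Vn1"`` (the tau-curve-variance comparator, one-sample only).
    Reported values are percentages rejected at each ``alpha``.
    """
    if (model is None) == (scenario is None):
        raise ValueError("give exactly one of model= or scenario=")
    if S < 1:
        raise ValueError("need at least one replication")
    if statistic not in ("Jn", "Vn1"):
        raise ValueError(f"unknown statistic {statistic!r}")
    ss = np.random.SeedSequence(seed)
    pvals = np.empty(S)
    for rep, child in enumerate(ss.spawn(S)):
        rng = np.random.default_rng(child)
        try:
            if scenario is not None:
                s1, s2 = generate_scenario(scenario, rng, n=n)
                res = wald_test(
                    s1, "two_sample_equality", sample2=s2,
                    fraction=fraction, bandwidth=bandwidth, B=B, rng=rng,
                )
                pvals[rep] = res.p_value
            else:
                smp = generate_model(model, n, rng, rho=rho)
                if statistic == "Jn":
                    res = wald_test(
                        smp, kind, fraction=fraction, bandwidth=bandwidth, B=B, rng=rng
                    )
                    pvals[rep] = res.p_value
                else:
                    from .bandwidth import median_bandwidth
                    from .wald import _target_points

                    h = bandwidth
                    if h is None:
                        h = median_bandwidth(smp, _target_points(smp.Z, fraction))
                    pvals[rep] = vn1_test(smp, h, B=B, rng=rng)
        except Exception as exc:
            raise RuntimeError(f"replication {rep} failed: {exc}") from exc
    label = f"scenario {scenario}" if scenario is not None else f"model {model}"
    rows = [
        {
            "model": label,
            "statistic": "Jn" if scenario is not None else statistic,
            "n": n,
            "alpha": float(a),
            "rejection_pct": float(np.mean(pvals <= a) * 100.0),
        }
        for a in alphas
    ]
    meta = {
        "seed": seed, "S": S, "B": B, "fraction": fraction,
        "bandwidth": bandwidth, "kind": kind, "n": n,
    }
    return ExperimentResult(pd.DataFrame(rows), pvals, meta)
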