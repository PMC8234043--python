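"""Core model objects for periodic self-exciting threshold INAR processes.

The process observed at time t = j + sT (cycle position j = 1..T, cycle
number s >= 0) is

    X_t = alpha_j(1) o X_{t-1} + Z_t   if X_{t-1} <= r_j
          alpha_j(2) o X_{t-1} + Z_t   if X_{t-1} >  r_j

where "o" is binomial thinning (each of the X_{t-1} individuals survives
independently with probability alpha) and Z_t is a non-negative integer
innovation with cycle-dependent mean lambda_j.  All parameters repeat with
period T, so the process is cyclostationary rather than stationary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Family",
    "InnovationSpec",
    "ModelSpec",
    "CountSeries",
    "ThetaVector",
    "binomial_thinning",
    "innovation_pmf",
    "innovation_moments",
    "simulate",
    "simulate_pinar",
    "conditional_mean",
    "conditional_variance",
]

# support truncation: smallest z* with CDF >= 1 - PMF_TAIL_TOL, capped
PMF_TAIL_TOL = 1e-12
PMF_SUPPORT_CAP = 10_000


class Family(str, enum.Enum):
    """Innovation distribution families."""

    POISSON = "poisson"
    GEOMETRIC = "geometric"
    MIXTURE = "mixture"
    ZT_POISSON = "zero_truncated_poisson"
    ZT_GEOMETRIC = "zero_truncated_geometric"


_ZERO_TRUNCATED = {Family.ZT_POISSON, Family.ZT_GEOMETRIC}


@dataclass(frozen=True)
class InnovationSpec:
    """Cycle-indexed innovation distribution.

    Parameters
    ----------
    family
        One of :class:`Family` (or its string value).
    lam
        Per-cycle parameter vector ``lambda_j > 0``, length T.  For the
        Poisson family this is the mean; for the geometric family the pmf is
        ``lambda^z / (1 + lambda)^(1+z)`` (mean lambda, variance
        lambda(1+lambda)); the mixture draws from Poisson(lambda_j) with
        probability rho_j and from the geometric otherwise.
    rho
        Per-cycle mixing probability, required iff ``family == MIXTURE``.
    """

    family: Family
    lam: np.ndarray
    rho: np.ndarray | None = None

    def __post_init__(self):
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if np.any(lam <= 0):
            raise ValueError("lambda_j must be positive for every cycle")
        object.__setattr__(self, "lam", lam)
        if fam is Family.MIXTURE:
            if self.rho is None:
                raise ValueError("mixture family requires rho")
            rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
            if rho.shape != lam.shape:
                raise ValueError("rho must have the same length as lam")
            if np.any((rho < 0) | (rho > 1)):
                raise ValueError("rho_j must lie in [0, 1]")
            object.__setattr__(self, "rho", rho)
        elif self.rho is not None:
            raise ValueError("rho is only meaningful for the mixture family")

    @property
    def T(self) -> int:
        return self.lam.shape[0]

    # -- pmf / moments ----------------------------------------------------

    def pmf(self, j: int, z) -> float | np.ndarray:
        """P(Z = z) for cycle position j (1-based)."""
        return innovation_pmf(self, j, z)

    def moments(self, j: int) -> tuple[float, float]:
        """(mean, variance) of the cycle-j innovation."""
        return innovation_moments(self, j)

    def support_cutoff(self, j: int) -> int:
        """Smallest z* with CDF(z*) >= 1 - 1e-12 (capped)."""
        lam = float(self.lam[j - 1])
        if self.family is Family.POISSON:
            hi = int(stats.poisson.ppf(1 - PMF_TAIL_TOL, lam))
        elif self.family is Family.GEOMETRIC:
            hi = int(stats.geom.ppf(1 - PMF_TAIL_TOL, 1.0 / (1.0 + lam)))
        elif self.family is Family.MIXTURE:
            hi = max(
                int(stats.poisson.ppf(1 - PMF_TAIL_TOL, lam)),
                int(stats.geom.ppf(1 - PMF_TAIL_TOL, 1.0 / (1.0 + lam))),
            )
        elif self.family is Family.ZT_POISSON:
            hi = int(stats.poisson.ppf(1 - PMF_TAIL_TOL, lam)) + 1
        else:  # ZT_GEOMETRIC
            hi = int(stats.geom.ppf(1 - PMF_TAIL_TOL, 1.0 / (1.0 + lam))) + 1
        return min(max(hi, 1), PMF_SUPPORT_CAP)

    def pmf_vector(self, j: int, n_max: int) -> np.ndarray:
        """pmf evaluated on 0..n_max as a dense vector."""
        return innovation_pmf(self, j, np.arange(n_max + 1))

    def sample(self, j: int, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``size`` innovations for cycle position j."""
        lam = float(self.lam[j - 1])
        p_geom = 1.0 / (1.0 + lam)
        if self.family is Family.POISSON:
            return rng.poisson(lam, size)
        if self.family is Family.GEOMETRIC:
            # numpy's geometric counts trials (support >= 1)
            return rng.geometric(p_geom, size) - 1
        if self.family is Family.MIXTURE:
            take_pois = rng.random(size) < self.rho[j - 1]
            out = rng.geometric(p_geom, size) - 1
            out[take_pois] = rng.poisson(lam, int(take_pois.sum()))
            return out
        if self.family is Family.ZT_POISSON:
            # inverse-cdf on the truncated support
            u = rng.random(size)
            p0 = math.exp(-lam)
            return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)
        # ZT_GEOMETRIC: memorylessness => 1 + geometric(number of failures)
        return rng.geometric(p_geom, size)


def innovation_pmf(spec: InnovationSpec, j: int, z):
    """Innovation pmf P(Z_{j+sT} = z); zero-truncated families return 0 at z=0."""
    z_arr = np.asarray(z)
    if np.any(z_arr != np.floor(z_arr)):
        raise ValueError("z must be integer-valued")
    lam = float(spec.lam[j - 1])
    p_geom = 1.0 / (1.0 + lam)
    valid = z_arr >= 0
    zv = np.where(valid, z_arr, 0).astype(np.int64)
    if spec.family is Family.POISSON:
        out = stats.poisson.pmf(zv, lam)
    elif spec.family is Family.GEOMETRIC:
        out = stats.geom.pmf(zv + 1, p_geom)  # lam^z / (1+lam)^(1+z)
    elif spec.family is Family.MIXTURE:
        rho = float(spec.rho[j - 1])
        out = rho * stats.poisson.pmf(zv, lam) + (1 - rho) * stats.geom.pmf(
            zv + 1, p_geom
        )
    elif spec.family is Family.ZT_POISSON:
        out = stats.poisson.pmf(zv, lam) / (-math.expm1(-lam))
        out = np.where(zv >= 1, out, 0.0)
    else:  # ZT_GEOMETRIC: geometric conditioned on z >= 1
        out = stats.geom.pmf(zv + 1, p_geom) / (1.0 - p_geom)
        out = np.where(zv >= 1, out, 0.0)
    out = np.where(valid, out, 0.0)
    return out if out.ndim else float(out)


def innovation_moments(spec: InnovationSpec, j: int) -> tuple[float, float]:
    """Exact mean and variance of the cycle-j innovation."""
    lam = float(spec.lam[j - 1])
    if spec.family is Family.POISSON:
        return lam, lam
    if spec.family is Family.GEOMETRIC:
        return lam, lam * (1.0 + lam)
    if spec.family is Family.MIXTURE:
        rho = float(spec.rho[j - 1])
        return lam, lam * lam * (1.0 - rho) + lam
    if spec.family is Family.ZT_POISSON:
        denom = -math.expm1(-lam)  # 1 - e^{-lam}
        mean = lam / denom
        second = (lam * lam + lam) / denom  # E Z^2 of Poisson over denom
        return mean, second - mean * mean
    # ZT_GEOMETRIC: 1 + geometric(failures) by memorylessness
    return 1.0 + lam, lam * (1.0 + lam)


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of a PSETINAR(2;1,1)_T process.

    ``alpha`` is a T x 2 matrix of survival probabilities: column 0 applies
    when the lagged count is at or below the cycle's threshold ``r_j``
    (regime 1), column 1 above it (regime 2).
    """

    T: int
    alpha: np.ndarray
    r: np.ndarray
    innovations: InnovationSpec

    def __post_init__(self):
        # the theory wants alpha in (0,1); the closed endpoints are kept
        # admissible so degenerate (pure-innovation / identity) processes can
        # be simulated in checks
        alpha = np.asarray(self.alpha, dtype=float).reshape(self.T, 2)
        if np.any((alpha < 0) | (alpha > 1)):
            raise ValueError("alpha_j(k) must lie in [0, 1]")
        r = np.asarray(self.r)
        if np.any(r != np.floor(r)):
            raise ValueError("thresholds r_j must be integers")
        r = r.astype(np.int64).reshape(self.T)
        if self.innovations.T != self.T:
            raise ValueError("innovation spec length must equal the period T")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "r", r)

    @property
    def beta(self) -> np.ndarray:
        """Parameter vector (alpha_1(1), alpha_1(2), lambda_1, ...)."""
        out = np.empty(3 * self.T)
        out[0::3] = self.alpha[:, 0]
        out[1::3] = self.alpha[:, 1]
        out[2::3] = self.innovations.lam
        return out


@dataclass(frozen=True)
class CountSeries:
    """Observed or simulated count series with cycle indexing t = j + sT.

    Observations are 1-based in time: ``x[i]`` is X_{i+1} and belongs to
    cycle position ``j = (i % T) + 1``.  ``x0`` is the pre-sample value X_0
    acting as the regressor for t = 1.
    """

    x: np.ndarray
    T: int
    x0: int = 0

    def __post_init__(self):
        x = np.asarray(self.x)
        if np.any(x != np.floor(x)) or np.any(x < 0):
            raise ValueError("counts must be non-negative integers")
        x = x.astype(np.int64)
        if x.size % self.T:
            raise ValueError("series length must be a whole number of cycles")
        if self.x0 < 0 or self.x0 != int(self.x0):
            raise ValueError("x0 must be a non-negative integer")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "x0", int(self.x0))

    @property
    def N(self) -> int:
        """Number of complete cycles."""
        return self.x.size // self.T

    @property
    def lagged(self) -> np.ndarray:
        """X_{t-1} aligned with x (X_0 prepended)."""
        return np.concatenate(([self.x0], self.x[:-1]))

    def cycle(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(X_{j+sT-1}, X_{j+sT}) pairs for cycle position j (1-based)."""
        idx = np.arange(j - 1, self.x.size, self.T)
        return self.lagged[idx], self.x[idx]


@dataclass(frozen=True)
class ThetaVector:
    """Per-cycle conditional-variance parameters.

    theta_j(k) = alpha_j(k)(1 - alpha_j(k)) is the thinning variance slope in
    regime k; sigma2z_j is the innovation variance.  The conditional variance
    of X_t given X_{t-1} = x in regime k is theta_j(k) * x + sigma2z_j.
    """

    theta1: np.ndarray
    theta2: np.ndarray
    sigma2z: np.ndarray

    def __post_init__(self):
        t1 = np.atleast_1d(np.asarray(self.theta1, dtype=float))
        t2 = np.atleast_1d(np.asarray(self.theta2, dtype=float))
        s2 = np.atleast_1d(np.asarray(self.sigma2z, dtype=float))
        if not (t1.shape == t2.shape == s2.shape):
            raise ValueError("theta components must share one length T")
        if np.any(t1 < 0) or np.any(t1 > 0.25) or np.any(t2 < 0) or np.any(t2 > 0.25):
            raise ValueError("theta_j(k) = alpha(1-alpha) must lie in [0, 0.25]")
        if np.any(s2 <= 0):
            raise ValueError("sigma2z must be positive (floor before building)")
        object.__setattr__(self, "theta1", t1)
        object.__setattr__(self, "theta2", t2)
        object.__setattr__(self, "sigma2z", s2)

    @classmethod
    def from_alpha(cls, alpha: np.ndarray, sigma2z) -> "ThetaVector":
        alpha = np.asarray(alpha, dtype=float).reshape(-1, 2)
        a = np.clip(alpha, 0.0, 1.0)
        return cls(a[:, 0] * (1 - a[:, 0]), a[:, 1] * (1 - a[:, 1]), sigma2z)

    def weights(self, x_prev: np.ndarray, j: int, r_j: int) -> np.ndarray:
        """Conditional variances V_theta(X_t | X_{t-1}) for cycle j at threshold r_j."""
        in1 = x_prev <= r_j
        v = np.where(in1, self.theta1[j - 1], self.theta2[j - 1]) * x_prev
        return v + self.sigma2z[j - 1]


def binomial_thinning(alpha: float, x: int, rng: np.random.Generator) -> int:
    """Binomial thinning alpha o x: sum of x iid Bernoulli(alpha) survivals."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if x < 0 or x != int(x):
        raise ValueError("x must be a non-negative integer")
    return int(rng.binomial(int(x), alpha))


def conditional_mean(spec: ModelSpec, x_prev: int, j: int) -> float:
    """E(X_t | X_{t-1} = x_prev) for cycle position j."""
    if x_prev < 0:
        raise ValueError("x_prev must be non-negative")
    lam = innovation_moments(spec.innovations, j)[0]
    k = 0 if x_prev <= spec.r[j - 1] else 1
    return spec.alpha[j - 1, k] * x_prev + lam


def conditional_variance(theta: ThetaVector, x_prev: int, j: int, r_j: int) -> float:
    """Var(X_t | X_{t-1} = x_prev) = theta_j(regime) * x_prev + sigma2z_j."""
    if x_prev < 0:
        raise ValueError("x_prev must be non-negative")
    th = theta.theta1[j - 1] if x_prev <= r_j else theta.theta2[j - 1]
    return float(th * x_prev + theta.sigma2z[j - 1])


def _simulate_path(
    T: int,
    alpha1: np.ndarray,
    alpha2: np.ndarray,
    r: np.ndarray,
    innovations: InnovationSpec,
    N: int,
    x0: int,
    burn_in: int,
    rng: np.random.Generator,
) -> CountSeries:
    if N < 1:
        raise ValueError("N must be >= 1")
    if burn_in % T:
        raise ValueError("burn_in must be a whole number of cycles (multiple of T)")
    n_total = burn_in + N * T
    # innovations drawn up-front, column per cycle position
    z = np.empty(n_total, dtype=np.int64)
    for j in range(1, T + 1):
        idx = np.arange(j - 1, n_total, T)
        z[idx] = innovations.sample(j, idx.size, rng)
    x = np.empty(n_total, dtype=np.int64)
    prev = int(x0)
    binom = rng.binomial
    for t in range(n_total):
        j = t % T
        a = alpha1[j] if prev <= r[j] else alpha2[j]
        surv = binom(prev, a) if prev > 0 else 0
        prev = int(surv) + int(z[t])
        x[t] = prev
    kept = x[burn_in:]
    new_x0 = int(x0) if burn_in == 0 else int(x[burn_in - 1])
    return CountSeries(x=kept, T=T, x0=new_x0)


def simulate(
    spec: ModelSpec,
    N: int,
    x0: int = 0,
    burn_in: int = 0,
    rng: np.random.Generator | int | None = None,
) -> CountSeries:
    """Simulate N complete cycles of the threshold process.

    ``burn_in`` extra leading observations (a whole number of cycles) are
    simulated and discarded, so the retained series always starts at a
    cycle-1 position; its X_0 field is then the last discarded value.
    """
    rng = np.random.default_rng(rng)
    return _simulate_path(
        spec.T, spec.alpha[:, 0], spec.alpha[:, 1], spec.r, spec.innovations,
        N, x0, burn_in, rng,
    )


def simulate_pinar(
    T: int,
    alpha: np.ndarray,
    innovations: InnovationSpec,
    N: int,
    x0: int = 0,
    burn_in: int = 0,
    rng: np.random.Generator | int | None = None,
) -> CountSeries:
    """Simulate the single-regime periodic INAR(1) baseline X_t = alpha_j o X_{t-1} + Z_t."""
    rng = np.random.default_rng(rng)
    alpha = np.asarray(alpha, dtype=float).reshape(T)
    r = np.zeros(T, dtype=np.int64)  # irrelevant: both regimes share alpha
    return _simulate_path(T, alpha, alpha, r, innovations, N, x0, burn_in, rng)
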