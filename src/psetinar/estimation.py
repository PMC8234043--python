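"""Parameter estimation for periodic threshold INAR processes.

Three routes are provided for the per-cycle parameters
beta_j = (alpha_j(1), alpha_j(2), lambda_j), always at fixed thresholds:

* CLS  — conditional least squares: closed-form per-cycle regression of X_t
  on (X_{t-1} I1, X_{t-1} I2, 1).
* MQL  — modified quasi-likelihood: the weighted estimating equations
  beta_hat = Q_N^{-1} q_N with inverse conditional-variance weights
  1 / V_theta(X_t | X_{t-1}), theta plugged in from a consistent first
  stage (CLS slopes plus a residual-based innovation-variance estimator).
* CML  — conditional maximum likelihood under a declared innovation family,
  maximizing the product of one-step transition probabilities (binomial
  thinning convolved with the innovation pmf).

The likelihood, the estimating equations and the plug-in information matrix
all factorize over cycle positions, so every solve is a 3x3 problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model_core import (
    CountSeries,
    Family,
    InnovationSpec,
    ThetaVector,
    innovation_pmf,
)

__all__ = [
    "EstimationResult",
    "cls_estimate",
    "variance_est_v1",
    "variance_est_v2",
    "mql_estimate",
    "mql_normal_equations",
    "cml_estimate",
    "transition_pmf",
    "asymptotic_covariance",
    "aic_bic",
    "VARIANCE_FLOOR",
]

VARIANCE_FLOOR = 1e-4  # floor for sigma2z estimates and quasi-likelihood weights


@dataclass
class EstimationResult:
    """Per-cycle parameter estimates with diagnostics.

    ``alpha`` holds the raw estimates (CLS/MQL values may fall outside
    [0, 1]; ``boundary`` marks those).  ``flags`` maps 1-based cycle indices
    to human-readable failure/warning messages.
    """

    method: str
    T: int
    alpha: np.ndarray  # (T, 2)
    lam: np.ndarray  # (T,)
    n_regime: np.ndarray  # (T, 2) counts N_j(k)
    theta: ThetaVector | None = None
    cov: np.ndarray | None = None  # 3T x 3T, block-diagonal
    loglik: float | None = None
    flags: dict[int, list[str]] = field(default_factory=dict)

    @property
    def beta_hat(self) -> np.ndarray:
        out = np.empty(3 * self.T)
        out[0::3] = self.alpha[:, 0]
        out[1::3] = self.alpha[:, 1]
        out[2::3] = self.lam
        return out

    @property
    def boundary(self) -> np.ndarray:
        """True where an alpha estimate lies outside [0, 1]."""
        with np.errstate(invalid="ignore"):
            return (self.alpha < 0) | (self.alpha > 1)

    @property
    def se(self) -> np.ndarray | None:
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))

    def _flag(self, j: int, msg: str) -> None:
        self.flags.setdefault(j, []).append(msg)

    def to_frame(self):
        """Long-format table (cycle, parameter, estimate, se, method)."""
        import pandas as pd

        se = self.se
        rows = []
        names = ["alpha(1)", "alpha(2)", "lambda"]
        for j in range(1, self.T + 1):
            vals = [self.alpha[j - 1, 0], self.alpha[j - 1, 1], self.lam[j - 1]]
            for i, (name, v) in enumerate(zip(names, vals)):
                s = se[3 * (j - 1) + i] if se is not None else np.nan
                rows.append(
                    {
                        "cycle": j,
                        "parameter": name,
                        "estimate": v if np.isfinite(v) else "-",
                        "se": s,
                        "method": self.method,
                    }
                )
        return pd.DataFrame(rows)


def _regime_split(series: CountSeries, r, j: int):
    r = np.asarray(r).reshape(series.T)
    xp, x = series.cycle(j)
    in1 = xp <= r[j - 1]
    return xp, x, in1


def cls_estimate(series: CountSeries, r) -> EstimationResult:
    """Conditional least squares at fixed thresholds.

    For each cycle position the closed-form OLS solution of
    X_t = alpha_j(1) X_{t-1} I1 + alpha_j(2) X_{t-1} I2 + lambda_j + error.
    """
    T = series.T
    res = EstimationResult(
        method="CLS",
        T=T,
        alpha=np.full((T, 2), np.nan),
        lam=np.full(T, np.nan),
        n_regime=np.zeros((T, 2), dtype=np.int64),
    )
    for j in range(1, T + 1):
        xp, x, in1 = _regime_split(series, r, j)
        res.n_regime[j - 1] = [int(in1.sum()), int((~in1).sum())]
        cols = [xp * in1, xp * (~in1), np.ones_like(xp, dtype=float)]
        active = [i for i in range(2) if np.any(cols[i] != 0)] + [2]
        for k in range(2):
            if res.n_regime[j - 1, k] == 0:
                res._flag(j, f"regime {k + 1} empty: alpha_{j}({k + 1}) unavailable")
            elif k not in active:
                res._flag(
                    j, f"regime {k + 1} has only zero regressors: alpha undefined"
                )
        A = np.column_stack([cols[i] for i in active]).astype(float)
        rank = np.linalg.matrix_rank(A)
        if rank < len(active):
            res._flag(j, "singular normal equations")
            continue
        sol = np.linalg.lstsq(A, x.astype(float), rcond=None)[0]
        est = dict(zip(active, sol))
        res.alpha[j - 1, 0] = est.get(0, np.nan)
        res.alpha[j - 1, 1] = est.get(1, np.nan)
        res.lam[j - 1] = est[2]
    return res


def variance_est_v1(series: CountSeries, r, alpha_hat, lam_hat):
    """Residual-based innovation-variance estimator (conditional route).

    Per cycle: mean squared one-step residual minus the mean thinning
    variance sum_k alpha(1-alpha) X_{t-1} I(k); floored at VARIANCE_FLOOR.
    Returns (sigma2z array, floored-mask array).
    """
    T = series.T
    alpha_hat = np.asarray(alpha_hat, dtype=float).reshape(T, 2)
    lam_hat = np.asarray(lam_hat, dtype=float).reshape(T)
    out = np.empty(T)
    floored = np.zeros(T, dtype=bool)
    for j in range(1, T + 1):
        xp, x, in1 = _regime_split(series, r, j)
        a1, a2 = alpha_hat[j - 1]
        fitted = np.where(in1, a1, a2) * xp + lam_hat[j - 1]
        thin_var = a1 * (1 - a1) * (xp * in1).mean() + a2 * (1 - a2) * (
            xp * (~in1)
        ).mean()
        out[j - 1] = np.mean((x - fitted) ** 2) - thin_var
        if out[j - 1] < VARIANCE_FLOOR:
            out[j - 1] = VARIANCE_FLOOR
            floored[j - 1] = True
    return out, floored


def variance_est_v2(series: CountSeries, r, alpha_hat):
    """Marginal-variance decomposition estimator of the innovation variance.

    Decomposes the per-cycle marginal variance of X_t into the thinning
    contributions of the two regimes (using the regime proportions and the
    within-regime moments of the lagged value) plus sigma2z; floored at
    VARIANCE_FLOOR.  Returns (sigma2z array, floored mask, per-cycle flags).
    """
    T = series.T
    alpha_hat = np.asarray(alpha_hat, dtype=float).reshape(T, 2)
    out = np.full(T, np.nan)
    floored = np.zeros(T, dtype=bool)
    flags: dict[int, list[str]] = {}
    for j in range(1, T + 1):
        xp, x, in1 = _regime_split(series, r, j)
        n1, n2 = int(in1.sum()), int((~in1).sum())
        if n1 == 0 or n2 == 0:
            flags.setdefault(j, []).append("empty regime: sigma2z_v2 unavailable")
            continue
        var_x = np.mean((x - x.mean()) ** 2)
        p1 = n1 / x.size
        a1, a2 = alpha_hat[j - 1]
        mu1, mu2 = xp[in1].mean(), xp[~in1].mean()
        s1 = np.mean((xp[in1] - mu1) ** 2)
        s2 = np.mean((xp[~in1] - mu2) ** 2)
        raw = (
            var_x
            - p1 * (a1**2 * s1 + a1 * (1 - a1) * mu1)
            - (1 - p1) * (a2**2 * s2 + a2 * (1 - a2) * mu2)
            - p1 * (1 - p1) * (a1 * mu1 - a2 * mu2) ** 2
        )
        if raw < VARIANCE_FLOOR:
            raw = VARIANCE_FLOOR
            floored[j - 1] = True
        out[j - 1] = raw
    return out, floored, flags


def _theta_from_cls(
    series: CountSeries, r, variance_estimator: str = "v1"
) -> tuple[ThetaVector, EstimationResult]:
    cls_res = cls_estimate(series, r)
    alpha_c = np.clip(np.nan_to_num(cls_res.alpha, nan=0.5), 0.0, 1.0)
    if variance_estimator == "v1":
        s2, _ = variance_est_v1(series, r, alpha_c, cls_res.lam)
    elif variance_estimator == "v2":
        s2, _, _ = variance_est_v2(series, r, alpha_c)
        s2 = np.where(np.isnan(s2), VARIANCE_FLOOR, s2)
    else:
        raise ValueError("variance_estimator must be 'v1' or 'v2'")
    return ThetaVector.from_alpha(alpha_c, s2), cls_res


def _mql_blocks(series: CountSeries, r, theta: ThetaVector):
    """Per-cycle (Q_j, q_j) of the weighted normal equations."""
    T = series.T
    rr = np.asarray(r).reshape(T)
    Qs, qs = [], []
    for j in range(1, T + 1):
        xp, x, in1 = _regime_split(series, r, j)
        w = 1.0 / np.maximum(theta.weights(xp, j, rr[j - 1]), VARIANCE_FLOOR)
        c1 = xp * in1
        c2 = xp * (~in1)
        Q = np.array(
            [
                [np.sum(w * c1 * c1), 0.0, np.sum(w * c1)],
                [0.0, np.sum(w * c2 * c2), np.sum(w * c2)],
                [np.sum(w * c1), np.sum(w * c2), np.sum(w)],
            ]
        )
        q = np.array([np.sum(w * x * c1), np.sum(w * x * c2), np.sum(w * x)])
        Qs.append(Q)
        qs.append(q)
    return Qs, qs


def mql_normal_equations(series: CountSeries, r, theta: ThetaVector):
    """Assembled block-diagonal system (Q_N, q_N) over all 3T parameters."""
    Qs, qs = _mql_blocks(series, r, theta)
    T = series.T
    Q = np.zeros((3 * T, 3 * T))
    for j, Qj in enumerate(Qs):
        Q[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] = Qj
    return Q, np.concatenate(qs)


def mql_estimate(
    series: CountSeries,
    r,
    theta: ThetaVector | None = None,
    variance_estimator: str = "v1",
) -> EstimationResult:
    """Modified quasi-likelihood estimation at fixed thresholds.

    When ``theta`` is not supplied it is built from clipped CLS slopes and
    the residual-based variance estimator (``variance_estimator`` selects
    the conditional 'v1' or marginal 'v2' route).
    """
    if theta is None:
        theta, _ = _theta_from_cls(series, r, variance_estimator)
    T = series.T
    res = EstimationResult(
        method="MQL",
        T=T,
        alpha=np.full((T, 2), np.nan),
        lam=np.full(T, np.nan),
        n_regime=np.zeros((T, 2), dtype=np.int64),
        theta=theta,
    )
    Qs, qs = _mql_blocks(series, r, theta)
    cls_fallback: EstimationResult | None = None
    for j in range(1, T + 1):
        xp, x, in1 = _regime_split(series, r, j)
        res.n_regime[j - 1] = [int(in1.sum()), int((~in1).sum())]
        Q, q = Qs[j - 1], qs[j - 1]
        # drop an all-zero alpha block (empty regime) instead of failing
        active = [i for i in range(2) if Q[i, i] > 0] + [2]
        Qa = Q[np.ix_(active, active)]
        if np.linalg.matrix_rank(Qa) < len(active):
            res._flag(j, "singular Q_{j,N}: falling back to CLS for this cycle")
            if cls_fallback is None:
                cls_fallback = cls_estimate(series, r)
            res.alpha[j - 1] = cls_fallback.alpha[j - 1]
            res.lam[j - 1] = cls_fallback.lam[j - 1]
            continue
        sol = dict(zip(active, np.linalg.solve(Qa, q[active])))
        res.alpha[j - 1, 0] = sol.get(0, np.nan)
        res.alpha[j - 1, 1] = sol.get(1, np.nan)
        res.lam[j - 1] = sol[2]
        for k in range(2):
            if res.n_regime[j - 1, k] == 0:
                res._flag(j, f"regime {k + 1} empty: alpha_{j}({k + 1}) unavailable")
    res.cov = asymptotic_covariance(series, r, theta)
    return res


def asymptotic_covariance(series: CountSeries, r, theta: ThetaVector) -> np.ndarray:
    """Plug-in asymptotic covariance of the MQL estimator.

    The per-cycle information block is estimated by H_j = Q_{j,N} / N
    (sample means replacing expectations), giving Cov(beta_hat_j) ~
    H_j^{-1} / N.  Singular blocks are left as NaN.
    """
    Qs, _ = _mql_blocks(series, r, theta)
    T = series.T
    N = series.N
    cov = np.full((3 * T, 3 * T), 0.0)
    for j, Q in enumerate(Qs):
        H = Q / N
        try:
            block = np.linalg.inv(H) / N
        except np.linalg.LinAlgError:
            block = np.full((3, 3), np.nan)
        cov[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] = block
    return cov


# ---------------------------------------------------------------------------
# conditional maximum likelihood


def transition_pmf(
    x_prev: int,
    x_next,
    alpha: float,
    innovations: InnovationSpec,
    j_next: int,
) -> np.ndarray | float:
    """One-step transition probability P(X_t = x_next | X_{t-1} = x_prev).

    Binomial(x_prev, alpha) survivors convolved with the cycle-j innovation:
    sum_{i=0}^{min(x_prev, x_next)} C(x_prev, i) alpha^i (1-alpha)^{x_prev-i}
    * P(Z = x_next - i).
    """
    x_next_arr = np.atleast_1d(np.asarray(x_next, dtype=np.int64))
    i = np.arange(int(x_prev) + 1)
    b = stats.binom.pmf(i, int(x_prev), alpha)
    z = innovation_pmf(innovations, j_next, np.maximum(x_next_arr[:, None] - i, -1))
    out = np.sum(b * z, axis=1)
    return out if np.ndim(x_next) else float(out[0])


def _cycle_loglik(xp, x, in1, a1, a2, lam, family: Family) -> float:
    """Vectorized sum of log one-step transition probabilities for one cycle."""
    imax = int(np.minimum(xp, x).max(initial=0))
    i = np.arange(imax + 1)
    a = np.where(in1, a1, a2)
    b = stats.binom.pmf(i[None, :], xp[:, None], a[:, None])
    spec = InnovationSpec(family=family, lam=np.array([lam]))
    z = innovation_pmf(spec, 1, np.maximum(x[:, None] - i[None, :], -1))
    mask = i[None, :] <= np.minimum(xp, x)[:, None]
    p = np.sum(b * z * mask, axis=1)
    return float(np.sum(np.log(np.clip(p, 1e-300, None))))


def cml_estimate(
    series: CountSeries,
    r,
    family: Family | str = Family.POISSON,
) -> EstimationResult:
    """Conditional maximum likelihood under a declared innovation family.

    The likelihood factorizes over cycle positions, so each cycle's
    (alpha_j(1), alpha_j(2), lambda_j) is maximized separately with box
    constraints, initialized at the clipped CLS estimate.
    """
    family = Family(family)
    if family is Family.MIXTURE:
        raise ValueError("CML for the mixture family is not supported")
    T = series.T
    cls_res = cls_estimate(series, r)
    res = EstimationResult(
        method="CML",
        T=T,
        alpha=np.full((T, 2), np.nan),
        lam=np.full(T, np.nan),
        n_regime=cls_res.n_regime.copy(),
        loglik=0.0,
    )
    eps = 1e-6
    for j in range(1, T + 1):
        xp, x, in1 = _regime_split(series, r, j)
        a0 = np.clip(np.nan_to_num(cls_res.alpha[j - 1], nan=0.5), eps, 1 - eps)
        l0 = max(np.nan_to_num(cls_res.lam[j - 1], nan=1.0), eps)
        if family in (Family.ZT_POISSON, Family.ZT_GEOMETRIC):
            l0 = max(l0, 0.5)

        def nll(p):
            return -_cycle_loglik(xp, x, in1, p[0], p[1], p[2], family)

        opt = optimize.minimize(
            nll,
            x0=[a0[0], a0[1], l0],
            method="L-BFGS-B",
            bounds=[(eps, 1 - eps), (eps, 1 - eps), (eps, None)],
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if not opt.success:
            res._flag(j, f"optimizer did not converge: {opt.message}")
        res.alpha[j - 1] = opt.x[:2]
        res.lam[j - 1] = opt.x[2]
        res.loglik += -float(opt.fun)
    return res


def aic_bic(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """Standard information criteria: AIC = -2l + 2p, BIC = -2l + p log n."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return -2.0 * loglik + 2.0 * n_params, -2.0 * loglik + n_params * np.log(n_obs)
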