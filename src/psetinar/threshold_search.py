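"""Threshold estimation by profiled sum-of-squares grid search.

For a candidate threshold vector r, the conditional least squares criterion
fits each cycle's regression X_t ~ alpha_1 X_{t-1} I1 + alpha_2 X_{t-1} I2
+ lambda in closed form and records the sum of squared residuals S_N(r).
The threshold estimate maximizes the improvement

    J_N(r) = S_N - S_N(r)

over the no-split (single-slope) fit S_N.  The quasi-likelihood variant
weights every sum by the inverse plug-in conditional variance
1 / V_theta(X_t | X_{t-1}).  Both objectives decompose as sums over cycle
positions in which r_j enters only through its own term, so the exact
maximizer is found by an exhaustive per-cycle scan over the integer
candidates between the smallest and largest lagged value of the cycle.

The innovation mean lambda is profiled out together with the slopes, which
is exactly why the search does not depend on any plug-in value of lambda;
:func:`jn_objective` still accepts an explicit lambda vector, in which case
it evaluates the cruder criterion that holds the intercept fixed and
profiles only the slopes.  That plug-in form is NOT consistent for the
split point (a misspecified intercept can favour a wrong split even as
N grows), so the search and the three-step procedure always profile.

The full procedure is a three-step plug-in scheme: an unweighted threshold
scan, a quasi-likelihood refit of the regression parameters at those
thresholds, then the weighted threshold scan with the refitted variance
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import (
    EstimationResult,
    VARIANCE_FLOOR,
    cls_estimate,
    mql_estimate,
    variance_est_v1,
    variance_est_v2,
)
from .model_core import CountSeries, ThetaVector

__all__ = [
    "ThresholdSearchResult",
    "ThreeStepResult",
    "jn_objective",
    "estimate_thresholds",
    "three_step_estimate",
]


@dataclass
class ThresholdSearchResult:
    """Result of a per-cycle exhaustive threshold scan.

    ``r_hat`` is float so that cycles with no admissible candidate (flagged
    "no piecewise phenomenon") can carry NaN.
    """

    r_hat: np.ndarray
    objective_profile: dict[int, dict[int, float]]
    method: str
    lam_used: np.ndarray
    flags: dict[int, list[str]] = field(default_factory=dict)

    @property
    def r_int(self) -> np.ndarray:
        """Integer thresholds with NaN cycles filled by the largest candidate
        (placing every observation in regime 1)."""
        out = self.r_hat.copy()
        for j, profile in self.objective_profile.items():
            if np.isnan(out[j - 1]):
                out[j - 1] = max(profile) if profile else 0
        return out.astype(np.int64)

    def profile_frame(self):
        """Long-format (cycle, candidate, objective) table."""
        import pandas as pd

        rows = [
            {"cycle": j, "candidate": c, "objective": v}
            for j, profile in self.objective_profile.items()
            for c, v in profile.items()
        ]
        return pd.DataFrame(rows)


def _wls_sse(cols, x, w):
    """Weighted least squares SSE of x on the given regressor columns.

    All-zero columns are dropped (their slope is pinned at 0, penalizing
    the fit); returns (sse, degenerate_flag).
    """
    active = [c for c in cols if np.any(c != 0)]
    degenerate = len(active) < len(cols)
    A = np.column_stack(active).astype(float)
    sw = np.sqrt(w)
    sol, *_ = np.linalg.lstsq(A * sw[:, None], x * sw, rcond=None)
    resid = x - A @ sol
    return float(np.sum(w * resid * resid)), degenerate


def _cycle_j_term(
    xp, x, r_cand, theta: ThetaVector | None, j: int, lam_j: float | None = None
):
    """J contribution of one cycle at one candidate threshold.

    With ``lam_j`` None (the default used by the search) the intercept is
    profiled together with the two regime slopes; with an explicit
    ``lam_j`` the intercept is held fixed and only the slopes are profiled
    (the literal plug-in criterion).  Returns (value, degenerate_flag).
    """
    in1 = xp <= r_cand
    if theta is not None:
        w = 1.0 / np.maximum(theta.weights(xp, j, r_cand), VARIANCE_FLOOR)
    else:
        w = np.ones_like(xp, dtype=float)
    xpf = xp.astype(float)
    ones = np.ones_like(xpf)
    if lam_j is None:
        s_nosplit, _ = _wls_sse([xpf, ones], x.astype(float), w)
        s_split, degenerate = _wls_sse(
            [xpf * in1, xpf * (~in1), ones], x.astype(float), w
        )
    else:
        y = x - lam_j
        s_nosplit, _ = _wls_sse([xpf], y, w)
        s_split, degenerate = _wls_sse([xpf * in1, xpf * (~in1)], y, w)
    return s_nosplit - s_split, degenerate


def jn_objective(
    series: CountSeries,
    r,
    lam=None,
    weights: ThetaVector | None = None,
) -> float:
    """Split-improvement objective J_N(r) (or weighted J-tilde), summed over cycles.

    With ``lam`` None the intercept is profiled (the criterion the search
    maximizes); an explicit per-cycle ``lam`` evaluates the plug-in form
    that holds the intercept fixed.
    """
    T = series.T
    r = np.asarray(r).reshape(T)
    if lam is not None:
        lam = np.asarray(lam, dtype=float).reshape(T)
    total = 0.0
    for j in range(1, T + 1):
        xp, x = series.cycle(j)
        lam_j = None if lam is None else lam[j - 1]
        val, _ = _cycle_j_term(xp, x, int(r[j - 1]), weights, j, lam_j)
        total += val
    return total


TRIM_FRACTION = 0.15  # minimum share of a cycle's points left in each regime


def _candidate_grid(
    xp: np.ndarray,
    lo: int | None,
    hi: int | None,
    trim: float = TRIM_FRACTION,
) -> list[int]:
    """Integer candidates between lo and hi leaving both regimes populated.

    A candidate must leave at least max(2, ceil(trim * n)) lagged values in
    each regime: fitting a separate slope to a near-empty regime produces
    spurious sum-of-squares improvements, so the scan is restricted to the
    central part of the lagged-value distribution (the usual trimming of
    threshold regression).
    """
    lo = int(xp.min()) if lo is None else int(lo)
    hi = int(xp.max()) if hi is None else int(hi)
    m = max(2, int(np.ceil(trim * xp.size)))
    out = []
    for c in range(lo, hi + 1):
        n1 = int(np.sum(xp <= c))
        if n1 >= m and xp.size - n1 >= m:
            out.append(c)
    return out


def estimate_thresholds(
    series: CountSeries,
    lam=None,
    method: str = "CLS",
    weights: ThetaVector | None = None,
    r_lower=None,
    r_upper=None,
    trim: float = TRIM_FRACTION,
    criterion: str = "profiled",
) -> ThresholdSearchResult:
    """Exhaustive per-cycle threshold scan maximizing J_N (CLS) or J-tilde (MQL).

    With ``criterion="profiled"`` (the default) the intercept is profiled
    jointly with the regime slopes, so the result does not depend on any
    plug-in innovation mean: ``lam`` is then only recorded as ``lam_used``
    (defaulting to the per-cycle sample means).  ``criterion="plugin"``
    evaluates the literal fixed-intercept objective at the supplied ``lam``
    — accurate when ``lam`` is (close to) the true innovation means, but
    NOT consistent under a misspecified intercept.  Ties are broken by the
    smallest maximizing candidate.  Cycles where no candidate leaves
    enough points in each regime are flagged as having no piecewise
    phenomenon.
    """
    method = method.upper()
    if method not in ("CLS", "MQL"):
        raise ValueError("method must be 'CLS' or 'MQL'")
    if method == "MQL" and weights is None:
        raise ValueError("MQL threshold search requires a ThetaVector of weights")
    if criterion not in ("profiled", "plugin"):
        raise ValueError("criterion must be 'profiled' or 'plugin'")
    theta = weights if method == "MQL" else None
    T = series.T
    if lam is None:
        lam = np.array([series.cycle(j)[1].mean() for j in range(1, T + 1)])
    lam = np.asarray(lam, dtype=float).reshape(T)
    lo = np.full(T, None) if r_lower is None else np.asarray(r_lower).reshape(T)
    hi = np.full(T, None) if r_upper is None else np.asarray(r_upper).reshape(T)

    res = ThresholdSearchResult(
        r_hat=np.full(T, np.nan),
        objective_profile={},
        method=method,
        lam_used=lam,
    )
    for j in range(1, T + 1):
        xp, x = series.cycle(j)
        candidates = _candidate_grid(xp, lo[j - 1], hi[j - 1], trim)
        profile: dict[int, float] = {}
        best, best_val = None, -np.inf
        lam_j = lam[j - 1] if criterion == "plugin" else None
        for c in candidates:
            val, _ = _cycle_j_term(xp, x, c, theta, j, lam_j)
            profile[c] = val
            if val > best_val:  # strict: ties keep the smallest candidate
                best, best_val = c, val
        res.objective_profile[j] = profile
        if best is None:
            res.flags.setdefault(j, []).append("no piecewise phenomenon")
        else:
            res.r_hat[j - 1] = best
    return res


@dataclass
class ThreeStepResult:
    """Output of the three-step threshold/parameter estimation procedure."""

    r_cls: ThresholdSearchResult  # step 1
    beta_step2: EstimationResult  # MQL fit at the CLS thresholds
    r_mql: ThresholdSearchResult  # step 3
    beta_final: EstimationResult  # MQL refit at the final thresholds

    @property
    def r_hat(self) -> np.ndarray:
        return self.r_mql.r_hat


def three_step_estimate(
    series: CountSeries,
    r_lower=None,
    r_upper=None,
    variance_estimator: str = "v1",
    trim: float = TRIM_FRACTION,
) -> ThreeStepResult:
    """Run the full three-step procedure.

    Step 1: CLS threshold scan with lambda_j = per-cycle sample means.
    Step 2: at those thresholds, CLS slopes feed the innovation-variance
    estimator; the quasi-likelihood refit gives beta_MQL.
    Step 3: weighted threshold scan with theta built from the step-2 slopes
    and variances, same candidate bounds; the regression parameters are then
    refit at the final thresholds.
    """
    r_cls = estimate_thresholds(
        series, method="CLS", r_lower=r_lower, r_upper=r_upper, trim=trim
    )
    r1 = r_cls.r_int
    cls_beta = cls_estimate(series, r1)
    alpha_c = np.clip(np.nan_to_num(cls_beta.alpha, nan=0.5), 0.0, 1.0)
    if variance_estimator == "v1":
        s2, _ = variance_est_v1(series, r1, alpha_c, cls_beta.lam)
    else:
        s2, _, _ = variance_est_v2(series, r1, alpha_c)
        s2 = np.where(np.isnan(s2), VARIANCE_FLOOR, s2)
    theta2 = ThetaVector.from_alpha(alpha_c, s2)
    beta_step2 = mql_estimate(series, r1, theta=theta2)
    theta3 = ThetaVector.from_alpha(
        np.clip(np.nan_to_num(beta_step2.alpha, nan=0.5), 0.0, 1.0), s2
    )
    r_mql = estimate_thresholds(
        series, method="MQL", weights=theta3, r_lower=r_lower, r_upper=r_upper,
        trim=trim,
    )
    beta_final = mql_estimate(series, r_mql.r_int, theta=theta3)
    return ThreeStepResult(
        r_cls=r_cls, beta_step2=beta_step2, r_mql=r_mql, beta_final=beta_final
    )
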