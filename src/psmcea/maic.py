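"""Anchored matching-adjusted indirect comparison (MAIC).

Reference-trial IPD is reweighted so its baseline moments equal the
comparator trial's published aggregates; anchored hazard ratios (each active
arm vs its own trial's shared chemotherapy-control anchor) are then combined
across trials by the Bucher method: log HR_AB = log HR_AC - log HR_BC with
variances adding.

Weights are of the method-of-moments / entropy-balancing form
w_i = exp(a' x_i): the coefficient vector solves the convex dual
min_a sum_i exp(a'(x_i - target)) by Newton iteration, whose first-order
condition is exact moment matching, sum_i w_i (x_i - target) = 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MATCHING_COVARIATES",
    "KEYNOTE_BASELINE",
    "InfeasibleTargetError",
    "MAICResult",
    "solve_weights",
    "effective_sample_size",
    "bucher_indirect",
    "anchored_maic",
]

#: The six matching factors (means/proportions only; first moments).
MATCHING_COVARIATES = ("male", "age", "brain_met", "stage_iv", "smoker", "ecog1")

#: Comparator-trial aggregate baseline profile (the matching target).
KEYNOTE_BASELINE = {
    "male": 0.8140,
    "age": 65.00,
    "brain_met": 0.0769,
    "stage_iv": 0.6315,
    "smoker": 0.9267,
    "ecog1": 0.7370,
}


class InfeasibleTargetError(ValueError):
    """A target moment lies outside the convex hull of the observed data."""


@dataclass
class MAICResult:
    weights: np.ndarray
    ess: float
    hr_ref_weighted: float          # reference active vs anchor, MAIC-weighted
    hr_ref_weighted_se: float       # SE of log-HR
    hr_comp: float                  # comparator active vs anchor (published)
    hr_comp_se: float
    hr_ref_vs_comp: float           # Bucher indirect estimate
    hr_ref_vs_comp_ci: tuple


def solve_weights(records: pd.DataFrame, target: dict,
                  tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Method-of-moments MAIC weights matching every target moment exactly.

    Returns nonnegative weights normalized to sum to n.  Covariates are
    standardized internally (the solution is invariant to affine rescaling).
    Raises :class:`InfeasibleTargetError`, naming the covariate, when a
    target lies outside the observed range.
    """
    cols = [c for c in target]
    X = records[cols].to_numpy(dtype=float)
    t = np.array([float(target[c]) for c in cols])
    for j, c in enumerate(cols):
        lo, hi = X[:, j].min(), X[:, j].max()
        if not (lo <= t[j] <= hi) or (lo == hi and t[j] != lo):
            raise InfeasibleTargetError(
                f"target for {c!r} ({t[j]:g}) outside observed range [{lo:g}, {hi:g}]"
            )
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - t) / scale  # centered at target, standardized

    def log_obj(a):
        eta = Z @ a
        m = eta.max()
        return m + np.log(np.exp(eta - m).sum())

    # damped Newton on log sum_i exp(Z a) (same minimizer as the dual itself)
    a = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        eta = Z @ a
        p = np.exp(eta - eta.max())
        p /= p.sum()
        grad = Z.T @ p
        if np.max(np.abs(grad)) < tol:
            break
        H = (Z * p[:, None]).T @ Z  # PD part of the logsumexp Hessian
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(len(a)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        f0, lam = log_obj(a), 1.0
        while lam > 1e-10 and log_obj(a - lam * step) > f0:
            lam *= 0.5
        a = a - lam * step
    else:
        raise RuntimeError("MAIC weight solver did not converge")

    eta = Z @ a
    w = np.exp(eta - eta.max())
    w = w / w.sum() * len(w)
    resid = np.max(np.abs((w @ Z) / len(w)))  # standardized, scale-invariant
    if resid > 1e-8:
        raise RuntimeError(f"moment matching residual {resid:g} exceeds tolerance")
    return w


def effective_sample_size(weights) -> float:
    """ESS = (sum w)^2 / sum w^2; equals n for uniform weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    sw2 = float((w ** 2).sum())
    if sw2 == 0:
        raise ValueError("weights are all zero")
    return float(w.sum() ** 2 / sw2)


def bucher_indirect(hr_a_vs_anchor: float, se_a: float,
                    hr_b_vs_anchor: float, se_b: float):
    """Bucher combination of two anchored hazard ratios: A vs B through the anchor.

    Returns (HR_AB, (ci_low, ci_high)); SEs are on the log scale and may be 0
    (degenerate CI).
    """
    if hr_a_vs_anchor <= 0 or hr_b_vs_anchor <= 0:
        raise ValueError("hazard ratios must be positive")
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    log_hr = np.log(hr_a_vs_anchor) - np.log(hr_b_vs_anchor)
    se = float(np.hypot(se_a, se_b))
    hr = float(np.exp(log_hr))
    return hr, (float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se)))


def anchored_maic(records: pd.DataFrame, target: dict,
                  hr_comp: float, hr_comp_se: float,
                  endpoint: str = "os") -> MAICResult:
    """Weight reference IPD to ``target``, re-estimate the anchored HR, and
    combine with the comparator trial's published HR by the Bucher method."""
    from .crossover import cox_hr

    w = solve_weights(records, target)
    active = records[records["arm"] == "active"]
    control = records[records["arm"] == "control"]
    w_series = pd.Series(w, index=records.index)
    weights = np.concatenate([w_series[active.index], w_series[control.index]])
    hr_ref, se_ref = cox_hr(active, control, weights=weights, endpoint=endpoint)
    hr_ab, ci = bucher_indirect(hr_ref, se_ref, hr_comp, hr_comp_se)
    return MAICResult(
        weights=w,
        ess=effective_sample_size(w),
        hr_ref_weighted=hr_ref,
        hr_ref_weighted_se=se_ref,
        hr_comp=hr_comp,
        hr_comp_se=hr_comp_se,
        hr_ref_vs_comp=hr_ab,
        hr_ref_vs_comp_ci=ci,
    )


def weighted_moments(records: pd.DataFrame, weights, covariates=MATCHING_COVARIATES) -> dict:
    """Weighted means of the matching covariates (diagnostic)."""
    w = np.asarray(weights, dtype=float)
    return {c: float(np.average(records[c].to_numpy(dtype=float), weights=w))
            for c in covariates}
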