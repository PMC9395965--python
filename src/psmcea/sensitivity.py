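"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the model at each parameter's low and high bound holding
the rest at base, measuring the effect on net monetary benefit (NMB =
WTP*dQALY - dCost) and, per the tornado convention of the source analysis,
on the raw incremental ratio dCost/dQALY.  NMB is the default ranking metric
because the ICER changes sign unstably in the southwest quadrant; ``metric=
"icer"`` ranks by the ratio's excursion instead.

The PSA is a second-order Monte Carlo: every non-constant parameter is drawn
from its Table distribution, survival-curve parameters are drawn by Cholesky
decomposition of their fitted covariance, the comparator hazard ratios from
a log-normal with a configured log-scale SE, and the model is re-run per
iteration.  Outputs: per-iteration increments, summary means, and the
cost-effectiveness acceptability curve CEAC(WTP) = P(NMB > 0).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import CalibratedModel
from .params import PARAMETER_TABLE, ModelParams, ParamSpec, fit_distribution
from .psm import WTP_HIGH, incremental_summary
from .survfit import sample_parameters

__all__ = ["one_way_dsa", "run_psa", "ceac", "PARAMETER_TABLE", "ParamSpec",
           "fit_distribution"]


def _increments(model: CalibratedModel, params: ModelParams, wtp: float, **kw):
    ref, comp = model.run(params, **kw)
    return incremental_summary(ref, comp, wtp=wtp)


def _raw_icer(inc) -> float:
    if inc.delta_qaly == 0:
        return float("inf") if inc.delta_cost > 0 else float("-inf")
    return inc.delta_cost / inc.delta_qaly


def one_way_dsa(model: CalibratedModel, specs=None, wtp: float = WTP_HIGH,
                metric: str = "nmb") -> pd.DataFrame:
    """Tornado table: one row per parameter, sorted by descending bar size.

    ``bar`` is |outcome(high) - outcome(low)| on the chosen metric; NMB and
    the incremental ratio are both reported for every row.
    """
    if metric not in ("nmb", "icer"):
        raise ValueError("metric must be 'nmb' or 'icer'")
    specs = PARAMETER_TABLE if specs is None else list(specs)
    base = model.params
    base_inc = _increments(model, base, wtp)
    rows = []
    for spec in specs:
        if spec.low > spec.high:
            raise ValueError(f"{spec.name}: low > high")
        lo = _increments(model, base.updated(**{spec.name: spec.low}), wtp)
        hi = _increments(model, base.updated(**{spec.name: spec.high}), wtp)
        bar_nmb = abs(hi.nmb - lo.nmb)
        bar_icer = abs(_raw_icer(hi) - _raw_icer(lo))
        rows.append({
            "parameter": spec.name, "low": spec.low, "high": spec.high,
            "nmb_low": lo.nmb, "nmb_high": hi.nmb,
            "icer_low": _raw_icer(lo), "icer_high": _raw_icer(hi),
            "bar": bar_nmb if metric == "nmb" else bar_icer,
        })
    out = pd.DataFrame(rows).sort_values("bar", ascending=False, ignore_index=True)
    out.attrs["base_nmb"] = base_inc.nmb
    out.attrs["base_icer"] = _raw_icer(base_inc)
    out.attrs["metric"] = metric
    return out


def run_psa(model: CalibratedModel, specs=None, n_iter: int = 10000,
            seed: int = 0, wtp: float = WTP_HIGH,
            sample_survival: bool = True) -> tuple[pd.DataFrame, dict]:
    """Second-order Monte Carlo over parameter and survival uncertainty.

    Returns (draws, summary): ``draws`` has one row per retained iteration
    with the sampled increments; ``summary`` reports mean increments, the
    probabilistic ICER of the means, and quadrant counts.  Iterations whose
    model run fails validation are dropped; more than 1% drops is an error.
    """
    specs = PARAMETER_TABLE if specs is None else list(specs)
    rng = np.random.default_rng(seed)
    active = [(s, fit_distribution(s)) for s in specs if s.dist != "constant"]

    if sample_survival:
        pfs_draws = sample_parameters(model.pfs_fit, n_iter, rng.integers(2**31))
        os_draws = sample_parameters(model.os_fit, n_iter, rng.integers(2**31))
        hr_pfs_draws = model.hr_pfs * np.exp(model.hr_log_se * rng.standard_normal(n_iter))
        hr_os_draws = model.hr_os * np.exp(model.hr_log_se * rng.standard_normal(n_iter))

    sampled = {s.name: np.clip(f(rng, n_iter), 0.0, None) for s, f in active}
    rows, dropped = [], 0
    for i in range(n_iter):
        p = model.params.updated(**{k: float(v[i]) for k, v in sampled.items()})
        kw = {}
        if sample_survival:
            kw = {"pfs_params": pfs_draws[i], "os_params": os_draws[i],
                  "hr_pfs": float(hr_pfs_draws[i]), "hr_os": float(hr_os_draws[i])}
        try:
            inc = _increments(model, p, wtp, **kw)
        except Exception:
            dropped += 1
            continue
        rows.append({"iteration": i, "delta_cost": inc.delta_cost,
                     "delta_qaly": inc.delta_qaly, "nmb": inc.nmb})
    if dropped > 0.01 * n_iter:
        raise RuntimeError(f"PSA dropped {dropped}/{n_iter} iterations")
    draws = pd.DataFrame(rows)
    dc, dq = draws["delta_cost"].to_numpy(), draws["delta_qaly"].to_numpy()
    summary = {
        "n_iter": n_iter,
        "n_retained": len(draws),
        "mean_delta_cost": float(dc.mean()),
        "mean_delta_qaly": float(dq.mean()),
        "probabilistic_icer": float(dc.mean() / dq.mean()) if dq.mean() != 0 else float("nan"),
        "quadrants": {
            "northeast": int(np.sum((dq > 0) & (dc > 0))),
            "southeast": int(np.sum((dq > 0) & (dc <= 0))),
            "southwest": int(np.sum((dq <= 0) & (dc <= 0))),
            "northwest": int(np.sum((dq <= 0) & (dc > 0))),
        },
    }
    return draws, summary


def ceac(draws: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """P(intervention cost-effective) = P(WTP*dQALY - dCost > 0) per WTP."""
    if len(draws) == 0:
        raise ValueError("no PSA draws")
    dc = draws["delta_cost"].to_numpy()
    dq = draws["delta_qaly"].to_numpy()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    prob = [(float(np.mean(w * dq - dc > 0))) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": prob})
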