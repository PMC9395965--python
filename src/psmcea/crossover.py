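"""Two-stage adjustment for treatment switching (crossover) in the control arm.

Control-arm patients who progress may cross over to the active therapy, which
dilutes the intention-to-treat overall-survival hazard ratio toward 1.  The
two-stage method re-baselines switchers at progression: a Weibull accelerated-
failure-time (AFT) model among progressed control patients regresses
post-progression survival on the switch indicator (plus baseline covariates),
giving an acceleration factor; switchers' post-switch survival is then shrunk
by that factor to a counterfactual no-switch time, optionally with
recensoring, and the hazard ratio is re-estimated on the adjusted data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, WeibullAFTFitter

__all__ = [
    "EstimationError",
    "AccelFactor",
    "TwoStageResult",
    "estimate_accel_factor",
    "counterfactual_times",
    "cox_hr",
    "two_stage_adjust",
    "DEFAULT_SECONDARY_COVARIATES",
]

#: Baseline covariates carried to the secondary (progression) baseline.
DEFAULT_SECONDARY_COVARIATES = ("male", "age", "brain_met", "stage_iv", "smoker", "ecog1")

_MIN_TIME = 1e-6  # AFT and Cox require strictly positive times


class EstimationError(RuntimeError):
    pass


@dataclass
class AccelFactor:
    factor: float
    ci_low: float
    ci_high: float
    n_switchers: int
    n_progressed: int


@dataclass
class TwoStageResult:
    accel: AccelFactor
    hr_unadjusted: float
    hr_unadjusted_se: float  # SE of log-HR
    hr_adjusted: float
    hr_adjusted_se: float
    recensored: bool

    @property
    def accel_factor(self) -> float:
        return self.accel.factor

    @property
    def n_switchers(self) -> int:
        return self.accel.n_switchers


def estimate_accel_factor(control_records: pd.DataFrame,
                          covariates=DEFAULT_SECONDARY_COVARIATES) -> AccelFactor:
    """Weibull AFT at the secondary baseline among progressed control patients.

    Post-progression survival (os_time - pfs_time, event = os_event) is
    regressed on the switch indicator plus ``covariates``; the returned factor
    is exp(coefficient on ``switched``), the multiplier switching applies to
    post-progression survival time, with a 95% Wald CI.
    """
    prog = control_records[(control_records["arm"] == "control")
                           & (control_records["pfs_event"] == 1)].copy()
    n_sw = int(prog["switched"].sum())
    if n_sw == 0 or n_sw == len(prog):
        raise EstimationError(
            "no common support: need both switchers and non-switchers among "
            f"progressed control patients (got {n_sw}/{len(prog)})"
        )
    df = pd.DataFrame({
        "T": np.maximum(prog["os_time"] - prog["pfs_time"], _MIN_TIME),
        "E": prog["os_event"].astype(int),
        "switched": prog["switched"].astype(float),
    })
    used = [c for c in covariates if c in prog.columns]
    for c in used:
        if prog[c].nunique() > 1:  # constant columns break the fit
            df[c] = prog[c].astype(float)
    aft = WeibullAFTFitter(penalizer=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aft.fit(df, duration_col="T", event_col="E")
    coef = float(aft.params_.loc[("lambda_", "switched")])
    se = float(aft.standard_errors_.loc[("lambda_", "switched")])
    return AccelFactor(
        factor=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        n_switchers=n_sw,
        n_progressed=len(prog),
    )


def counterfactual_times(control_records: pd.DataFrame, accel_factor: float,
                         recensor: bool = True,
                         censor_time: float | None = None) -> pd.DataFrame:
    """Shrink switchers' post-switch survival to counterfactual no-switch times.

    For switchers: adjusted OS = switch_time + (OS - switch_time)/factor.
    Non-switchers are unchanged.  With ``recensor=True`` all control times are
    recensored at min(censor_time, censor_time/factor) so the adjusted arm is
    not informatively censored; ``censor_time`` is then required.
    """
    if accel_factor <= 0:
        raise ValueError("accel_factor must be positive")
    out = control_records.copy()
    sw = out["switched"] == 1
    if ((out.loc[sw, "switch_time"] > out.loc[sw, "os_time"]).any()
            or (out.loc[sw, "switch_time"] < out.loc[sw, "pfs_time"] - 1e-9).any()):
        raise ValueError("switch_time must lie in [pfs_time, os_time]")
    out.loc[sw, "os_time"] = (
        out.loc[sw, "switch_time"]
        + (out.loc[sw, "os_time"] - out.loc[sw, "switch_time"]) / accel_factor
    )
    if recensor:
        if censor_time is None:
            raise ValueError("recensoring requires censor_time")
        c_star = min(censor_time, censor_time / accel_factor)
        over = out["os_time"] > c_star
        out.loc[over, "os_time"] = c_star
        out.loc[over, "os_event"] = 0
    return out


def cox_hr(active_records: pd.DataFrame, control_records: pd.DataFrame,
           weights=None, endpoint: str = "os") -> tuple[float, float]:
    """Cox partial-likelihood HR of active vs control (Efron ties).

    Optional per-record ``weights`` (active then control, for MAIC); returns
    (HR, SE of log-HR).  Scale-invariant in the weights.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    df = pd.concat([
        pd.DataFrame({"T": active_records[tcol], "E": active_records[ecol], "treat": 1.0}),
        pd.DataFrame({"T": control_records[tcol], "E": control_records[ecol], "treat": 0.0}),
    ], ignore_index=True)
    if df["E"].sum() == 0:
        raise EstimationError("no events in either arm")
    df["T"] = np.maximum(df["T"], _MIN_TIME)
    kwargs = {}
    if weights is not None:
        df["w"] = np.asarray(weights, dtype=float)
        kwargs = {"weights_col": "w", "robust": True}
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="T", event_col="E", **kwargs)
    beta = float(cph.params_.loc["treat"])
    se = float(cph.standard_errors_.loc["treat"])
    return float(np.exp(beta)), se


def two_stage_adjust(records: pd.DataFrame, censor_time: float,
                     recensor: bool = True,
                     covariates=DEFAULT_SECONDARY_COVARIATES) -> TwoStageResult:
    """Full two-stage pipeline on a trial IPD table.

    Estimates the acceleration factor in the control arm, rebuilds
    counterfactual control-arm survival, and returns the OS hazard ratio
    before and after adjustment.
    """
    active = records[records["arm"] == "active"]
    control = records[records["arm"] == "control"]
    hr0, se0 = cox_hr(active, control)
    accel = estimate_accel_factor(control, covariates)
    adj = counterfactual_times(control, accel.factor, recensor=recensor,
                               censor_time=censor_time)
    hr1, se1 = cox_hr(active, adj)
    return TwoStageResult(accel, hr0, se0, hr1, se1, recensored=recensor)
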