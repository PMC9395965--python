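"""Three-state partitioned survival model (PSM).

State occupancy comes directly from the survival curves on a 3-week cycle
grid: progression-free PF(t) = min(S_PFS(t), S_OS(t)), post-progression
PP(t) = S_OS(t) - PF(t), dead = 1 - S_OS(t); occupancies sum to one at every
cycle by construction.  State-time quantities (life-years, QALYs, monitoring
costs) are accrued by trapezoid integration over each cycle interval with
continuous-time discounting; event-type quantities (drug doses, new
progressions, deaths) are discounted at the time they occur.

Perspective is the health system (direct medical costs only, 2021 USD);
costs and outcomes are discounted at 5%/year by default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "CYCLE_WEEKS", "MONTHS_PER_CYCLE", "CYCLE_YEARS",
    "ValidationError", "PSMTrace", "Regimen", "CEResult", "Incremental",
    "build_trace", "discount_factor", "accrue_costs", "accrue_qalys",
    "run_arm", "incremental_summary",
    "SINTILIMAB_REGIMEN", "PEMBROLIZUMAB_REGIMEN",
]

CYCLE_WEEKS = 3
MONTHS_PER_CYCLE = CYCLE_WEEKS * 7 / 30.4375
CYCLE_YEARS = CYCLE_WEEKS * 7 / 365.25
WTP_LOW, WTP_HIGH = 11250.0, 33749.0  # 1x and 3x GDP per capita, USD/QALY


class ValidationError(ValueError):
    pass


def discount_factor(t_years, annual_rate: float = 0.05):
    """Continuous-convention discount factor (1 + r)^(-t)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    return np.power(1.0 + annual_rate, -np.asarray(t_years, dtype=float))


@dataclass
class PSMTrace:
    """Per-cycle state occupancy on the cycle grid (boundaries 0..n_cycles)."""

    t_months: np.ndarray
    s_pfs: np.ndarray   # after the ordering constraint s_pfs <= s_os
    s_os: np.ndarray
    cycle_weeks: int = CYCLE_WEEKS

    @property
    def t_years(self):
        return self.t_months * (30.4375 / 365.25)

    @property
    def occ_pf(self):
        return self.s_pfs

    @property
    def occ_pp(self):
        return self.s_os - self.s_pfs

    @property
    def occ_dead(self):
        return 1.0 - self.s_os

    @property
    def deaths(self):
        """Deaths during cycle c (index 1..n); index 0 is zero."""
        d = np.zeros_like(self.s_os)
        d[1:] = np.maximum(self.s_os[:-1] - self.s_os[1:], 0.0)
        return d

    @property
    def progressions(self):
        """New progressors during cycle c: decline of the PFS curve net of
        the deaths attributed to the PF state (proportional to PF's share of
        survivors at the cycle start, the usual PSM approximation)."""
        p = np.zeros_like(self.s_pfs)
        pf_share = np.divide(self.s_pfs[:-1], self.s_os[:-1],
                             out=np.zeros_like(self.s_pfs[:-1]),
                             where=self.s_os[:-1] > 0)
        deaths = np.maximum(self.s_os[:-1] - self.s_os[1:], 0.0)
        decline = np.maximum(self.s_pfs[:-1] - self.s_pfs[1:], 0.0)
        p[1:] = np.maximum(decline - deaths * pf_share, 0.0)
        return p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(len(self.t_months)),
            "t_months": self.t_months,
            "s_pfs": self.s_pfs,
            "s_os": self.s_os,
            "occ_pf": self.occ_pf,
            "occ_pp": self.occ_pp,
            "occ_dead": self.occ_dead,
            "deaths": self.deaths,
        })


def build_trace(pfs_curve, os_curve, horizon_years: float,
                cycle_weeks: int = CYCLE_WEEKS) -> PSMTrace:
    """Evaluate the two curves on the cycle grid and partition the cohort.

    ``pfs_curve`` and ``os_curve`` are callables S(t_months) -> [0, 1].
    The ordering constraint S_PFS <= S_OS is enforced by taking the minimum
    before partitioning.
    """
    if horizon_years <= 0:
        raise ValidationError("horizon must be positive")
    months_per_cycle = cycle_weeks * 7 / 30.4375
    n_cycles = math.ceil(horizon_years * 365.25 / (cycle_weeks * 7))
    t = np.arange(n_cycles + 1) * months_per_cycle
    s_pfs = np.asarray(pfs_curve(t), dtype=float)
    s_os = np.asarray(os_curve(t), dtype=float)
    for name, s in (("PFS", s_pfs), ("OS", s_os)):
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValidationError(f"{name} curve returned values outside [0, 1]")
    s_pfs = np.clip(s_pfs, 0.0, 1.0)
    s_os = np.clip(s_os, 0.0, 1.0)
    return PSMTrace(t, np.minimum(s_pfs, s_os), s_os, cycle_weeks)


def _state_time(occ, t_years, annual_rate, integration="trapezoid"):
    """Discounted years spent in a state (trapezoid over cycle intervals)."""
    df = discount_factor(t_years, annual_rate)
    g = occ * df
    dt = np.diff(t_years)
    if integration == "trapezoid":
        return float(np.sum(0.5 * (g[:-1] + g[1:]) * dt))
    if integration == "right":
        return float(np.sum(g[1:] * dt))
    raise ValueError(f"unknown integration rule {integration!r}")


@dataclass
class Regimen:
    """Treatment strategy: drugs, dosing, assistance program, service use.

    Drug costs accrue over PF occupancy at the start of each cycle.
    Combination chemotherapy is capped at ``chemo_max_cycles`` cycles; the
    immunotherapy continues while progression-free up to
    ``immuno_max_months``.  The patient assistance program (PAP) is a
    paid-dose schedule: the first ``pap_paid_doses`` doses are charged, later
    doses are free (fractional values prorate the marginal dose).  Service
    frequencies are per-cycle counts of Table-row unit items; the ``*_scale``
    factors are calibration knobs (dimensionless).
    """

    name: str
    ae_arm: str
    immuno_price_param: str
    immuno_vials_per_cycle: float = 2.0      # 200 mg / 100 mg vial
    immuno_max_months: float = 24.0
    pap_paid_doses: float = float("inf")
    chemo_components: tuple = ()             # ((price_param, vials_per_cycle), ...)
    chemo_max_cycles: int = 4
    admin_freq: dict = field(default_factory=dict)
    monitor_pf_freq: dict = field(default_factory=dict)
    manage_pp_freq: dict = field(default_factory=dict)
    admin_scale: float = 1.0
    monitor_scale: float = 1.0

    def pap_multiplier(self, dose_index: int) -> float:
        """Charged fraction of dose ``dose_index`` (1-based)."""
        k = self.pap_paid_doses
        if math.isinf(k):
            return 1.0
        if dose_index <= math.floor(k):
            return 1.0
        if dose_index == math.floor(k) + 1:
            return k - math.floor(k)
        return 0.0


def _per_cycle_price(freq: dict, params: ModelParams) -> float:
    return sum(params[item] * count for item, count in freq.items())


def accrue_costs(trace: PSMTrace, regimen: Regimen, params: ModelParams,
                 annual_rate: float = 0.05, dosing=None,
                 integration: str = "trapezoid") -> dict:
    """Discounted cost components for one arm.

    Returns a dict with keys drug, administration, management, ae,
    subsequent, eol, total.  Dosing assumptions (65 kg, 1.6 m^2) are embedded
    in the regimen's vials-per-cycle counts.
    """
    ty = trace.t_years
    df = discount_factor(ty, annual_rate)
    occ_pf_start = trace.occ_pf[:-1]          # occupancy when cycle's dose is given
    t_start_months = trace.t_months[:-1]
    df_start = df[:-1]
    n_doses = len(occ_pf_start)

    on_immuno = t_start_months < regimen.immuno_max_months
    pap = np.array([regimen.pap_multiplier(i + 1) for i in range(n_doses)])
    immuno_price = params[regimen.immuno_price_param] * regimen.immuno_vials_per_cycle
    drug = float(np.sum(occ_pf_start * df_start * on_immuno * pap * immuno_price))

    chemo_price = sum(params[p] * vials for p, vials in regimen.chemo_components)
    chemo_cycles = np.arange(n_doses) < regimen.chemo_max_cycles
    drug += float(np.sum(occ_pf_start * df_start * chemo_cycles * chemo_price))

    admin_price = _per_cycle_price(regimen.admin_freq, params) * regimen.admin_scale
    administration = float(np.sum(occ_pf_start * df_start * on_immuno * admin_price))

    monitor_price = _per_cycle_price(regimen.monitor_pf_freq, params) * regimen.monitor_scale
    manage_price = _per_cycle_price(regimen.manage_pp_freq, params) * regimen.monitor_scale
    # state-time costs: per-cycle price / cycle-years gives a rate per year
    management = (
        monitor_price / CYCLE_YEARS * _state_time(trace.occ_pf, ty, annual_rate, integration)
        + manage_price / CYCLE_YEARS * _state_time(trace.occ_pp, ty, annual_rate, integration)
    )

    ae = float(sum(inc * cost for inc, cost, _d, _u in params.ae_terms(regimen.ae_arm)))
    subsequent = float(np.sum(trace.progressions * df) * params["subsequent_treatment"])
    eol = float(np.sum(trace.deaths * df) * params["end_of_life"])

    out = {
        "drug": drug,
        "administration": administration,
        "management": management,
        "ae": ae,
        "subsequent": subsequent,
        "eol": eol,
    }
    out["total"] = sum(out.values())
    return out


def accrue_qalys(trace: PSMTrace, params: ModelParams, ae_arm: str,
                 annual_rate: float = 0.05, u_pf: float | None = None,
                 u_pp: float | None = None,
                 integration: str = "trapezoid") -> dict:
    """Discounted QALY components and life-years for one arm.

    AE QALY loss = sum over events of incidence x disutility x duration;
    it is subtracted from the PF component (AEs occur on treatment).
    """
    u_pf = params["u_pf"] if u_pf is None else u_pf
    u_pp = params["u_pp"] if u_pp is None else u_pp
    for u in (u_pf, u_pp):
        if not (0.0 <= u <= 1.0):
            raise ValidationError(f"utility {u} outside [0, 1]")
    ty = trace.t_years
    ly_pf = _state_time(trace.occ_pf, ty, annual_rate, integration)
    ly_pp = _state_time(trace.occ_pp, ty, annual_rate, integration)
    ly_undisc = _state_time(trace.occ_pf + trace.occ_pp, ty, 0.0, integration)
    ae_loss = float(sum(inc * disu * dur / 365.25
                        for inc, _c, dur, disu in params.ae_terms(ae_arm)))
    qaly_pf = u_pf * ly_pf - ae_loss
    qaly_pp = u_pp * ly_pp
    return {
        "qaly_pf": qaly_pf,
        "qaly_pp": qaly_pp,
        "qaly_total": qaly_pf + qaly_pp,
        "ly_pf": ly_pf,
        "ly_pp": ly_pp,
        "ly": ly_pf + ly_pp,
        "ly_undiscounted": ly_undisc,
        "ae_qaly_loss": ae_loss,
    }


@dataclass
class CEResult:
    arm: str
    qalys: dict
    costs: dict

    @property
    def qaly_total(self) -> float:
        return self.qalys["qaly_total"]

    @property
    def cost_total(self) -> float:
        return self.costs["total"]

    @property
    def ly(self) -> float:
        return self.qalys["ly"]


def run_arm(name: str, pfs_curve, os_curve, regimen: Regimen,
            params: ModelParams, horizon_years: float = 20.0,
            annual_rate: float = 0.05, u_pf=None, u_pp=None,
            integration: str = "trapezoid") -> CEResult:
    trace = build_trace(pfs_curve, os_curve, horizon_years)
    costs = accrue_costs(trace, regimen, params, annual_rate, integration=integration)
    qalys = accrue_qalys(trace, params, regimen.ae_arm, annual_rate,
                         u_pf=u_pf, u_pp=u_pp, integration=integration)
    return CEResult(name, qalys, costs)


@dataclass
class Incremental:
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None
    label: str
    nmb: float
    wtp: float


def incremental_summary(result_a: CEResult, result_b: CEResult,
                        wtp: float = WTP_HIGH) -> Incremental:
    """Increments of A vs B, ICER with dominance labels, and NMB at ``wtp``.

    In the southwest quadrant (A cheaper, less effective) the cheaper
    strategy is preferred when the ICER exceeds the willingness to pay.
    """
    dc = result_a.cost_total - result_b.cost_total
    dq = result_a.qaly_total - result_b.qaly_total
    dly = result_a.ly - result_b.ly
    nmb = wtp * dq - dc
    if dq == 0:
        icer, label = None, "undefined ICER (equal effectiveness)"
    elif dq > 0 and dc <= 0:
        icer, label = None, "dominant"
    elif dq < 0 and dc >= 0:
        icer, label = None, "dominated"
    else:
        icer = dc / dq
        quadrant = "northeast" if dq > 0 else "southwest"
        label = f"ICER ({quadrant} quadrant)"
    return Incremental(dc, dq, dly, icer, label, nmb, wtp)


# ---------------------------------------------------------------------------
# Default regimens.  Vials per cycle follow 65 kg / 1.6 m^2 dosing rounded up
# to whole vials: sintilimab & pembrolizumab 200 mg = 2 x 100 mg;
# gemcitabine 1250 mg/m^2 days 1+8 = 4 x 1 g; cisplatin 75 mg/m^2 = 4 x 30 mg;
# carboplatin AUC 6 = 6 x 100 mg; nab-paclitaxel 100 mg/m^2 days 1,8,15 =
# 5 x 100 mg.  Administration / monitoring frequencies are per-cycle counts
# (package defaults; the paper defers these to supplementary tables).
# ---------------------------------------------------------------------------

SINTILIMAB_REGIMEN = Regimen(
    name="sintilimab+chemo",
    ae_arm="sint",
    immuno_price_param="sintilimab",
    chemo_components=(("gemcitabine", 4.0), ("cisplatin_high", 4.0)),
    admin_freq={"diagnosis": 1.0, "iv_injection": 3.0, "nursing": 4.0, "hospitalization": 4.0},
    monitor_pf_freq={"imaging": 0.5, "blood_chemistry": 1.0, "blood_routine": 1.0, "urine_routine": 1.0},
    manage_pp_freq={"imaging": 0.25, "blood_chemistry": 0.5, "blood_routine": 0.5,
                    "urine_routine": 0.5, "diagnosis": 0.5},
)

PEMBROLIZUMAB_REGIMEN = Regimen(
    name="pembrolizumab+chemo",
    ae_arm="pembro",
    immuno_price_param="pembrolizumab",
    chemo_components=(("paclitaxel_high", 5.0), ("carboplatin_high", 6.0)),
    admin_freq={"diagnosis": 1.0, "iv_injection": 2.0, "nursing": 3.0, "hospitalization": 3.0},
    monitor_pf_freq={"imaging": 0.5, "blood_chemistry": 1.0, "blood_routine": 1.0, "urine_routine": 1.0},
    manage_pp_freq={"imaging": 0.25, "blood_chemistry": 0.5, "blood_routine": 0.5,
                    "urine_routine": 0.5, "diagnosis": 0.5},
)
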