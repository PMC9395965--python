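"""Scenario-analysis utilities: QLQ-C30 to EQ-5D-5L mapping.

The scenario replaces literature health-state utilities with utilities
mapped from cancer-specific quality-of-life questionnaire (EORTC QLQ-C30)
scores collected in the reference trial: a linear mapping produces an
EQ-5D-5L index per visit, per-patient means are taken within the
progression-free (PF) and post-progression (PP) states, patients whose PF
utility falls below their PP utility are excluded as logically inconsistent,
and the comparator arm's utilities are adjusted for its different burden of
grade >=3 adverse events (mapped utilities already embed the reference
arm's AEs).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import AE_EVENTS, ModelParams

__all__ = [
    "QLQ_DOMAINS", "MappingCoefficients", "SYNTHETIC_MAPPING",
    "map_to_utility", "state_utilities", "adjust_comparator_utilities",
    "generate_synthetic_qlq",
]

#: QLQ-C30 domains used by the mapping (0-100 scoring-manual scale).
QLQ_DOMAINS = ("physical", "role", "emotional", "social", "pain", "fatigue", "global_health")


@dataclass
class MappingCoefficients:
    """Linear QLQ-C30 -> EQ-5D-5L index mapping, clamped to a value-set range."""

    intercept: float
    slopes: dict = field(default_factory=dict)   # domain -> coefficient
    utility_range: tuple = (-0.391, 1.0)


#: A synthetic coefficient set for demonstration and testing only — NOT any
#: published mapping algorithm.  Functioning domains enter positively and
#: symptom domains negatively, per-point magnitudes chosen so typical scores
#: land in the usual utility range.
SYNTHETIC_MAPPING = MappingCoefficients(
    intercept=0.20,
    slopes={
        "physical": 0.0045,
        "role": 0.0015,
        "emotional": 0.0012,
        "social": 0.0010,
        "pain": -0.0020,
        "fatigue": -0.0015,
        "global_health": 0.0018,
    },
)


def map_to_utility(record, coeffs: MappingCoefficients) -> float:
    """Evaluate the linear predictor for one visit record and clamp it.

    ``record`` is a mapping (dict or DataFrame row) with the domain scores
    the coefficient set requires; a missing domain raises KeyError.
    """
    value = coeffs.intercept
    for domain, slope in coeffs.slopes.items():
        score = record[domain]
        if score is None or (isinstance(score, float) and np.isnan(score)):
            raise KeyError(f"missing required domain score {domain!r}")
        if not (0.0 <= score <= 100.0):
            raise ValueError(f"{domain} score {score} outside [0, 100]")
        value += slope * float(score)
    lo, hi = coeffs.utility_range
    return float(min(max(value, lo), hi))


def state_utilities(records: pd.DataFrame, coeffs: MappingCoefficients,
                    filter_inconsistent: bool = True) -> tuple[float, float, int]:
    """Cohort PF and PP utilities from longitudinal visit records.

    Per patient, visit utilities are averaged within each state; patients
    with mean(PF) < mean(PP) are excluded when ``filter_inconsistent`` (the
    logical-consistency filter).  Returns (u_pf, u_pp, n_included) where the
    cohort values are means over the included patients with the relevant
    state observed.
    """
    util = records.apply(lambda row: map_to_utility(row, coeffs), axis=1)
    df = pd.DataFrame({"patient_id": records["patient_id"],
                       "state": records["state"], "utility": util})
    per_patient = df.pivot_table(index="patient_id", columns="state",
                                 values="utility", aggfunc="mean")
    if "PF" not in per_patient.columns or "PP" not in per_patient.columns:
        raise RuntimeError("need patients observed in both PF and PP states")
    if filter_inconsistent:
        both = per_patient.dropna()
        keep = both[both["PF"] >= both["PP"]].index
        only_one = per_patient[per_patient.isna().any(axis=1)].index
        per_patient = per_patient.loc[per_patient.index.isin(keep.union(only_one))]
    if per_patient["PF"].dropna().empty or per_patient["PP"].dropna().empty:
        raise RuntimeError("no patients remain with both states observed")
    u_pf = float(per_patient["PF"].mean())
    u_pp = float(per_patient["PP"].mean())
    return u_pf, u_pp, int(len(per_patient))


def adjust_comparator_utilities(u_ref_pf: float, u_ref_pp: float,
                                params: ModelParams, exposure_years_pf: float,
                                ref_arm: str = "sint",
                                comp_arm: str = "pembro") -> tuple[float, float]:
    """Shift the comparator's PF utility for its different AE burden.

    Mapped utilities embed the reference arm's AE experience, so the
    comparator's PF utility is

        u_comp_pf = u_ref_pf
            + sum_AE (inc_ref - inc_comp) * disutility * (duration/365.25)
              / exposure_years_pf

    i.e. the differential per-patient AE QALY loss annualized over time in
    the PF state (AEs occur on treatment).  The PP utility is returned
    unchanged.  Results are clamped to [0, 1].
    """
    if exposure_years_pf <= 0:
        raise ValueError("exposure_years_pf must be positive")
    diff = 0.0
    for ev in AE_EVENTS:
        inc_ref = params[f"inc_{ref_arm}_{ev}"]
        inc_comp = params[f"inc_{comp_arm}_{ev}"]
        diff += (inc_ref - inc_comp) * params[f"disu_{ev}"] * params[f"dur_{ev}"] / 365.25
    u_comp_pf = u_ref_pf + diff / exposure_years_pf
    return float(min(max(u_comp_pf, 0.0), 1.0)), float(u_ref_pp)


def generate_synthetic_qlq(n_patients: int = 100, visits_per_state: int = 3,
                           seed: int = 0,
                           inconsistent_fraction: float = 0.2) -> pd.DataFrame:
    """Synthetic longitudinal QLQ-C30 records for the mapping scenario.

    Each patient contributes visits in PF and (for progressors) PP; PF
    visits carry better functioning / lower symptom scores.  A configurable
    fraction of patients is generated with the states swapped so the
    logical-consistency filter has something to remove.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"Q{i:04d}"
        swap = rng.uniform() < inconsistent_fraction
        for state, quality in (("PF", 1.0), ("PP", 0.0)):
            q = 1.0 - quality if swap else quality
            for v in range(visits_per_state):
                row = {"patient_id": pid, "visit": v, "state": state}
                for d in ("physical", "role", "emotional", "social", "global_health"):
                    base = 75 if q else 45
                    row[d] = float(np.clip(rng.normal(base, 10), 0, 100))
                for d in ("pain", "fatigue"):
                    base = 25 if q else 55
                    row[d] = float(np.clip(rng.normal(base, 10), 0, 100))
                rows.append(row)
    return pd.DataFrame(rows)
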