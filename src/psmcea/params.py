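"""Model parameter table: unit costs, utilities, AE inputs, and their
uncertainty distributions.

Every row carries a deterministic value, a distribution family for the
probabilistic sensitivity analysis (gamma / beta / normal / constant), and
low/high bounds that double as the one-way DSA range.  Distribution moments
are derived from the bounds by the 95%-CI width rule, SD = (high - low)/3.92,
with the mean at the deterministic value (method of moments for gamma and
beta).  All costs are 2021 USD (6.44 CNY/USD); drug acquisition prices are
held constant in the PSA and varied only in the DSA.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParamSpec", "PARAMETER_TABLE", "base_values", "fit_distribution",
           "AE_EVENTS", "ModelParams"]


@dataclass(frozen=True)
class ParamSpec:
    name: str
    value: float
    dist: str            # gamma | beta | normal | constant
    low: float
    high: float
    group: str = ""

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"{self.name}: low > high")
        if self.dist == "beta" and not (0.0 <= self.value <= 1.0):
            raise ValueError(f"{self.name}: beta mean must be in [0, 1]")


def _p(*args, group=""):
    return ParamSpec(*args, group=group)


PARAMETER_TABLE: list[ParamSpec] = [
    # unit drug costs ($ per vial)
    _p("sintilimab", 441.69, "constant", 353.36, 441.69, group="drug"),
    _p("pembrolizumab", 2783.78, "constant", 2227.02, 2783.78, group="drug"),
    _p("paclitaxel_high", 26.26, "gamma", 21.00, 31.40, group="drug"),
    _p("paclitaxel_low", 11.02, "gamma", 10.56, 11.47, group="drug"),
    _p("carboplatin_high", 8.04, "gamma", 4.72, 8.37, group="drug"),
    _p("carboplatin_low", 4.72, "gamma", 3.77, 5.66, group="drug"),
    _p("gemcitabine", 9.32, "gamma", 1.24, 9.94, group="drug"),
    _p("cisplatin_low", 1.86, "gamma", 1.13, 2.96, group="drug"),
    _p("cisplatin_high", 2.66, "gamma", 1.18, 6.80, group="drug"),
    _p("subsequent_treatment", 4351.23, "constant", 3480.98, 5221.47, group="drug"),
    _p("end_of_life", 2298.86, "gamma", 892.71, 6140.16, group="cost"),
    # unit follow-up costs ($)
    _p("imaging", 57.48, "gamma", 45.99, 68.98, group="followup"),
    _p("blood_chemistry", 46.50, "gamma", 37.20, 55.80, group="followup"),
    _p("blood_routine", 3.11, "gamma", 2.49, 3.73, group="followup"),
    _p("urine_routine", 0.62, "gamma", 0.50, 0.75, group="followup"),
    # unit medical service costs ($)
    _p("diagnosis", 3.11, "gamma", 1.55, 4.66, group="service"),
    _p("iv_injection", 1.71, "gamma", 1.55, 2.14, group="service"),
    _p("nursing", 3.73, "gamma", 2.98, 4.47, group="service"),
    _p("hospitalization", 6.53, "gamma", 5.22, 7.83, group="service"),
    # unit AE management costs ($ per episode)
    _p("ae_cost_neutropenia", 115.01, "gamma", 51.11, 357.80, group="ae_cost"),
    _p("ae_cost_leukopenia", 115.01, "gamma", 51.11, 357.80, group="ae_cost"),
    _p("ae_cost_thrombocytopenia", 1505.92, "gamma", 1240.17, 1771.67, group="ae_cost"),
    _p("ae_cost_anemia", 138.75, "gamma", 106.73, 160.10, group="ae_cost"),
    # grade >=3 AE incidences, intervention arm
    _p("inc_sint_neutropenia", 0.151, "beta", 0.12, 0.18, group="ae_inc"),
    _p("inc_sint_leukopenia", 0.117, "beta", 0.09, 0.14, group="ae_inc"),
    _p("inc_sint_anemia", 0.128, "beta", 0.10, 0.15, group="ae_inc"),
    _p("inc_sint_thrombocytopenia", 0.134, "beta", 0.11, 0.16, group="ae_inc"),
    # grade >=3 AE incidences, comparator arm (no grade>=3 leukopenia reported)
    _p("inc_pembro_neutropenia", 0.23, "beta", 0.18, 0.28, group="ae_inc"),
    _p("inc_pembro_thrombocytopenia", 0.083, "beta", 0.07, 0.10, group="ae_inc"),
    _p("inc_pembro_anemia", 0.158, "beta", 0.13, 0.19, group="ae_inc"),
    _p("inc_pembro_leukopenia", 0.0, "constant", 0.0, 0.0, group="ae_inc"),
    # AE durations (days)
    _p("dur_neutropenia", 4.19, "normal", 3.35, 5.03, group="ae_dur"),
    _p("dur_anemia", 6.83, "normal", 5.46, 8.20, group="ae_dur"),
    _p("dur_leukopenia", 4.5, "normal", 3.60, 5.40, group="ae_dur"),
    _p("dur_thrombocytopenia", 47.29, "normal", 37.83, 56.75, group="ae_dur"),
    # health-state utilities
    _p("u_pf", 0.804, "beta", 0.643, 0.965, group="utility"),
    _p("u_pp", 0.321, "beta", 0.257, 0.385, group="utility"),
    # AE disutilities
    _p("disu_neutropenia", 0.20, "beta", 0.16, 0.24, group="disutility"),
    _p("disu_leukopenia", 0.20, "beta", 0.16, 0.24, group="disutility"),
    _p("disu_thrombocytopenia", 0.11, "beta", 0.09, 0.13, group="disutility"),
    _p("disu_anemia", 0.07, "beta", 0.06, 0.09, group="disutility"),
]

#: AE bookkeeping: event -> (cost, duration, disutility) parameter stems.
AE_EVENTS = ("neutropenia", "leukopenia", "thrombocytopenia", "anemia")


def base_values() -> dict:
    return {spec.name: spec.value for spec in PARAMETER_TABLE}


def fit_distribution(spec: ParamSpec):
    """Build a sampler ``f(rng, size=None)`` for a parameter row.

    Gamma and beta are parameterized by method of moments with mean equal to
    the deterministic value and SD = (high - low)/3.92; normal likewise;
    constant is degenerate.  Infeasible moments raise ValueError.
    """
    m = spec.value
    sd = (spec.high - spec.low) / 3.92
    if spec.dist == "constant" or sd == 0:
        return lambda rng, size=None: (np.full(size, m) if size else m)
    if spec.dist == "gamma":
        if m <= 0:
            raise ValueError(f"{spec.name}: gamma mean must be positive")
        shape = (m / sd) ** 2
        scale = sd ** 2 / m
        return lambda rng, size=None: rng.gamma(shape, scale, size)
    if spec.dist == "beta":
        if not (0.0 < m < 1.0):
            raise ValueError(f"{spec.name}: beta mean must be inside (0, 1)")
        nu = m * (1 - m) / sd ** 2 - 1.0
        if nu <= 0:
            raise ValueError(f"{spec.name}: beta variance infeasible for mean {m}")
        return lambda rng, size=None: rng.beta(m * nu, (1 - m) * nu, size)
    if spec.dist == "normal":
        return lambda rng, size=None: rng.normal(m, sd, size)
    raise ValueError(f"{spec.name}: unknown distribution {spec.dist!r}")


class ModelParams(dict):
    """Named parameter values; starts from the deterministic table."""

    @classmethod
    def base(cls) -> "ModelParams":
        return cls(base_values())

    def updated(self, **changes) -> "ModelParams":
        out = ModelParams(self)
        out.update(changes)
        return out

    def ae_terms(self, arm: str):
        """Per-event (incidence, cost, duration_days, disutility) for an arm."""
        return [
            (self[f"inc_{arm}_{ev}"], self[f"ae_cost_{ev}"],
             self[f"dur_{ev}"], self[f"disu_{ev}"])
            for ev in AE_EVENTS
        ]
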