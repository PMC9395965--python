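"""Synthetic two-arm trial IPD with the structure the downstream analysis needs.

The generator emulates a first-line randomized oncology trial: baseline
covariates drawn from marginal prevalences (the six matching factors: sex,
age, brain metastasis, stage IV, smoking history, ECOG performance status 1),
latent progression-free survival (PFS) per arm, overall survival built as
OS = PFS + an independent post-progression survival draw (so PFS <= OS holds
structurally), optional crossover of progressed control-arm patients to the
active therapy (an accelerated-failure-time effect multiplying their
post-progression time), and administrative censoring.  Times are in months.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .survfit import FAMILIES

__all__ = [
    "ConfigurationError",
    "TrialScenario",
    "ORIENT_BASELINE",
    "default_scenario",
    "simulate_trial",
    "apply_crossover",
    "censor_records",
    "write_ipd",
    "read_ipd",
    "load_scenario",
]

IPD_COLUMNS = [
    "patient_id", "arm", "age", "male", "brain_met", "stage_iv", "smoker",
    "ecog1", "pfs_time", "pfs_event", "os_time", "os_event", "switched",
    "switch_time",
]

#: Reference-trial "before adjustment" baseline profile (six matching factors).
ORIENT_BASELINE = {
    "male": 0.9160,
    "age": (61.48, 8.0),  # mean, sd; sd is a package choice (not published)
    "brain_met": 0.0392,
    "stage_iv": 0.6583,
    "smoker": 0.8459,
    "ecog1": 0.8543,
}


class ConfigurationError(ValueError):
    """Invalid scenario or model configuration."""


@dataclass
class TrialScenario:
    """Generating law of a synthetic two-arm trial.

    ``pfs`` and ``pps`` map arm -> (family, params): the latent PFS law and
    the latent post-progression survival law (OS = PFS + PPS).  ``covariates``
    maps a covariate name to a prevalence (binary) or (mean, sd) pair (age).
    """

    n_per_arm: int = 179
    covariates: dict = field(default_factory=lambda: dict(ORIENT_BASELINE))
    pfs: dict = field(default_factory=lambda: {
        "active": ("exponential", (np.log(2) / 5.5,)),
        "control": ("exponential", (np.log(2) / 4.9,)),
    })
    pps: dict = field(default_factory=lambda: {
        "active": ("exponential", (np.log(2) / 13.0,)),
        "control": ("exponential", (np.log(2) / 8.0,)),
    })
    crossover_prob: float = 0.45
    crossover_accel: float = 1.3
    censor_time: float = 24.0
    seed: int = 0

    def validate(self):
        if self.n_per_arm <= 0:
            raise ConfigurationError("n_per_arm must be positive")
        if not (0.0 <= self.crossover_prob <= 1.0):
            raise ConfigurationError("crossover_prob must be in [0, 1]")
        if self.crossover_accel <= 0:
            raise ConfigurationError("crossover_accel must be positive")
        if self.censor_time < 0:
            raise ConfigurationError("censor_time must be non-negative")
        for d in (self.pfs, self.pps):
            for arm, (family, _params) in d.items():
                if family not in FAMILIES:
                    raise ConfigurationError(f"unknown survival family {family!r} for arm {arm!r}")
        for name, spec in self.covariates.items():
            if np.isscalar(spec) and not (0.0 <= spec <= 1.0):
                raise ConfigurationError(f"prevalence of {name!r} must be in [0, 1]")


def default_scenario(**overrides) -> TrialScenario:
    """The study conditions the analysis assumes (see docs/methods.md)."""
    return replace(TrialScenario(), **overrides)


def sample_survival_times(family, params, n, rng):
    """Draw n times from a family under the package's pinned parameterization."""
    if family == "exponential":
        (rate,) = params
        return rng.exponential(1.0 / rate, n)
    if family == "weibull":
        shape, scale = params
        return scale * rng.weibull(shape, n)
    if family == "lognormal":
        mu, sigma = params
        return rng.lognormal(mu, sigma, n)
    if family == "loglogistic":
        shape, scale = params
        u = rng.uniform(size=n)
        return scale * np.power(1.0 / u - 1.0, 1.0 / shape)
    if family == "gompertz":
        shape, rate = params
        u = rng.uniform(size=n)
        if abs(shape) < 1e-12:
            return -np.log(u) / rate
        arg = 1.0 - shape * np.log(u) / rate
        if np.any(arg <= 0):  # negative shape => cure fraction; not simulable
            raise ConfigurationError("gompertz with negative shape has improper survival")
        return np.log(arg) / shape
    if family == "generalized_gamma":
        a, c, scale = params
        return stats.gengamma.rvs(a, c, scale=scale, size=n, random_state=rng)
    raise ConfigurationError(f"unknown survival family {family!r}")


def _draw_covariates(covariates, n, rng):
    out = {}
    for name, spec in covariates.items():
        if np.isscalar(spec):
            out[name] = (rng.uniform(size=n) < float(spec)).astype(int)
        else:
            mean, sd = spec
            out[name] = np.maximum(rng.normal(mean, sd, n), 18.0)
    return out


def simulate_trial(scenario: TrialScenario) -> pd.DataFrame:
    """Simulate a two-arm trial; one IPD record per patient.

    Latent OS is PFS plus an independent post-progression draw, crossover is
    applied to latent times, and administrative censoring at
    ``scenario.censor_time`` is applied last.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    frames = []
    for arm in ("active", "control"):
        n = scenario.n_per_arm
        cov = _draw_covariates(scenario.covariates, n, rng)
        pfs = sample_survival_times(*scenario.pfs[arm], n, rng)
        pps = sample_survival_times(*scenario.pps[arm], n, rng)
        df = pd.DataFrame({
            "patient_id": [f"{arm[:1].upper()}{i:05d}" for i in range(n)],
            "arm": arm,
            **cov,
            "pfs_time": pfs,
            "pfs_event": 1,
            "os_time": pfs + pps,
            "os_event": 1,
            "switched": 0,
            "switch_time": np.nan,
        })
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    records = apply_crossover(
        records, scenario.crossover_prob, scenario.crossover_accel,
        seed=rng.integers(2**31),
    )
    return censor_records(records, scenario.censor_time)


def apply_crossover(records: pd.DataFrame, crossover_prob: float,
                    crossover_accel: float, seed) -> pd.DataFrame:
    """Switch progressed control patients to the active therapy.

    Each control-arm record with an observed progression switches with
    probability ``crossover_prob``; a switcher's post-progression survival
    time is multiplied by ``crossover_accel`` (a latent accelerated-failure-
    time effect, applied before any recensoring).  The active arm is
    untouched.  With ``crossover_prob == 0`` the output equals the input.
    """
    if crossover_accel <= 0:
        raise ConfigurationError("crossover_accel must be positive")
    if not (0.0 <= crossover_prob <= 1.0):
        raise ConfigurationError("crossover_prob must be in [0, 1]")
    out = records.copy()
    if crossover_prob == 0:
        return out
    rng = np.random.default_rng(seed)
    eligible = (out["arm"] == "control") & (out["pfs_event"] == 1)
    switch = eligible & (rng.uniform(size=len(out)) < crossover_prob)
    pps = out.loc[switch, "os_time"] - out.loc[switch, "pfs_time"]
    out.loc[switch, "os_time"] = out.loc[switch, "pfs_time"] + pps * crossover_accel
    out.loc[switch, "switched"] = 1
    out.loc[switch, "switch_time"] = out.loc[switch, "pfs_time"]
    return out


def censor_records(records: pd.DataFrame, censor_time: float) -> pd.DataFrame:
    """Administrative censoring at ``censor_time`` months."""
    out = records.copy()
    for t, e in (("pfs_time", "pfs_event"), ("os_time", "os_event")):
        observed = out[t] <= censor_time
        out[e] = (out[e].astype(bool) & observed).astype(int)
        out[t] = np.minimum(out[t], censor_time)
    # a switch can only be recorded if progression was observed
    lost = (out["switched"] == 1) & (out["switch_time"] > censor_time)
    out.loc[lost, "switched"] = 0
    out.loc[lost, "switch_time"] = np.nan
    return out


def write_ipd(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=IPD_COLUMNS, na_rep="")


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(IPD_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"IPD file missing columns: {sorted(missing)}")
    return df


def load_scenario(path) -> TrialScenario:
    """Read a TrialScenario from a YAML config (key per field)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("pfs", "pps"):
        if key in raw:
            raw[key] = {arm: (fam, tuple(params)) for arm, (fam, params) in raw[key].items()}
    if "covariates" in raw:
        raw["covariates"] = {
            k: (tuple(v) if isinstance(v, (list, tuple)) else float(v))
            for k, v in raw["covariates"].items()
        }
    return TrialScenario(**raw)
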