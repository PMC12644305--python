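"""Configuration objects for the simulation and the analysis pipeline.

Two dataclasses control everything: :class:`SimConfig` fixes the synthetic
cohort-generating mechanism (sample size, confounding structure, event
rarity) and :class:`AnalysisConfig` fixes the analysis choices (assessment
window, quantile convention, instrument cut-offs, number of empirical
covariates).  Both round-trip through YAML so a single config file can
drive the command-line interface.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import yaml

logger = logging.getLogger("hdps")

#: The three care facets ("dimensions") that generate proxy codes.
DIMENSIONS = ("observation", "prescription", "hospitalisation")

#: Harmonized code classes never allowed into the empirical covariate pool:
#: the drug classes that define the two treatment arms (bronchodilator
#: agonists, antimuscarinics, inhaled corticosteroids as BNF-paragraph-like
#: classes) and the outcome diagnosis class (COVID-19, ICD-10 U07).
DEFAULT_EXCLUDED_CODES = frozenset({"030101", "030102", "030200", "U07"})


@dataclass(frozen=True)
class LatentEffects:
    """Log-scale effects of the two unmeasured severity constructs.

    ``*_exposure`` are log-odds contributions to treatment assignment,
    ``*_outcome`` are log-hazard contributions to the event rate.  Both
    latents are standard normal, so an effect of 1.0 means one SD of the
    latent shifts the exposure odds (or event hazard) by e^1 ≈ 2.7-fold.
    """

    severity_exposure: float = 0.5
    severity_outcome: float = 0.5
    frailty_exposure: float = 0.3
    frailty_outcome: float = 0.5

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"latent effect '{f.name}' must be finite, got {v!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic active-comparator EHR study.

    Defaults emulate a COPD-like cohort observed over a 184-day pandemic
    window: two treatment arms confounded both by measured binary
    covariates and by latent severity/frailty that surface only as proxy
    codes in three data dimensions; a rare outcome (~1% cumulative risk)
    with little random censoring.
    """

    n_patients: int = 20_000
    p_exposed_target: float = 0.4

    # per-dimension code counts
    n_true_confounder_codes: int = 8
    n_instrument_codes: int = 2
    n_noise_codes: int = 20

    latent_effects: LatentEffects = field(default_factory=LatentEffects)
    #: conditional (true) exposure effect on the log-hazard scale; 0 = null
    true_log_hr: float = 0.0
    #: events per person-day at the covariate baseline; the default gives
    #: roughly 1% cumulative risk over the window at the cohort's covariate mix
    baseline_hazard: float = 8e-6
    followup_days: int = 184
    #: probability of random (non-administrative) censoring over follow-up
    censor_rate: float = 0.02

    # code-emission structure
    confounder_slope: float = 4.0
    instrument_rr_ce: float = 3.2
    instrument_prev_unexposed: float = 0.30
    #: fraction of raw code variants deliberately absent from mapping tables
    fraction_unmapped: float = 0.05

    seed: int = 42

    def validate(self) -> None:
        for name in ("p_exposed_target", "censor_rate", "fraction_unmapped",
                     "instrument_prev_unexposed"):
            v = getattr(self, name)
            if not (0 <= v < 1) or (name == "p_exposed_target" and v == 0):
                raise ValueError(f"'{name}' must lie in [0, 1), got {v!r}")
        for name in ("n_patients", "n_true_confounder_codes",
                     "n_instrument_codes", "n_noise_codes"):
            v = getattr(self, name)
            if v < 0 or (name == "n_patients" and v == 0):
                raise ValueError(f"'{name}' must be a non-negative count, got {v!r}")
        if self.followup_days <= 0:
            raise ValueError(f"'followup_days' must be positive, got {self.followup_days!r}")
        for name in ("true_log_hr", "baseline_hazard", "confounder_slope",
                     "instrument_rr_ce"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"'{name}' must be finite, got {v!r}")
        if self.baseline_hazard <= 0:
            raise ValueError(f"'baseline_hazard' must be positive, got {self.baseline_hazard!r}")
        self.latent_effects.validate()


@dataclass(frozen=True)
class AnalysisConfig:
    """Choices of the estimation pipeline, all with their defaults.

    ``quantile_rule`` selects how the sporadic/frequent recurrence
    thresholds are computed from the positive per-patient counts:
    ``"linear"`` (interpolating sample quantile, the R/numpy default) or
    ``"nearest_rank"`` (k-th smallest with k = ceil(q*m)).
    ``rr_cd_stratum`` selects where the covariate–outcome relative risk is
    estimated: the unexposed stratum (classic) or the full cohort.
    """

    window_days: int = 365
    quantile_rule: str = "linear"
    rr_cd_stratum: str = "unexposed"
    zero_cell_correction: float = 0.1
    rr_ce_cut: float = 1.1
    rr_cd_cut: float = 0.5
    k_values: Sequence[int] = (100, 250, 500, 750, 1000)
    one_by_one_max_rank: int = 250
    cohort_def: str = "include_triple"
    excluded_codes: frozenset = DEFAULT_EXCLUDED_CODES
    rd_se_method: str = "influence"

    def validate(self) -> None:
        if self.window_days <= 0:
            raise ValueError(f"'window_days' must be positive, got {self.window_days!r}")
        if self.quantile_rule not in ("linear", "nearest_rank"):
            raise ValueError(f"unknown quantile_rule {self.quantile_rule!r}")
        if self.rr_cd_stratum not in ("unexposed", "full"):
            raise ValueError(f"unknown rr_cd_stratum {self.rr_cd_stratum!r}")
        if self.cohort_def not in ("include_triple", "exclude_triple"):
            raise ValueError(f"unknown cohort_def {self.cohort_def!r}")
        if self.rd_se_method not in ("influence", "bootstrap"):
            raise ValueError(f"unknown rd_se_method {self.rd_se_method!r}")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        d = {}
        for f in dataclasses.fields(obj):
            d[f.name] = _to_plain(getattr(obj, f.name))
        return d
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(sim: SimConfig, analysis: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"simulation": _to_plain(sim), "analysis": _to_plain(analysis)}, fh)


def load_config(path) -> tuple[SimConfig, AnalysisConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim_raw = dict(raw.get("simulation", {}))
    if "latent_effects" in sim_raw:
        sim_raw["latent_effects"] = LatentEffects(**sim_raw["latent_effects"])
    ana_raw = dict(raw.get("analysis", {}))
    if "excluded_codes" in ana_raw:
        ana_raw["excluded_codes"] = frozenset(ana_raw["excluded_codes"])
    if "k_values" in ana_raw:
        ana_raw["k_values"] = tuple(ana_raw["k_values"])
    sim = SimConfig(**sim_raw)
    ana = AnalysisConfig(**ana_raw)
    sim.validate()
    ana.validate()
    return sim, ana
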