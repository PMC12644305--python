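"""Weighted exposure-effect estimators on the trimmed cohort.

Hazard ratios come from an IPT-weighted Cox model with a single exposure
term, Efron handling of tied (day-resolution) event times, and a robust
sandwich variance — the weights are estimated, so the model-based variance
would be dishonest.  Odds ratios come from a weighted logistic model with
the same sandwich variance, risk differences from weighted (Hajek) risk
means with an influence-function standard error (stratified bootstrap
optional), survival curves from a weighted Kaplan–Meier estimator, and the
proportional-hazards assumption is checked with scaled Schoenfeld
residuals — as a diagnostic only, never altering the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

Z95 = 1.959963984540054


@dataclass
class EffectEstimate:
    """One estimand for one (cohort, covariate-set) combination.

    ``point`` is on the natural scale (ratio for HR/OR, additive for RD);
    ``se`` is on the estimation scale (log for ratios) and the Wald 95% CI
    is point ± 1.96·se there.
    """

    estimand: str  # HR | OR | RD
    point: float
    se: float
    ci_lower: float
    ci_upper: float
    n: int
    n_events: int
    k: int | None = None
    cohort: str = ""
    outcome: str = ""
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {"estimand": self.estimand, "point": self.point, "se": self.se,
                "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
                "n": self.n, "n_events": self.n_events, "k": self.k,
                "cohort": self.cohort, "outcome": self.outcome}


def _check_arms_have_events(event: np.ndarray, exposure: np.ndarray, what: str):
    for arm in (0, 1):
        if event[exposure == arm].sum() == 0:
            raise ValueError(f"inestimable {what}: zero events in arm {arm}")


def weighted_cox_hr(time, event, exposure, weights=None, return_fit: bool = False):
    """IPT-weighted Cox HR for a binary exposure (robust variance, Efron ties)."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=np.int8)
    e = np.asarray(exposure, dtype=np.int8)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    _check_arms_have_events(d, e, "HR")
    df = pd.DataFrame({"time": t, "event": d, "exposure": e.astype(float), "w": w})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event", weights_col="w",
                robust=True, fit_options={"precision": 1e-12, "max_steps": 500})
    log_hr = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    est = EffectEstimate(
        estimand="HR", point=float(np.exp(log_hr)), se=se,
        ci_lower=float(np.exp(log_hr - Z95 * se)),
        ci_upper=float(np.exp(log_hr + Z95 * se)),
        n=len(t), n_events=int(d.sum()),
        extra={"log_point": log_hr})
    if return_fit:
        return est, cph, df
    return est


def weighted_logistic_or(event, exposure, weights=None) -> EffectEstimate:
    """IPT-weighted logistic OR with a robust (HC0) sandwich variance."""
    d = np.asarray(event, dtype=float)
    e = np.asarray(exposure, dtype=float)
    w = np.ones(len(d)) if weights is None else np.asarray(weights, dtype=float)
    _check_arms_have_events(d.astype(np.int8), e.astype(np.int8), "OR")
    X = sm.add_constant(e)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(d, X, family=sm.families.Binomial(), freq_weights=w
                         ).fit(cov_type="HC0")
    except Exception as err:
        raise ValueError(f"logistic model failed (separation?): {err}") from err
    log_or = float(fit.params[1])
    se = float(fit.bse[1])
    return EffectEstimate(
        estimand="OR", point=float(np.exp(log_or)), se=se,
        ci_lower=float(np.exp(log_or - Z95 * se)),
        ci_upper=float(np.exp(log_or + Z95 * se)),
        n=len(d), n_events=int(d.sum()),
        extra={"log_point": log_or})


def weighted_risk_difference(event, exposure, weights=None,
                             se_method: str = "influence",
                             n_boot: int = 200, seed: int = 0) -> EffectEstimate:
    """Weighted risk difference r1 - r0 with Hajek group means.

    ``se_method='influence'`` uses the first-order influence function of
    the ratio-of-sums estimator; ``'bootstrap'`` resamples patients within
    each arm.
    """
    d = np.asarray(event, dtype=float)
    e = np.asarray(exposure, dtype=np.int8)
    w = np.ones(len(d)) if weights is None else np.asarray(weights, dtype=float)
    n = len(d)
    for arm in (0, 1):
        if (e == arm).sum() == 0:
            raise ValueError(f"empty arm {arm}")

    def hajek(mask):
        return float((w[mask] * d[mask]).sum() / w[mask].sum())

    r1, r0 = hajek(e == 1), hajek(e == 0)
    rd = r1 - r0
    if se_method == "influence":
        phi = np.zeros(n)
        m1 = w[e == 1].sum() / n
        m0 = w[e == 0].sum() / n
        phi[e == 1] = w[e == 1] * (d[e == 1] - r1) / m1
        phi[e == 0] = -w[e == 0] * (d[e == 0] - r0) / m0
        se = float(np.sqrt((phi ** 2).sum()) / n)
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx1 = np.flatnonzero(e == 1)
        idx0 = np.flatnonzero(e == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            s1 = rng.choice(idx1, size=idx1.size, replace=True)
            s0 = rng.choice(idx0, size=idx0.size, replace=True)
            reps[b] = ((w[s1] * d[s1]).sum() / w[s1].sum()
                       - (w[s0] * d[s0]).sum() / w[s0].sum())
        se = float(reps.std(ddof=1))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return EffectEstimate(
        estimand="RD", point=float(rd), se=se,
        ci_lower=float(rd - Z95 * se), ci_upper=float(rd + Z95 * se),
        n=n, n_events=int(d.sum()),
        extra={"risk_exposed": r1, "risk_unexposed": r0})


def weighted_survival_curves(time, event, exposure, weights=None
                             ) -> dict[str, pd.DataFrame]:
    """Weighted Kaplan–Meier curves per arm, as tidy (time, survival) tables."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=np.int8)
    e = np.asarray(exposure, dtype=np.int8)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for label, arm in (("unexposed", 0), ("exposed", 1)):
        mask = e == arm
        kmf = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(t[mask], d[mask], weights=w[mask])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[label] = sf
    return out


def schoenfeld_ph_check(cox_fit: CoxPHFitter, df: pd.DataFrame) -> dict:
    """Scaled-Schoenfeld test of proportional hazards for the exposure term.

    Returns the test statistic, p-value, and the OLS slope of the scaled
    residuals against event time.  Purely diagnostic; with fewer than two
    events the check is not computable and an ``insufficient_events`` flag
    is returned instead.
    """
    n_events = int(df["event"].sum())
    if n_events < 2:
        return {"insufficient_events": True, "n_events": n_events}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = proportional_hazard_test(cox_fit, df, time_transform="identity")
        stat = float(np.asarray(res.summary["test_statistic"])[0])
        p = float(np.asarray(res.summary["p"])[0])
        scaled = cox_fit.compute_residuals(df, "scaled_schoenfeld")
    times = scaled.index.to_numpy(dtype=float)
    y = scaled.iloc[:, 0].to_numpy(dtype=float)
    slope = float(np.polyfit(times, y, 1)[0]) if len(times) > 1 else float("nan")
    return {"insufficient_events": False, "n_events": n_events,
            "statistic": stat, "p_value": p, "slope": slope}
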