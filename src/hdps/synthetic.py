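"""Synthetic EHR generator for an active-comparator cohort study.

Everything downstream of this module treats its output as it would treat a
real extract: a one-row-per-patient cohort table, long code-event tables in
three dimensions (primary-care observations, prescriptions,
hospitalisations), and source→harmonized code-mapping tables.  The
generator's job is to embed a *known* confounding structure so the
adjustment machinery can be validated:

* Two latent standard-normal constructs — disease severity and frailty —
  raise both the odds of receiving the exposure drug class and the hazard
  of the outcome.  They are withheld from every estimation table, so a
  propensity score built on the measured covariates alone is confounded.
* Each latent emits *proxy codes*: per dimension, a bank of confounder
  codes whose occurrence probability is logistic in the latent, with
  intercepts spread over a wide range so the resulting binary indicators
  threshold the latent at many different points (a staircase that a
  logistic propensity model can use to recover the latent).
* Instrument-like codes occur with a fixed prevalence ratio between the
  two arms (by construction exposure-associated only), and noise codes
  occur independently of everything.
* Measured ("prespecified") covariates are independent binaries and
  categoricals with prevalences loosely matching a UK COPD cohort; some
  shift treatment choice, some shift the outcome hazard, so they confound
  measurably and conventional weighting has work to do.

Survival is exponential with a log-linear hazard, administratively censored
at the end of the window plus light random censoring; times are rounded up
to whole days, so ties occur as they do in day-resolution data.

Output schemas (all plain CSV, written/read by the helpers at the bottom):

* cohort: ``patient_id, exposure, age_group, gender_female, bmi_group,
  smoking_former, ethnicity, imd_quintile, cancer, diabetes, ckd, cvd,
  hypertension, past_asthma, immunosuppression, flu_vaccine,
  pneumo_vaccine, exacerbation_group, triple_therapy, latent_severity,
  latent_frailty, time_to_event, event``
* code events: ``patient_id, dimension, raw_code, event_date`` with
  ``event_date`` in whole days *before* the index date (≥ 1)
* mapping tables: ``source_code, target_code``
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import DIMENSIONS, SimConfig, logger

# ---------------------------------------------------------------------------
# prespecified covariates
# ---------------------------------------------------------------------------

#: binary prespecified covariates and their marginal prevalences
BINARY_COVARIATES = {
    "gender_female": 0.46,
    "smoking_former": 0.57,
    "cancer": 0.19,
    "diabetes": 0.25,
    "ckd": 0.30,
    "cvd": 0.29,
    "hypertension": 0.51,
    "past_asthma": 0.17,
    "immunosuppression": 0.012,
    "flu_vaccine": 0.79,
    "pneumo_vaccine": 0.12,
}

CATEGORICAL_COVARIATES = {
    "age_group": (["35-54", "55-64", "65-74", "75plus"], [0.18, 0.25, 0.30, 0.27]),
    "bmi_group": (["underweight", "normal", "overweight", "obese"],
                  [0.05, 0.32, 0.315, 0.315]),
    "ethnicity": (["White", "SouthAsian", "Black", "Mixed", "Other"],
                  [0.895, 0.022, 0.011, 0.006, 0.066]),
    "imd_quintile": (["1", "2", "3", "4", "5"], [0.135, 0.17, 0.18, 0.225, 0.29]),
    "exacerbation_group": (["0", "1", "2plus"], [0.62, 0.23, 0.15]),
}

#: missing-data rates for the three fields the analysis has rules for
MISSING_RATES = {"bmi_group": 0.007, "ethnicity": 0.099, "imd_quintile": 0.0005}

PRESPECIFIED_COLUMNS = list(BINARY_COVARIATES) + list(CATEGORICAL_COVARIATES)

#: columns the estimation modules are never allowed to see
LATENT_COLUMNS = ("latent_severity", "latent_frailty")

# log-odds contributions of measured covariates to exposure
_EXPOSURE_EFFECTS = {
    "past_asthma": 1.1,
    "gender_female": 0.08,
    "smoking_former": 0.2,
    "pneumo_vaccine": -0.4,
    ("exacerbation_group", "1"): 0.3,
    ("exacerbation_group", "2plus"): 0.5,
}

# log-hazard contributions of measured covariates to the outcome
_OUTCOME_EFFECTS = {
    "gender_female": -0.3,
    "cvd": 0.4,
    "diabetes": 0.2,
    "ckd": 0.3,
    "immunosuppression": 0.5,
    ("age_group", "55-64"): 0.5,
    ("age_group", "65-74"): 1.0,
    ("age_group", "75plus"): 1.6,
    ("exacerbation_group", "2plus"): 0.3,
}


def _covariate_lp(cohort: pd.DataFrame, effects: dict) -> np.ndarray:
    lp = np.zeros(len(cohort))
    for key, beta in effects.items():
        if isinstance(key, tuple):
            col, level = key
            lp += beta * (cohort[col].to_numpy() == level)
        else:
            lp += beta * cohort[key].to_numpy(dtype=float)
    return lp


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate the patient table: covariates, exposure, survival outcome.

    The exposure intercept is calibrated (root-finding on the realised
    linear predictor) so the marginal exposed fraction hits
    ``p_exposed_target`` in expectation.  The true conditional exposure
    effect on the outcome hazard is ``config.true_log_hr``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    cohort = pd.DataFrame({"patient_id": np.arange(n, dtype=np.int64)})
    for col, p in BINARY_COVARIATES.items():
        cohort[col] = (rng.random(n) < p).astype(np.int8)
    for col, (levels, probs) in CATEGORICAL_COVARIATES.items():
        cohort[col] = rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)
    for col, rate in MISSING_RATES.items():
        miss = rng.random(n) < rate
        cohort.loc[miss, col] = np.nan

    sev = rng.standard_normal(n)
    fra = rng.standard_normal(n)
    cohort["latent_severity"] = sev
    cohort["latent_frailty"] = fra

    le = config.latent_effects
    eta = (_covariate_lp(cohort, _EXPOSURE_EFFECTS)
           + le.severity_exposure * sev + le.frailty_exposure * fra)

    def gap(alpha: float) -> float:
        return float(expit(alpha + eta).mean()) - config.p_exposed_target

    alpha = brentq(gap, -25.0, 25.0, xtol=1e-10)
    exposure = (rng.random(n) < expit(alpha + eta)).astype(np.int8)
    cohort["exposure"] = exposure

    # triple therapy is a step-up for uncontrolled disease: flag a
    # severity-increasing share of the exposed arm
    triple = np.zeros(n, dtype=np.int8)
    exp_mask = exposure == 1
    triple[exp_mask] = rng.random(exp_mask.sum()) < expit(1.0 + 0.8 * sev[exp_mask])
    cohort["triple_therapy"] = triple

    log_hazard = (np.log(config.baseline_hazard)
                  + _covariate_lp(cohort, _OUTCOME_EFFECTS)
                  + le.severity_outcome * sev + le.frailty_outcome * fra
                  + config.true_log_hr * exposure)
    t_event = rng.exponential(1.0, size=n) / np.exp(log_hazard)
    if config.censor_rate > 0:
        cens_rate = -np.log1p(-config.censor_rate) / config.followup_days
        t_cens = rng.exponential(1.0 / cens_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_admin = float(config.followup_days)
    t_obs = np.minimum.reduce([t_event, t_cens, np.full(n, t_admin)])
    cohort["event"] = ((t_event <= t_cens) & (t_event <= t_admin)).astype(np.int8)
    cohort["time_to_event"] = np.maximum(np.ceil(t_obs), 1).astype(np.int64)
    return cohort


def estimation_view(cohort: pd.DataFrame) -> pd.DataFrame:
    """The cohort as the analysis is allowed to see it: latents removed."""
    return cohort.drop(columns=[c for c in LATENT_COLUMNS if c in cohort.columns])


# ---------------------------------------------------------------------------
# code emission
# ---------------------------------------------------------------------------

def code_registry(config: SimConfig) -> pd.DataFrame:
    """Ground-truth table of every harmonized concept the generator emits.

    Columns: dimension, code (harmonized form seen after mapping and
    truncation), kind ∈ {confounder, instrument, noise, treatment},
    latent ∈ {severity, frailty, ""}.
    """
    rows = []
    for dim in DIMENSIONS:
        for j in range(config.n_true_confounder_codes):
            latent = "severity" if j % 2 == 0 else "frailty"
            rows.append((dim, _concept_code(dim, "confounder", j), "confounder", latent))
        for j in range(config.n_instrument_codes):
            rows.append((dim, _concept_code(dim, "instrument", j), "instrument", ""))
        for j in range(config.n_noise_codes):
            rows.append((dim, _concept_code(dim, "noise", j), "noise", ""))
    rows += [("prescription", "030200", "treatment", ""),
             ("prescription", "030101", "treatment", ""),
             ("prescription", "030102", "treatment", "")]
    return pd.DataFrame(rows, columns=["dimension", "code", "kind", "latent"])


_KIND_LETTER = {"confounder": {"severity": "S", "frailty": "R"},
                "instrument": "V", "noise": "N"}
_RX_KIND_PREFIX = {"confounder": {"severity": "10", "frailty": "11"},
                   "instrument": "12", "noise": "13"}


def _concept_code(dim: str, kind: str, j: int) -> str:
    """Harmonized code for concept *j*: 3-char ICD-like for observation and
    hospitalisation dimensions, 6-char BNF-paragraph-like for prescriptions."""
    if dim == "prescription":
        prefix = _RX_KIND_PREFIX[kind]
        if kind == "confounder":
            prefix = prefix["severity" if j % 2 == 0 else "frailty"]
        return f"{prefix}{j:02d}00"
    letter = _KIND_LETTER[kind]
    if kind == "confounder":
        letter = letter["severity" if j % 2 == 0 else "frailty"]
    return f"{letter}{j:02d}"


def _raw_variants(dim: str, kind: str, j: int) -> list[str]:
    """Two raw source codes per concept (a many-to-one mapping downstream).

    Hospitalisation raw codes are already ICD-like (concept code plus a
    4th character) and need truncation only; the other dimensions use
    opaque SNOMED-/dm+d-like tokens that require the mapping tables.
    """
    base = _concept_code(dim, kind, j)
    if dim == "hospitalisation":
        return [base + "1", base + "2"]
    stem = {"observation": "sno", "prescription": "dmd"}[dim]
    return [f"{stem}{base}a", f"{stem}{base}b"]


def emit_code_events(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Emit the long code-event table for all three dimensions.

    Per concept a patient either has no occurrences or a count in 1..10
    (1 + Binomial(9, q)); for confounder concepts both the occurrence
    probability and q increase with the patient's latent, so once /
    sporadic / frequent recurrence levels all carry signal.  Observation
    events are dated up to two years back (so some fall outside a 12-month
    window and only the ever-present redefinition sees them); prescription
    and hospitalisation events stay within the last year.  Exposure-defining
    drug codes are emitted for every patient's own regimen and must be
    removed by the code-exclusion step, never by this module.
    """
    config.validate()
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31 - 1))
    n = len(cohort)
    sev = cohort["latent_severity"].to_numpy()
    fra = cohort["latent_frailty"].to_numpy()
    exposure = cohort["exposure"].to_numpy()

    # Confounder codes threshold each latent on an explicit global grid:
    # code (dim, j) for latent L fires with prob expit(slope * (L - t)),
    # with thresholds t spread over (-1.5, 2.0) across all three dimensions
    # jointly.  The indicators form a staircase covering the range where
    # both the exposure odds and the outcome hazard vary, so a logistic
    # propensity model on them can reconstruct the latent.
    n_per_latent = {0: (config.n_true_confounder_codes + 1) // 2,   # severity
                    1: config.n_true_confounder_codes // 2}          # frailty
    grids = {par: np.linspace(-1.5, 2.0, 3 * n_c) if n_c else np.empty(0)
             for par, n_c in n_per_latent.items()}

    frames = []
    for di, dim in enumerate(DIMENSIONS):
        date_hi = 730 if dim == "observation" else 365
        specs = []  # (kind, j, occurrence prob vector, count prob vector)
        for j in range(config.n_true_confounder_codes):
            par = j % 2  # 0 severity, 1 frailty
            latent = sev if par == 0 else fra
            t = grids[par][di * n_per_latent[par] + j // 2]
            p = expit(config.confounder_slope * (latent - t))
            q = expit(-1.2 + 0.8 * latent)
            specs.append(("confounder", j, p, q))
        p1 = min(config.instrument_prev_unexposed * config.instrument_rr_ce, 0.95)
        for j in range(config.n_instrument_codes):
            p = np.where(exposure == 1, p1, config.instrument_prev_unexposed)
            specs.append(("instrument", j, p, np.full(n, 0.22)))
        if config.n_noise_codes > 0:
            noise_p = np.linspace(0.05, 0.30, config.n_noise_codes)
        for j in range(config.n_noise_codes):
            specs.append(("noise", j, np.full(n, noise_p[j]), np.full(n, 0.22)))

        for kind, j, p, q in specs:
            occur = rng.random(n) < p
            idx = np.flatnonzero(occur)
            counts = 1 + rng.binomial(9, q[idx])
            pid = np.repeat(cohort["patient_id"].to_numpy()[idx], counts)
            total = counts.sum()
            variants = np.asarray(_raw_variants(dim, kind, j), dtype=object)
            frames.append(pd.DataFrame({
                "patient_id": pid,
                "dimension": dim,
                "raw_code": variants[rng.integers(0, 2, size=total)],
                "event_date": rng.integers(1, date_hi + 1, size=total),
            }))

    # index-regimen prescriptions (to be excluded downstream)
    for raw, mask in (("dmd030200a", exposure == 1),      # ICS
                      ("dmd030101a", np.ones(n, bool)),   # LABA (both arms)
                      ("dmd030102a", exposure == 0)):     # LAMA
        idx = np.flatnonzero(mask)
        counts = 1 + rng.binomial(9, 0.5, size=idx.size)
        pid = np.repeat(cohort["patient_id"].to_numpy()[idx], counts)
        frames.append(pd.DataFrame({
            "patient_id": pid,
            "dimension": "prescription",
            "raw_code": raw,
            "event_date": rng.integers(1, 366, size=counts.sum()),
        }))

    events = pd.concat(frames, ignore_index=True)
    logger.info("emitted %d code events for %d patients", len(events), n)
    return events


# ---------------------------------------------------------------------------
# mapping tables
# ---------------------------------------------------------------------------

def make_mapping_tables(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Toy source→harmonized mapping tables with deliberate gaps.

    Returns a dict with keys ``observation`` (SNOMED-like → 4-char
    ICD-like, truncated downstream), ``prescription`` (dm+d-like → 6-char
    BNF-paragraph-like) and ``prescription_fallback`` (dm+d-like → 8-char
    chapter string whose first six characters are used).  A
    ``fraction_unmapped`` share of raw variants is withheld from every
    table to exercise the unmapped-report path; among the mapped
    prescription variants a fixed share is routed to the fallback table
    only.  Hospitalisation codes are ICD-like at source and need no table.
    """
    config.validate()
    rng = np.random.default_rng(np.random.default_rng(config.seed + 1).integers(2**31 - 1))
    kinds = ([("confounder", j) for j in range(config.n_true_confounder_codes)]
             + [("instrument", j) for j in range(config.n_instrument_codes)]
             + [("noise", j) for j in range(config.n_noise_codes)])

    obs_rows, rx_rows, rx_fb_rows = [], [], []
    for dim, rows in (("observation", obs_rows), ("prescription", rx_rows)):
        variants = [(kind, j, v, raw) for kind, j in kinds
                    for v, raw in enumerate(_raw_variants(dim, kind, j))]
        n_unmapped = round(config.fraction_unmapped * len(variants))
        withheld = set(rng.choice(len(variants), size=n_unmapped, replace=False)
                       ) if n_unmapped else set()
        for i, (kind, j, v, raw) in enumerate(variants):
            if i in withheld:
                continue  # deliberately unmapped
            target = _concept_code(dim, kind, j)
            if dim == "observation":
                rows.append((raw, f"{target}{v + 1}"))  # 4 chars, truncates back
            elif rng.random() < 0.25:
                rx_fb_rows.append((raw, f"{target}xx"))  # chapter-string analogue
            else:
                rows.append((raw, target))
    rx_rows += [("dmd030200a", "030200"), ("dmd030101a", "030101"),
                ("dmd030102a", "030102")]

    cols = ["source_code", "target_code"]
    return {
        "observation": pd.DataFrame(obs_rows, columns=cols),
        "prescription": pd.DataFrame(rx_rows, columns=cols),
        "prescription_fallback": pd.DataFrame(rx_fb_rows, columns=cols),
    }


# ---------------------------------------------------------------------------
# CSV round-trip helpers
# ---------------------------------------------------------------------------

_COHORT_DTYPES = {"patient_id": np.int64, "exposure": np.int8, "event": np.int8,
                  "time_to_event": np.int64, "triple_therapy": np.int8}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in CATEGORICAL_COVARIATES})
    for col, dt in _COHORT_DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dt)
    return df


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"raw_code": str, "dimension": str})
    df["patient_id"] = df["patient_id"].astype(np.int64)
    df["event_date"] = df["event_date"].astype(np.int64)
    return df


def write_mapping(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_mapping(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str)
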