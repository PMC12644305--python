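"""End-to-end analysis orchestration and sensitivity machinery.

``run_analysis`` composes the whole pipeline for one choice of k (number
of empirical covariates; k = 0 is the conventional, prespecified-only
analysis): missing-data rules → code mapping and exclusions → assessment
window → recurrence covariates → outcome-specific Bross prioritisation →
propensity model on prespecified + top-k → stabilized weights → common-
support trim → weighted outcome models.  ``vary_k`` sweeps the k grid and
``one_by_one_trajectory`` adds the ranked covariates one at a time
(refitting the PS from scratch at each step, with the ranking frozen),
recording the effect estimate together with the max weight and effective
sample size so weight pathologies are visible alongside the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, SimConfig, logger
from . import code_mapping, covariates as cov, outcomes, prioritisation, synthetic, weighting

PRESPECIFIED_BINARY = list(synthetic.BINARY_COVARIATES)
PRESPECIFIED_CATEGORICAL = list(synthetic.CATEGORICAL_COVARIATES)


def apply_missing_data_rules(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the study's missing-data rules.

    Missing BMI goes to the 'normal' category (extreme values are the ones
    that get recorded); missing ethnicity becomes its own 'Unknown' level;
    rows with missing IMD are dropped (poor-quality records).  Missingness
    anywhere else is not covered by a rule and raises.
    """
    out = cohort.copy()
    report = {}
    if "bmi_group" in out.columns:
        n = int(out["bmi_group"].isna().sum())
        out["bmi_group"] = out["bmi_group"].fillna("normal")
        report["bmi_to_normal"] = n
    if "ethnicity" in out.columns:
        n = int(out["ethnicity"].isna().sum())
        out["ethnicity"] = out["ethnicity"].fillna("Unknown")
        report["ethnicity_to_unknown"] = n
    if "imd_quintile" in out.columns:
        drop = out["imd_quintile"].isna()
        report["imd_dropped"] = int(drop.sum())
        out = out.loc[~drop]
    other = out.columns[out.isna().any()].tolist()
    if other:
        raise ValueError(f"missing values without a handling rule in: {other}")
    logger.info("missing-data rules: %s", report)
    return out.reset_index(drop=True), report


def prespecified_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encoded prespecified-covariate design matrix (drop-first),
    indexed by patient_id, with deterministic column order."""
    df = cohort.set_index("patient_id")
    parts = [df[PRESPECIFIED_BINARY].astype(float)]
    for col in PRESPECIFIED_CATEGORICAL:
        dummies = pd.get_dummies(df[col], prefix=col, drop_first=True, dtype=float)
        parts.append(dummies[sorted(dummies.columns)])
    return pd.concat(parts, axis=1)


@dataclass
class PreparedStudy:
    """Everything that is computed once per (cohort definition, outcome)."""

    cohort: pd.DataFrame          # estimation view, missing rules applied
    design_pre: pd.DataFrame      # prespecified design matrix
    hdps_matrix: pd.DataFrame     # recurrence-covariate matrix
    hdps_metadata: pd.DataFrame
    ranked_scores: pd.DataFrame
    unmapped: pd.DataFrame
    missing_report: dict
    outcome: str = "event"
    cohort_def: str = "include_triple"


def prepare_study(cohort: pd.DataFrame, events: pd.DataFrame,
                  mapping_tables: dict[str, pd.DataFrame],
                  analysis: AnalysisConfig,
                  cohort_def: str | None = None,
                  outcome: str = "event") -> PreparedStudy:
    """Run every stage up to (and including) covariate prioritisation."""
    analysis.validate()
    cohort_def = cohort_def or analysis.cohort_def
    est = synthetic.estimation_view(cohort)
    if cohort_def == "exclude_triple":
        keep = ~((est["exposure"] == 1) & (est["triple_therapy"] == 1))
        logger.info("cohort definition '%s': dropped %d triple-therapy users",
                    cohort_def, int((~keep).sum()))
        est = est.loc[keep].reset_index(drop=True)
    est, missing_report = apply_missing_data_rules(est)
    events = events[events["patient_id"].isin(est["patient_id"])]

    mapped = code_mapping.map_all_dimensions(events, mapping_tables,
                                             exclusion_spec=analysis.excluded_codes)
    windowed = cov.restrict_assessment_window(mapped.events, analysis.window_days)
    matrix, metadata = cov.build_recurrence_covariates(
        windowed, est["patient_id"].to_numpy(),
        ever_present_events=mapped.events,
        quantile_rule=analysis.quantile_rule)
    matrix, metadata = cov.deduplicate_covariates(matrix, metadata)

    exposure = est.set_index("patient_id")["exposure"].loc[matrix.index].to_numpy()
    outcome_vec = est.set_index("patient_id")[outcome].loc[matrix.index].to_numpy()
    scores = prioritisation.score_covariates(
        matrix, exposure, outcome_vec,
        rr_cd_stratum=analysis.rr_cd_stratum,
        zero_cell_correction=analysis.zero_cell_correction)
    scores = prioritisation.exclude_instrument_like(
        scores, analysis.rr_ce_cut, analysis.rr_cd_cut)
    ranked = prioritisation.rank_covariates(scores)

    return PreparedStudy(cohort=est, design_pre=prespecified_design(est),
                         hdps_matrix=matrix, hdps_metadata=metadata,
                         ranked_scores=ranked, unmapped=mapped.unmapped,
                         missing_report=missing_report,
                         outcome=outcome, cohort_def=cohort_def)


@dataclass
class AnalysisResult:
    """Fitted estimates and diagnostics for one k."""

    k: int
    estimates: dict[str, outcomes.EffectEstimate]
    ps_result: weighting.PropensityResult
    weights: pd.Series            # retained patients only
    support_bounds: tuple[float, float]
    n_trimmed: dict
    diagnostics: dict
    balance: pd.DataFrame | None = None
    ph_check: dict | None = None
    survival: dict | None = None


def fit_for_k(prepared: PreparedStudy, k: int,
              analysis: AnalysisConfig | None = None,
              with_balance: bool = False) -> AnalysisResult:
    """Propensity model with top-k empirical covariates, then all estimands."""
    analysis = analysis or AnalysisConfig()
    est = prepared.cohort.set_index("patient_id")
    design = prepared.design_pre
    if k > 0:
        ids = prioritisation.top_k_ids(prepared.ranked_scores, k)
        design = pd.concat([design, prepared.hdps_matrix[ids].astype(float)], axis=1)
    exposure = est["exposure"].loc[design.index]

    ps_res = weighting.fit_propensity_model(design, exposure)
    w_all = weighting.stabilized_weights(ps_res.ps, exposure)
    mask, bounds, n_trimmed = weighting.trim_common_support(ps_res.ps, exposure)

    kept = mask[mask].index
    e = exposure.loc[kept].to_numpy()
    w = w_all.loc[kept].to_numpy()
    d = est[prepared.outcome].loc[kept].to_numpy()
    t = est["time_to_event"].loc[kept].to_numpy()

    hr, cox_fit, cox_df = outcomes.weighted_cox_hr(t, d, e, w, return_fit=True)
    estimates = {
        "HR": hr,
        "OR": outcomes.weighted_logistic_or(d, e, w),
        "RD": outcomes.weighted_risk_difference(d, e, w,
                                                se_method=analysis.rd_se_method),
    }
    for est_obj in estimates.values():
        est_obj.k = k
        est_obj.cohort = prepared.cohort_def
        est_obj.outcome = prepared.outcome

    diag = weighting.weight_diagnostics(w, e)
    diag["n_retained"] = int(mask.sum())
    balance = None
    if with_balance:
        cols = design.loc[kept]
        balance = weighting.balance_table(
            cols, e, {"unweighted": None, "weighted": w})
    ph = outcomes.schoenfeld_ph_check(cox_fit, cox_df)
    surv = outcomes.weighted_survival_curves(t, d, e, w)
    return AnalysisResult(k=k, estimates=estimates, ps_result=ps_res,
                          weights=pd.Series(w, index=kept, name="weight"),
                          support_bounds=bounds, n_trimmed=n_trimmed,
                          diagnostics=diag, balance=balance, ph_check=ph,
                          survival=surv)


def run_analysis(sim: SimConfig, analysis: AnalysisConfig, k: int,
                 cohort_def: str | None = None, outcome: str = "event",
                 outdir: str | Path | None = None,
                 with_balance: bool = False) -> AnalysisResult:
    """Simulate, prepare and fit one analysis end to end.

    With ``outdir`` set, writes the tidy results file plus the score,
    balance and diagnostic tables; identical config and seed give
    byte-identical files.
    """
    cohort = synthetic.generate_cohort(sim)
    events = synthetic.emit_code_events(cohort, sim)
    tables = synthetic.make_mapping_tables(sim)
    prepared = prepare_study(cohort, events, tables, analysis,
                             cohort_def=cohort_def, outcome=outcome)
    result = fit_for_k(prepared, k, analysis, with_balance=with_balance)
    if outdir is not None:
        persist_result(prepared, result, Path(outdir))
    return result


def vary_k(prepared: PreparedStudy, k_values,
           analysis: AnalysisConfig | None = None) -> pd.DataFrame:
    """Fit the pipeline at each k and return the tidy estimates table."""
    rows = []
    for k in k_values:
        res = fit_for_k(prepared, k, analysis)
        for est in res.estimates.values():
            row = est.as_row()
            row.update({"max_weight": res.diagnostics["max_weight"],
                        "ess_exposed": res.diagnostics["ess_exposed"],
                        "ess_unexposed": res.diagnostics["ess_unexposed"]})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SensitivityTrajectory:
    """One-by-one covariate-addition trajectory."""

    steps: pd.DataFrame = field(default_factory=pd.DataFrame)


def one_by_one_trajectory(prepared: PreparedStudy, max_rank: int = 250,
                          analysis: AnalysisConfig | None = None
                          ) -> SensitivityTrajectory:
    """Add the Bross-ranked covariates one at a time (ranking frozen).

    For each j = 1..max_rank the propensity model is refitted from scratch
    with the prespecified covariates plus the top-j empirical ones, and the
    HR is recorded with the max weight and per-arm effective sample sizes.
    A single influential covariate thus shows up as a jump at its rank.
    """
    analysis = analysis or AnalysisConfig()
    available = int(prepared.ranked_scores["rank"].notna().sum())
    if max_rank > available:
        logger.warning("one-by-one: max_rank %d exceeds %d retained covariates; "
                       "truncating", max_rank, available)
        max_rank = available
    rows = []
    for j in range(1, max_rank + 1):
        res = fit_for_k(prepared, j, analysis)
        hr = res.estimates["HR"]
        rows.append({
            "n_covariates": j,
            "hr": hr.point, "log_hr": hr.extra["log_point"],
            "ci_lower": hr.ci_lower, "ci_upper": hr.ci_upper,
            "max_weight": res.diagnostics["max_weight"],
            "ess_exposed": res.diagnostics["ess_exposed"],
            "ess_unexposed": res.diagnostics["ess_unexposed"],
        })
    return SensitivityTrajectory(steps=pd.DataFrame(rows))


def persist_result(prepared: PreparedStudy, result: AnalysisResult,
                   outdir: Path) -> None:
    """Write the tidy artifact set for one analysis into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([e.as_row() for e in result.estimates.values()]).to_csv(
        outdir / "estimates.csv", index=False)
    result.ps_result.ps.rename("ps").reset_index().to_csv(
        outdir / "propensity_scores.csv", index=False)
    prepared.ranked_scores.to_csv(outdir / "bross_scores.csv", index=False)
    prepared.hdps_metadata.to_csv(outdir / "covariate_metadata.csv", index=False)
    prepared.unmapped.to_csv(outdir / "unmapped_codes.csv", index=False)
    if result.balance is not None:
        result.balance.to_csv(outdir / "balance.csv", index=False)
    diag = dict(result.diagnostics)
    diag.update({"support_lower": result.support_bounds[0],
                 "support_upper": result.support_bounds[1],
                 "trimmed_exposed": result.n_trimmed["exposed"],
                 "trimmed_unexposed": result.n_trimmed["unexposed"],
                 **{f"missing_{k}": v for k, v in prepared.missing_report.items()}})
    pd.DataFrame([diag]).to_csv(outdir / "diagnostics.csv", index=False)
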