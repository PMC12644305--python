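"""Recurrence covariates: binary patient-level variables from code events.

For every (dimension, harmonized code) the per-patient occurrence count in
the assessment window is summarised into up to three nested indicators:

* ``once``      — the code occurred at least once;
* ``sporadic``  — count ≥ median of the positive counts for that code;
* ``frequent``  — count ≥ 75th percentile of the positive counts.

Thresholds are computed among patients with at least one occurrence, and
ties qualify (≥).  For the primary-care *observation* dimension the
``once`` indicator is redefined as "code ever recorded before the index
date" (no window), reflecting that chronic conditions are not re-recorded
at every consultation; sporadic/frequent still use windowed counts.  No
marginal-prevalence filter is applied — rare codes can still be important
confounders and are left for the prioritisation step to judge.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import logger

LEVELS = ("once", "sporadic", "frequent")


def covariate_id(dimension: str, code: str, level: str) -> str:
    return f"{dimension}:{code}:{level}"


def restrict_assessment_window(events: pd.DataFrame, window_days: int = 365
                               ) -> pd.DataFrame:
    """Keep events dated 1..window_days days before the index date."""
    if window_days <= 0:
        raise ValueError(f"window_days must be positive, got {window_days!r}")
    keep = (events["event_date"] >= 1) & (events["event_date"] <= window_days)
    out = events.loc[keep].reset_index(drop=True)
    logger.info("assessment window (%d days): kept %d of %d events",
                window_days, len(out), len(events))
    return out


def positive_count_quantile(counts: np.ndarray, q: float, rule: str = "linear"
                            ) -> float:
    """Quantile of the positive per-patient counts under the declared rule.

    ``linear`` interpolates (the R default, type 7); ``nearest_rank`` takes
    the k-th smallest with k = ceil(q*m), an integer threshold on integer
    counts.  Exposed as a choice because published applications rarely
    state their estimator.
    """
    counts = np.sort(np.asarray(counts))
    m = len(counts)
    if m == 0:
        raise ValueError("no positive counts")
    if rule == "linear":
        return float(np.quantile(counts, q))
    if rule == "nearest_rank":
        k = max(1, math.ceil(q * m))
        return float(counts[k - 1])
    raise ValueError(f"unknown quantile rule {rule!r}")


def build_recurrence_covariates(windowed_events: pd.DataFrame,
                                patient_ids: pd.Index | np.ndarray,
                                ever_present_events: pd.DataFrame | None = None,
                                quantile_rule: str = "linear",
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the 0/1 covariate matrix and its metadata table.

    Parameters
    ----------
    windowed_events
        Mapped events already restricted to the assessment window.
    patient_ids
        Full cohort index; patients without events get all-zero rows.
    ever_present_events
        Unrestricted observation-dimension event stream used to redefine
        the ``once`` indicators of that dimension.  When omitted the
        windowed definition is used everywhere.

    Returns
    -------
    matrix : DataFrame
        int8 matrix indexed by patient_id, one column per covariate id.
    metadata : DataFrame
        columns ``covariate_id, dimension, code, level, threshold``.
    """
    patient_index = pd.Index(np.asarray(patient_ids), name="patient_id")
    counts = (windowed_events.groupby(["dimension", "harmonized_code", "patient_id"])
              .size().rename("n"))
    ever = None
    if ever_present_events is not None:
        obs = ever_present_events[ever_present_events["dimension"] == "observation"]
        ever = (obs.groupby(["harmonized_code", "patient_id"]).size().rename("n"))

    columns: dict[str, pd.Series] = {}
    meta_rows = []
    zero = pd.Series(0, index=patient_index, dtype=np.int8)

    seen = set(counts.index.droplevel("patient_id").unique())
    if ever is not None:
        seen |= {("observation", code) for code in ever.index.get_level_values(0).unique()}
    for dim, code in sorted(seen):
        if (dim, code) in counts.index:
            c = counts.loc[(dim, code)]
        else:
            c = pd.Series(dtype=np.int64)
        pos = c.to_numpy()
        thresholds: dict[str, float] = {}
        if len(pos) > 0:
            thresholds["once"] = 1.0
            thresholds["sporadic"] = positive_count_quantile(pos, 0.5, quantile_rule)
            thresholds["frequent"] = positive_count_quantile(pos, 0.75, quantile_rule)
        elif dim == "observation" and ever is not None and code in ever.index.get_level_values(0):
            thresholds["once"] = 1.0  # ever-present only
        else:
            continue  # zero positive counts: nothing to emit
        aligned = c.reindex(patient_index, fill_value=0)
        for level in LEVELS:
            if level not in thresholds:
                continue
            thr = thresholds[level]
            if dim == "observation" and level == "once" and ever is not None:
                e = ever.loc[code].reindex(patient_index, fill_value=0) if code in ever.index.get_level_values(0) else zero
                col = (e >= 1).astype(np.int8)
            else:
                col = (aligned >= thr).astype(np.int8)
            columns[covariate_id(dim, code, level)] = col
            meta_rows.append((covariate_id(dim, code, level), dim, code, level, thr))

    matrix = pd.DataFrame(columns, index=patient_index, dtype=np.int8)
    metadata = pd.DataFrame(meta_rows, columns=["covariate_id", "dimension",
                                                "code", "level", "threshold"])
    logger.info("built %d recurrence covariates over %d codes",
                matrix.shape[1], len(seen))
    return matrix, metadata


def deduplicate_covariates(matrix: pd.DataFrame, metadata: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse identical columns *within* a code to the lowest level.

    When thresholds coincide (e.g. all positive counts equal 1) the three
    indicators are the same column; keeping all of them would feed the
    propensity model perfectly collinear copies.  Distinct codes with
    coincidentally equal columns are both retained — deduplication is a
    within-code contract only.
    """
    level_order = {lv: i for i, lv in enumerate(LEVELS)}
    keep: list[str] = []
    for (_, _), group in metadata.groupby(["dimension", "code"], sort=False):
        ordered = group.sort_values("level", key=lambda s: s.map(level_order))
        kept_cols: list[str] = []
        for cid in ordered["covariate_id"]:
            col = matrix[cid]
            if any(col.equals(matrix[k]) for k in kept_cols):
                continue
            kept_cols.append(cid)
        keep.extend(kept_cols)
    dropped = matrix.shape[1] - len(keep)
    if dropped:
        logger.info("deduplication removed %d degenerate covariate columns", dropped)
    keep_set = set(keep)
    meta = metadata[metadata["covariate_id"].isin(keep_set)].reset_index(drop=True)
    return matrix[meta["covariate_id"].tolist()], meta


def write_covariates(matrix: pd.DataFrame, metadata: pd.DataFrame,
                     matrix_path, metadata_path) -> None:
    matrix.reset_index().to_csv(matrix_path, index=False)
    metadata.to_csv(metadata_path, index=False)


def read_covariates(matrix_path, metadata_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    matrix = pd.read_csv(matrix_path).set_index("patient_id")
    matrix = matrix.astype(np.int8)
    metadata = pd.read_csv(metadata_path)
    return matrix, metadata
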