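"""Bross-formula prioritisation of candidate confounders.

Each candidate binary covariate C is scored by the multiplicative bias an
unmeasured confounder with its prevalence/association profile could
inflict on the exposure–outcome association:

    bias = [P_C1 * (RR_CD - 1) + 1] / [P_C0 * (RR_CD - 1) + 1]

with P_C1 = P(C=1 | exposed), P_C0 = P(C=1 | unexposed) and RR_CD the
covariate–outcome relative risk; RR_CD < 1 is replaced by its reciprocal
inside the formula so protective and harmful associations rank
symmetrically.  Covariates are ranked by |log bias| descending.
Instrument-like covariates — strongly exposure-associated but nearly
outcome-independent (|log RR_CE| > 1.1 and |log RR_CD| < 0.5) — are
flagged and removed before ranking, since adjusting for instruments can
amplify bias.

RR_CD is estimated within the unexposed stratum by default (classic hdPS
behaviour; the full cohort is a config option), and any 2x2 table with a
zero cell gets 0.1 added to every cell so rare-outcome covariates remain
scoreable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import logger

SCORE_COLUMNS = ["covariate_id", "p_c1", "p_c0", "rr_ce", "rr_cd",
                 "bias_mult", "abs_log_bias", "iv_flag", "rank"]


def _corrected_rr(events_1, n_1, events_0, n_0, correction: float):
    """Relative risk P(D|C=1)/P(D|C=0) with all-cell correction on zeros.

    Accepts scalars or aligned arrays; the correction is applied per table
    only where some cell of that table is zero.
    """
    a = np.asarray(events_1, dtype=float)
    n1 = np.asarray(n_1, dtype=float)
    b = np.asarray(events_0, dtype=float)
    n0 = np.asarray(n_0, dtype=float)
    zero = (a == 0) | (n1 - a == 0) | (b == 0) | (n0 - b == 0)
    a_c = np.where(zero, a + correction, a)
    n1_c = np.where(zero, n1 + 2 * correction, n1)
    b_c = np.where(zero, b + correction, b)
    n0_c = np.where(zero, n0 + 2 * correction, n0)
    return (a_c / n1_c) / (b_c / n0_c)


def crosstab_stats(covariate, exposure, outcome,
                   rr_cd_stratum: str = "unexposed",
                   zero_cell_correction: float = 0.1):
    """Prevalences and relative risks for one candidate covariate.

    Returns ``(p_c1, p_c0, rr_cd, rr_ce)``.  RR_CE is the ratio of
    covariate prevalences between arms; RR_CD is the outcome relative risk
    across covariate levels inside the chosen stratum.
    """
    c = np.asarray(covariate, dtype=np.int8)
    e = np.asarray(exposure, dtype=np.int8)
    d = np.asarray(outcome, dtype=np.int8)
    n1 = int(e.sum())
    n0 = int(len(e) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both exposure arms must be non-empty")
    c1 = int(c[e == 1].sum())
    c0 = int(c[e == 0].sum())
    p_c1 = c1 / n1
    p_c0 = c0 / n0
    rr_ce = float(_corrected_rr(c1, n1, c0, n0, zero_cell_correction))
    if rr_cd_stratum == "unexposed":
        mask = e == 0
    elif rr_cd_stratum == "full":
        mask = np.ones_like(e, dtype=bool)
    else:
        raise ValueError(f"unknown rr_cd_stratum {rr_cd_stratum!r}")
    cs, ds = c[mask], d[mask]
    n_c1 = int(cs.sum())
    n_c0 = int(len(cs) - n_c1)
    d_c1 = int(ds[cs == 1].sum())
    d_c0 = int(ds[cs == 0].sum())
    rr_cd = float(_corrected_rr(d_c1, n_c1, d_c0, n_c0, zero_cell_correction))
    return p_c1, p_c0, rr_cd, rr_ce


def bross_bias(p_c1, p_c0, rr_cd):
    """Bias multiplier and |log bias| for given prevalences and RR_CD.

    Accepts scalars or arrays.  RR_CD below 1 is inverted so the score is
    direction-agnostic.
    """
    p1 = np.asarray(p_c1, dtype=float)
    p0 = np.asarray(p_c0, dtype=float)
    rr = np.asarray(rr_cd, dtype=float)
    if np.any(~np.isfinite(p1)) or np.any(~np.isfinite(p0)) or np.any(~np.isfinite(rr)):
        raise ValueError("bross_bias inputs must be finite")
    if np.any(rr <= 0):
        raise ValueError("RR_CD must be positive after zero-cell correction")
    rr_sym = np.where(rr < 1, 1.0 / rr, rr)
    bias = (p1 * (rr_sym - 1) + 1) / (p0 * (rr_sym - 1) + 1)
    abs_log = np.abs(np.log(bias))
    if np.isscalar(p_c1) or np.ndim(p_c1) == 0:
        return float(bias), float(abs_log)
    return bias, abs_log


def score_covariates(matrix: pd.DataFrame, exposure, outcome,
                     rr_cd_stratum: str = "unexposed",
                     zero_cell_correction: float = 0.1) -> pd.DataFrame:
    """Score every column of the covariate matrix (vectorised).

    Returns one row per covariate with the crosstab statistics, the bias
    multiplier and |log bias|; ``iv_flag`` and ``rank`` are filled by
    :func:`exclude_instrument_like` and :func:`rank_covariates`.
    """
    e = np.asarray(exposure, dtype=np.int8)
    d = np.asarray(outcome, dtype=np.int8)
    C = matrix.to_numpy(dtype=np.float64)
    n1 = int(e.sum())
    n0 = int(len(e) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both exposure arms must be non-empty")
    c1 = C.T @ (e == 1)
    c0 = C.T @ (e == 0)
    p_c1 = c1 / n1
    p_c0 = c0 / n0
    rr_ce = _corrected_rr(c1, n1, c0, n0, zero_cell_correction)
    mask = (e == 0) if rr_cd_stratum == "unexposed" else np.ones_like(e, dtype=bool)
    if rr_cd_stratum not in ("unexposed", "full"):
        raise ValueError(f"unknown rr_cd_stratum {rr_cd_stratum!r}")
    Cs = C[mask]
    ds = d[mask].astype(float)
    n_c1 = Cs.sum(axis=0)
    n_c0 = mask.sum() - n_c1
    d_c1 = Cs.T @ ds
    d_c0 = ds.sum() - d_c1
    rr_cd = _corrected_rr(d_c1, n_c1, d_c0, n_c0, zero_cell_correction)
    bias, abs_log = bross_bias(p_c1, p_c0, rr_cd)
    return pd.DataFrame({
        "covariate_id": matrix.columns,
        "p_c1": p_c1, "p_c0": p_c0, "rr_ce": rr_ce, "rr_cd": rr_cd,
        "bias_mult": bias, "abs_log_bias": abs_log,
        "iv_flag": False, "rank": pd.NA,
    })


def exclude_instrument_like(scores: pd.DataFrame,
                            rr_ce_cut: float = 1.1,
                            rr_cd_cut: float = 0.5) -> pd.DataFrame:
    """Set ``iv_flag`` where |log RR_CE| > cut and |log RR_CD| < cut."""
    out = scores.copy()
    out["iv_flag"] = ((np.abs(np.log(out["rr_ce"])) > rr_ce_cut)
                      & (np.abs(np.log(out["rr_cd"])) < rr_cd_cut))
    n = int(out["iv_flag"].sum())
    if n:
        logger.info("flagged %d instrument-like covariates", n)
    return out


def rank_covariates(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank retained (non-flagged) covariates by |log bias| descending.

    Ties are broken lexicographically on the covariate id so rankings are
    reproducible across runs and platforms.  Flagged covariates keep a
    null rank and never enter a top-k selection.
    """
    out = scores.copy()
    retained = out.loc[~out["iv_flag"]].sort_values(
        ["abs_log_bias", "covariate_id"], ascending=[False, True])
    out["rank"] = pd.NA
    out.loc[retained.index, "rank"] = np.arange(1, len(retained) + 1)
    out["rank"] = out["rank"].astype("Int64")
    return out


def top_k_ids(ranked: pd.DataFrame, k: int) -> list[str]:
    """Covariate ids with ranks 1..k; warns and uses all when k exceeds
    the number retained."""
    retained = ranked.dropna(subset=["rank"]).sort_values("rank")
    if k > len(retained):
        logger.warning("requested top %d covariates but only %d retained; using all",
                       k, len(retained))
        k = len(retained)
    return retained["covariate_id"].head(k).tolist()


def dimension_provenance(ranked: pd.DataFrame, metadata: pd.DataFrame, k: int
                         ) -> pd.DataFrame:
    """Counts and shares of each dimension among the top-k covariates."""
    ids = top_k_ids(ranked, k)
    dims = metadata.set_index("covariate_id").loc[ids, "dimension"]
    counts = dims.value_counts().rename_axis("dimension").reset_index(name="n")
    counts["share"] = counts["n"] / counts["n"].sum()
    return counts
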