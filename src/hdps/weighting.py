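"""Propensity-score estimation, stabilized ATE weights, trimming, balance.

The propensity score is the modelled probability of receiving the exposure
drug class, fitted by plain logistic regression on the prespecified
covariates plus however many empirical (recurrence) covariates the caller
supplies.  Stabilized weights p_E/PS and (1-p_E)/(1-PS) target the average
treatment effect; scores are trimmed to the region of common support (the
PS interval where both arms are represented, bounds inclusive); balance is
summarised by standardized mean differences, with the Yang–Dalton
Mahalanobis formulation giving a single SMD per categorical covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .config import logger


@dataclass
class PropensityResult:
    """Fitted PS model: per-patient scores plus bookkeeping."""

    ps: pd.Series
    params: pd.Series
    converged: bool
    dropped_columns: list[str]
    p_exposed: float


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns that are linearly dependent on earlier ones (QR with
    pivoting on the centred design)."""
    if X.shape[1] == 0:
        return X, []
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    _, r, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    dropped_idx = sorted(piv[rank:])
    dropped = [X.columns[i - 1] for i in dropped_idx if i > 0]
    if dropped:
        logger.warning("dropping %d collinear propensity-model columns: %s",
                       len(dropped), dropped[:10])
        X = X.drop(columns=dropped)
    return X, dropped


def _separating_columns(X: pd.DataFrame, exposure: np.ndarray) -> list[str]:
    """Binary columns whose positive level sits entirely in one arm."""
    out = []
    for col in X.columns:
        v = X[col].to_numpy()
        if set(np.unique(v)) <= {0, 1}:
            arm = exposure[v == 1]
            if len(arm) > 0 and (arm.min() == arm.max()):
                out.append(col)
    return out


def fit_propensity_model(covariate_matrix: pd.DataFrame, exposure
                         ) -> PropensityResult:
    """Logistic PS model (with intercept) on the supplied design matrix.

    An empty matrix yields the intercept-only model, i.e. PS equal to the
    observed exposure prevalence for everyone.  Collinear columns are
    dropped with a warning; perfect separation raises with the offending
    columns named.
    """
    e = np.asarray(exposure, dtype=float)
    X, dropped = _drop_collinear(covariate_matrix)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + list(X.columns)
    try:
        with np.errstate(all="ignore"):
            try:
                fit = sm.Logit(e, design).fit(disp=0, maxiter=100, method="newton",
                                              tol=1e-10)
            except np.linalg.LinAlgError:
                fit = sm.Logit(e, design).fit(disp=0, maxiter=500, method="lbfgs")
    except Exception as err:  # statsmodels PerfectSeparationError and kin
        seps = _separating_columns(X, e)
        raise ValueError(
            f"propensity model failed ({err}); candidate separating columns: {seps}"
        ) from err
    ps = np.asarray(fit.predict(design))
    eps = 1e-10
    if np.any(ps <= eps) or np.any(ps >= 1 - eps):
        seps = _separating_columns(X, e)
        raise ValueError(
            f"propensity model produced degenerate scores; candidate separating "
            f"columns: {seps}")
    retvals = getattr(fit, "mle_retvals", {}) or {}
    converged = bool(retvals.get("converged", True))
    index = covariate_matrix.index
    return PropensityResult(
        ps=pd.Series(ps, index=index, name="ps"),
        params=pd.Series(fit.params, index=names),
        converged=converged,
        dropped_columns=dropped,
        p_exposed=float(e.mean()),
    )


def stabilized_weights(ps, exposure) -> pd.Series:
    """Stabilized ATE weights: p_E/PS (exposed), (1-p_E)/(1-PS) (unexposed)."""
    ps_arr = np.asarray(ps, dtype=float)
    e = np.asarray(exposure, dtype=np.int8)
    if np.any(ps_arr <= 0) or np.any(ps_arr >= 1):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    p_e = float(e.mean())
    w = np.where(e == 1, p_e / ps_arr, (1 - p_e) / (1 - ps_arr))
    index = ps.index if isinstance(ps, pd.Series) else None
    return pd.Series(w, index=index, name="weight")


def trim_common_support(ps, exposure):
    """Retain patients inside the common-support PS interval.

    Returns ``(mask, (lower, upper), n_excluded_by_arm)`` where the bounds
    are the max of the arm-wise minima and the min of the arm-wise maxima,
    inclusive.
    """
    ps_arr = np.asarray(ps, dtype=float)
    e = np.asarray(exposure, dtype=np.int8)
    if (e == 1).sum() == 0 or (e == 0).sum() == 0:
        raise ValueError("both arms must be non-empty")
    lower = max(ps_arr[e == 1].min(), ps_arr[e == 0].min())
    upper = min(ps_arr[e == 1].max(), ps_arr[e == 0].max())
    if lower > upper:
        raise ValueError("no common support: arm-wise PS ranges are disjoint")
    mask = (ps_arr >= lower) & (ps_arr <= upper)
    n_excl = {"exposed": int((~mask & (e == 1)).sum()),
              "unexposed": int((~mask & (e == 0)).sum())}
    logger.info("common-support trim [%0.4f, %0.4f] excluded %d exposed, "
                "%d unexposed", lower, upper, n_excl["exposed"], n_excl["unexposed"])
    if isinstance(ps, pd.Series):
        mask = pd.Series(mask, index=ps.index)
    return mask, (float(lower), float(upper)), n_excl


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    m = float((w * x).sum() / sw)
    v = float((w * (x - m) ** 2).sum() / sw)
    return m, v


def standardized_mean_difference(column, exposure, weights=None) -> float:
    """Absolute SMD between arms, optionally weighted.

    Binary/continuous columns use |m1-m0| / sqrt((v1+v0)/2) with weighted
    group means and (frequency-weight form) variances.  Categorical
    columns (non-numeric) use the Yang–Dalton Mahalanobis statistic over
    the K-1 level-proportion vectors.  A zero pooled variance with unequal
    means reports +inf.
    """
    e = np.asarray(exposure, dtype=np.int8)
    col = pd.Series(np.asarray(column, dtype=object)) if not isinstance(column, pd.Series) else column
    w = np.ones(len(e)) if weights is None else np.asarray(weights, dtype=float)

    if not pd.api.types.is_numeric_dtype(pd.Series(col).infer_objects()):
        return _categorical_smd(pd.Series(col).astype(str).to_numpy(), e, w)

    x = pd.Series(col).astype(float).to_numpy()
    m1, v1 = _weighted_mean_var(x[e == 1], w[e == 1])
    m0, v0 = _weighted_mean_var(x[e == 0], w[e == 0])
    pooled = (v1 + v0) / 2
    diff = abs(m1 - m0)
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled))


def _categorical_smd(x: np.ndarray, e: np.ndarray, w: np.ndarray) -> float:
    levels = sorted(pd.unique(x))
    if len(levels) < 2:
        return 0.0
    ref = levels[1:]  # K-1 proportions

    def props(mask):
        sw = w[mask].sum()
        return np.array([(w[mask] * (x[mask] == lv)).sum() / sw for lv in ref])

    p1, p0 = props(e == 1), props(e == 0)

    def cov(p):
        return np.diag(p) - np.outer(p, p)

    s = (cov(p1) + cov(p0)) / 2
    diff = p1 - p0
    val = float(diff @ np.linalg.pinv(s) @ diff)
    return float(np.sqrt(max(val, 0.0)))


def balance_table(columns: pd.DataFrame, exposure,
                  weight_sets: dict[str, pd.Series | np.ndarray | None]
                  ) -> pd.DataFrame:
    """SMD per covariate under each weighting scheme.

    ``weight_sets`` maps a scheme label (e.g. ``unweighted``,
    ``conventional``, ``hdps``) to a weight vector (or None for unit
    weights); output has one row per column of ``columns`` and one SMD
    column per scheme.
    """
    rows = {}
    for name in columns.columns:
        rows[name] = {f"smd_{label}": standardized_mean_difference(
            columns[name], exposure, w) for label, w in weight_sets.items()}
    out = pd.DataFrame(rows).T.rename_axis("covariate").reset_index()
    return out


def effective_sample_size(weights) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w ** 2).sum())


def weight_diagnostics(weights, exposure) -> dict:
    """Extreme-weight diagnostics reported instead of truncation."""
    w = np.asarray(weights, dtype=float)
    e = np.asarray(exposure, dtype=np.int8)
    return {
        "mean_weight": float(w.mean()),
        "max_weight": float(w.max()),
        "ess_exposed": effective_sample_size(w[e == 1]),
        "ess_unexposed": effective_sample_size(w[e == 0]),
    }


def ps_density_table(ps, exposure, weights=None, gridsize: int = 128
                     ) -> pd.DataFrame:
    """Per-arm (weighted) PS densities on a common grid, for external
    plotting of the overlap diagnostic."""
    from scipy.stats import gaussian_kde

    ps_arr = np.asarray(ps, dtype=float)
    e = np.asarray(exposure, dtype=np.int8)
    w = np.ones(len(e)) if weights is None else np.asarray(weights, dtype=float)
    grid = np.linspace(ps_arr.min(), ps_arr.max(), gridsize)
    out = {"ps": grid}
    for label, mask in (("exposed", e == 1), ("unexposed", e == 0)):
        kde = gaussian_kde(ps_arr[mask], weights=w[mask])
        out[f"density_{label}"] = kde(grid)
    return pd.DataFrame(out)
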