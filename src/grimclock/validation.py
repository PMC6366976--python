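"""Survival-association and meta-analysis statistics for clock validation.

Covers the statistics used to validate composite methylation clocks on
cohort data: Cox proportional-hazards associations with Huber sandwich
(optionally cluster-aggregated) standard errors, inverse-variance
fixed-effect meta-analysis with Cochran's Q heterogeneity test, Stouffer
z pooling weighted by sqrt(n), null-model deviance residuals as a
per-person excess-mortality score, biweight midcorrelation, and
extreme-quantile contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from scipy import stats

from .errors import (
    ConvergenceError,
    InvalidArgumentError,
    NoEstimableStrataError,
    NoEventsError,
    NoVariationError,
    TieResolutionError,
    UndefinedCorrelationError,
)
from .outcomes import SurvivalOutcome


@dataclass
class CoxResult:
    """One proportional-hazards association (Wald inference)."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MetaResult:
    """Fixed-effect pooled estimate with heterogeneity statistics."""

    beta: float
    se: float
    p: float
    q: float
    q_df: int
    het_p: float
    i2: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))


def cox_association(
    predictor: np.ndarray,
    outcome: SurvivalOutcome,
    adjust: pd.DataFrame | np.ndarray | None = None,
    cluster: np.ndarray | None = None,
) -> CoxResult:
    """Cox regression of the outcome on [predictor, adjust] with robust SE.

    Uses the Huber sandwich variance estimator; when ``cluster`` labels
    are given the score contributions are aggregated within clusters
    first (pedigrees, repeated measures).  Returns Wald CI and p-value
    for the predictor.
    """
    x = np.asarray(predictor, dtype=float)
    if outcome.n_events < 2:
        raise NoEventsError("need at least 2 observed events")
    if np.std(x) == 0:
        raise NoVariationError("predictor is constant")

    df = pd.DataFrame({"predictor": x, "time": outcome.time, "event": outcome.event})
    if adjust is not None:
        adj = pd.DataFrame(adjust).reset_index(drop=True)
        adj.columns = [str(c) for c in adj.columns]
        for col in adj.columns:
            df[f"adj_{col}"] = adj[col].to_numpy(dtype=float)
    cluster_col = None
    if cluster is None and outcome.cluster is not None:
        cluster = outcome.cluster
    if cluster is not None:
        df["cluster"] = np.asarray(cluster)
        cluster_col = "cluster"

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                robust=True,
                cluster_col=cluster_col,
                fit_options={"precision": 1e-9},
            )
    except (_LLConvergenceError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(
            f"Cox model failed to converge (separation or collinearity?): {exc}"
        ) from exc
    row = cph.summary.loc["predictor"]
    return CoxResult(
        beta=float(row["coef"]),
        se=float(row["se(coef)"]),
        hr=float(row["exp(coef)"]),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
        n=len(outcome),
        events=outcome.n_events,
    )


def mortality_deviance_residual(outcome: SurvivalOutcome) -> np.ndarray:
    """Per-person excess-mortality score from a null survival model.

    Martingale residuals of the covariate-free model,
    ``m_i = event_i − H0(t_i)`` with ``H0`` the Nelson–Aalen cumulative
    hazard, transformed to deviance residuals
    ``sign(m) * sqrt(−2 (m + event * log(event − m)))``.  Positive values
    mean dying earlier than the cohort baseline predicts.
    """
    if outcome.n_events < 1:
        raise NoEventsError("deviance residuals undefined without events")
    time, event = outcome.time, outcome.event
    order = np.argsort(time, kind="stable")
    n = time.size
    # Nelson-Aalen increments d/n at each distinct event time
    cumhaz_at = {}
    at_risk = n
    cumhaz = 0.0
    i = 0
    t_sorted = time[order]
    e_sorted = event[order]
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        d = int(e_sorted[i : j + 1].sum())
        if d:
            cumhaz += d / at_risk
        cumhaz_at[t_sorted[i]] = cumhaz
        at_risk -= j - i + 1
        i = j + 1
    H = np.array([cumhaz_at[t] for t in time])
    m = event - H
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = m + np.where(event == 1, np.log(np.maximum(event - m, 1e-300)), 0.0)
    dev = np.sign(m) * np.sqrt(np.maximum(-2.0 * inner, 0.0))
    return dev


def fixed_effect_meta(betas: np.ndarray, ses: np.ndarray) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q.

    Weights 1/se^2; Q tested against chi-square with k−1 df; I^2 =
    max(0, (Q − df)/Q) reported alongside.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    ses = np.atleast_1d(np.asarray(ses, dtype=float))
    if betas.size == 0 or betas.shape != ses.shape:
        raise InvalidArgumentError("betas and ses must be equal-length, nonempty")
    if np.any(ses <= 0):
        raise InvalidArgumentError("standard errors must be positive")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(2 * stats.norm.sf(abs(z)))
    q_df = betas.size - 1
    q = float(np.sum(w * (betas - pooled) ** 2)) if q_df > 0 else 0.0
    het_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else 1.0
    i2 = max(0.0, (q - q_df) / q) if q > 0 else 0.0
    return MetaResult(
        beta=pooled, se=pooled_se, p=p, q=q, q_df=q_df, het_p=het_p, i2=i2
    )


def stouffer_meta(
    z_scores: np.ndarray, sample_sizes: np.ndarray
) -> tuple[float, float]:
    """Stouffer pooling of signed z-scores weighted by sqrt(n).

    pooled z = sum(w_i z_i) / sqrt(sum w_i^2) with w_i = sqrt(n_i);
    returns (pooled z, two-sided p).
    """
    z = np.atleast_1d(np.asarray(z_scores, dtype=float))
    n = np.atleast_1d(np.asarray(sample_sizes, dtype=float))
    if z.size == 0 or z.shape != n.shape:
        raise InvalidArgumentError("z_scores and sample_sizes must align, nonempty")
    if np.any(n <= 0):
        raise InvalidArgumentError("sample sizes must be positive")
    w = np.sqrt(n)
    pooled = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p = float(2 * stats.norm.sf(abs(pooled)))
    return pooled, p


def bicor(
    x: np.ndarray, y: np.ndarray, mad_fallback_pearson: bool = False
) -> float:
    """Biweight midcorrelation: a median/MAD-based robust correlation.

    Deviations from the median are scaled by 9*MAD and downweighted by
    Tukey's biweight (1−u^2)^2 for |u| < 1, zero beyond; the correlation
    of the weighted deviations lies in [−1, 1] and resists gross
    outliers.  With a zero MAD the statistic is undefined; pass
    ``mad_fallback_pearson=True`` to fall back to Pearson instead of
    raising (the default error keeps pathological inputs visible).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise InvalidArgumentError("need two aligned vectors of length >= 3")

    def weighted_dev(v: np.ndarray) -> np.ndarray | None:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a = weighted_dev(x)
    b = weighted_dev(y)
    if a is None or b is None:
        if mad_fallback_pearson:
            if np.std(x) == 0 or np.std(y) == 0:
                raise UndefinedCorrelationError("zero spread in input vector")
            return float(np.corrcoef(x, y)[0, 1])
        raise UndefinedCorrelationError(
            "median absolute deviation is zero; bicor undefined"
        )
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        raise UndefinedCorrelationError("all weights vanished")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def extreme_group_contrast(
    predictor: np.ndarray,
    outcome: SurvivalOutcome,
    q: float = 0.2,
    adjust: pd.DataFrame | None = None,
    cluster: np.ndarray | None = None,
) -> CoxResult:
    """Hazard contrast of the top-q versus bottom-q predictor tails.

    Builds a 0/1 indicator (bottom tail = 0, top tail = 1, middle
    excluded) and delegates to :func:`cox_association`.  ``q=0.5`` is a
    median split with no exclusions (ties at the median go to the bottom
    group).
    """
    x = np.asarray(predictor, dtype=float)
    if not 0 < q <= 0.5:
        raise InvalidArgumentError("q must lie in (0, 0.5]")
    lo = np.quantile(x, q)
    hi = np.quantile(x, 1 - q)
    if lo > hi or (lo == hi and q < 0.5):
        raise TieResolutionError(
            "predictor ties flood the quantile tails; groups overlap"
        )
    bottom = x <= lo
    top = x >= hi
    both = bottom & top  # only possible at lo == hi (median split)
    top[both] = False
    keep = bottom | top
    indicator = np.where(top, 1.0, 0.0)[keep]
    sub_outcome = outcome.subset(keep)
    sub_adjust = None if adjust is None else pd.DataFrame(adjust)[keep]
    sub_cluster = None if cluster is None else np.asarray(cluster)[keep]
    return cox_association(indicator, sub_outcome, sub_adjust, sub_cluster)


def run_stratified_meta(
    data: pd.DataFrame,
    predictor: str,
    time: str = "time",
    event: str = "event",
    adjust: tuple[str, ...] = (),
    stratum: str = "stratum",
    cluster: str | None = None,
) -> tuple[dict[str, CoxResult], MetaResult, pd.DataFrame]:
    """Per-stratum Cox fits pooled by fixed-effect meta-analysis.

    ``data`` is a long table with one row per sample; strata failing the
    per-stratum preconditions (too few events, constant predictor,
    non-convergence) are dropped with a warning.  Returns the per-stratum
    results, the pooled :class:`MetaResult` (log-hazard scale), and a
    forest-plot-ready table (stratum, n, events, hr, ci, weight).
    """
    results: dict[str, CoxResult] = {}
    for label, grp in data.groupby(stratum, sort=True):
        try:
            outcome = SurvivalOutcome(
                time=grp[time].to_numpy(),
                event=grp[event].to_numpy(),
                cluster=None if cluster is None else grp[cluster].to_numpy(),
            )
            results[str(label)] = cox_association(
                grp[predictor].to_numpy(),
                outcome,
                adjust=grp[list(adjust)] if adjust else None,
            )
        except Exception as exc:  # degenerate stratum: flag and drop
            warnings.warn(f"stratum {label!r} dropped: {exc}", stacklevel=2)
    if not results:
        raise NoEstimableStrataError("no stratum produced an estimable fit")

    betas = np.array([r.beta for r in results.values()])
    ses = np.array([r.se for r in results.values()])
    meta = fixed_effect_meta(betas, ses)
    weights = (1.0 / ses**2) / np.sum(1.0 / ses**2)
    forest = pd.DataFrame(
        {
            "stratum": list(results),
            "n": [r.n for r in results.values()],
            "events": [r.events for r in results.values()],
            "hr": [r.hr for r in results.values()],
            "ci_low": [r.ci_low for r in results.values()],
            "ci_high": [r.ci_high for r in results.values()],
            "weight": weights,
        }
    )
    return results, meta, forest
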