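"""Stage 2: compose surrogates into a mortality clock in units of years.

A penalized Cox proportional-hazards model regresses time-to-death on the
component features (age, sex, and the stage-1 surrogates — or raw CpGs
for the single-stage comparator).  Its linear predictor X'b — the log
hazard ratio relative to baseline — is then linearly rescaled so that its
mean and variance on the training data match those of chronological age,
giving an age-like estimate; the residual of that estimate on age is the
age-acceleration measure used in association tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from sklearn.model_selection import KFold

from .errors import (
    DegenerateCalibrationError,
    DegenerateRegressionError,
    InvalidArgumentError,
    MissingFeatureError,
    NoEventsError,
)
from .outcomes import SurvivalOutcome


@dataclass
class CompositeClock:
    """A fitted composite mortality clock.

    ``cox_coefficients`` are log hazard ratios per component unit;
    ``calibration_slope``/``calibration_intercept`` map the linear
    predictor to years so that, on the training data, the calibrated
    estimate matches the mean and variance of chronological age.
    """

    component_names: list[str]
    cox_coefficients: np.ndarray
    calibration_slope: float
    calibration_intercept: float
    train_age_mean: float
    train_age_var: float
    train_lp_mean: float
    train_lp_var: float
    penalty_strength: float = float("nan")
    mixing_parameter: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.cox_coefficients = np.asarray(self.cox_coefficients, dtype=float)
        if len(self.component_names) != self.cox_coefficients.size:
            raise InvalidArgumentError("component names and coefficients must align")

    def linear_predictor(self, component_values: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.component_names if c not in component_values]
        if missing:
            raise MissingFeatureError(missing)
        X = component_values[self.component_names].to_numpy(dtype=float)
        return X @ self.cox_coefficients

    def estimate_years(self, component_values: pd.DataFrame) -> np.ndarray:
        lp = self.linear_predictor(component_values)
        return self.calibration_slope * lp + self.calibration_intercept


@dataclass
class ClockOutput:
    """Per-sample clock evaluation: years estimate, acceleration, and parts."""

    grimage: np.ndarray
    age_accel: np.ndarray
    linear_predictor: np.ndarray
    component_values: pd.DataFrame


def calibrate_to_years(
    linear_predictor: np.ndarray, age: np.ndarray
) -> tuple[float, float]:
    """Slope/intercept mapping a linear predictor onto the age scale.

    slope = sd(age)/sd(lp) and intercept = mean(age) − slope·mean(lp), so
    ``slope*lp + intercept`` reproduces the age vector's mean and
    variance exactly (sample variance, n−1 denominator).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    age = np.asarray(age, dtype=float)
    sd_lp = lp.std(ddof=1)
    if sd_lp == 0 or not np.isfinite(sd_lp):
        raise DegenerateCalibrationError("linear predictor has zero variance")
    slope = age.std(ddof=1) / sd_lp
    intercept = float(age.mean() - slope * lp.mean())
    return float(slope), intercept


def age_acceleration(estimate: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Raw residual of an age estimate regressed on chronological age.

    Ordinary least squares with intercept; residuals therefore have zero
    mean and zero Pearson correlation with age on the set they were
    residualized on (positive values = older than expected).
    """
    estimate = np.asarray(estimate, dtype=float)
    age = np.asarray(age, dtype=float)
    if estimate.size < 3:
        raise InvalidArgumentError("need at least 3 samples to residualize")
    if age.std() == 0:
        raise DegenerateRegressionError("age has zero variance")
    C = np.column_stack([np.ones_like(age), age])
    coef, *_ = np.linalg.lstsq(C, estimate, rcond=None)
    return estimate - C @ coef


def percentile_hazard(hr_per_year: float, accel_years: float) -> float:
    """Hazard ratio implied by an age-acceleration offset.

    With a per-year hazard ratio ``h``, a person ``d`` years of
    acceleration from the stratum average faces hazard ``h**d`` relative
    to that average (e.g. fast agers at +8.3 years under h=1.10 face
    about twice the average hazard; slow agers at −7.5 about half).
    """
    if hr_per_year <= 0:
        raise InvalidArgumentError("hr_per_year must be positive")
    return float(hr_per_year**accel_years)


def breslow_partial_loglik(
    linear_predictor: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow log partial likelihood of a linear predictor."""
    lp = np.asarray(linear_predictor, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")  # decreasing time
    lp, time, event = lp[order], time[order], event[order]
    # risk set of t_i = all with time >= t_i = prefix under decreasing sort;
    # ties share one risk-set denominator (Breslow)
    cum = np.logaddexp.accumulate(lp)
    loglik = 0.0
    i = 0
    n = lp.size
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        d = event[i : j + 1]
        if d.any():
            loglik += float(lp[i : j + 1][d == 1].sum()) - d.sum() * float(cum[j])
        i = j + 1
    return loglik


def _fit_coxnet_cv(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    mixing_parameter: float,
    n_folds: int,
    seed: int,
    n_alphas: int,
    penalty_factor: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Elastic-net Cox with penalty chosen by cross-validated held-out
    Breslow partial likelihood; returns (coefficients, chosen alpha).

    The penalty is the largest alpha whose mean held-out partial
    likelihood is within one standard error of the best (the
    one-standard-error rule), which keeps the composite sparse when
    components carry no mortality information.
    """
    y = Surv.from_arrays(event=outcome.event.astype(bool), time=outcome.time)
    l1_ratio = max(mixing_parameter, 1e-3)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio,
        n_alphas=n_alphas,
        normalize=True,
        penalty_factor=penalty_factor,
        fit_baseline_model=False,
    )
    path.fit(X, y)
    alphas = path.alphas_

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_scores: list[np.ndarray] = []
    for train_idx, test_idx in cv.split(X):
        if outcome.event[train_idx].sum() < 2 or outcome.event[test_idx].sum() < 1:
            continue
        fold = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio,
            alphas=alphas,
            normalize=True,
            penalty_factor=penalty_factor,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold.fit(X[train_idx], y[train_idx])
        fitted = {a: k for k, a in enumerate(fold.alphas_)}
        row = np.full(len(alphas), np.nan)
        for k, a in enumerate(alphas):
            if a not in fitted:
                continue
            lp = X[test_idx] @ fold.coef_[:, fitted[a]]
            row[k] = breslow_partial_loglik(
                lp, outcome.time[test_idx], outcome.event[test_idx]
            )
        fold_scores.append(row)
    score_matrix = np.array(fold_scores)
    complete = ~np.isnan(score_matrix).any(axis=0)
    mean_scores = np.full(len(alphas), -np.inf)
    mean_scores[complete] = score_matrix[:, complete].mean(axis=0)
    best = int(np.argmax(mean_scores))
    se_best = float(
        np.nanstd(score_matrix[:, best], ddof=1) / np.sqrt(score_matrix.shape[0])
    )
    # alphas_ is decreasing: the first index meeting the bar is the
    # largest (most parsimonious) acceptable penalty
    chosen = best
    for k in range(best + 1):
        if complete[k] and mean_scores[k] >= mean_scores[best] - se_best:
            chosen = k
            break
    # a parsimonious choice that zeroes every coefficient yields no
    # usable linear predictor; fall back to the CV optimum then
    if not path.coef_[:, chosen].any() and path.coef_[:, best].any():
        chosen = best
    return path.coef_[:, chosen], float(alphas[chosen])


def train_composite_clock(
    component_values: pd.DataFrame,
    outcome: SurvivalOutcome,
    age_column: str = "Age",
    mixing_parameter: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    unpenalized: tuple[str, ...] = (),
) -> CompositeClock:
    """Fit the composite clock on a component matrix.

    ``component_values`` holds one column per candidate component
    (chronological age, sex indicator, and the surrogate estimates); by
    default all components are penalized, matching the design in which
    even age and sex are automatically selected.  ``unpenalized`` names
    components to force-include with zero penalty (typically
    ``("Age", "Female")``), which keeps the chosen penalty large — and
    the surrogate block sparse — when a strong age effect would otherwise
    drag the cross-validated penalty toward zero.  Zero-coefficient
    components are dropped from the returned clock.  The calibration to
    years is computed on the training linear predictor and the
    ``age_column``.
    """
    if outcome.n_events < 2:
        raise NoEventsError("need at least 2 observed events")
    if age_column not in component_values:
        raise InvalidArgumentError(f"component matrix must contain {age_column!r}")
    if len(component_values) != len(outcome):
        raise InvalidArgumentError("components and outcome must align")

    frame = component_values.copy()
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant component columns: {constant}", stacklevel=2
        )
        frame = frame.drop(columns=constant)

    X = frame.to_numpy(dtype=float)
    penalty_factor = None
    if unpenalized:
        unknown = [c for c in unpenalized if c not in frame.columns]
        if unknown:
            raise InvalidArgumentError(f"unpenalized components absent: {unknown}")
        penalty_factor = np.array(
            [0.0 if c in unpenalized else 1.0 for c in frame.columns]
        )
    coef, alpha = _fit_coxnet_cv(
        X, outcome, mixing_parameter, n_folds, seed, n_alphas,
        penalty_factor=penalty_factor,
    )
    lp = X @ coef
    slope, intercept = calibrate_to_years(lp, component_values[age_column])

    keep = coef != 0
    return CompositeClock(
        component_names=[c for c, k in zip(frame.columns, keep) if k],
        cox_coefficients=coef[keep],
        calibration_slope=slope,
        calibration_intercept=intercept,
        train_age_mean=float(np.mean(component_values[age_column])),
        train_age_var=float(np.var(component_values[age_column], ddof=1)),
        train_lp_mean=float(lp.mean()),
        train_lp_var=float(lp.var(ddof=1)),
        penalty_strength=alpha,
        mixing_parameter=mixing_parameter,
        seed=seed,
    )


def train_single_stage_clock(
    methylation: pd.DataFrame,
    age: np.ndarray,
    sex: np.ndarray,
    outcome: SurvivalOutcome,
    mixing_parameter: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    unpenalized: tuple[str, ...] = (),
) -> CompositeClock:
    """Single-stage comparator: penalized Cox directly on the CpGs.

    Identical fitting and calibration machinery as the two-stage clock,
    with components = [Age, Female, all CpGs]; intended for head-to-head
    comparison on held-out data.
    """
    frame = methylation.copy()
    frame.insert(0, "Age", np.asarray(age, dtype=float))
    frame.insert(1, "Female", np.asarray(sex, dtype=float))
    return train_composite_clock(
        frame,
        outcome,
        age_column="Age",
        mixing_parameter=mixing_parameter,
        n_folds=n_folds,
        seed=seed,
        n_alphas=n_alphas,
        unpenalized=unpenalized,
    )


def apply_clock(
    clock: CompositeClock,
    component_values: pd.DataFrame,
    age: np.ndarray | None = None,
    residualize: bool = True,
    reference: tuple[float, float] | None = None,
) -> ClockOutput:
    """Evaluate a clock and derive age acceleration.

    By default the acceleration residuals are computed within the dataset
    being analyzed; ``reference=(slope, intercept)`` instead subtracts a
    stored regression of estimate on age (for applying a training-set
    residualization to new data).
    """
    lp = clock.linear_predictor(component_values)
    grim = clock.calibration_slope * lp + clock.calibration_intercept
    if age is None:
        if "Age" not in component_values:
            raise InvalidArgumentError("age vector required for acceleration")
        age = component_values["Age"].to_numpy(dtype=float)
    age = np.asarray(age, dtype=float)
    if reference is not None:
        slope, intercept = reference
        accel = grim - (intercept + slope * age)
    elif residualize:
        accel = age_acceleration(grim, age)
    else:
        accel = grim - age
    return ClockOutput(
        grimage=grim,
        age_accel=accel,
        linear_predictor=lp,
        component_values=component_values,
    )


def apply_coefficient_table(
    table,
    methylation: pd.DataFrame,
    age: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    missing_policy: str = "error",
    reference_medians: pd.Series | dict | None = None,
) -> np.ndarray:
    """Apply an external linear score (coefficient table) to new samples.

    ``table`` is any object with a ``weights`` mapping of feature id to
    weight (see :class:`grimclock.io.CoefficientTable`); the reserved ids
    ``Intercept``, ``Age`` and ``Female`` address the intercept and
    covariates.  CpGs absent from the matrix are filled with reference
    medians (or the in-matrix median of partially observed columns) under
    ``missing_policy="median-impute"``, else raise.
    """
    weights = dict(table.weights if hasattr(table, "weights") else table)
    n = len(methylation)
    score = np.full(n, float(weights.pop("Intercept", 0.0)))
    if "Age" in weights:
        if age is None:
            raise InvalidArgumentError("table uses Age but no age vector given")
        score = score + weights.pop("Age") * np.asarray(age, dtype=float)
    if "Female" in weights:
        if sex is None:
            raise InvalidArgumentError("table uses Female but no sex vector given")
        score = score + weights.pop("Female") * np.asarray(sex, dtype=float)

    missing = [c for c in weights if c not in methylation.columns]
    if missing:
        if missing_policy != "median-impute":
            raise MissingFeatureError(missing)
        unresolvable = [
            c
            for c in missing
            if reference_medians is None or c not in reference_medians
        ]
        if unresolvable:
            raise MissingFeatureError(
                unresolvable, "absent CpGs need reference medians for imputation"
            )
    for cpg, w in weights.items():
        if cpg in methylation.columns:
            col = methylation[cpg].to_numpy(dtype=float)
            if np.isnan(col).any():
                if missing_policy != "median-impute":
                    raise MissingFeatureError(
                        [cpg], f"CpG {cpg!r} has missing values under policy=error"
                    )
                fill = (
                    float(reference_medians[cpg])
                    if reference_medians is not None and cpg in reference_medians
                    else float(np.nanmedian(col))
                )
                col = np.where(np.isnan(col), fill, col)
        else:
            col = np.full(n, float(reference_medians[cpg]))
        score = score + w * col
    return score
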