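"""Stage 1: train, evaluate, and select DNAm surrogate biomarkers.

Each surrogate is a sparse linear estimator of one plasma-protein level
(or smoking pack-years) built from CpG beta values plus chronological age
and sex.  Fitting is elastic net with the penalty strength chosen by
k-fold cross-validation; age and sex enter unpenalized by default.  A
surrogate is retained for the composite clock only if its prediction
correlates with the observed target above a threshold (default r > 0.35)
in both the training and the test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .errors import (
    DegenerateTargetError,
    ImputationError,
    InvalidArgumentError,
    MissingFeatureError,
)

SELECTION_THRESHOLD = 0.35


@dataclass
class SurrogateModel:
    """Sparse linear estimator of one biomarker from CpGs, age, and sex.

    Prediction is purely linear:
    ``intercept + age*age_weight + sex*sex_weight + beta . cpg_weights``.
    Only CpGs with nonzero weight are stored.
    """

    target_name: str
    cpg_ids: list[str]
    cpg_weights: np.ndarray
    age_weight: float
    sex_weight: float
    intercept: float
    penalty_strength: float  # cross-validated lambda
    mixing_parameter: float

    def __post_init__(self) -> None:
        self.cpg_weights = np.asarray(self.cpg_weights, dtype=float)
        if len(self.cpg_ids) != self.cpg_weights.size:
            raise InvalidArgumentError("cpg_ids and cpg_weights must align")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise InvalidArgumentError("cpg_ids must be unique")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)


@dataclass
class SurrogateReport:
    """Train/test reproducibility of one surrogate and its selection flag."""

    target_name: str
    train_r: float
    test_r: float
    n_cpgs_selected: int
    selected: bool
    undefined_correlation: bool = False


def impute_median(
    values: pd.DataFrame | np.ndarray,
    reference_medians: pd.Series | dict | None = None,
) -> pd.DataFrame | np.ndarray:
    """Replace missing entries by the column median.

    With ``reference_medians`` (e.g. medians stored from a training
    cohort), those values are used for the matching columns instead of
    the in-matrix medians.  Observed entries are never touched.
    """
    is_frame = isinstance(values, pd.DataFrame)
    frame = values.copy() if is_frame else pd.DataFrame(np.asarray(values, float))
    if not is_frame:
        frame = frame.copy()
    for col in frame.columns:
        column = frame[col]
        if not column.isna().any():
            continue
        if reference_medians is not None and col in reference_medians:
            fill = reference_medians[col]
        elif column.notna().any():
            fill = column.median()
        else:
            raise ImputationError(
                f"column {col!r} is fully missing and no reference median given"
            )
        frame[col] = column.fillna(fill)
    return frame if is_frame else frame.to_numpy()


def _residualizer(age: np.ndarray, sex: np.ndarray):
    """Return (C, project) for the covariate block [1, age, sex]."""
    C = np.column_stack([np.ones_like(age, dtype=float), age, sex])

    def residualize(M: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(C, M, rcond=None)
        return M - C @ coef

    return C, residualize


def train_surrogate(
    methylation: pd.DataFrame,
    age: np.ndarray,
    sex: np.ndarray,
    target: np.ndarray,
    target_name: str = "target",
    mixing_parameter: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    penalize_covariates: bool = False,
    n_alphas: int = 30,
    path_eps: float = 0.05,
    tol: float = 1e-3,
    penalty_strength: float | None = None,
    cpg_whitelist: list[str] | None = None,
) -> SurrogateModel:
    """Fit one elastic-net surrogate of ``target`` on [age, sex, CpGs].

    The penalty strength is chosen at the minimum of the ``n_folds``-fold
    cross-validated squared prediction error.  By default age and sex are
    unpenalized adjustment covariates: the target and the (internally
    standardized) CpG matrix are first residualized on [1, age, sex],
    which yields the exact solution of the partially-penalized convex
    problem, and the covariate weights are then recovered by least
    squares given the fitted CpG block.  With
    ``penalize_covariates=True`` age and sex join the penalized design
    instead.

    Returns the sparse model with only nonzero CpG weights retained,
    with coefficients on the original beta scale.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    y = np.asarray(target, dtype=float)
    if not (len(methylation) == age.size == sex.size == y.size):
        raise InvalidArgumentError("methylation, age, sex, target must align")
    if n_folds < 2:
        raise InvalidArgumentError("n_folds must be >= 2")
    if not 0 <= mixing_parameter <= 1:
        raise InvalidArgumentError("mixing_parameter must lie in [0, 1]")
    if np.std(y) == 0:
        raise DegenerateTargetError(f"target {target_name!r} is constant")

    if cpg_whitelist is not None:
        keep = [c for c in methylation.columns if c in set(cpg_whitelist)]
        methylation = methylation[keep]
    X = methylation.to_numpy(dtype=float)
    cpg_ids = np.asarray(methylation.columns)

    # standardize CpGs internally; zero-variance CpGs cannot be selected
    col_sd = X.std(axis=0, ddof=1)
    usable = col_sd > 0
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / col_sd[usable]

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    # l1_ratio=0 (pure ridge) is unsupported by the coordinate-descent
    # path; nudge it to a tiny L1 share.
    l1_ratio = max(mixing_parameter, 1e-3)

    if penalize_covariates:
        design = np.column_stack([Xs, (age - age.mean()) / age.std(ddof=1), sex])
        if penalty_strength is not None:
            enet = ElasticNet(alpha=penalty_strength, l1_ratio=l1_ratio, tol=tol)
        else:
            enet = ElasticNetCV(
                l1_ratio=l1_ratio, alphas=n_alphas, eps=path_eps, tol=tol,
                cv=cv, random_state=seed,
            )
        enet.fit(design, y)
        coef_cpg_std = enet.coef_[: Xs.shape[1]]
        age_w = enet.coef_[-2] / age.std(ddof=1)
        sex_w = enet.coef_[-1]
        intercept = float(
            enet.intercept_
            - np.sum(coef_cpg_std * X[:, usable].mean(axis=0) / col_sd[usable])
            - age_w * age.mean()
        )
    else:
        C, residualize = _residualizer(age, sex)
        y_r = residualize(y[:, None]).ravel()
        X_r = residualize(Xs)
        if penalty_strength is not None:
            enet = ElasticNet(
                alpha=penalty_strength, l1_ratio=l1_ratio, tol=tol,
                fit_intercept=False,
            )
        else:
            enet = ElasticNetCV(
                l1_ratio=l1_ratio,
                alphas=n_alphas,
                eps=path_eps,
                tol=tol,
                cv=cv,
                random_state=seed,
                fit_intercept=False,
            )
        enet.fit(X_r, y_r)
        coef_cpg_std = enet.coef_
        # covariate weights by OLS of (y - CpG contribution) on [1, age, sex]
        cpg_contrib = Xs @ coef_cpg_std
        gamma, *_ = np.linalg.lstsq(C, y - cpg_contrib, rcond=None)
        # unfold the internal standardization back to the beta scale
        offset = np.sum(coef_cpg_std * X[:, usable].mean(axis=0) / col_sd[usable])
        intercept = float(gamma[0] - offset)
        age_w = float(gamma[1])
        sex_w = float(gamma[2])

    beta_scale = np.zeros(X.shape[1])
    beta_scale[usable] = coef_cpg_std / col_sd[usable]
    nz = beta_scale != 0
    return SurrogateModel(
        target_name=target_name,
        cpg_ids=list(cpg_ids[nz]),
        cpg_weights=beta_scale[nz],
        age_weight=float(age_w),
        sex_weight=float(sex_w),
        intercept=intercept,
        penalty_strength=float(
            enet.alpha_ if penalty_strength is None else penalty_strength
        ),
        mixing_parameter=float(mixing_parameter),
    )


def predict_surrogate(
    model: SurrogateModel,
    methylation: pd.DataFrame,
    age: np.ndarray,
    sex: np.ndarray,
    missing_policy: str = "error",
    reference_medians: pd.Series | dict | None = None,
) -> np.ndarray:
    """Evaluate one surrogate on new samples.

    ``missing_policy="median-impute"`` fills CpGs absent from the matrix
    with the supplied reference medians; with ``"error"`` any missing CpG
    raises :class:`MissingFeatureError` listing the offending ids.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    missing = [c for c in model.cpg_ids if c not in methylation.columns]
    if missing:
        if missing_policy != "median-impute":
            raise MissingFeatureError(missing)
        if reference_medians is None or any(c not in reference_medians for c in missing):
            raise MissingFeatureError(
                missing, "missing CpGs need reference medians for imputation"
            )
    score = model.intercept + model.age_weight * age + model.sex_weight * sex
    for cpg, w in zip(model.cpg_ids, model.cpg_weights):
        if cpg in methylation.columns:
            col = methylation[cpg].to_numpy(dtype=float)
        else:
            col = np.full(len(methylation), float(reference_medians[cpg]))
        score = score + w * col
    return np.asarray(score, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """(r, undefined?) — undefined when either vector has zero spread."""
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), True
    return float(np.corrcoef(a, b)[0, 1]), False


def evaluate_and_select(
    models: list[SurrogateModel],
    train,
    test,
    threshold: float = SELECTION_THRESHOLD,
) -> list[SurrogateReport]:
    """Score each surrogate on both splits and apply the selection rule.

    ``train`` and ``test`` must expose ``methylation``, ``age``, ``sex``
    and a ``targets`` DataFrame holding each model's target column
    (:class:`~grimclock.cohort_sim.SimulatedCohort` does).  A surrogate is
    selected iff its Pearson correlation with the observed target
    strictly exceeds ``threshold`` in *both* splits.  Reports are sorted
    by target name.
    """
    reports = []
    for model in models:
        for slice_ in (train, test):
            if model.target_name not in slice_.targets.columns:
                raise InvalidArgumentError(
                    f"target {model.target_name!r} absent from cohort slice"
                )
        rs = []
        undefined = False
        for slice_ in (train, test):
            pred = predict_surrogate(
                model, slice_.methylation, slice_.age, slice_.sex
            )
            obs = slice_.targets[model.target_name].to_numpy(dtype=float)
            r, und = _pearson(pred, obs)
            undefined = undefined or und
            rs.append(r)
        selected = (not undefined) and rs[0] > threshold and rs[1] > threshold
        reports.append(
            SurrogateReport(
                target_name=model.target_name,
                train_r=rs[0],
                test_r=rs[1],
                n_cpgs_selected=model.n_cpgs,
                selected=selected,
                undefined_correlation=undefined,
            )
        )
    return sorted(reports, key=lambda r: r.target_name)
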