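"""Delimited-text and JSON formats for matrices, tables, models, and runs.

All artifacts are diff-able text: tab-separated matrices and tables, JSON
for fitted clocks, YAML for run configuration.  Every artifact written by
the CLI carries a header comment with the run seed and a hash of the
configuration so a report step can verify artifact/config consistency.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_sim import SimConfig
from .errors import InvalidArgumentError, ParseError, SchemaError, ValidationError
from .outcomes import SurvivalOutcome
from .stage1 import SurrogateModel
from .stage2 import CompositeClock

FLOAT_FORMAT = "%.17g"  # exact double round-trip
RESERVED_FEATURES = ("Intercept", "Age", "Female")
PHENOTYPE_REQUIRED = ("sample_id", "age", "sex", "time", "event")


# ---------------------------------------------------------------- helpers


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# grimclock {parts}\n"


def read_header_meta(path: str | Path) -> dict:
    """Parse the ``# grimclock k=v ...`` header comment of an artifact."""
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("# grimclock"):
        for token in first.split()[2:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    return meta


def config_hash(config: dict | "RunConfig") -> str:
    """Short stable hash of a configuration's semantic content."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ----------------------------------------------------- methylation matrix


def write_methylation(
    matrix: pd.DataFrame,
    path: str | Path,
    orientation: str = "cpg-by-sample",
    meta: dict | None = None,
) -> None:
    """Write a sample-by-CpG beta matrix as tab-separated text."""
    out = matrix.T if orientation == "cpg-by-sample" else matrix
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        out.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_methylation(
    path: str | Path, orientation: str = "cpg-by-sample"
) -> pd.DataFrame:
    """Read and validate a beta matrix; returns samples x CpGs.

    Non-numeric cells raise :class:`ParseError` with their location;
    values outside [0, 1] raise :class:`ValidationError` listing the
    offending CpG/sample pairs; duplicate identifiers are rejected.
    """
    if orientation not in ("cpg-by-sample", "sample-by-cpg"):
        raise InvalidArgumentError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, float_precision="round_trip"
    )
    matrix = raw.T if orientation == "cpg-by-sample" else raw
    matrix.index.name = "sample_id"
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate CpG ids: {dupes}")
    for col in matrix.columns:
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        bad = coerced.isna() & matrix[col].notna()
        if bad.any():
            sample = matrix.index[bad][0]
            raise ParseError(
                f"non-numeric value {matrix.loc[sample, col]!r} "
                f"at CpG {col!r}, sample {sample!r}"
            )
        matrix[col] = coerced
    values = matrix.to_numpy(dtype=float)
    out_of_range = (values < 0) | (values > 1)
    if out_of_range.any():
        rows, cols = np.nonzero(out_of_range)
        offenders = [
            f"(CpG {matrix.columns[c]!r}, sample {matrix.index[r]!r}: "
            f"{values[r, c]})"
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise ValidationError(
            f"beta values outside [0, 1]: {', '.join(offenders)}"
        )
    return matrix


# ----------------------------------------------------- phenotype table


def write_phenotypes(
    table: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        table.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_phenotypes(
    path: str | Path, required: tuple[str, ...] = PHENOTYPE_REQUIRED
) -> tuple[pd.DataFrame, SurvivalOutcome]:
    """Read a phenotype table and its survival outcome.

    Requires at minimum sample_id, age, sex, time, event; missing
    biomarker cells stay NaN for downstream median imputation.  Event
    values outside {0, 1} raise a :class:`ValidationError` naming the
    row.
    """
    table = pd.read_csv(
        path, sep="\t", comment="#", float_precision="round_trip"
    )
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"phenotype table missing required columns: {missing}")
    bad = ~table["event"].isin([0, 1])
    if bad.any():
        row = table.index[bad][0]
        raise ValidationError(
            f"event value {table.loc[row, 'event']!r} outside {{0,1}} "
            f"in row {row} (sample {table.loc[row, 'sample_id']!r})"
        )
    outcome = SurvivalOutcome(
        time=table["time"].to_numpy(dtype=float),
        event=table["event"].to_numpy(dtype=int),
        stratum=table["stratum"].to_numpy() if "stratum" in table else None,
    )
    return table, outcome


def align_samples(
    methylation: pd.DataFrame, phenotypes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Align a methylation matrix and phenotype table by sample_id.

    Returns (methylation, phenotypes, permuted) with rows in the
    phenotype table's order; raises if the sample sets differ.
    """
    pheno_ids = phenotypes["sample_id"].astype(str)
    meth_ids = methylation.index.astype(str)
    if set(pheno_ids) != set(meth_ids):
        only_p = sorted(set(pheno_ids) - set(meth_ids))[:5]
        only_m = sorted(set(meth_ids) - set(pheno_ids))[:5]
        raise ValidationError(
            f"sample sets differ (phenotypes-only: {only_p}, "
            f"methylation-only: {only_m})"
        )
    permuted = not (meth_ids == pheno_ids.to_numpy()).all()
    if permuted:
        methylation = methylation.loc[pheno_ids]
    return methylation, phenotypes, permuted


# ----------------------------------------------------- coefficient tables


@dataclass
class CoefficientTable:
    """Linear-score coefficients keyed by feature id.

    Reserved ids ``Intercept``, ``Age`` and ``Female`` address the
    intercept and covariates; all other ids are CpGs.  Feature ids are
    unique and there is at most one Intercept row.
    """

    weights: dict[str, float]
    name: str = "score"

    def __post_init__(self) -> None:
        if len(self.weights) != len(set(self.weights)):
            raise ValidationError("duplicate feature ids in coefficient table")

    @classmethod
    def from_surrogate(cls, model: SurrogateModel) -> "CoefficientTable":
        weights = {"Intercept": model.intercept}
        if model.age_weight:
            weights["Age"] = model.age_weight
        if model.sex_weight:
            weights["Female"] = model.sex_weight
        weights.update(dict(zip(model.cpg_ids, model.cpg_weights.tolist())))
        return cls(weights=weights, name=model.target_name)

    def to_surrogate(self, target_name: str | None = None) -> SurrogateModel:
        cpgs = {
            k: v for k, v in self.weights.items() if k not in RESERVED_FEATURES
        }
        return SurrogateModel(
            target_name=target_name or self.name,
            cpg_ids=list(cpgs),
            cpg_weights=np.array(list(cpgs.values())),
            age_weight=float(self.weights.get("Age", 0.0)),
            sex_weight=float(self.weights.get("Female", 0.0)),
            intercept=float(self.weights.get("Intercept", 0.0)),
            penalty_strength=float("nan"),
            mixing_parameter=float("nan"),
        )


def write_coefficient_table(
    table: CoefficientTable, path: str | Path, meta: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        fh.write("feature_id\tweight\n")
        for feature, weight in table.weights.items():
            fh.write(f"{feature}\t{FLOAT_FORMAT % weight}\n")


def read_coefficient_table(path: str | Path) -> CoefficientTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", float_precision="round_trip"
    )
    if list(df.columns) != ["feature_id", "weight"]:
        raise SchemaError(
            f"coefficient table needs columns feature_id, weight; got {list(df.columns)}"
        )
    if df["feature_id"].duplicated().any():
        dupes = df["feature_id"][df["feature_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate feature ids: {dupes}")
    if (df["feature_id"] == "Intercept").sum() > 1:
        raise ValidationError("more than one Intercept row")
    weights = dict(zip(df["feature_id"], df["weight"].astype(float)))
    return CoefficientTable(weights=weights, name=Path(path).stem)


# ----------------------------------------------------- clock JSON


def write_clock(
    clock: CompositeClock, path: str | Path, meta: dict | None = None
) -> None:
    payload = {
        "component_names": clock.component_names,
        "cox_coefficients": clock.cox_coefficients.tolist(),
        "calibration_slope": clock.calibration_slope,
        "calibration_intercept": clock.calibration_intercept,
        "train_age_mean": clock.train_age_mean,
        "train_age_var": clock.train_age_var,
        "train_lp_mean": clock.train_lp_mean,
        "train_lp_var": clock.train_lp_var,
        "penalty_strength": clock.penalty_strength,
        "mixing_parameter": clock.mixing_parameter,
        "seed": clock.seed,
        "provenance": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_clock(path: str | Path) -> CompositeClock:
    with open(path) as fh:
        payload = json.load(fh)
    return CompositeClock(
        component_names=payload["component_names"],
        cox_coefficients=np.array(payload["cox_coefficients"], dtype=float),
        calibration_slope=payload["calibration_slope"],
        calibration_intercept=payload["calibration_intercept"],
        train_age_mean=payload["train_age_mean"],
        train_age_var=payload["train_age_var"],
        train_lp_mean=payload["train_lp_mean"],
        train_lp_var=payload["train_lp_var"],
        penalty_strength=payload.get("penalty_strength", float("nan")),
        mixing_parameter=payload.get("mixing_parameter", 0.5),
        seed=payload.get("seed"),
    )


# ----------------------------------------------------- run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: paths, settings, seed."""

    seed: int = 0
    # stage-1 settings
    mixing_parameter: float = 0.5
    n_folds: int = 10
    threshold: float = 0.35
    train_fraction: float = 0.7
    missing_policy: str = "error"
    whitelist: str | None = None
    # stage-2 settings
    stage2_mixing_parameter: float = 0.5
    stage2_n_folds: int = 10
    # simulation settings
    sim: SimConfig = field(default_factory=SimConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out = asdict(self)
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sim = payload.pop("sim", {})
        if isinstance(sim, dict):
            if "age_range" in sim:
                sim["age_range"] = tuple(sim["age_range"])
            if sim.get("log_hr_per_biomarker_sd") is not None:
                sim["log_hr_per_biomarker_sd"] = tuple(
                    sim["log_hr_per_biomarker_sd"]
                )
            sim = SimConfig(**sim)
        return cls(sim=sim, **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def hash(self) -> str:
        return config_hash(self)
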