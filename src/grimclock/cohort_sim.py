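"""Synthetic methylation cohorts with the structure the clock method assumes.

The generator produces beta-valued CpG matrices, plasma-biomarker analogues
driven by sparse CpG signals plus age and sex, a pack-years-like exposure,
and proportional-hazards mortality with independent censoring.  Everything
downstream (surrogate training, composite clock fitting, survival
validation) can therefore be exercised and its effect sizes recovered
against the stored generating truth, without access-controlled array data.

The simulated world is deliberately simple: samples are independent (no
pedigree correlation), CpG noise is Gaussian on the logit scale, and the
baseline hazard is exponential.  These choices are documented in
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import InvalidArgumentError
from .outcomes import SurvivalOutcome

# Per-signal-biomarker covariate effects, in units of the standardized CpG
# signal's SD.  Plasma proteins in the source domain correlate with age at
# r ~ 0-0.9 and show modest sex differences; 0.3 / 0.15 give moderate,
# non-dominant covariate structure.
_AGE_EFFECT_SD = 0.3
_SEX_EFFECT_SD = 0.15

# Pack-years scale: mean ~10, SD ~15, floored at zero (typical cohort
# distributions are zero-inflated with a long right tail).
_PACKYEARS_MEAN = 10.0
_PACKYEARS_SD = 15.0

# Logit-scale SD of per-sample CpG noise around each CpG's baseline level.
_CPG_NOISE_SD = 0.35


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    ``log_hr_per_biomarker_sd`` gives the true log hazard ratio per SD of
    each *signal* biomarker; its length must equal ``n_signal_biomarkers``.
    """

    n_samples: int = 1000
    n_cpgs: int = 2000
    n_biomarkers: int = 20
    n_signal_biomarkers: int = 6
    cpgs_per_biomarker: int = 30
    biomarker_r2: float = 0.5
    age_range: tuple[float, float] = (50.0, 80.0)
    female_fraction: float = 0.5
    log_hr_per_biomarker_sd: tuple[float, ...] | None = None
    log_hr_per_year_age: float = 0.09
    baseline_hazard_rate: float = 0.02
    target_censoring: float = 0.3
    n_strata: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_cpgs, self.n_biomarkers, self.n_strata) < 1:
            raise InvalidArgumentError("counts must be positive")
        if not 0 <= self.n_signal_biomarkers <= self.n_biomarkers:
            raise InvalidArgumentError(
                "n_signal_biomarkers must lie in [0, n_biomarkers]"
            )
        if self.cpgs_per_biomarker > self.n_cpgs:
            raise InvalidArgumentError("cpgs_per_biomarker exceeds n_cpgs")
        if not 0 < self.biomarker_r2 < 1:
            raise InvalidArgumentError("biomarker_r2 must lie in (0, 1)")
        if not 0 <= self.target_censoring < 1:
            raise InvalidArgumentError("target_censoring must lie in [0, 1)")
        if self.baseline_hazard_rate <= 0:
            raise InvalidArgumentError("baseline_hazard_rate must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise InvalidArgumentError("age_range must be an increasing interval")
        if self.log_hr_per_biomarker_sd is None:
            self.log_hr_per_biomarker_sd = tuple(
                0.25 for _ in range(self.n_signal_biomarkers)
            )
        else:
            self.log_hr_per_biomarker_sd = tuple(self.log_hr_per_biomarker_sd)
        if len(self.log_hr_per_biomarker_sd) != self.n_signal_biomarkers:
            raise InvalidArgumentError(
                "log_hr_per_biomarker_sd must have length n_signal_biomarkers"
            )


@dataclass
class CohortTruth:
    """The generating parameters recorded alongside each cohort."""

    cpg_baselines: np.ndarray
    # per signal biomarker: CpG ids, weights, age/sex effects, and the
    # realized noiseless signal (the "true linear predictor")
    biomarker_cpg_ids: dict[str, list[str]]
    biomarker_cpg_weights: dict[str, np.ndarray]
    biomarker_age_weight: dict[str, float]
    biomarker_sex_weight: dict[str, float]
    biomarker_signal: dict[str, np.ndarray]
    log_hr_per_biomarker_sd: dict[str, float]
    log_hr_per_year_age: float
    survival_linear_predictor: np.ndarray
    stratum_log_offsets: np.ndarray


@dataclass
class SimulatedCohort:
    """One synthetic cohort: methylation, phenotypes, survival, and truth."""

    methylation: pd.DataFrame  # samples x CpGs, values in [0, 1]
    age: np.ndarray
    sex: np.ndarray  # 1 = female
    biomarkers: pd.DataFrame  # samples x biomarkers
    pack_years: np.ndarray
    outcome: SurvivalOutcome
    stratum: np.ndarray
    truth: CohortTruth
    config: SimConfig

    @property
    def sample_ids(self) -> pd.Index:
        return self.methylation.index

    @property
    def targets(self) -> pd.DataFrame:
        """Biomarkers plus pack-years, as candidate surrogate targets."""
        out = self.biomarkers.copy()
        out["pack_years"] = self.pack_years
        return out

    def subset(self, index) -> "SimulatedCohort":
        """Positional row-subset (used for train/test splits)."""
        index = np.asarray(index)
        return SimulatedCohort(
            methylation=self.methylation.iloc[index],
            age=self.age[index],
            sex=self.sex[index],
            biomarkers=self.biomarkers.iloc[index],
            pack_years=self.pack_years[index],
            outcome=self.outcome.subset(index),
            stratum=self.stratum[index],
            truth=self.truth,
            config=self.config,
        )

    def phenotype_frame(self) -> pd.DataFrame:
        """Phenotype table in the on-disk layout (one row per sample)."""
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "age": self.age, "sex": self.sex}
        )
        for name in self.biomarkers.columns:
            df[name] = self.biomarkers[name].to_numpy()
        df["pack_years"] = self.pack_years
        df["time"] = self.outcome.time
        df["event"] = self.outcome.event
        df["stratum"] = self.stratum
        return df


def simulate_methylation(
    n_samples: int, n_cpgs: int, seed: int, noise_sd: float = _CPG_NOISE_SD
) -> pd.DataFrame:
    """Draw a sample-by-CpG beta matrix.

    Each CpG j receives a baseline level b_j uniform on [0.05, 0.95];
    individual values are b_j perturbed by Gaussian noise on the logit
    scale and mapped back through the logistic function, so every entry
    lies strictly inside (0, 1).

    Returns a DataFrame indexed by synthetic sample ids with stable
    synthetic CpG column names (``cg000001`` ...).
    """
    if n_samples < 1 or n_cpgs < 1:
        raise InvalidArgumentError("n_samples and n_cpgs must be >= 1")
    rng = np.random.default_rng(seed)
    baselines = rng.uniform(0.05, 0.95, size=n_cpgs)
    noise = rng.normal(0.0, noise_sd, size=(n_samples, n_cpgs))
    values = expit(logit(baselines)[None, :] + noise)
    cpg_ids = [f"cg{j + 1:06d}" for j in range(n_cpgs)]
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    df = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                      columns=cpg_ids)
    df.attrs["cpg_baselines"] = baselines
    return df


def simulate_survival(
    linear_predictor: np.ndarray,
    baseline_hazard_rate: float,
    target_censoring: float,
    seed: int,
) -> SurvivalOutcome:
    """Draw right-censored exponential survival under proportional hazards.

    Event times are exponential with per-sample rate
    ``baseline_hazard_rate * exp(lp - mean(lp))``; centering the linear
    predictor keeps the marginal event-time scale comparable across
    configurations.  Censoring times are independent exponentials whose
    rate is solved numerically so the expected censored fraction equals
    ``target_censoring``; ``target_censoring=0`` disables censoring.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise InvalidArgumentError("linear predictor must be finite")
    if baseline_hazard_rate <= 0:
        raise InvalidArgumentError("baseline_hazard_rate must be positive")
    if not 0 <= target_censoring < 1:
        raise InvalidArgumentError("target_censoring must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rates = baseline_hazard_rate * np.exp(lp - lp.mean())
    event_times = rng.exponential(1.0 / rates)
    if target_censoring == 0:
        return SurvivalOutcome(time=event_times, event=np.ones(lp.size, dtype=int))

    # For exponential censoring at rate c, P(censored | rate lambda_i)
    # = c / (c + lambda_i); solve mean_i for the target fraction.
    def expected_censoring(c: float) -> float:
        return float(np.mean(c / (c + rates))) - target_censoring

    hi = rates.max() * target_censoring / (1 - target_censoring) + 1e-12
    lo = rates.min() * target_censoring / (1 - target_censoring)
    c = brentq(expected_censoring, lo * 0.5, hi * 2.0 + 1.0)
    censor_times = rng.exponential(1.0 / c, size=lp.size)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return SurvivalOutcome(time=time, event=event)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort from one :class:`SimConfig`.

    Signal biomarkers are a sparse CpG linear combination plus age and sex
    terms, with Gaussian noise scaled so the noiseless signal explains
    ``biomarker_r2`` of the realized variance.  Non-signal biomarkers are
    standard-normal noise independent of methylation.  Pack-years follow
    the same signal recipe, rescaled and floored at zero.  Mortality is
    proportional-hazards in the standardized signal biomarkers and age,
    with small multiplicative per-stratum hazard offsets when
    ``n_strata > 1``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # independent sub-streams so adding samples/CpGs perturbs nothing else
    meth_seed, pheno_seed, surv_seed = rng.integers(0, 2**31 - 1, size=3)

    methylation = simulate_methylation(cfg.n_samples, cfg.n_cpgs, int(meth_seed))
    X = methylation.to_numpy()
    cpg_ids = list(methylation.columns)

    prng = np.random.default_rng(int(pheno_seed))
    age = prng.uniform(*cfg.age_range, size=cfg.n_samples)
    sex = (prng.uniform(size=cfg.n_samples) < cfg.female_fraction).astype(int)
    age_z = _standardize(age)
    sex_c = sex - sex.mean()

    biomarker_names = [f"protein_{k + 1}" for k in range(cfg.n_biomarkers)]
    signal_names = biomarker_names[: cfg.n_signal_biomarkers]

    truth = CohortTruth(
        cpg_baselines=methylation.attrs["cpg_baselines"],
        biomarker_cpg_ids={},
        biomarker_cpg_weights={},
        biomarker_age_weight={},
        biomarker_sex_weight={},
        biomarker_signal={},
        log_hr_per_biomarker_sd={},
        log_hr_per_year_age=cfg.log_hr_per_year_age,
        survival_linear_predictor=np.zeros(cfg.n_samples),
        stratum_log_offsets=np.zeros(cfg.n_strata),
    )

    def make_signal(name: str) -> np.ndarray:
        idx = prng.choice(cfg.n_cpgs, size=cfg.cpgs_per_biomarker, replace=False)
        w = prng.normal(0.0, 1.0, size=cfg.cpgs_per_biomarker)
        cpg_part = X[:, idx] @ w
        cpg_part = _standardize(cpg_part)
        a = prng.normal(0.0, _AGE_EFFECT_SD)
        s = prng.normal(0.0, _SEX_EFFECT_SD)
        signal = cpg_part + a * age_z + s * sex_c
        truth.biomarker_cpg_ids[name] = [cpg_ids[j] for j in idx]
        truth.biomarker_cpg_weights[name] = w
        truth.biomarker_age_weight[name] = a
        truth.biomarker_sex_weight[name] = s
        truth.biomarker_signal[name] = signal
        return signal

    values = {}
    for name in biomarker_names:
        if name in signal_names:
            signal = make_signal(name)
            noise_sd = np.sqrt(
                signal.var(ddof=1) * (1 - cfg.biomarker_r2) / cfg.biomarker_r2
            )
            values[name] = signal + prng.normal(0.0, noise_sd, size=cfg.n_samples)
        else:
            values[name] = prng.normal(0.0, 1.0, size=cfg.n_samples)
    biomarkers = pd.DataFrame(values, index=methylation.index)

    py_signal = make_signal("pack_years")
    noise_sd = np.sqrt(
        py_signal.var(ddof=1) * (1 - cfg.biomarker_r2) / cfg.biomarker_r2
    )
    py_raw = py_signal + prng.normal(0.0, noise_sd, size=cfg.n_samples)
    pack_years = np.maximum(
        0.0, _PACKYEARS_MEAN + _PACKYEARS_SD * _standardize(py_raw)
    )

    stratum = np.array(
        [f"stratum_{i % cfg.n_strata + 1}" for i in range(cfg.n_samples)]
    )
    if cfg.n_strata > 1:
        offsets = np.linspace(-0.1, 0.1, cfg.n_strata)
    else:
        offsets = np.zeros(1)
    truth.stratum_log_offsets = offsets

    lp = cfg.log_hr_per_year_age * (age - age.mean())
    for name, loghr in zip(signal_names, cfg.log_hr_per_biomarker_sd):
        lp = lp + loghr * _standardize(biomarkers[name].to_numpy())
        truth.log_hr_per_biomarker_sd[name] = loghr
    lp = lp + offsets[np.arange(cfg.n_samples) % cfg.n_strata]
    truth.survival_linear_predictor = lp

    outcome = simulate_survival(
        lp, cfg.baseline_hazard_rate, cfg.target_censoring, int(surv_seed)
    )
    outcome.stratum = stratum

    return SimulatedCohort(
        methylation=methylation,
        age=age,
        sex=sex,
        biomarkers=biomarkers,
        pack_years=pack_years,
        outcome=outcome,
        stratum=stratum,
        truth=truth,
        config=cfg,
    )


def train_test_split_cohort(
    cohort: SimulatedCohort, train_fraction: float = 0.7, seed: int = 0
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Seeded random split into training and test subsets."""
    if not 0 < train_fraction < 1:
        raise InvalidArgumentError("train_fraction must lie in (0, 1)")
    n = len(cohort.age)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    return cohort.subset(order[:n_train]), cohort.subset(order[n_train:])
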