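"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import grimclock as g


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with 3 signal biomarkers out of 6 (fast to fit)."""
    cfg = g.SimConfig(
        n_samples=400,
        n_cpgs=300,
        n_biomarkers=6,
        n_signal_biomarkers=3,
        cpgs_per_biomarker=15,
        biomarker_r2=0.6,
        seed=42,
    )
    return g.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def component_survival():
    """Component matrix + survival with 3 of 8 informative components."""
    rng = np.random.default_rng(77)
    n = 1200
    age = rng.uniform(50, 80, n)
    comps = pd.DataFrame({"Age": age, "Female": rng.integers(0, 2, n).astype(float)})
    for k in range(8):
        comps[f"surr_{k + 1}"] = rng.normal(size=n)
    true = {"surr_1": 0.3, "surr_2": 0.3, "surr_3": -0.3}
    lp = 0.08 * (age - age.mean())
    for name, beta in true.items():
        lp = lp + beta * comps[name].to_numpy()
    outcome = g.simulate_survival(lp, 0.02, 0.3, seed=78)
    return comps, outcome, true
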