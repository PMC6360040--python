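import numpy as np
import pytest

from plateletscore.cohort import MarginalSpec, SimulationConfig, generate_cohort
from plateletscore.presets import study_config
from plateletscore.scoring import score_cohort


@pytest.fixture(scope="session")
def cohort():
    """One study-sized synthetic cohort (251 subjects, 125/126 sex split)."""
    return generate_cohort(study_config(seed=20240917))


@pytest.fixture(scope="session")
def scored(cohort):
    data, scores = score_cohort(cohort.data)
    return data, scores


def small_config(targets: dict[tuple[str, str], float] | None = None,
                 n: int = 251, seed: int = 0) -> SimulationConfig:
    """Four standard-normal variables with configurable rank correlations;
    used wherever the copula machinery itself is under test."""
    names = ["v1", "v2", "v3", "v4"]
    marg = {k: MarginalSpec(family="normal", loc=0.0, scale=1.0) for k in names}
    r = np.eye(4)
    if targets:
        idx = {k: i for i, k in enumerate(names)}
        for (a, b), rho in targets.items():
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
    return SimulationConfig(
        n_subjects=n, female_fraction=0.5, seed=seed, marginals=marg,
        rank_correlation=r,
    )
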