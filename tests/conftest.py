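import numpy as np
import pytest

from neurocascade import CohortConfig, generate_cohort, inject_missingness
from neurocascade.dataset import CohortDataset


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale complete cohort at the default configuration."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def missing_cohort():
    """Default cohort with the sparse missingness pattern injected."""
    cfg = CohortConfig(seed=1)
    return inject_missingness(generate_cohort(cfg), cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Small complete cohort for fast classifier tests."""
    return generate_cohort(
        CohortConfig(
            n_subjects=400,
            n_domains=6,
            vars_per_domain=4,
            n_informative=10,
            effect_size=1.0,
            seed=2,
        )
    )


def toy_dataset(values, labels, roles=None):
    """Hand-built CohortDataset: first column mmse_total, rest battery."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    if roles is None:
        roles = ["mmse_total"] + ["battery_subscore"] * (m - 1)
    names = [f"v{j}" for j in range(m)]
    return CohortDataset(
        values=values, labels=np.asarray(labels), variable_names=names, variable_roles=roles
    )
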