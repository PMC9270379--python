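import numpy as np
import pytest

from gxestab import (
    AnovaSimSpec,
    BisegSimSpec,
    McmcSettings,
    TrialDesign,
    simulate_anova_trial,
    simulate_biseg_trial,
)


@pytest.fixture(scope="session")
def study_shaped_table():
    """Balanced 43 x 4 x 3 trial drawn from the additive-effects model."""
    return simulate_anova_trial(AnovaSimSpec(seed=11))


@pytest.fixture(scope="session")
def small_table():
    """Small balanced trial (6 genotypes x 4 environments x 3 reps)."""
    return simulate_anova_trial(
        AnovaSimSpec(design=TrialDesign(6, 4, 3), seed=5)
    )


@pytest.fixture(scope="session")
def biseg_table():
    """Trial generated from the hinge model with known coefficients."""
    rng = np.random.default_rng(7)
    betas = np.column_stack(
        [rng.normal(100, 10, 8), rng.normal(1, 0.3, 8), rng.normal(0.5, 0.5, 8)]
    )
    spec = BisegSimSpec(
        betas=betas, index=np.array([-9.0, -3.0, 4.0, 8.0]), sigma=4.0, seed=7
    )
    return spec, simulate_biseg_trial(spec)


@pytest.fixture()
def quick_mcmc():
    """Short sampling protocol for unit tests."""
    return McmcSettings(n_chains=2, n_iterations=3000, burn_in=500, thin=1, seed=42)
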