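import numpy as np
import pytest

import pyrofar as pf

# Las Conchas fire sizes (ha), actual and counterfactual landscapes,
# frozen here independently of the bundled CSV so the fixture is
# checked value-by-value.
ACTUAL_SIZES = [74034, 76379, 78883, 79492, 82179,
                82263, 82428, 83019, 83339, 86471]
COUNTERFACTUAL_SIZES = [93697, 97847, 99808, 100588, 103237,
                        105645, 105974, 108534, 111411, 112049]


@pytest.fixture(scope="session")
def las_conchas():
    return pf.las_conchas_pair()


@pytest.fixture(scope="session")
def lc_curve(las_conchas):
    """KDE attribution curve for the Las Conchas pair, default settings."""
    return pf.attribution_curves(las_conchas)


@pytest.fixture(scope="session")
def treatment_experiment():
    """Paired simulation: untreated vs 5% vs 25% randomly treated
    landscapes, 2,000 fires each under common random numbers."""
    base = pf.LandscapeGrid.uniform(64, 64, 10.0)
    return pf.run_paired_experiment(
        base, [0.0, 0.05, 0.25],
        params=pf.SpreadParams(),
        config=pf.SimConfig(n_fires=2000, seed=7),
    )


def lognormal_ensemble(label, n, mu, sigma, seed):
    rng = np.random.default_rng(seed)
    return pf.FireSizeEnsemble(label, rng.lognormal(mu, sigma, n))
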