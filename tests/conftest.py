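import numpy as np
import pytest

from dlnmm.model import DLNMCountModel
from dlnmm.simulate import (
    SimConfig,
    default_crossbasis_specs,
    default_truth,
    simulate_counts,
    simulate_exposures,
)


@pytest.fixture(scope="session")
def small_panel():
    """A compact synthetic region: 3 subregions x 5 years, 2 exposures."""
    cfg = SimConfig(n_subregions=3, n_weeks=5 * 52, seed=11)
    exposures = simulate_exposures(cfg)
    specs = default_crossbasis_specs(
        exposures,
        max_lags={"temperature": 4, "precipitation": 4},
        names=["temperature", "precipitation"],
    )
    truth = default_truth(specs, exposures, n_subregions=3, seed=11, pi=0.05)
    counts = simulate_counts(exposures, truth, specs, seed=12)
    return {"config": cfg, "exposures": exposures, "specs": specs,
            "truth": truth, "counts": counts}


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """A fitted ZINB random-intercept model on the small panel."""
    model = DLNMCountModel.from_panels(
        small_panel["counts"],
        small_panel["exposures"],
        specs=small_panel["specs"],
        family="zinb",
        random_intercept=True,
    )
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
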