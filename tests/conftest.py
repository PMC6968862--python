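import numpy as np
import pytest

import cohgraph as cg


@pytest.fixture(scope="session")
def small_cohort():
    """One subject per class, 20 epochs, couplings 0 / 0.5 / 1.0 in alpha."""
    cfg = cg.SimConfig(
        n_subjects_per_class=1,
        n_epochs_per_subject=20,
        seed=11,
        planted_band="alpha",
        planted_electrodes=("T3", "Cz"),
        coupling_strength_by_class={"HA": 0.0, "AA": 0.5, "LA": 1.0},
    )
    recordings, logs, truth = cg.generate_cohort(cfg)
    return cfg, recordings, logs, truth


@pytest.fixture(scope="session")
def noise_epochs():
    """57 epochs of independent white noise across the 19 channels."""
    rng = np.random.default_rng(42)
    return cg.EpochSet(rng.standard_normal((57, 19, 200)), fs=200.0)
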