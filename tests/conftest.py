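import numpy as np
import pytest
from hypothesis import settings

from conngat.synthetic import SyntheticSpec, cohort_to_dataset, generate_cohort

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tiny_cohort():
    """12-ROI, 10-subject, 2-task cohort with a planted age effect."""
    spec = SyntheticSpec(
        n_subjects=10, n_rois=12, n_tasks=2, rank=3, effect_factors=(1,),
        effect_size=1.0, timepoints=40, noise_sd=1.0, seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_data(tiny_cohort):
    return cohort_to_dataset(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_model(tiny_data):
    """A briefly trained small model shared by forward/explainer tests."""
    from conngat.model import ConnectomeGATRegressor

    est = ConnectomeGATRegressor(
        rank=3, nmf_iters=80, epochs=40, learning_rate=3e-3, weight_decay=0.0,
        hidden_dim=4, head_hidden=12, seed=0,
    )
    return est.fit(tiny_data, train_idx=np.arange(8))
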