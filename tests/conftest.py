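import numpy as np
import pytest

from gaitaug.core import Window


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_windows(rng):
    """500 random 1024x3 windows with mixed labels."""
    out = []
    for i in range(500):
        out.append(
            Window(
                values=rng.normal(size=(1024, 3)),
                subject_id=f"S{i % 40:03d}",
                side="left" if i % 2 == 0 else "right",
                label="PD" if i % 2 == 0 else "HP",
                source_offset=100 * i,
            )
        )
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny full-effect cohort reused by pipeline-level tests."""
    from gaitaug.presets import desk_synth_config
    from gaitaug.synth import generate_cohort

    return generate_cohort(desk_synth_config(class_effect=1.0, master_seed=7, n_per_class=4))
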