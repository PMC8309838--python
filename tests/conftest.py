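import numpy as np
import pytest

import thermoga as tg


@pytest.fixture(scope="session")
def space():
    return tg.build_parameter_space()


@pytest.fixture(scope="session")
def roi_pair():
    """One synthetic cancer exam, 32x32, full mask."""
    spec = tg.SynthSpec(
        n_exams=2, image_shape=(32, 32), class_balance=0.5, seed=42
    )
    return tg.make_roi_pairs(spec)[0]


@pytest.fixture(scope="session")
def random_roi():
    rng = np.random.default_rng(5)
    values = 33.0 + rng.standard_normal((24, 24))
    return tg.RoiMatrix(values=values, mask=None, side="left")


@pytest.fixture(scope="session")
def constant_roi():
    return tg.RoiMatrix(values=np.full((16, 16), 33.0), mask=None, side="left")


@pytest.fixture(scope="session")
def small_table():
    """60 exams x 18 columns, 5 informative at effect 1.5."""
    spec = tg.SynthSpec(
        n_exams=60, n_features=18, n_informative=5, effect_size=1.5, seed=7
    )
    data, _informative = tg.make_feature_table(spec)
    return data


@pytest.fixture(scope="session")
def tiny_ga_cfg():
    return tg.GAConfig(
        population_size=14,
        generations=3,
        quotas={"selection": 1, "crossover": 4, "asexual": 2, "mutation": 1, "random": 6},
        seed=1,
    )


@pytest.fixture(scope="session")
def tiny_fs_cfg():
    return tg.FSConfig(
        population_size=14,
        generations=4,
        quotas={"selection": 2, "crossover": 4, "mutation": 1, "random": 7},
        seed=1,
    )
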