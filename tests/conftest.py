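import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import enumstack as es

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_cohort() -> es.LabeledCohort:
    return es.worked_fixture()


@pytest.fixture(scope="session")
def separable_cohort() -> es.LabeledCohort:
    """Strongly separated 3-class cohort; simple learners reach ~1.0 accuracy."""
    spec = es.SyntheticSpec(
        n_samples_per_cohort=(90,),
        n_classes=3,
        n_features=12,
        n_informative=6,
        effect_size=4.0,
        seed=42,
    )
    return es.generate_cohorts(spec)[0]


def random_prediction(n: int, classes=("A", "B", "C"), seed: int = 0):
    """A random labelled prediction problem with every class present."""
    rng = np.random.default_rng(seed)
    classes = tuple(classes)
    k = len(classes)
    labels = pd.Series(
        [classes[i % k] for i in range(n)], index=[f"s{i}" for i in range(n)]
    ).sample(frac=1.0, random_state=seed)
    probs = pd.DataFrame(
        rng.dirichlet(np.ones(k), size=n), index=labels.index, columns=classes
    )
    return labels, es.ProbabilityPrediction(classes, probs)


@pytest.fixture
def tiny_protocol() -> es.TuneProtocol:
    return es.TuneProtocol(max_iterations=3, early_stop_patience=2, seed=11)
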