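import numpy as np
import pandas as pd
import pytest

from popcellmeta import synthetic
from popcellmeta.datatypes import GROUPS, PlantedEffect

SUBCLUSTERS = [f"SC{i}" for i in range(8)]


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.generate_cohort(12, 1.0, seed=7)


@pytest.fixture(scope="session")
def small_composition(small_cohort):
    return synthetic.generate_composition(small_cohort, SUBCLUSTERS, [], seed=11)


@pytest.fixture(scope="session")
def planted_composition(small_cohort):
    effects = [PlantedEffect("SC2", "amyloid_sqrt", {g: 0.6 for g in GROUPS})]
    return (
        synthetic.generate_composition(small_cohort, SUBCLUSTERS, effects, seed=13),
        effects,
    )
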