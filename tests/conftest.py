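import numpy as np
import pandas as pd
import pytest

from cyclemap.synthetic import CohortSpec, default_panel, generate_cohort
from cyclemap.preprocess import ProliferationGate, SampleZScorer


# enough samples per condition for a rank test to be able to reach p < 0.05
SMALL_SPEC = CohortSpec(
    n_samples={"healthy": 4, "MASH": 6},
    cells_per_sample=130,
    endocycle_prob={"healthy": 0.02, "MASH": 0.10},
    seed=7,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A compact cohort (~1050 cells) for fast pipeline tests."""
    return generate_cohort(SMALL_SPEC, panel)


@pytest.fixture(scope="session")
def small_gated(small_cohort):
    """The small cohort, z-scored per sample and gated on pRB."""
    z = SampleZScorer().fit_transform(small_cohort)
    gate = ProliferationGate().fit(z)
    kept, removed = gate.split(z)
    return kept, removed, gate
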