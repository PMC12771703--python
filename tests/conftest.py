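import numpy as np
import pandas as pd
import pytest

import psaphen as pp


@pytest.fixture(scope="session")
def default_config5000():
    return pp.GeneratorConfig(n_patients=5000, seed=2)


@pytest.fixture(scope="session")
def cohort5000(default_config5000):
    cohort, truth = pp.generate_baseline(default_config5000)
    return cohort, truth


@pytest.fixture(scope="session")
def prep5000(default_config5000, cohort5000):
    cohort, truth = cohort5000
    prep = pp.prepare_cohort(cohort, default_config5000.schema())
    return prep, truth.loc[prep.cohort.index]


@pytest.fixture(scope="session")
def fit5000(prep5000):
    """K=5 mixture fit on the default synthetic cohort at n=5000."""
    prep, truth = prep5000
    model = pp.MixedMixture(n_components=5, n_restarts=10, random_state=2).fit(prep.encoded)
    return model, prep, truth


@pytest.fixture
def toy_schema():
    return pp.FeatureSchema(
        [
            pp.Feature("age", "continuous", "demographic", units="years"),
            pp.Feature("tjc68", "continuous", "tender-joint"),
            pp.Feature("sex", "binary", "demographic", ("male", "female")),
            pp.Feature(
                "race",
                "categorical",
                "demographic",
                ("White", "Black/African American", "Asian", "Native Hawaiian or Other Pacific Islander", "multiple/others"),
            ),
        ]
    )


@pytest.fixture
def toy_csv(tmp_path):
    def write(text: str, name: str = "cohort.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write
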