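import numpy as np
import pytest

from salmon.data_model import Block, ExpressionMatrix, OmicsBundle, SurvivalData
from salmon.synthetic import ModulePlan, SyntheticSpec, generate, worked_example_cohort


@pytest.fixture(scope="session")
def worked_cohort():
    return worked_example_cohort()


@pytest.fixture(scope="session")
def planted_cohort():
    """100 samples, two strongly correlated 12-gene blocks plus noise genes."""
    spec = SyntheticSpec(
        n_samples=100,
        n_genes=40,
        module_plan=[ModulePlan(12, 1.0, 0.3), ModulePlan(12, 1.0, 0.3)],
        true_log_hazard={"mrna_f1": 1.5},
        censoring=0.3,
        seed=1,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def signal_cohort():
    """n=400 cohort with one informative latent factor (coef 1.5) and three
    uninformative ones, ~30% censoring."""
    spec = SyntheticSpec(
        n_samples=400,
        n_genes=60,
        module_plan=[ModulePlan(12, 1.0, 0.3)] + [ModulePlan(8, 1.0, 0.4)] * 3,
        true_log_hazard={"mrna_f1": 1.5},
        censoring=0.3,
        seed=2,
    )
    return generate(spec)


@pytest.fixture
def toy_expr():
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 1.0, 4.0, 3.0],
            [4.0, 3.0, 2.0, 1.0],
        ]
    )
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"])


def make_survival(times, events):
    return SurvivalData(np.asarray(times, float), np.asarray(events, int))


def make_bundle(x, times, events, name="cov", feature_ids=None):
    x = np.asarray(x, float)
    if feature_ids is None:
        feature_ids = [f"x{i + 1}" for i in range(x.shape[1])]
    return OmicsBundle(
        [f"s{i + 1}" for i in range(x.shape[0])],
        {name: Block(name, x, feature_ids)},
        make_survival(times, events),
    )
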