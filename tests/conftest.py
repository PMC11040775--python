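import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import omicrate as oc

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo():
    """Small complete synthetic study with planted truth (session-shared, read-only)."""
    study, truth = oc.generate_study(oc.FixtureSpec(seed=11, n_features=150))
    return study, truth


@pytest.fixture(scope="session")
def demo_study(demo):
    return demo[0]


@pytest.fixture(scope="session")
def demo_model(demo_study):
    return demo_study.model("Differential_Expression")


@pytest.fixture()
def registry(tmp_path):
    return oc.Registry(tmp_path / "registry")


def make_results(n=10, seed=0, prefix="f"):
    """Tiny handmade results frame with conventional column names."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "feature_id": [f"{prefix}{i}" for i in range(n)],
        "logFC": rng.normal(0, 2, n),
        "t": rng.normal(0, 3, n),
        "p_value": rng.uniform(0, 1, n),
        "adj_p_value": rng.uniform(0, 1, n),
    })
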