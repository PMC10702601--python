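import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import canospec as cs
from canospec.types import SceneConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale stand with field-plot-proportioned class counts (1/100)."""
    cfg = SceneConfig(class_counts=(1088, 757, 830), n_trees=4)
    return cs.generate_stand(cfg, seed=7)


@pytest.fixture(scope="session")
def default_scene():
    """The default study-condition stand (counts = field plot / 10)."""
    return cs.generate_stand(SceneConfig(), seed=1)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run shared by pipeline + acceptance tests."""
    out = tmp_path_factory.mktemp("run")
    results = cs.run_all(None, seed=1, out_dir=out)
    return results, out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
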