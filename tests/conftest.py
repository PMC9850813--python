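import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import naspatial as ns

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path_graph():
    """Three areas in a path a-b-c."""
    return ns.build_graph([("a", "b"), ("b", "c")], ["a", "b", "c"])


@pytest.fixture
def square_graph():
    """Four areas in a 4-cycle a-b-c-d-a."""
    return ns.build_graph(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")], ["a", "b", "c", "d"]
    )


@pytest.fixture(scope="session")
def small_study():
    """A small confounded synthetic study reused across model tests."""
    cfg = ns.GeneratorConfig(n_areas=60)
    return ns.generate_study(cfg, seed=42)


def make_strata(rng: np.random.Generator, n_areas: int) -> pd.DataFrame:
    rows = []
    for i in range(n_areas):
        for s in ns.STRATA:
            pop = float(rng.integers(50, 5000))
            rows.append(
                {
                    "area_id": f"m{i}",
                    "stratum": s,
                    "population": pop,
                    "cases": int(rng.poisson(0.01 * pop)),
                }
            )
    return pd.DataFrame(rows)
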