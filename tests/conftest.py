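import numpy as np
import pytest

import solvscreen as sv


@pytest.fixture(scope="session")
def world():
    """The default synthetic dataset: 160 records at noise 0.03, seed 1."""
    spec = sv.GeneratorSpec(seed=1)
    comps = sv.generate_components(spec)
    records, truth = sv.generate_records(spec, comps)
    x, y = sv.build_feature_matrix(records)
    return {"spec": spec, "components": comps, "records": records,
            "truth": truth, "x": x, "y": y}


@pytest.fixture(scope="session")
def ensemble40(world):
    """A full 40-network ensemble trained on the default dataset (shared
    across the acceptance and screening tests; ~1 min to fit)."""
    return sv.SannEnsembleRegressor(n_networks=40, random_state=1).fit(
        world["x"], world["y"])


@pytest.fixture(scope="session")
def fixture_table():
    return sv.build_fixture()
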