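import numpy as np
import pytest

from patchpk.config import default_model
from patchpk.structural import DualRouteParams, weekly_regimen


@pytest.fixture(scope="session")
def ee_pop():
    return default_model("EE")


@pytest.fixture(scope="session")
def lng_pop():
    return default_model("LNG")


@pytest.fixture(scope="session")
def ee_regimen():
    return weekly_regimen(n_weeks=12, drugs=("EE",))


@pytest.fixture(scope="session")
def lng_regimen():
    return weekly_regimen(n_weeks=12, drugs=("LNG",))


@pytest.fixture
def simple_params():
    """CL=1 L/h, V=10 L -> k=0.1/h; convenient round numbers."""
    return DualRouteParams(CL=1.0, V=10.0, ka=1.0, F=0.3, F_rel=0.5)


def random_params(rng: np.random.Generator, drug: str, week_effects: bool = True):
    """Log-uniform random parameter draws spanning two decades."""
    lng = drug == "LNG"
    return DualRouteParams(
        CL=float(10 ** rng.uniform(0, 2)),
        V=float(10 ** rng.uniform(1, 3)),
        ka=float(10 ** rng.uniform(-2.5, -0.5)),
        F=0.27 if lng else 0.30,
        F_rel=float(rng.uniform(0.1, 0.9)),
        D2=float(rng.uniform(5.0, 150.0)) if lng else 0.0,
        zero_route_fraction_rule="first" if lng else "zero",
        wk3_V_mult=float(rng.uniform(0.7, 1.3)) if (lng and week_effects) else 1.0,
        wk3_CL_mult=float(rng.uniform(0.7, 1.3)) if (lng and week_effects) else 1.0,
    )
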