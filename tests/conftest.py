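import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import venomphylo as vp
from venomphylo.diet_scoring import (
    QualitativeDietReport,
    QuantitativeDietReport,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_tree():
    """Three-tip calibrated tree: ((A:100,B:100):200,C:300); in Myr."""
    return vp.read_newick("((A:100,B:100):200,C:300);")


@pytest.fixture
def deep_toy_tree():
    """Five-hundred-Myr tree where A diverged from C 3.0 and from E 5.0
    Hmya ago."""
    return vp.read_newick("(((A:100,B:100):200,C:300):200,E:500);")


@pytest.fixture
def table1_reports():
    """The worked qualitative + quantitative diet example for
    Amaurobius similis: seven prey groups, three with quantitative
    proportions."""
    qual = QualitativeDietReport(
        "Amaurobius similis",
        {
            "g1": "common", "g2": "common", "g3": "major",
            "g4": "uncommon", "g5": "rare", "g6": "common", "g7": "rare",
        },
    )
    quant = QuantitativeDietReport(
        "Amaurobius similis", {"g1": 0.21, "g3": 0.75, "g5": 0.01}
    )
    return qual, quant


@pytest.fixture(scope="session")
def prey_tree():
    return vp.prey_reference_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
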