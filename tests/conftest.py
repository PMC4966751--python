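import numpy as np
import pytest

from mirtrio.io_formats import TripletAlignment
from mirtrio.synthetic_data import CategoryParams, SimulationConfig, simulate_triplets


def make_aln(human, chimp, orang, locus_id="t"):
    return TripletAlignment(human, chimp, orang, locus_id=locus_id)


@pytest.fixture(scope="session")
def small_dataset():
    """~100-locus two-category dataset shared by the slower integration tests."""
    cfg = SimulationConfig(
        seed=11,
        categories={
            "primate-specific": CategoryParams(n=60, rate_human=0.0056, rate_chimp=0.0066),
            "ConFam": CategoryParams(
                n=40, rate_human=0.0014, rate_chimp=0.0023, conservation="ConFam",
                clustered_fraction=0.5, multiple_fraction=0.6, genic_fraction=0.4,
            ),
        },
    )
    return simulate_triplets(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
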