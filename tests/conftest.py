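import warnings

import numpy as np
import pytest

import nucleoidscope as ns

# equal-occupancy stratification routinely reduces strata on a ~5 Mb genome;
# the warning is expected and would otherwise drown test output
warnings.filterwarnings("ignore", message="only .* distinct distances")


@pytest.fixture(scope="session")
def layout():
    return ns.default_layout()


@pytest.fixture(scope="session")
def small_layout():
    """1.2 Mb two-chromosome layout for fast unit tests."""
    return ns.make_genome_layout(
        {"chr1": 800_000, "chr2": 400_000},
        prophage_regions=(("chr1", 500_000, 600_000),),
    )


@pytest.fixture(scope="session")
def wt_sim(layout):
    """Default wild-type-like simulation at 10 kb: (true, observed, bias)."""
    return ns.simulate_contact_map(layout, ns.wt_params(seed=1), 10_000)


@pytest.fixture(scope="session")
def wt_balanced(wt_sim):
    _, observed, _ = wt_sim
    return ns.ice_normalize(observed)


@pytest.fixture(scope="session")
def mutant_sim(layout):
    return ns.simulate_contact_map(layout, ns.mutant_params(seed=2), 10_000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
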