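import numpy as np
import pandas as pd
import pytest

from icstme import LatticeState, RateParams, Slide
from icstme.synth import SlideSpec, generate_slide

#: all-zero kinetic rates; individual tests switch on single processes
ZERO_RATES = dict(
    r_prolif_mel=0.0,
    l=0.0,
    bC=0.0,
    bM=0.0,
    r_death_ex=0.0,
    r_hop_T=0.0,
    r_hop_M=0.0,
    r_prolif_T0=0.0,
    k_prolif=0.0,
    r_recruit0=0.0,
    k_recruit=0.0,
)


def rates(**kw) -> RateParams:
    """RateParams with every process off except the ones given."""
    return RateParams(**{**ZERO_RATES, **kw})


@pytest.fixture
def mixed_slide() -> Slide:
    """A well-mixed 200 x 200 um slide with all three input cell types."""
    return generate_slide(
        SlideSpec(
            "mixed",
            {"melanoma": 80, "t_active": 50, "tam": 30},
            width=200.0,
            height=200.0,
            seed=7,
        )
    )


@pytest.fixture
def spread_melanoma_lattice() -> LatticeState:
    """50 melanoma cells scattered on a large lattice with unlimited capacity."""
    rng = np.random.default_rng(0)
    counts = np.zeros((4, 40, 40), np.int64)
    for _ in range(50):
        counts[0, rng.integers(40), rng.integers(40)] += 1
    return LatticeState(counts, cap=10**6)


def make_cells(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["x", "y", "cell_type"])
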