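import numpy as np
import pandas as pd
import pytest

import basepro as bp


@pytest.fixture(scope="session")
def small_cohort():
    """100-sample cohort with 4 planted events; shared across read-only tests."""
    cfg = bp.SimulationConfig(
        n_samples=100,
        n_genes=2000,
        events=bp.synthetic_data.default_events(4),
        seed=11,
    )
    return bp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort_400():
    """The signature-recovery study condition: n=400, one 150-gene event of
    effect 1.0 log2 units in 20% of samples."""
    cfg = bp.SimulationConfig(
        n_samples=400,
        n_genes=2000,
        events=(bp.EventSpec("G0100_mut", carrier_fraction=0.20, set_size=150, effect=1.0),),
        seed=20,
    )
    return bp.simulate_cohort(cfg)


def write_tsv(path, text):
    path.write_text(text.replace(" | ", "\t"))
    return path
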