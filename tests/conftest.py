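import numpy as np
import pandas as pd
import pytest

from adipolipid.lipids import AbundanceTable
from adipolipid.synthetic import CohortSpec, simulate_cohort


@pytest.fixture
def small_table() -> AbundanceTable:
    """Three discordant pairs, four species, hand-chosen values."""
    subjects = ["p1_heavy", "p1_lean", "p2_heavy", "p2_lean",
                "p3_heavy", "p3_lean"]
    data = pd.DataFrame(
        [[3.0, 1.5, 4.0, 2.0, 6.0, 3.0],     # PC, heavy = 2x lean
         [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],     # PE, heavy = lean
         [2.0, 2.5, 1.0, 1.25, 4.0, 5.0],    # SM, heavy = 0.8x lean
         [8.0, 4.0, 10.0, 5.0, 12.0, 6.0]],  # TG (non-PL)
        index=["PC(16:0/18:1)", "PE(P-16:0/20:4)", "SM(d18:1/16:0)",
               "TG(52:2)"],
        columns=subjects)
    metadata = pd.DataFrame({
        "pair_id": ["p1", "p1", "p2", "p2", "p3", "p3"],
        "role": ["heavy", "lean"] * 3,
        "group": ["discordant"] * 6,
        "bmi": [30.0, 25.0, 31.0, 26.0, 29.0, 24.0],
        "fcs": [100.0, 85.0, 105.0, 88.0, 98.0, 84.0],
    }, index=subjects)
    return AbundanceTable(data=data, metadata=metadata)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort with planted effects plus its truth."""
    return simulate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
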