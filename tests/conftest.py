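import numpy as np
import pandas as pd
import pytest

from patmb.io import CohortMetadata, OtuTable
from patmb.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_table():
    """3 OTUs x 2 samples with Greengenes-style taxonomy."""
    return OtuTable(
        sample_ids=["s1", "s2"],
        otu_ids=["OTU_a", "OTU_b", "OTU_c"],
        counts=np.array([[5, 0, 3], [1, 2, 4]]),
        taxonomy={
            "OTU_a": "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Lactobacillaceae; g__Lactobacillus",
            "OTU_b": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__; g__",
            "OTU_c": "Unclassified",
        },
    )


def make_metadata(n_mice=4, days=(21, 25, 29, 33), group="control",
                  diet_switch_day=41):
    rows = []
    for m in range(n_mice):
        mouse = f"{group[0].upper()}{m + 1}"
        for t, day in enumerate(days, start=1):
            rows.append(
                {
                    "sample_id": f"{mouse}_tp{t:02d}",
                    "mouse_id": mouse,
                    "cage_id": f"{group}_c{m // 2 + 1}",
                    "group": group,
                    "day_of_life": day,
                    "timepoint_index": t,
                    "diet": "high_fat" if day >= diet_switch_day else "normal_chow",
                }
            )
    return CohortMetadata(pd.DataFrame(rows).set_index("sample_id"),
                          diet_switch_day=diet_switch_day)


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort (4 groups x 3 mice x 14 timepoints)."""
    cfg = SimulationConfig(seed=7)
    table, meta, truth = simulate_cohort(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def control_cohort():
    """A 6-mouse control-only cohort used for maturity-model tests."""
    cfg = SimulationConfig(seed=11, n_mice_per_group={"control": 6})
    table, meta, truth = simulate_cohort(cfg)
    return cfg, table, meta, truth
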