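import numpy as np
import pandas as pd
import pytest

from enterosig import AbundanceTable, default_bank


@pytest.fixture
def small_table() -> AbundanceTable:
    """Six OTUs in two phyla / four genera, four samples."""
    counts = pd.DataFrame(
        {
            "s1": [10, 5, 3, 2, 7, 1],
            "s2": [8, 6, 2, 4, 5, 0],
            "s3": [12, 3, 5, 1, 9, 2],
            "s4": [6, 7, 1, 3, 4, 1],
        },
        index=[f"otu{i}" for i in range(6)],
    )
    lineages = pd.Series(
        {
            "otu0": "k__Bacteria;p__Firmicutes;g__Lactococcus",
            "otu1": "k__Bacteria;p__Firmicutes;g__Flintibacter",
            "otu2": "k__Bacteria;p__Bacteroidetes;g__Duncaniella",
            "otu3": "k__Bacteria;p__Bacteroidetes;g__Duncaniella",
            "otu4": "k__Bacteria;p__Bacteroidetes;g__?",
            "otu5": "p__Firmicutes;g__Lactococcus",
        }
    )
    return AbundanceTable(counts=counts, lineages=lineages, level="otu")


@pytest.fixture
def three_groups():
    """Group labels for a 3x3 toy design."""
    return np.array(["ND"] * 3 + ["HFD"] * 3 + ["HFD-T070"] * 3)


@pytest.fixture
def bank():
    return default_bank(("ND", "HFD", "HFD-T070"))
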