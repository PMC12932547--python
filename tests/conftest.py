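import numpy as np
import pandas as pd
import pytest

from irmdma import AbundanceTable, StudyDesign


def make_table(values, taxa=None, samples=None, unit="percent"):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(
        pd.DataFrame(values, index=pd.Index(taxa, name="taxon"), columns=samples), unit
    )


def make_design(rows):
    """rows: (sample, site, host_role, group, replicate) tuples."""
    return StudyDesign(
        pd.DataFrame(rows, columns=["sample", "site", "host_role", "group", "replicate"])
    )


@pytest.fixture
def two_group_design():
    rows = []
    for g, site in (("A", "s1"), ("B", "s2")):
        for r in range(1, 4):
            rows.append((f"{g}{r}", site, "target", g, str(r)))
    return make_design(rows)


@pytest.fixture
def two_group_table(two_group_design):
    # 3 taxa x 6 samples, percent columns sum to 100
    vals = np.array(
        [
            [10, 20, 30, 60, 50, 40],
            [50, 40, 30, 20, 30, 40],
            [40, 40, 40, 20, 20, 20],
        ],
        dtype=float,
    )
    return make_table(vals, taxa=["Ga", "Gb", "Gc"], samples=two_group_design.samples)
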