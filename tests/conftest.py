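import numpy as np
import pytest

from xolint.datatypes import ChromosomeDataset, CrossoverSample, LengthTable, Space


@pytest.fixture
def worked_dataset() -> ChromosomeDataset:
    """Three samples on L = 1 with hand-checkable pair statistics.

    Counts (2, 1, 2): ⟨N⟩ = 5/3, φ = 12/25, d_obs = 0.7, d_noint = 0.44,
    L_int = 0.416 (all derivable by enumerating the 10 pooled pairs).
    """
    return ChromosomeDataset(
        chromosome_id="chr1",
        length_L=1.0,
        space=Space.SC_UM,
        samples=[
            CrossoverSample("a", np.array([0.2, 0.8])),
            CrossoverSample("b", np.array([0.5])),
            CrossoverSample("c", np.array([0.1, 0.9])),
        ],
    )


@pytest.fixture
def length_table() -> LengthTable:
    return LengthTable({"chr1": (30.4, 15.2), "chr2": (20.0, None)})


def dataset_from_counts(counts, length_l=1.0) -> ChromosomeDataset:
    """Samples with prescribed CO counts at evenly spread positions."""
    samples = [
        CrossoverSample(f"s{i}", np.linspace(0.1, 0.9, c) * length_l)
        for i, c in enumerate(counts)
    ]
    return ChromosomeDataset("chr", length_l, Space.SC_UM, samples)
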