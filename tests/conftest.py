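import numpy as np
import pandas as pd
import pytest

from wci.tables import TaxaCountTable


@pytest.fixture
def small_table() -> TaxaCountTable:
    """3-sample x 4-taxon table with two groups (one group of 2 is invalid,
    so a fourth sample keeps labels legal where needed)."""
    counts = pd.DataFrame(
        [[2, 3, 5, 0], [10, 0, 5, 5], [1, 1, 1, 1], [4, 4, 4, 8]],
        index=["s1", "s2", "s3", "s4"],
        columns=["TaxA", "TaxB", "TaxC", "Ralstonia"],
    )
    labels = pd.Series(["BCa", "BCa", "HC", "HC"], index=counts.index, name="group")
    return TaxaCountTable(counts=counts, labels=labels)


def random_count_table(rng: np.random.Generator, n_samples: int, n_taxa: int) -> TaxaCountTable:
    counts = pd.DataFrame(
        rng.integers(0, 60, size=(n_samples, n_taxa)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    counts.iloc[:, 0] += 1  # no zero-depth samples
    labels = pd.Series(
        ["BCa"] * (n_samples // 2) + ["HC"] * (n_samples - n_samples // 2),
        index=counts.index,
        name="group",
    )
    return TaxaCountTable(counts=counts, labels=labels)
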