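import numpy as np
import pytest

from coremarkers import BinaryLabels, ExpressionDataset


@pytest.fixture(scope="session")
def worked_example():
    """Six samples (3R/3NR), five genes: g1 and g2 separate perfectly,
    g3-g5 are constant. With Q=2 the core set must be exactly {g1, g2}."""
    values = np.array(
        [
            [10.0, 11.0, 12.0, 1.0, 2.0, 3.0],   # g1
            [8.0, 9.0, 10.0, 0.0, 1.0, 2.0],     # g2
            [5.0] * 6,                            # g3
            [5.0] * 6,                            # g4
            [5.0] * 6,                            # g5
        ]
    )
    dataset = ExpressionDataset(
        gene_ids=np.array(["g1", "g2", "g3", "g4", "g5"]),
        sample_ids=np.array([f"s{i}" for i in range(1, 7)]),
        values=values,
    )
    labels = BinaryLabels(
        dataset.sample_ids, np.array(["R", "R", "R", "NR", "NR", "NR"])
    )
    return dataset, labels


def brute_force_auc(values_r, values_nr) -> float:
    """Independent oracle: explicit double loop over all (R, NR) pairs,
    counting 1 per win and 0.5 per tie."""
    wins = 0.0
    for a in values_r:
        for b in values_nr:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(values_r) * len(values_nr))
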