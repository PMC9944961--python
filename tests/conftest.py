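import numpy as np
import pandas as pd
import pytest

import normnet as nn


@pytest.fixture(scope="session")
def small_study():
    """A 4-school cohort used by several integration-style tests."""
    config = nn.CohortConfig(n_schools=4, school_size_range=(60, 90), seed=11)
    return config, nn.generate_study(config)


@pytest.fixture(scope="session")
def small_tables(small_study):
    _, study = small_study
    table = pd.concat([t for t, _ in study], ignore_index=True)
    networks = [net for _, net in study]
    return table, networks


@pytest.fixture(scope="session")
def true_assignments(small_tables):
    """Assignment frame built from the generator's planted groups."""
    from normnet.data import side_of_group
    from normnet.influence import categorize_ego

    table, _ = small_tables
    base = table[table["wave"] == "baseline"].set_index(["school", "student"])
    follow = table[table["wave"] == "followup"].set_index(["school", "student"])
    rows = []
    for key in base.index:
        s0 = side_of_group(base.loc[key, "true_group"])
        s1 = side_of_group(follow.loc[key, "true_group"])
        rows.append(
            {
                "school": key[0],
                "student": key[1],
                "class_t0": int(base.loc[key, "true_group"]),
                "class_t1": int(follow.loc[key, "true_group"]),
                "side_t0": s0,
                "side_t1": s1,
                "transition_category": categorize_ego(s0, s1),
            }
        )
    return pd.DataFrame(rows)


def align_labels(true_z, labels, k):
    """Best-permutation agreement between two labelings."""
    from scipy.optimize import linear_sum_assignment

    cost = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            cost[a, b] = -np.sum((np.asarray(true_z) == a) & (np.asarray(labels) == b))
    r, c = linear_sum_assignment(cost)
    return -cost[r, c].sum() / len(true_z)
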