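import numpy as np
import pandas as pd
import pytest

from fibermeta import CountTable, SampleMetadata


@pytest.fixture
def tiny_table():
    return CountTable(
        ("otuA", "otuB", "otuC"),
        ("s1", "s2", "s3", "s4"),
        np.array(
            [
                [10, 0, 5, 3],
                [2, 8, 1, 9],
                [0, 4, 6, 2],
            ]
        ),
    )


@pytest.fixture
def tiny_metadata():
    rows = []
    for k, subj in enumerate(["u1", "u2"]):
        rows.append({"sample_id": f"s{2 * k + 1}", "subject_id": subj,
                     "study_id": "st1", "timepoint": "before", "order": 0})
        rows.append({"sample_id": f"s{2 * k + 2}", "subject_id": subj,
                     "study_id": "st1", "timepoint": "after", "order": 1})
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def small_study():
    """One simulated study with planted responders (seeded, modest size)."""
    from fibermeta import simulate_tree, plant_conserved_traits, \
        simulate_intervention_studies

    tree = simulate_tree(60, 0.15, seed=7)
    traits, _ = plant_conserved_traits(tree, 2, 2, 0.02, seed=7)
    studies, truth = simulate_intervention_studies(
        tree, traits, n_studies=1, subjects_per_study=10, depth_mean=3000,
        seed=7,
    )
    table, meta = studies[0]
    return table, meta, truth, tree
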