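import numpy as np
import pytest

from neurodistill import FeatureTable, SimConfig, TrialDataset, generate


@pytest.fixture
def tiny_dataset():
    """12 trials × 6 voxels, 2 ROIs, hand-built with every split present."""
    rng = np.random.default_rng(42)
    splits = (
        ["train"] * 4 + ["validation"] * 4 + ["test_perception"] * 2
        + ["test_imagery"] * 2
    )
    cats = [0, 1, 0, 1, 0, 1, 0, 1, 10, 11, 10, 11]
    return TrialDataset(
        subject_id="toy",
        activity=rng.standard_normal((12, 6)),
        trial_category=cats,
        trial_split=splits,
        trial_run=[0] * 6 + [1] * 6,
        voxel_roi=["V1", "V1", "V1", "FFA", "FFA", "FFA"],
    )


@pytest.fixture
def tiny_features():
    rng = np.random.default_rng(7)
    return [
        FeatureTable(
            feature_name="layer1",
            values=rng.standard_normal((4, 5)),
            category_ids=[0, 1, 10, 11],
            unit_ids=[f"u{i}" for i in range(5)],
        )
    ]


SMALL_SIM = SimConfig(
    n_regions=4,
    voxels_per_region=12,
    n_train_categories=20,
    n_test_categories=8,
    train_trials=80,
    test_reps_perception=4,
    test_reps_imagery=2,
    n_feature_layers=2,
    units_per_layer=6,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated subject shared across tests (read-only)."""
    return generate(SMALL_SIM)


@pytest.fixture(scope="session")
def default_sim():
    """One subject at the default study conditions (read-only)."""
    return generate(SimConfig(rng_seed=3))
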