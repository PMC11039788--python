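import numpy as np
import pytest

import braingat as bg


@pytest.fixture(scope="session")
def small_spec():
    """A miniature strong-effect cohort: fast enough for unit tests while
    exercising both planted effects."""
    return bg.SyntheticCohortSpec(
        n_subjects_per_group=6, n_roi=16, n_timepoints=64,
        planted_rois=(2, 5, 9), connectivity_effect=0.9, spectral_effect=1.0,
        oscillation_period=16, noise_sd=0.5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return bg.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return bg.featurize_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return np.array([s.label for s in small_cohort])


@pytest.fixture(scope="session")
def small_fcs(small_cohort):
    return [bg.pearson_fc(s) for s in small_cohort]


@pytest.fixture(scope="session")
def small_graphs(small_features, small_fcs, small_labels):
    adj = bg.build_adjacency(small_fcs, small_labels, threshold=0.4)
    return bg.build_graphs(small_features, adj, small_labels)
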