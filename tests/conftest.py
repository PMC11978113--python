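import numpy as np
import pytest

from mbpower import CountMatrix, default_community_model, simulate_community


@pytest.fixture(scope="session")
def reference_model():
    return default_community_model()


@pytest.fixture(scope="session")
def small_dataset(reference_model):
    """Moderate synthetic pilot dataset shared across tests."""
    return simulate_community(reference_model, 300, 30, 30, seed=101)


def make_counts(counts, group=None):
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    if group is None:
        half = n_samples // 2
        group = np.array(
            ["control"] * half + ["treatment"] * (n_samples - half), dtype=object
        )
    return CountMatrix(
        counts=counts,
        taxon_ids=[f"t{i}" for i in range(n_taxa)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        group=np.asarray(group, dtype=object),
    )


@pytest.fixture
def null_model(reference_model):
    """Reference model with the fold-change distribution degenerate at zero."""
    import copy

    model = copy.deepcopy(reference_model)
    lm = model.lfc_mixture
    lm.weights_ = np.array([1.0])
    lm.lambda_ = np.array([0.0])
    lm.mean_coefs_ = np.array([[0.0, 0.0]])
    lm.logsd_coefs_ = np.array([[-30.0, 0.0]])
    lm.n_components_ = 1
    lm.variance_form_ = "linear"
    return model
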