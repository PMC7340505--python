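import numpy as np
import pytest

import cytorisk as ck


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on test order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_planted():
    """Reduced planted cohort: 28 patients x 300 cells x 10 markers."""
    tables, manifest, truth = ck.make_fixture(
        "planted_gnp_gpp", seed=7, cells_per_patient=300, n_markers=10
    )
    return tables, manifest, truth


@pytest.fixture(scope="session")
def small_planted_fit(small_planted):
    """One fitted pipeline run on the reduced planted cohort."""
    tables, manifest, _ = small_planted
    cfg = ck.RunConfig(embedding_method="none", k_range=(4, 12), seed=7)
    return ck.RiskStratification(tables, manifest, config=cfg).fit()


@pytest.fixture(scope="session")
def two_blob():
    tables, manifest, truth = ck.make_fixture("two_blob", seed=11)
    return tables, manifest, truth


def _true_cluster_of_pooled(pooled, truth):
    """Nearest-planted-center assignment of pooled cells (ground truth)."""
    d = ((pooled.values[:, None, :] - truth.cluster_centers[None, :, :]) ** 2).sum(-1)
    return d.argmin(axis=1)


@pytest.fixture(scope="session")
def truth_mapper():
    return _true_cluster_of_pooled
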