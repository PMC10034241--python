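import numpy as np
import pytest

from flcpipe.cohort import decade_bins
from flcpipe.incidence import ClaimsBinStats
from flcpipe.simulate import CohortSimParams, LabSimParams


@pytest.fixture(scope="session")
def bins5():
    return decade_bins(50)


@pytest.fixture(scope="session")
def recovery_props(bins5):
    """Age-bin FLC proportions declining steeply with age."""
    return dict(zip(bins5, [0.5, 0.3, 0.1, 0.02, 0.005]))


@pytest.fixture(scope="session")
def claims_means(bins5):
    return dict(zip(bins5, [150.0, 300.0, 900.0, 2500.0, 6000.0]))


@pytest.fixture(scope="session")
def claims_bin_stats(bins5, claims_means):
    return [
        ClaimsBinStats(
            bin=b, mean_count=claims_means[b], sd_count=0.05 * claims_means[b],
            years_used=(2017, 2018, 2019),
        )
        for b in bins5
    ]


def make_cohort_params(bins, props, n=5000, seed=0, **kw):
    return CohortSimParams(
        n_patients=n,
        age_bin_flc_proportions=props,
        age_distribution={b: 1.0 / len(bins) for b in bins},
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def cohort_params(bins5, recovery_props):
    return make_cohort_params(bins5, recovery_props, n=5000, seed=11)


def separated_lab_params(n_clusters=4, n=400, separation=10.0, seed=42, **kw):
    """Gaussian mixture with unit scales and centers ``separation`` SDs apart."""
    centers = np.full((n_clusters, 11), 100.0)
    for i in range(n_clusters):
        centers[i, i % 11] += separation
    return LabSimParams(
        n_clusters=n_clusters,
        cluster_centers=centers,
        cluster_scales=np.ones((n_clusters, 11)),
        cluster_weights=[1.0 / n_clusters] * n_clusters,
        n_encounters=n,
        ammonia_floor=50.0,
        seed=seed,
        **kw,
    )
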