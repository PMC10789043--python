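import numpy as np
import pytest
from scipy.stats import skewnorm

from snvlink.mixture import MixtureFit, fit_count_mixture
from snvlink.simulate import AmbientMixture, SimConfig, generate_screen

#: generating parameters of the mixture-recovery study: three well-separated
#: skew-normal components on the log-count scale
MIXTURE_TRUTH = {
    "weights": np.array([0.5, 0.3, 0.2]),
    "locations": np.array([2.0, 4.0, 5.5]),
    "scales": np.array([0.4, 0.5, 0.4]),
    "alphas": np.array([2.0, -2.0, -2.0]),
}


def simulate_mixture_counts(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    t = MIXTURE_TRUTH
    comp = rng.choice(3, p=t["weights"], size=n)
    x = skewnorm.rvs(
        t["alphas"][comp], loc=t["locations"][comp], scale=t["scales"][comp],
        random_state=rng,
    )
    return np.maximum(np.rint(np.exp(x)).astype(np.int64), 1)


@pytest.fixture(scope="session")
def recovered_mixture_fit() -> MixtureFit:
    """EM fit of 20,000 counts drawn from MIXTURE_TRUTH (shared: ~5 s)."""
    counts = simulate_mixture_counts(20_000, seed=42)
    return fit_count_mixture(counts, seed=1)


def no_ambient_fit(min_count: int = 2) -> MixtureFit:
    """MixtureFit at the generating parameters with zero ambient mass."""
    m = AmbientMixture()
    return MixtureFit(
        weights=np.array([0.0, 0.6, 0.4]),
        locations=np.array(m.locations),
        scales=np.array(m.scales),
        skews=np.array(m.alphas),
        log_likelihood=0.0,
        n_observations=0,
        converged=True,
        min_count=min_count,
        max_observed=1000,
    )


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_barcodes=40, cells_per_barcode_rna=12, n_genes=300,
        n_signature_genes=30, seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


def noise_free_config(**overrides) -> SimConfig:
    """The noise-free limit: no dropout, no spurious calls, no ambient."""
    base = dict(
        dropout_rate=0.0, het_noise_rate=0.0, n_noise_sites=0,
        recurrent_artifact_sites=0, p_ambient=0.0,
        ambient_mixture=AmbientMixture(weights=(0.0, 0.6, 0.4)),
    )
    base.update(overrides)
    return small_config(**base)


@pytest.fixture(scope="session")
def small_screen():
    """A 40-barcode screen at default noise (shared across tests)."""
    return generate_screen(small_config())


@pytest.fixture(scope="session")
def noise_free_screen():
    return generate_screen(noise_free_config(seed=7))
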