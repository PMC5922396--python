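import numpy as np
import pandas as pd
import pytest

from ctcev.simulate.images import ImageSimParams, generate_cartridge
from ctcev.pipeline import extract_objects


def noiseless_params(**overrides):
    """Simulation params with the noise model and PSF switched off, so
    planted intensities and geometry are analytically exact."""
    base = dict(
        frames=2,
        frame_shape=(128, 128),
        n_ctc=0,
        n_tdev=0,
        n_leukocyte=0,
        n_bare_nucleus=0,
        n_debris=0,
        noise_sd=0.0,
        psf_sigma=0.0,
        background_level=0.0,
        seed=1,
    )
    base.update(overrides)
    return ImageSimParams(**base)


@pytest.fixture(scope="session")
def default_snr_cartridge():
    """One full cartridge at default SNR with its ground truth and extracted
    feature table (shared across tests; generation is the expensive step)."""
    params = ImageSimParams(seed=3, n_ctc=20, n_tdev=400)
    stack, truth = generate_cartridge(params)
    events = extract_objects(stack)
    return params, stack, truth, events


@pytest.fixture
def random_feature_table():
    """Random event-feature rows spanning both sides of every gate threshold."""

    def make(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "event": np.arange(n),
                "mean_dna": rng.uniform(0, 100, n),
                "mean_marker1": rng.uniform(0, 12, n),
                "mean_ck": rng.uniform(0, 150, n),
                "mean_cd45": rng.uniform(0, 12, n),
                "mean_marker2": rng.uniform(0, 12, n),
                "size_ck": rng.integers(0, 500, n),
                "dna_overlay_ck": rng.uniform(0, 1, n),
            }
        )

    return make


def simulate_survival_frame(
    n, beta_by_col, seed, baseline_rate=0.05, censor_rate=0.0125, corr=None
):
    """Small direct proportional-hazards generator for survival unit tests:
    standard-normal covariates (optionally correlated), exponential baseline,
    independent exponential censoring."""
    rng = np.random.default_rng(seed)
    cols = list(beta_by_col)
    k = len(cols)
    if corr is None:
        X = rng.normal(size=(n, k))
    else:
        X = rng.multivariate_normal(np.zeros(k), corr, size=n)
    eta = X @ np.array([beta_by_col[c] for c in cols])
    t = rng.exponential(1.0 / (baseline_rate * np.exp(eta)))
    df = pd.DataFrame(X, columns=cols)
    if censor_rate > 0:
        c = rng.exponential(1.0 / censor_rate, size=n)
        df["os_months"] = np.minimum(t, c)
        df["event"] = (t <= c).astype(int)
    else:
        df["os_months"] = t
        df["event"] = 1
    return df
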