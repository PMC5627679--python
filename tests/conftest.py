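import numpy as np
import pytest

import saxsizer as sx


@pytest.fixture(scope="session")
def truth():
    return sx.TruthSpec()


@pytest.fixture(scope="session")
def contrast(truth):
    return truth.contrast


def make_curve(truth, noise_level=0.01, seed=0, **lab_kwargs):
    lab = sx.LabProfile(noise_level=noise_level, **lab_kwargs)
    return sx.simulate_dataset(truth, lab, seed=seed)


def make_rebinned(truth, noise_level=0.01, seed=0, **lab_kwargs):
    return sx.rebin_log(sx.clip_q(make_curve(truth, noise_level, seed, **lab_kwargs)))


@pytest.fixture(scope="session")
def clean_rebinned(truth):
    """Near-noiseless rebinned curve from the default truth."""
    return make_rebinned(truth, noise_level=1e-8, seed=11)


@pytest.fixture(scope="session")
def noisy_rebinned(truth):
    """Realistically noisy (1%) rebinned curve."""
    return make_rebinned(truth, noise_level=0.01, seed=12)


@pytest.fixture(scope="session")
def small_round_robin(truth):
    """Compact 8-lab ensemble for pipeline-level tests."""
    return sx.simulate_round_robin(n_labs=8, truth=truth, master_seed=3)


@pytest.fixture(scope="session")
def fast_mc_config():
    return sx.McConfig(n_contributions=80, n_repetitions=4, max_iterations=30_000,
                       seed=5)


def exact_forward_curve(truth, n_points=90, noise_floor=0.01, dataset_id="forward"):
    """Curve generated with the same quadrature the LSQ fit uses internally
    (no noise), so a perfect fit has ~zero residuals."""
    from saxsizer.scattering_models import lognormal_grid, polydisperse_intensity

    q = np.geomspace(0.1, 3.0, n_points)
    dist = lognormal_grid(truth.params, n=200)
    I = polydisperse_intensity(q, dist, truth.contrast,
                               number_density=truth.number_density(),
                               background=truth.background)
    return sx.ScatteringCurve(dataset_id, q, I, noise_floor * np.abs(I),
                              absolute_units=True, i_unit="m^-1")
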