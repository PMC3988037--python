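import numpy as np
import pytest

from rootmech import GeneratorConfig, RootMaterialParams, table2_presets


@pytest.fixture(scope="session")
def presets():
    return table2_presets()


@pytest.fixture
def pow2_params():
    """Parameters with a power-of-two peak stress.

    Scaling by a power of two is exact in binary floating point, so
    normalising a noiseless model curve recovers the dimensionless stress
    ratios bit-for-bit; residuals against the generating modulus are then
    exactly zero rather than a few ulp.
    """
    return RootMaterialParams.from_peak(sigma_p=32.0, eps_p=0.25, E0=256.0)


@pytest.fixture
def noiseless_curve(pow2_params):
    from rootmech import generate_curve

    cfg = GeneratorConfig(params=pow2_params, n_points=101, noise_sd=0.0, seed=0)
    return generate_curve(cfg)


@pytest.fixture
def random_E_values():
    rng = np.random.default_rng(20260927)
    return 1.0 + 9.0 * rng.random(200)  # 200 draws in (1, 10]
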