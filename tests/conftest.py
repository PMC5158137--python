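import numpy as np
import pytest

from mtnet import synth


@pytest.fixture()
def parallel_network():
    """A spaced (non-overlapping) parallel network at 30 deg with its truth."""
    spec = synth.NetworkSpec(
        orientation_mode="single_angle",
        placement="spaced",
        mean_angle=30.0,
        n_filaments=15,
        seed=2,
    )
    return synth.generate_filament_image(spec)


@pytest.fixture()
def noiseless_curve():
    """A noiseless forward-modelled approach curve, E = 500 Pa, z0 = 1000 nm."""
    spec = synth.CurveSpec(youngs_modulus=500.0, deflection_noise_sd=0.0, seed=1)
    return synth.generate_force_curve(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
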