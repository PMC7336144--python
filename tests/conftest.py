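import numpy as np
import pytest

import tractofit as tf


@pytest.fixture(scope="session")
def scheme61():
    """The emulated two-shell protocol: 1 b0 + 30 + 30 directions."""
    return tf.make_gradient_scheme(1, [(1000, 30), (2000, 30)], seed=0)


@pytest.fixture(scope="session")
def crossing_phantom(scheme61):
    """Two orthogonal bundles + 30 spurious streamlines, with the signal,
    system matrix and ground-truth coefficients precomputed."""
    phantom, tractogram = tf.two_bundle_phantom(seed=11, n_streamlines=6)
    tractogram = tf.add_spurious_streamlines(tractogram, phantom, 30, seed=11)
    volume = tf.simulate_dwi(phantom, scheme61)
    sm = tf.build_system_matrix(tractogram, phantom.grid_dims,
                                phantom.voxel_size, scheme61, phantom.params,
                                phantom.ec_orientation_source())
    x_true = tf.true_coefficient_vector(phantom, tractogram, sm)
    return {"phantom": phantom, "tractogram": tractogram, "volume": volume,
            "system_matrix": sm, "x_true": x_true}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
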