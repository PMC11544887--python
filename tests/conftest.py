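import numpy as np
import pytest

from tumortract import phantom


@pytest.fixture(scope="session")
def gtab64():
    return phantom.make_gradient_table(64, 1000.0, n_b0=1, seed=7)


@pytest.fixture(scope="session")
def gtab27():
    return phantom.make_gradient_table(27, 1200.0, n_b0=1, seed=7)


@pytest.fixture(scope="session")
def gtab512():
    return phantom.make_gradient_table(512, 1200.0, n_b0=1, seed=7)


@pytest.fixture(scope="session")
def single_fiber_spec():
    """Small grid fully covered by one straight bundle along +x."""
    return phantom.PhantomSpec(
        grid_shape=(6, 6, 6),
        voxel_size=(2.0, 2.0, 2.0),
        bundles=[phantom.Bundle(centerline=[[-10.0, 6.0, 6.0], [25.0, 6.0, 6.0]],
                                radius=6.2, volume_fraction=1.0)],
    )


@pytest.fixture(scope="session")
def single_fiber_dwi(single_fiber_spec, gtab64):
    return phantom.simulate_dwi(single_fiber_spec, gtab64, snr=np.inf, seed=0)


def straight_peak_field(shape=(40, 40, 20), voxel_size=(1.0, 1.0, 1.0),
                        direction=(1.0, 0.0, 0.0)):
    """Uniform single-peak field used by tracking tests."""
    from tumortract.recon import PeakField

    d = np.zeros(shape + (1, 3))
    d[..., 0, :] = np.asarray(direction) / np.linalg.norm(direction)
    qa = np.ones(shape + (1,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size)
    aff[:3, 3] = 0.5 * np.asarray(voxel_size)
    return PeakField(directions=d, qa=qa,
                     n_peaks=np.ones(shape, dtype=np.int32),
                     voxel_size=voxel_size, affine=aff)
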