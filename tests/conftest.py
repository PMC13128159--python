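import numpy as np
import pytest

from prunedet.phantom import PhantomSpec, build_dataset


EASY_SPEC = PhantomSpec(image_size=128, tumor_count_range=(1, 2),
                        tumor_radius_range=(10, 18),
                        tumor_contrast_range=(0.5, 0.9), noise_sigma=0.02)


@pytest.fixture(scope="session")
def easy_spec():
    return EASY_SPEC


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small on-disk phantom dataset shared across tests."""
    root = tmp_path_factory.mktemp("phantoms")
    manifest = build_dataset(20, EASY_SPEC, seed=3, out_dir=root)
    return root, manifest


def numeric_grad(objective, array, eps=1e-3):
    """Central-difference gradient of a scalar objective wrt a numpy array."""
    g = np.zeros_like(array, dtype=np.float64)
    it = np.nditer(array, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = array[i]
        array[i] = orig + eps
        fp = objective()
        array[i] = orig - eps
        fm = objective()
        array[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
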