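import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, shape=(64, 64), n_seeds=4, n_grow=600):
    """Random connected blob: grow from seed pixels by repeated dilation of
    random subsets.  Guaranteed non-empty."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    r = rng.integers(8, shape[0] - 8)
    c = rng.integers(8, shape[1] - 8)
    mask[r, c] = True
    for _ in range(n_seeds):
        grown = ndimage.binary_dilation(mask, iterations=rng.integers(2, 6))
        keep = rng.random(shape) < rng.uniform(0.4, 0.9)
        mask |= grown & keep
    # keep the largest component so the blob is connected
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask.astype(np.uint8)
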