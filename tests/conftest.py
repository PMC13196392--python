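"""Shared fixtures: phantom samples and a trained desk segmenter.

Heavy artifacts are session-scoped so the suite pays for phantom generation
and segmenter training once.
"""

import numpy as np
import pytest

from osteoscreen.phantom import PhantomConfig, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def implant_config():
    return PhantomConfig(implant_probability=0.5)


@pytest.fixture(scope="session")
def one_phantom(phantom_config):
    return generate_phantom(phantom_config, seed=42)


@pytest.fixture(scope="session")
def small_cohort(phantom_config):
    samples, manifest = generate_cohort(30, 0.2, phantom_config, seed=7)
    return samples, manifest


@pytest.fixture(scope="session")
def trained_segmenter(implant_config):
    from osteoscreen.segment import train_segmenter

    train = [generate_phantom(implant_config, 500 + i) for i in range(16)]
    return train_segmenter(train, seed=3)


def brute_force_variogram(img, mask, d_max):
    """O(n^2) all-pairs oracle for the experimental variogram.

    Enumerates every ordered pixel pair at axis-aligned offsets (0, d) and
    (d, 0) with both endpoints in the mask.
    """
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = img.shape
    out = {}
    for d in range(1, d_max + 1):
        ssq, n = 0.0, 0
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                if c + d < w and mask[r, c + d]:
                    ssq += (img[r, c] - img[r, c + d]) ** 2
                    n += 1
                if r + d < h and mask[r + d, c]:
                    ssq += (img[r, c] - img[r + d, c]) ** 2
                    n += 1
        if n:
            out[d] = (ssq / (2.0 * n), n)
    return out
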