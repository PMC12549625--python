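import numpy as np
import pytest

import cubecipher as cc

#: Fixed key reused across the suite; any valid 64-hex-char string works.
KEY = "00112233445566778899aabbccddeeff00112233445566778899aabbccddeeff"


@pytest.fixture(scope="session")
def key() -> str:
    return KEY


@pytest.fixture(scope="session")
def plant_img() -> np.ndarray:
    """Default 128x128 synthetic plant fixture (seed 1)."""
    return cc.generate_plant_image(cc.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def plant_cipher(plant_img, key):
    """(ciphertext, record) of the default fixture under the fixed key."""
    return cc.encrypt(plant_img, key)


def random_key(rng: np.random.Generator) -> str:
    return bytes(rng.integers(0, 256, 32, dtype=np.uint8)).hex()


def random_image(rng: np.random.Generator, h: int, w: int, ch: int) -> np.ndarray:
    img = rng.integers(0, 256, (h, w, ch), dtype=np.uint8)
    return img[:, :, 0] if ch == 1 else img
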