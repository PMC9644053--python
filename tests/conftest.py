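from __future__ import annotations

import numpy as np
import pytest

from alseg.core_types import ImageSample, MaskStack, make_pool


def flat_sample(sid: str, value: float = 0.5, size: int = 4) -> ImageSample:
    """A uniform image with a small centered foreground square mask."""
    pixels = np.full((size, size), value)
    femur = np.zeros((size, size), dtype=np.uint8)
    femur[size // 4 : 3 * size // 4, size // 4 : 3 * size // 4] = 1
    acet = np.zeros_like(femur)
    acet[0 : size // 2, 0 : size // 2] = 1
    return ImageSample(id=sid, pixels=pixels, mask=MaskStack.from_foreground(femur, acet))


def gradient_sample(sid: str, offset: float, size: int = 4) -> ImageSample:
    """A sample whose pixel pattern is a shifted ramp (distinct per offset)."""
    base = np.linspace(0.0, 0.5, size * size).reshape(size, size)
    pixels = np.clip(base + offset, 0.0, 1.0)
    femur = (pixels > pixels.mean()).astype(np.uint8)
    acet = np.zeros_like(femur)
    acet[:, : size // 2] = 1
    return ImageSample(id=sid, pixels=pixels, mask=MaskStack.from_foreground(femur, acet))


@pytest.fixture
def ten_sample_pool():
    samples = [gradient_sample(f"s{i:02d}", offset=i * 0.05) for i in range(10)]
    return make_pool(samples, labeled_ids=["s00", "s01"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
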