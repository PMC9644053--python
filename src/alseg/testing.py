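"""Test doubles for the segmenter contract.

A :class:`ConstantSegmenter` emits a fixed probability per sample id (or a
global default), which makes entropy orderings and loop bookkeeping exactly
predictable — the AL cycle runs through its real code path at negligible
cost.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core_types import ImageSample, PredictiveEnsemble


class ConstantSegmenter:
    """Contract-satisfying stub emitting per-sample constant probabilities.

    ``probabilities`` maps sample id to the constant filling both output
    channels; unmapped ids get ``default``. ``noise_scale`` adds seeded
    uniform jitter per stochastic pass so Monte Carlo Dropout has spread
    when ``supports_dropout`` is true.
    """

    def __init__(
        self,
        probabilities: Mapping[str, float] | None = None,
        default: float = 0.5,
        supports_dropout: bool = True,
        noise_scale: float = 0.0,
    ) -> None:
        self.probabilities = dict(probabilities or {})
        self.default = default
        self.supports_dropout = supports_dropout
        self.noise_scale = noise_scale
        self.is_trained = True
        self.train_calls: list[int] = []

    def train(self, labeled, validation, config) -> None:
        self.train_calls.append(len(labeled))

    def _maps(self, samples: Sequence[ImageSample]) -> np.ndarray:
        h, w = samples[0].shape
        out = np.empty((len(samples), 2, h, w))
        for i, s in enumerate(samples):
            out[i] = self.probabilities.get(s.id, self.default)
        return out

    def predict(self, samples: Sequence[ImageSample]) -> np.ndarray:
        return self._maps(samples)

    def predict_stochastic(
        self, samples: Sequence[ImageSample], k: int, seed: int
    ) -> PredictiveEnsemble:
        base = self._maps(samples)
        rng = np.random.default_rng(seed)
        passes = np.stack(
            [
                np.clip(
                    base
                    + (
                        rng.uniform(-self.noise_scale, self.noise_scale, base.shape)
                        if self.supports_dropout and self.noise_scale > 0
                        else 0.0
                    ),
                    0.0,
                    1.0,
                )
                for _ in range(k)
            ]
        )
        return PredictiveEnsemble(
            passes=passes, ids=tuple(s.id for s in samples), seed=seed
        )
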