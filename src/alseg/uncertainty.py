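"""Monte Carlo Dropout ensembles and class-wise Shannon entropy scoring.

Uncertainty sampling needs a predictive distribution, not a point estimate.
Running inference k times with dropout active treats each dropout
configuration as a Monte Carlo draw from the model space; averaging the k
probability maps gives the mean prediction, and a per-class Shannon entropy
of that mean — computed for the femur and acetabulum sigmoid channels
separately, then averaged — scores each sample's uncertainty.

Two entropy variants are provided. The default scores each pixel as
-p log2 p, the literal class-wise form; ``variant="binary"`` uses the full
binary entropy -p log2 p - (1-p) log2 (1-p) of the sigmoid output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .core_types import ImageSample, PredictiveEnsemble, SegmenterContract

EntropyVariant = Literal["literal", "binary"]

_CLIP = 1e-7  # probability clip for the binary variant's logs


@dataclass(frozen=True)
class MeanPrediction:
    """Averaged probability maps N x C' x H x W from a k-pass ensemble."""

    maps: np.ndarray
    ids: tuple[str, ...]
    k_used: int

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=np.float64)
        if m.ndim != 4:
            raise ValueError(f"maps must be N x C x H x W, got shape {m.shape}")
        if m.shape[0] != len(self.ids):
            raise ValueError("sample axis does not match ids")
        if not np.isfinite(m).all() or m.min() < 0.0 or m.max() > 1.0:
            raise ValueError("mean prediction must be finite in [0, 1]")
        object.__setattr__(self, "maps", m)


@dataclass(frozen=True)
class EntropyScores:
    """Per-id scalar uncertainty scores, optionally with per-pixel maps."""

    scores: Mapping[str, float]
    entropy_maps: np.ndarray | None = None

    def __post_init__(self) -> None:
        for sid, val in self.scores.items():
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"entropy score for {sid!r} must be finite and >= 0")


def mc_ensemble(
    model: SegmenterContract,
    samples: Sequence[ImageSample],
    k: int = 30,
    seed: int = 0,
) -> PredictiveEnsemble:
    """Run k stochastic forward passes with dropout active.

    Reproducible given ``seed``. Rejects models without dropout layers:
    without stochastic units every pass is the deterministic prediction and
    the ensemble carries no uncertainty signal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not model.supports_dropout:
        raise ValueError(
            "Monte Carlo Dropout requires a model with dropout layers "
            "(supports_dropout is False)"
        )
    return model.predict_stochastic(samples, k=k, seed=seed)


def mean_prediction(ensemble: PredictiveEnsemble) -> MeanPrediction:
    """Elementwise arithmetic mean over the ensemble's k passes."""
    return MeanPrediction(
        maps=ensemble.passes.mean(axis=0), ids=ensemble.ids, k_used=ensemble.k
    )


def _pixel_entropy(p: np.ndarray, variant: EntropyVariant) -> np.ndarray:
    """Per-pixel entropy term; 0*log2(0) := 0 by continuity."""
    if variant == "literal":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = -p * np.log2(p)
        return np.where(p > 0, term, 0.0)
    if variant == "binary":
        q = np.clip(p, _CLIP, 1 - _CLIP)
        return -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    raise ValueError(f"unknown entropy variant {variant!r}")


def class_wise_entropy(
    prediction: MeanPrediction,
    variant: EntropyVariant = "literal",
    keep_maps: bool = False,
) -> EntropyScores:
    """Score each sample by class-wise Shannon entropy of its mean prediction.

    For each foreground channel the per-pixel entropy is averaged over all
    H x W pixels; the per-channel values are then averaged across channels.
    A score of 0 means every pixel probability is exactly 0 or 1 (the model
    is certain everywhere); all-0.5 maps score 0.5 under the literal variant.
    """
    maps = prediction.maps
    if not np.isfinite(maps).all():
        raise ValueError("non-finite probabilities in mean prediction")
    per_pixel = _pixel_entropy(maps, variant)  # N x C x H x W
    per_sample = per_pixel.mean(axis=(1, 2, 3))
    scores = {sid: float(v) for sid, v in zip(prediction.ids, per_sample)}
    return EntropyScores(
        scores=scores, entropy_maps=per_pixel if keep_maps else None
    )
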