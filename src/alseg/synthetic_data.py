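"""Synthetic hip phantoms and a small reference segmenter.

The real corpus this framework targets — ventrodorsal canine hip
radiographs — is private, so the generator emulates its statistical
structure: one grayscale image per "patient" containing two overlapping
low-contrast structures, a femoral head (filled ellipse) partially seated
in an acetabulum rendered as an annulus sector ("crescent") opening toward
it, with additive Gaussian noise and per-class binary masks whose femur
and acetabulum channels overlap where the shapes intersect. Geometry is
jittered per sample; everything is a deterministic function of
(params, seed).

The reference segmenter is a deliberately small pixel-feature multilayer
perceptron with inverted dropout: each pixel is described by its intensity,
Gaussian-smoothed intensities at three scales, a difference-of-Gaussians,
Sobel gradient magnitude, and its normalized image coordinates; a single
hidden layer maps these to two sigmoid channels (femur, acetabulum). It is
trained with the package's dice+focal objective under the standard
callback harness (LR reduction and early stopping on validation dice) and
honors the full segmenter contract, including Monte Carlo Dropout — which
is all the acquisition queries require of a model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import sobel
from skimage.transform import resize as _sk_resize

from .core_types import ImageSample, MaskStack, PredictiveEnsemble
from .metrics_losses import dice_focal_gradient, dice_score


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomParams:
    """Generator knobs for the synthetic hip-phantom corpus.

    ``contrast`` scales the foreground-over-background intensity lift in
    (0, 1]; ``noise_sigma`` is the additive Gaussian noise level; jitter
    ranges are fractions of the image's shorter side. ``clone_groups``
    optionally replaces the first ``clone_groups * clone_size`` samples
    with exact duplicates in groups, giving diversity queries something to
    collapse. Defaults are desk-scale: 64 x 64 images, a 202-image corpus,
    low contrast and visible noise.
    """

    n_images: int = 202
    image_size: tuple[int, int] = (64, 64)
    femur_radius_frac: tuple[float, float] = (0.16, 0.22)
    center_jitter_frac: float = 0.05
    cup_inner_frac: float = 0.72      # inner radius as a fraction of femur radius
    cup_outer_frac: float = 1.40      # outer radius as a fraction of femur radius
    cup_span_degrees: tuple[float, float] = (150.0, 210.0)
    contrast: float = 0.30
    noise_sigma: float = 0.08
    background_level: float = 0.30
    clone_groups: int = 0
    clone_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        h, w = self.image_size
        short = min(h, w)
        max_reach = (self.femur_radius_frac[1] * self.cup_outer_frac
                     + 2 * self.center_jitter_frac)
        if max_reach * short > short / 2:
            raise ValueError(
                "shapes not representable: cup radius plus jitter exceeds the "
                f"image half-size at image_size={self.image_size}"
            )


def _render_phantom(
    rng: np.random.Generator, params: PhantomParams
) -> tuple[np.ndarray, MaskStack]:
    h, w = params.image_size
    short = min(h, w)
    jit = params.center_jitter_frac * short

    # femoral head: filled ellipse, mildly anisotropic
    fc_r = h * 0.55 + rng.uniform(-jit, jit)
    fc_c = w * 0.48 + rng.uniform(-jit, jit)
    base_r = rng.uniform(*params.femur_radius_frac) * short
    rad_r = base_r * rng.uniform(0.9, 1.1)
    rad_c = base_r * rng.uniform(0.9, 1.1)

    rr, cc = np.mgrid[0:h, 0:w]
    femur = (((rr - fc_r) / rad_r) ** 2 + ((cc - fc_c) / rad_c) ** 2 <= 1.0)

    # acetabulum: annulus sector centered just above the head, opening down
    # onto it; inner radius below the femur radius guarantees overlap
    ac_r = fc_r - base_r * rng.uniform(0.35, 0.55)
    ac_c = fc_c + rng.uniform(-jit, jit) * 0.5
    r_in = base_r * params.cup_inner_frac
    r_out = base_r * params.cup_outer_frac
    dist = np.hypot(rr - ac_r, cc - ac_c)
    # angle measured from "up" in image coords; sector spans the upper arc
    ang = np.degrees(np.arctan2(cc - ac_c, -(rr - ac_r)))  # 0 = up, ±180 = down
    half_span = rng.uniform(*params.cup_span_degrees) / 2.0
    tilt = rng.uniform(-15.0, 15.0)
    acetabulum = (dist >= r_in) & (dist <= r_out) & (np.abs(ang - tilt) <= half_span)

    image = np.full((h, w), params.background_level)
    image += params.contrast * 0.55 * femur
    image += params.contrast * 0.35 * acetabulum
    if params.noise_sigma > 0:
        image += rng.normal(0.0, params.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    mask = MaskStack.from_foreground(
        femur.astype(np.uint8), acetabulum.astype(np.uint8)
    )
    return image, mask


def generate_phantoms(params: PhantomParams) -> list[ImageSample]:
    """Generate the synthetic corpus; bit-identical for identical params."""
    if params.n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(params.seed)
    samples: list[ImageSample] = []
    n_cloned = params.clone_groups * params.clone_size
    if n_cloned > params.n_images:
        raise ValueError("clone_groups * clone_size exceeds n_images")

    rendered: list[tuple[np.ndarray, MaskStack]] = []
    for g in range(params.clone_groups):
        rendered.extend([_render_phantom(rng, params)] * params.clone_size)
    while len(rendered) < params.n_images:
        rendered.append(_render_phantom(rng, params))

    width = len(str(params.n_images - 1))
    for i, (img, mask) in enumerate(rendered):
        samples.append(ImageSample(id=f"phantom-{i:0{width}d}", pixels=img, mask=mask))
    return samples


def split_corpus(
    samples: Sequence[ImageSample],
    fractions: tuple[float, float, float] = (0.15, 0.15, 0.03),
    seed: int = 0,
) -> tuple[list[ImageSample], list[ImageSample], list[ImageSample], list[ImageSample]]:
    """Seeded shuffle into (test, validation, initial labeled, unlabeled).

    Partition sizes are ``round half-up(N * fraction)`` for the first three
    sets; the remainder flows to the unlabeled pool. A non-zero fraction
    that rounds to an empty partition is rejected.
    """
    f_test, f_val, f_init = fractions
    if min(fractions) < 0 or sum(fractions) > 1:
        raise ValueError("fractions must be non-negative and sum to <= 1")
    n = len(samples)
    sizes = [int(math.floor(n * f + 0.5)) for f in (f_test, f_val, f_init)]
    for f, size, name in zip(fractions, sizes, ("test", "validation", "initial")):
        if f > 0 and size == 0:
            raise ValueError(f"{name} fraction {f} yields an empty partition at N={n}")
    if sum(sizes) > n:
        raise ValueError("fractions round to more samples than available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [samples[i] for i in order]
    a, b, c = sizes
    return (
        shuffled[:a],
        shuffled[a : a + b],
        shuffled[a + b : a + b + c],
        shuffled[a + b + c :],
    )


def resize_pair(
    image: np.ndarray,
    mask: MaskStack,
    target: tuple[int, int] = (544, 448),
) -> tuple[np.ndarray, MaskStack]:
    """Resize an image (bilinear) and its mask (nearest neighbor) together.

    Nearest-neighbor keeps every mask channel strictly binary, and because
    all channels share one index map the background-complement relation is
    preserved.
    """
    if target[0] < 1 or target[1] < 1:
        raise ValueError(f"target size must be positive, got {target}")
    if image.shape == tuple(target):
        return image.copy(), MaskStack(mask.channels.copy(), mask.class_names)
    out_img = _sk_resize(
        np.asarray(image, dtype=np.float64), target, order=1,
        anti_aliasing=True, preserve_range=True,
    )
    out_img = np.clip(out_img, 0.0, 1.0)
    out_ch = np.stack(
        [
            _sk_resize(ch, target, order=0, anti_aliasing=False, preserve_range=True)
            for ch in mask.channels
        ]
    ).astype(np.uint8)
    return out_img, MaskStack(out_ch, mask.class_names)


# ---------------------------------------------------------------------------
# reference segmenter
# ---------------------------------------------------------------------------

_N_FEATURES = 8


def _pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel descriptors: (H*W) x 8, float32."""
    h, w = pixels.shape
    g1 = gaussian_filter(pixels, 1.0)
    g2 = gaussian_filter(pixels, 2.0)
    g4 = gaussian_filter(pixels, 4.0)
    grad = sobel(pixels)
    rr, cc = np.mgrid[0:h, 0:w]
    feats = np.stack(
        [pixels, g1, g2, g4, g1 - g4, grad, rr / max(h - 1, 1), cc / max(w - 1, 1)],
        axis=-1,
    )
    return feats.reshape(h * w, _N_FEATURES).astype(np.float32)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    """Plain Adam over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class ReferenceSegmenter:
    """Pixel-feature MLP with one hidden layer and inverted dropout.

    Satisfies :class:`~alseg.core_types.SegmenterContract`: two sigmoid
    output channels (femur, acetabulum), deterministic given seeds, and
    ``predict_stochastic`` draws fresh dropout masks per pass so Monte
    Carlo Dropout works out of the box. With ``dropout_rate=0`` all
    stochastic passes are identical.
    """

    hidden_units: int = 24
    dropout_rate: float = 0.25
    seed: int = 0
    alpha: float = 0.25
    gamma: float = 2.0
    _params: list[np.ndarray] | None = field(default=None, repr=False)
    _feature_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    is_trained: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {self.dropout_rate}")
        rng = np.random.default_rng(self.seed)
        h = self.hidden_units
        self._params = [
            (rng.standard_normal((_N_FEATURES, h)) * np.sqrt(2.0 / _N_FEATURES)).astype(
                np.float32
            ),
            np.zeros(h, dtype=np.float32),
            (rng.standard_normal((h, 2)) * np.sqrt(2.0 / h)).astype(np.float32),
            np.zeros(2, dtype=np.float32),
        ]

    @property
    def supports_dropout(self) -> bool:
        return self.dropout_rate > 0.0

    # -- internals ----------------------------------------------------------

    def _features(self, sample: ImageSample) -> np.ndarray:
        cached = self._feature_cache.get(sample.id)
        if cached is None or cached.shape[0] != sample.pixels.size:
            cached = _pixel_features(sample.pixels)
            self._feature_cache[sample.id] = cached
        return cached

    def _forward(
        self, x: np.ndarray, dropout_rng: np.random.Generator | None
    ) -> tuple[np.ndarray, ...]:
        w1, b1, w2, b2 = self._params
        z1 = x @ w1 + b1
        # leaky ReLU: a fully dead hidden layer is an absorbing state under
        # aggressive Adam steps, and a dead model cannot recover
        a = np.where(z1 > 0, z1, 0.01 * z1)
        if dropout_rng is not None and self.dropout_rate > 0:
            keep = 1.0 - self.dropout_rate
            mask = (dropout_rng.random(a.shape) < keep).astype(np.float32) / keep
            a_d = a * mask
        else:
            mask = None
            a_d = a
        p = _sigmoid(a_d @ w2 + b2)
        return p, a_d, mask, z1

    def _predict_pixels(
        self, samples: Sequence[ImageSample], dropout_rng=None
    ) -> np.ndarray:
        """N x 2 x H x W probabilities for equally-sized samples."""
        h, w = samples[0].shape
        x = np.concatenate([self._features(s) for s in samples])
        p, *_ = self._forward(x, dropout_rng)
        return (
            p.reshape(len(samples), h * w, 2).transpose(0, 2, 1).reshape(len(samples), 2, h, w)
        ).astype(np.float64)

    # -- contract -----------------------------------------------------------

    def train(
        self,
        labeled: Sequence[ImageSample],
        validation: Sequence[ImageSample],
        config,
    ) -> None:
        """Fit from scratch with Adam on the dice+focal objective.

        Monitors validation macro dice; the learning rate is multiplied by
        ``config.lr_factor`` after ``config.lr_patience`` epochs without
        improvement and training stops after ``config.early_stop_patience``.
        """
        if not labeled:
            raise ValueError("cannot train on an empty labeled set")
        if any(s.mask is None for s in labeled):
            raise ValueError("every training sample needs a mask")
        h, w = labeled[0].shape
        rng = np.random.default_rng(config.seed)
        feats = [self._features(s) for s in labeled]
        targets = [s.mask.foreground().astype(np.float32) for s in labeled]

        opt = _Adam(self._params, config.learning_rate)
        best_val = -np.inf
        best_params: list[np.ndarray] | None = None
        since_improve = 0
        since_lr_cut = 0
        n_px = h * w
        self.history_: list[dict] = []

        frac = getattr(config, "pixel_fraction", 1.0)
        n_sub = max(1, int(round(frac * n_px)))
        flat_targets = [t.reshape(2, n_px) for t in targets]
        if validation:
            x_val = np.concatenate([self._features(s) for s in validation])
            truth_val = np.stack([s.mask.foreground() for s in validation])

        for _epoch in range(config.max_epochs):
            order = rng.permutation(len(labeled))
            for start in range(0, len(order), config.batch_size):
                idx = order[start : start + config.batch_size]
                if n_sub < n_px:
                    # a fresh pixel subsample per image each step: cheap SGD
                    # over pixels; the dice sums run over the subsample
                    px_idx = [rng.permutation(n_px)[:n_sub] for _ in idx]
                    x = np.concatenate([feats[i][px_idx[j]] for j, i in enumerate(idx)])
                    g = np.stack(
                        [flat_targets[i][:, px_idx[j]] for j, i in enumerate(idx)]
                    )[..., None]  # B x 2 x n_sub x 1
                else:
                    x = np.concatenate([feats[i] for i in idx])
                    g = np.stack([targets[i] for i in idx])  # B x 2 x H x W
                p, a_d, mask, z1 = self._forward(x, rng)
                p_maps = (
                    p.reshape(len(idx), n_sub, 2).transpose(0, 2, 1).reshape(g.shape)
                )
                dp_maps = dice_focal_gradient(
                    p_maps.astype(np.float64), g, self.alpha, self.gamma
                )
                dp = (
                    dp_maps.reshape(len(idx), 2, n_sub).transpose(0, 2, 1).reshape(-1, 2)
                ).astype(np.float32)
                dz2 = dp * p * (1.0 - p)
                w1, b1, w2, b2 = self._params
                dw2 = a_d.T @ dz2
                db2 = dz2.sum(axis=0)
                da = dz2 @ w2.T
                if mask is not None:
                    da = da * mask
                dz1 = da * np.where(z1 > 0, 1.0, 0.01).astype(np.float32)
                dw1 = x.T @ dz1
                db1 = dz1.sum(axis=0)
                opt.step(self._params, [dw1, db1, dw2, db2])

            if not validation:
                continue
            p_val, *_ = self._forward(x_val, None)
            preds = (
                p_val.reshape(len(validation), n_px, 2)
                .transpose(0, 2, 1)
                .reshape(len(validation), 2, h, w)
            )
            val_dice = dice_score(preds, truth_val).macro
            self.history_.append(
                {"epoch": _epoch, "val_dice": val_dice, "lr": opt.lr,
                 "mean_p": float(preds.mean())}
            )
            if val_dice > best_val + 1e-4:
                best_val = val_dice
                best_params = [p.copy() for p in self._params]
                since_improve = 0
                since_lr_cut = 0
            else:
                since_improve += 1
                since_lr_cut += 1
                if since_lr_cut >= config.lr_patience:
                    opt.lr *= config.lr_factor
                    since_lr_cut = 0
                if since_improve >= config.early_stop_patience:
                    break
        # keep the weights of the best validation epoch, not the last one:
        # a run that wanders into the all-background minimum late would
        # otherwise discard a good earlier fit
        if best_params is not None and best_val > 0:
            self._params = best_params
        self.is_trained = True

    def predict(self, samples: Sequence[ImageSample]) -> np.ndarray:
        if not self.is_trained:
            raise RuntimeError("the segmenter is untrained; call train() first")
        if not samples:
            raise ValueError("no samples to predict")
        return self._predict_pixels(samples)

    def predict_stochastic(
        self, samples: Sequence[ImageSample], k: int, seed: int
    ) -> PredictiveEnsemble:
        if not self.is_trained:
            raise RuntimeError("the segmenter is untrained; call train() first")
        if k < 1:
            raise ValueError("k must be >= 1")
        rng = np.random.default_rng(seed)
        h, w = samples[0].shape
        n, n_px = len(samples), samples[0].pixels.size
        w1, b1, w2, b2 = self._params
        x = np.concatenate([self._features(s) for s in samples])
        z1 = x @ w1 + b1
        a = np.where(z1 > 0, z1, 0.01 * z1)
        keep = 1.0 - self.dropout_rate
        passes = np.empty((k, n, 2, h, w))
        for j in range(k):
            if self.supports_dropout:
                # dropout acts after the shared hidden activation, so the
                # first-layer product is computed once for all k passes
                mask = (rng.random(a.shape, dtype=np.float32) < keep) / np.float32(keep)
                p = _sigmoid((a * mask) @ w2 + b2)
            else:
                p = _sigmoid(a @ w2 + b2)
            passes[j] = p.reshape(n, n_px, 2).transpose(0, 2, 1).reshape(n, 2, h, w)
        return PredictiveEnsemble(
            passes=passes, ids=tuple(s.id for s in samples), seed=seed
        )


def reference_segmenter(
    seed: int = 0, hidden_units: int = 24, dropout_rate: float = 0.25
) -> ReferenceSegmenter:
    """Factory for the reference segmenter honoring the segmenter contract.

    ``seed`` comes first so the function can be used directly as a model
    factory in the experiment loop.
    """
    return ReferenceSegmenter(
        hidden_units=hidden_units, dropout_rate=dropout_rate, seed=seed
    )
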