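"""Image features for the diversity-based queries.

The cluster-based and representative queries operate on a flattened-pixel
feature space: images are optionally thumbnailed, flattened row-major,
min-max normalized per feature, and reduced by PCA keeping 99% of the
explained variance. The pipeline is deliberately simple — the queries care
about relative geometry (cluster structure, centroid distances), not about
a learned embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.decomposition import PCA

from .core_types import ImageSample

Provenance = Literal["raw", "normalized", "reduced"]


@dataclass(frozen=True)
class FeatureMatrix:
    """N x D feature rows, one per sample id, with pipeline provenance."""

    rows: np.ndarray
    ids: tuple[str, ...]
    provenance: Provenance = "raw"

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.ndim != 2:
            raise ValueError(f"feature rows must be 2-D, got shape {rows.shape}")
        if rows.shape[0] != len(self.ids):
            raise ValueError(f"{rows.shape[0]} rows but {len(self.ids)} ids")
        if not np.isfinite(rows).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.provenance == "normalized" and rows.size:
            if rows.min() < -1e-12 or rows.max() > 1 + 1e-12:
                raise ValueError("normalized features must lie in [0, 1]")
        object.__setattr__(self, "rows", rows)

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def dim(self) -> int:
        return self.rows.shape[1]


@dataclass(frozen=True)
class PcaModel:
    """A fitted PCA basis keeping the minimal components reaching the target.

    ``components`` is d x D (row-orthonormal), ``mean`` the column means of
    the fitting data, ``explained_variance_ratio`` the per-component ratios
    of the kept components.
    """

    components: np.ndarray
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    target_variance: float = 0.99

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def flatten_images(
    samples: Sequence[ImageSample],
    thumbnail_size: tuple[int, int] | None = None,
) -> FeatureMatrix:
    """Flatten sample pixels row-major into an N x D raw feature matrix.

    With ``thumbnail_size`` each image is first resized (bilinear,
    anti-aliased) to that (H, W); without it all images must already share
    dimensions.
    """
    if not samples:
        raise ValueError("no samples to featurize")
    shapes = {s.shape for s in samples}
    if thumbnail_size is None:
        if len(shapes) > 1:
            raise ValueError(
                f"mixed image sizes {sorted(shapes)}; pass thumbnail_size to unify"
            )
        rows = np.stack([s.pixels.ravel(order="C") for s in samples])
    else:
        thumbnail_size = tuple(thumbnail_size)
        rows = np.stack(
            [
                s.pixels.ravel(order="C")
                if s.shape == thumbnail_size
                else _sk_resize(
                    s.pixels, thumbnail_size, order=1, anti_aliasing=True,
                    preserve_range=True,
                ).ravel(order="C")
                for s in samples
            ]
        )
    return FeatureMatrix(rows=rows, ids=tuple(s.id for s in samples), provenance="raw")


def min_max_normalize(features: FeatureMatrix) -> FeatureMatrix:
    """Per-feature min-max rescale of a raw matrix into [0, 1].

    Each column x maps to (x - min) / (max - min). Constant columns carry no
    information to rescale; they map to all-zero with a warning.
    """
    if features.provenance != "raw":
        raise ValueError(f"expected raw features, got {features.provenance!r}")
    if features.n == 0:
        raise ValueError("cannot normalize an empty feature matrix")
    rows = features.rows
    col_min = rows.min(axis=0)
    span = rows.max(axis=0) - col_min
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) mapped to 0",
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    out = (rows - col_min) / safe_span
    out[:, constant] = 0.0
    return FeatureMatrix(rows=out, ids=features.ids, provenance="normalized")


def fit_pca(features: FeatureMatrix, target_variance: float = 0.99) -> PcaModel:
    """Fit PCA keeping the fewest components whose cumulative explained
    variance ratio reaches ``target_variance``.

    Requires normalized features with N >= 2 and non-zero total variance.
    """
    if features.provenance != "normalized":
        raise ValueError(f"expected normalized features, got {features.provenance!r}")
    if features.n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 0 < target_variance <= 1:
        raise ValueError("target_variance must be in (0, 1]")
    rows = features.rows
    if np.allclose(rows.var(axis=0), 0.0):
        raise ValueError("no informative features: total variance is zero")
    # Fit the full basis, then cut at the minimal cumulative ratio ourselves
    # so minimality is explicit (sklearn's fractional n_components does the
    # same, but only with the 'full' solver).
    pca = PCA(svd_solver="full")
    pca.fit(rows)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, target_variance - 1e-12) + 1)
    d = min(d, len(cum))
    return PcaModel(
        components=pca.components_[:d].copy(),
        mean=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_[:d].copy(),
        target_variance=target_variance,
    )


def transform(model: PcaModel, features: FeatureMatrix) -> FeatureMatrix:
    """Mean-center and project features onto the model's retained components."""
    if features.dim != model.components.shape[1]:
        raise ValueError(
            f"feature dimension {features.dim} != model dimension "
            f"{model.components.shape[1]}"
        )
    reduced = (features.rows - model.mean) @ model.components.T
    return FeatureMatrix(rows=reduced, ids=features.ids, provenance="reduced")


def reduce_features(
    samples: Sequence[ImageSample],
    thumbnail_size: tuple[int, int] | None = None,
    target_variance: float = 0.99,
    fit_samples: Sequence[ImageSample] | None = None,
) -> FeatureMatrix:
    """Full pipeline: flatten -> min-max normalize -> PCA -> project.

    The PCA basis is fit on ``fit_samples`` when given (e.g. the union of
    labeled and unlabeled pools so both live in one space), otherwise on
    ``samples`` themselves. Normalization statistics always come from the
    fitting set so projections are comparable.
    """
    fit_set = list(fit_samples) if fit_samples is not None else list(samples)
    raw_fit = flatten_images(fit_set, thumbnail_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm_fit = min_max_normalize(raw_fit)
    model = fit_pca(norm_fit, target_variance)

    if fit_samples is None:
        return transform(model, norm_fit)
    # project the requested subset using the fitting set's statistics
    raw = flatten_images(list(samples), thumbnail_size)
    col_min = raw_fit.rows.min(axis=0)
    span = raw_fit.rows.max(axis=0) - col_min
    safe_span = np.where(span == 0, 1.0, span)
    norm_rows = np.clip((raw.rows - col_min) / safe_span, 0.0, 1.0)
    norm = FeatureMatrix(rows=norm_rows, ids=raw.ids, provenance="normalized")
    return transform(model, norm)
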