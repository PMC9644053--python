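"""Domain types shared by every module, plus the segmenter contract.

The active-learning machinery never touches a concrete network: acquisition
queries and the experiment loop see only :class:`SegmenterContract`, so any
model with two sigmoid output channels (femur, acetabulum) and optional
dropout layers can be plugged in. All selections are expressed as stable
string ids, never positional indices, so pool mutation cannot corrupt
references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

DEFAULT_CLASS_NAMES = ("background", "femur", "acetabulum")
#: output channels of a segmenter: femur, acetabulum (background is implicit)
FOREGROUND_CLASSES = ("femur", "acetabulum")


@dataclass(frozen=True)
class MaskStack:
    """Per-class binary masks aligned to one image.

    ``channels`` is C x H x W with C = 3 in the order (background, femur,
    acetabulum). Femur and acetabulum may overlap — the femoral head sits
    inside the acetabulum — and background is defined as the complement of
    the union of the foreground channels, so a mask is generable from
    foreground annotations alone.
    """

    channels: np.ndarray
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels)
        if ch.ndim != 3:
            raise ValueError(f"mask channels must be C x H x W, got shape {ch.shape}")
        if ch.shape[0] != len(self.class_names):
            raise ValueError(
                f"{ch.shape[0]} channels but {len(self.class_names)} class names"
            )
        if not np.isin(ch, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "channels", ch)

    @classmethod
    def from_foreground(cls, femur: np.ndarray, acetabulum: np.ndarray) -> "MaskStack":
        """Build a 3-channel stack from the two foreground masks.

        Background is 1 minus the elementwise union of the foreground
        channels.
        """
        femur = np.asarray(femur)
        acetabulum = np.asarray(acetabulum)
        if femur.shape != acetabulum.shape:
            raise ValueError("foreground masks must share a shape")
        union = np.maximum(femur, acetabulum)
        return cls(np.stack([1 - union, femur, acetabulum]).astype(np.uint8))

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.channels.shape[1], self.channels.shape[2]

    def foreground(self) -> np.ndarray:
        """The 2 x H x W foreground channels (femur, acetabulum)."""
        return self.channels[1:]


@dataclass(frozen=True)
class ImageSample:
    """One grayscale image (one 'patient'), optionally with its mask.

    ``pixels`` is H x W with finite intensities normalized to [0, 1].
    """

    id: str
    pixels: np.ndarray
    mask: MaskStack | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError(f"sample {self.id!r}: non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(f"sample {self.id!r}: pixels outside [0, 1]")
        if self.mask is not None and self.mask.spatial_shape != px.shape:
            raise ValueError(
                f"sample {self.id!r}: mask shape {self.mask.spatial_shape} "
                f"!= image shape {px.shape}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Pool:
    """An ordered sample collection split into labeled / unlabeled partitions.

    The partitions are disjoint id sets over the samples. Order of
    ``samples`` is the stable order used for all tie-breaking.
    """

    samples: tuple[ImageSample, ...]
    labeled_ids: frozenset[str]
    unlabeled_ids: frozenset[str]

    def __post_init__(self) -> None:
        all_ids = {s.id for s in self.samples}
        if self.labeled_ids & self.unlabeled_ids:
            raise ValueError("labeled and unlabeled partitions overlap")
        unknown = (self.labeled_ids | self.unlabeled_ids) - all_ids
        if unknown:
            raise ValueError(f"partition references unknown ids: {sorted(unknown)}")

    def sample(self, sample_id: str) -> ImageSample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise KeyError(sample_id)

    def labeled_samples(self) -> list[ImageSample]:
        return [s for s in self.samples if s.id in self.labeled_ids]

    def unlabeled_samples(self) -> list[ImageSample]:
        """Unlabeled samples in stable (input) order."""
        return [s for s in self.samples if s.id in self.unlabeled_ids]

    @property
    def n_labeled(self) -> int:
        return len(self.labeled_ids)

    @property
    def n_unlabeled(self) -> int:
        return len(self.unlabeled_ids)


@dataclass(frozen=True)
class PredictiveEnsemble:
    """k stochastic forward passes over N samples: k x N x C' x H x W."""

    passes: np.ndarray
    ids: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.passes, dtype=np.float64)
        if p.ndim != 5:
            raise ValueError(f"passes must be k x N x C x H x W, got shape {p.shape}")
        if p.shape[0] < 1:
            raise ValueError("ensemble needs k >= 1 passes")
        if p.shape[1] != len(self.ids):
            raise ValueError("pass count axis does not match ids")
        if not np.isfinite(p).all() or p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("ensemble probabilities must be finite in [0, 1]")
        object.__setattr__(self, "passes", p)

    @property
    def k(self) -> int:
        return self.passes.shape[0]


@dataclass(frozen=True)
class QueryResult:
    """Selected ids plus per-sample scores and wall time for one acquisition."""

    selected_ids: tuple[str, ...]
    query_name: str
    elapsed_seconds: float
    scores: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected_ids)) != len(self.selected_ids):
            raise ValueError("selected ids must be distinct")
        if self.elapsed_seconds < 0:
            raise ValueError("elapsed time must be non-negative")


@dataclass
class ALRunRecord:
    """Per-iteration metrics for one repeat of one query strategy."""

    query_name: str
    repeat_index: int
    rows: list[dict] = field(default_factory=list)

    def append(self, **row) -> None:
        if self.rows and row["n_labeled"] <= self.rows[-1]["n_labeled"]:
            raise ValueError("|L_t| must be strictly increasing across iterations")
        self.rows.append(dict(row))


@runtime_checkable
class SegmenterContract(Protocol):
    """What any pluggable segmenter must provide.

    ``predict`` returns N x C' x H x W probability maps in [0, 1] with
    C' = 2 sigmoid channels (femur, acetabulum). ``predict_stochastic``
    runs k forward passes with dropout active; with dropout disabled the
    k passes must be identical.
    """

    supports_dropout: bool

    def train(
        self,
        labeled: Sequence[ImageSample],
        validation: Sequence[ImageSample],
        config,
    ) -> None: ...

    def predict(self, samples: Sequence[ImageSample]) -> np.ndarray: ...

    def predict_stochastic(
        self, samples: Sequence[ImageSample], k: int, seed: int
    ) -> PredictiveEnsemble: ...


def make_pool(samples: Iterable[ImageSample], labeled_ids: Iterable[str] = ()) -> Pool:
    """Build a pool, partitioning samples into labeled and unlabeled sets.

    Every sample not named in ``labeled_ids`` starts in the unlabeled pool.

    Raises
    ------
    ValueError
        If an id is duplicated among samples or a labeled id is unknown.
    """
    samples = tuple(samples)
    seen: set[str] = set()
    for s in samples:
        if s.id in seen:
            raise ValueError(f"duplicate sample id: {s.id!r}")
        seen.add(s.id)
    labeled = frozenset(labeled_ids)
    unknown = labeled - seen
    if unknown:
        raise ValueError(f"labeled ids not present in samples: {sorted(unknown)}")
    return Pool(samples=samples, labeled_ids=labeled, unlabeled_ids=frozenset(seen - labeled))


def move_to_labeled(pool: Pool, ids: Iterable[str]) -> Pool:
    """Move ids from the unlabeled to the labeled partition.

    Models the annotation step L_t = L_{t-1} ∪ U_t^n with the batch removed
    from the next iteration's unlabeled pool. Total sample count is conserved.
    """
    ids = frozenset(ids)
    stray = ids - pool.unlabeled_ids
    if stray:
        raise ValueError(f"ids not in the unlabeled partition: {sorted(stray)}")
    return Pool(
        samples=pool.samples,
        labeled_ids=pool.labeled_ids | ids,
        unlabeled_ids=pool.unlabeled_ids - ids,
    )
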