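"""The active-learning experiment engine.

One AL cycle iterates: acquire a batch of min(n, |U_t|) unlabeled ids with
the configured query (timed), reveal their held ground-truth masks
(simulated annotation), retrain a fresh model from scratch on the grown
labeled set, and evaluate test dice — until the unlabeled pool is empty,
which takes exactly ceil(|U_0| / n) iterations. The test and validation
sets are fixed up front and never enter the pool. A full experiment
repeats the cycle several times with derived seeds and averages the
per-iteration curves; the fully-supervised upper bound trains once on all
trainable data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_types import ALRunRecord, ImageSample, Pool, QueryResult, SegmenterContract, move_to_labeled
from .metrics_losses import DiceReport, dice_score
from .queries import (
    cluster_query,
    cwe_mcd_query,
    random_query,
    representative_cwe_mcd_query,
    representative_query,
)
from .uncertainty import EntropyVariant

#: queries that run Monte Carlo Dropout and therefore need dropout layers
_MCD_QUERIES = frozenset({"cwe_mcd", "representative_cwe_mcd"})


@dataclass(frozen=True)
class TrainConfig:
    """Training-harness constants passed to the segmenter's ``train``.

    Defaults mirror the study protocol: Adam at learning rate 1e-2, batch
    size 8, up to 500 epochs, learning rate cut by 0.1 after 8 epochs
    without validation-dice improvement, early stop after 10.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-2
    batch_size: int = 8
    max_epochs: int = 500
    lr_factor: float = 0.1
    lr_patience: int = 8
    early_stop_patience: int = 10
    monitor: str = "val_dice"
    pixel_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pixel_fraction <= 1:
            raise ValueError("pixel_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ALConfig:
    """Everything one AL experiment needs.

    ``n`` is the acquisition batch size, ``k`` the Monte Carlo Dropout pass
    count, ``repeats`` the number of full-cycle repetitions averaged, and
    the three fractions define the test / validation / initial-labeled
    split (the remainder is the unlabeled pool).
    """

    query_name: str = "random"
    n: int = 15
    k: int = 30
    repeats: int = 10
    test_fraction: float = 0.15
    val_fraction: float = 0.15
    initial_fraction: float = 0.03
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    entropy_variant: EntropyVariant = "literal"
    thumbnail_size: tuple[int, int] | None = (64, 64)
    target_variance: float = 0.99

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("batch size n must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.test_fraction + self.val_fraction + self.initial_fraction > 1:
            raise ValueError("split fractions must sum to <= 1")


ModelFactory = Callable[[int], SegmenterContract]
PoolFactory = Callable[[int, int], tuple[Pool, Sequence[ImageSample], Sequence[ImageSample]]]


def derive_seed(master: int, *stream: int) -> int:
    """Deterministic sub-seed below 2^31 from a master seed and counters."""
    ss = np.random.SeedSequence([int(master), *map(int, stream)])
    return int(ss.generate_state(1)[0] % (2**31))


def _run_query(
    pool: Pool, model: SegmenterContract, config: ALConfig, seed: int
) -> QueryResult:
    name = config.query_name
    if name == "random":
        return random_query(pool, config.n, seed=seed)
    if name == "cluster":
        return cluster_query(
            pool, config.n, seed=seed,
            thumbnail_size=config.thumbnail_size,
            target_variance=config.target_variance,
        )
    if name == "representative":
        return representative_query(
            pool, config.n,
            thumbnail_size=config.thumbnail_size,
            target_variance=config.target_variance,
        )
    if name == "cwe_mcd":
        return cwe_mcd_query(
            pool, config.n, model, k=config.k, seed=seed,
            entropy_variant=config.entropy_variant,
        )
    if name == "representative_cwe_mcd":
        return representative_cwe_mcd_query(
            pool, config.n, model, k=config.k, seed=seed,
            thumbnail_size=config.thumbnail_size,
            target_variance=config.target_variance,
            entropy_variant=config.entropy_variant,
        )
    raise ValueError(f"unknown query name {name!r}")


def evaluate_model(
    model: SegmenterContract, samples: Sequence[ImageSample]
) -> DiceReport:
    """Macro test dice of a model over samples with ground-truth masks."""
    preds = model.predict(samples)
    truth = np.stack([s.mask.foreground() for s in samples])
    return dice_score(preds, truth)


def _train_fresh(
    model_factory: ModelFactory,
    labeled: Sequence[ImageSample],
    validation: Sequence[ImageSample],
    config: ALConfig,
    seed: int,
) -> SegmenterContract:
    model = model_factory(seed)
    model.train(labeled, validation, replace(config.train, seed=seed))
    return model


def expected_iterations(n_unlabeled: int, n: int) -> int:
    """ceil(|U_0| / n) — the AL iteration count until pool exhaustion."""
    return math.ceil(n_unlabeled / n)


def run_al_cycle(
    pool: Pool,
    test_samples: Sequence[ImageSample],
    val_samples: Sequence[ImageSample],
    model_factory: ModelFactory,
    config: ALConfig,
    repeat_index: int = 0,
) -> ALRunRecord:
    """One full AL cycle: query → annotate → retrain from scratch → evaluate.

    Iteration 0 records the model trained on the initial labeled set alone
    (query time 0); each later iteration moves one acquired batch and
    retrains. Terminates when the unlabeled pool is empty.
    """
    if pool.n_labeled == 0:
        raise ValueError("the pool needs a non-empty initial labeled partition")
    if config.query_name in _MCD_QUERIES:
        probe = model_factory(derive_seed(config.seed, repeat_index, 0, 99))
        if not probe.supports_dropout:
            raise ValueError(
                f"query {config.query_name!r} needs Monte Carlo Dropout but the "
                "model factory produces a dropout-free model"
            )

    record = ALRunRecord(query_name=config.query_name, repeat_index=repeat_index)
    current = pool
    model = _train_fresh(
        model_factory, current.labeled_samples(), val_samples, config,
        derive_seed(config.seed, repeat_index, 0, 0),
    )
    report = evaluate_model(model, test_samples)
    record.append(
        iteration=0, n_labeled=current.n_labeled, n_unlabeled=current.n_unlabeled,
        dice_test_macro=report.macro, dice_femur=report.per_class["femur"],
        dice_acetabulum=report.per_class["acetabulum"], query_seconds=0.0,
    )

    t = 0
    while current.n_unlabeled > 0:
        t += 1
        result = _run_query(current, model, config, derive_seed(config.seed, repeat_index, t, 1))
        current = move_to_labeled(current, result.selected_ids)
        model = _train_fresh(
            model_factory, current.labeled_samples(), val_samples, config,
            derive_seed(config.seed, repeat_index, t, 0),
        )
        report = evaluate_model(model, test_samples)
        record.append(
            iteration=t, n_labeled=current.n_labeled, n_unlabeled=current.n_unlabeled,
            dice_test_macro=report.macro, dice_femur=report.per_class["femur"],
            dice_acetabulum=report.per_class["acetabulum"],
            query_seconds=result.elapsed_seconds,
        )
    return record


def records_to_frame(records: Sequence[ALRunRecord]) -> pd.DataFrame:
    """Flatten run records into the long results table."""
    rows = []
    for rec in records:
        for row in rec.rows:
            rows.append({"query": rec.query_name, "repeat": rec.repeat_index, **row})
    return pd.DataFrame(
        rows,
        columns=[
            "query", "repeat", "iteration", "n_labeled", "n_unlabeled",
            "dice_test_macro", "dice_femur", "dice_acetabulum", "query_seconds",
        ],
    )


def average_curve(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-iteration means of dice and query time across repeats."""
    return (
        frame.groupby(["query", "iteration"], as_index=False)
        .agg(
            n_labeled=("n_labeled", "mean"),
            dice_test_macro=("dice_test_macro", "mean"),
            dice_femur=("dice_femur", "mean"),
            dice_acetabulum=("dice_acetabulum", "mean"),
            query_seconds=("query_seconds", "mean"),
        )
        .sort_values(["query", "iteration"], kind="stable")
        .reset_index(drop=True)
    )


def run_experiment(
    pool_factory: PoolFactory,
    model_factory: ModelFactory,
    config: ALConfig,
) -> tuple[list[ALRunRecord], pd.DataFrame]:
    """Repeat the AL cycle ``config.repeats`` times and average the curves.

    Each repeat gets its own derived seed (and, through ``pool_factory``, its
    own shuffled split), so repeats are independent but the whole experiment
    is reproducible from the master seed.
    """
    records = []
    for r in range(config.repeats):
        pool, test, val = pool_factory(r, derive_seed(config.seed, r, 0, 2))
        rep_config = replace(config, seed=config.seed)
        records.append(
            run_al_cycle(pool, test, val, model_factory, rep_config, repeat_index=r)
        )
    return records, average_curve(records_to_frame(records))


def run_upper_bound(
    pool: Pool,
    test_samples: Sequence[ImageSample],
    val_samples: Sequence[ImageSample],
    model_factory: ModelFactory,
    config: ALConfig,
    repeat_index: int = 0,
) -> DiceReport:
    """Train once on L_0 ∪ U_0 (all trainable data) and report test dice."""
    full = move_to_labeled(pool, pool.unlabeled_ids)
    model = _train_fresh(
        model_factory, full.labeled_samples(), val_samples, config,
        derive_seed(config.seed, repeat_index, 0, 3),
    )
    return evaluate_model(model, test_samples)
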