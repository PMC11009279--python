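"""Synthetic corpora and embeddings with controllable class structure.

Generates everything the pipeline consumes without any external service:
two-class corpora at a configurable prevalence, per-class lognormal word
counts matched to printed class means/medians, PCL-5 item vectors whose
totals land in per-class ranges straddling the screening cutoff, optional
missing items, and unit-norm Gaussian embeddings whose class mean directions
sit a configurable distance ``delta`` apart.

Narrative text is token soup from a small vocabulary with class-weighted
frequencies; class-1 narratives are additionally guaranteed to contain one
marker token so keyword-based chat mocks have a recoverable signal.
Linguistic realism is a non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import (
    CUTOFF,
    ITEM_MAX,
    N_ITEMS,
    NarrativeRecord,
    Pcl5Response,
)
from .errors import ValidationError

#: printed class word-count statistics (mean, median) the defaults target
CLASS1_WORD_STATS = (194.67, 158.0)
CLASS0_WORD_STATS = (155.39, 106.0)

MARKER_TOKEN = "flashbacks"

_SHARED_VOCAB = (
    "the baby was born at hospital after hours of labor and my midwife "
    "nurse doctor came in to check on us then we went home with our little "
    "one feeling very tired but also happy about everything that happened "
    "during delivery"
).split()

_CLASS1_VOCAB = (
    "terrified panic emergency blood pain screaming alone scared trauma "
    "nightmare helpless rushed cord monitor alarm surgery"
).split()

_CLASS0_VOCAB = (
    "calm peaceful smooth gentle supported relaxed quick easy joyful "
    "comfortable prepared"
).split()


def lognormal_params(mean: float, median: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and median."""
    if median <= 0 or mean < median:
        raise ValidationError("need mean >= median > 0 for a lognormal fit")
    mu = math.log(median)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    return mu, sigma


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; every stochastic choice flows from ``seed``."""

    n_subjects: int = 1295
    prevalence: float = 190 / 1295
    word_stats_class1: tuple[float, float] = CLASS1_WORD_STATS
    word_stats_class0: tuple[float, float] = CLASS0_WORD_STATS
    min_words: int = 5
    max_words: int = 2000
    dimension: int = 1536
    delta: float = 1.0  # distance between class mean directions
    noise_scale: float = 1.0
    pcl5_range_class1: tuple[int, int] = (CUTOFF, 60)
    pcl5_range_class0: tuple[int, int] = (0, 25)
    missing_item_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be at least 2")
        if not 0 < self.prevalence < 1:
            raise ValidationError("prevalence must be in (0, 1)")
        if self.min_words > self.max_words:
            raise ValidationError("min_words must not exceed max_words")
        if self.min_words < 1:
            raise ValidationError("min_words must be at least 1")
        if self.dimension < 2:
            raise ValidationError("dimension must be at least 2")
        if self.delta < 0:
            raise ValidationError("delta must be non-negative")
        if not 0 <= self.missing_item_rate < 1:
            raise ValidationError("missing_item_rate must be in [0, 1)")
        for lo, hi, cls in (
            (*self.pcl5_range_class1, 1),
            (*self.pcl5_range_class0, 0),
        ):
            if not 0 <= lo <= hi <= N_ITEMS * ITEM_MAX:
                raise ValidationError(f"invalid PCL-5 range for class {cls}")
        lo1 = self.pcl5_range_class1[0]
        hi0 = self.pcl5_range_class0[1]
        if lo1 < CUTOFF or hi0 >= CUTOFF:
            raise ValidationError(
                "class PCL-5 ranges must respect the cutoff "
                f"(class 1 >= {CUTOFF}, class 0 < {CUTOFF})"
            )

    @property
    def n_class1(self) -> int:
        """Exact allocation: round(n * prevalence), clipped to keep both
        classes non-empty."""
        n1 = round(self.n_subjects * self.prevalence)
        return min(max(n1, 1), self.n_subjects - 1)


def _draw_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """Random composition of ``total`` severity points over 20 items, each
    capped at 4."""
    items = np.zeros(N_ITEMS, dtype=np.int64)
    for _ in range(total):
        open_slots = np.flatnonzero(items < ITEM_MAX)
        items[int(rng.choice(open_slots))] += 1
    return items


def _draw_narrative(
    n_words: int, cls_label: int, rng: np.random.Generator
) -> str:
    if cls_label == 1:
        vocab = _SHARED_VOCAB + _CLASS1_VOCAB
        weights = np.concatenate(
            [np.ones(len(_SHARED_VOCAB)),
             3.0 * np.ones(len(_CLASS1_VOCAB))]
        )
    else:
        vocab = _SHARED_VOCAB + _CLASS0_VOCAB
        weights = np.concatenate(
            [np.ones(len(_SHARED_VOCAB)),
             2.0 * np.ones(len(_CLASS0_VOCAB))]
        )
    weights = weights / weights.sum()
    tokens = list(rng.choice(vocab, size=n_words, p=weights))
    if cls_label == 1 and MARKER_TOKEN not in tokens:
        tokens[int(rng.integers(n_words))] = MARKER_TOKEN
    return " ".join(tokens)


def generate_corpus(config: SynthConfig) -> list[NarrativeRecord]:
    """Generate labeled narrative records; deterministic given config.seed.

    Class labels use exact allocation (round(n * prevalence) class-1
    subjects) and are shuffled into a random order. PCL-5 totals are drawn
    uniformly in the per-class ranges and split across items; missing items
    are applied only to zero-valued items, so the missing-coded-as-zero
    total — and hence the label — is unchanged.
    """
    rng = np.random.default_rng([config.seed, 0])
    # separate stream so toggling missingness cannot perturb any other draw
    missing_rng = np.random.default_rng([config.seed, 2])
    n1 = config.n_class1
    labels = np.array([1] * n1 + [0] * (config.n_subjects - n1))
    rng.shuffle(labels)

    mu1, sigma1 = lognormal_params(*config.word_stats_class1)
    mu0, sigma0 = lognormal_params(*config.word_stats_class0)

    records: list[NarrativeRecord] = []
    for idx, cls_label in enumerate(labels):
        cls_label = int(cls_label)
        mu, sigma = (mu1, sigma1) if cls_label == 1 else (mu0, sigma0)
        n_words = int(round(rng.lognormal(mu, sigma)))
        n_words = int(np.clip(n_words, config.min_words, config.max_words))
        narrative = _draw_narrative(n_words, cls_label, rng)

        lo, hi = (
            config.pcl5_range_class1
            if cls_label == 1
            else config.pcl5_range_class0
        )
        total = int(rng.integers(lo, hi + 1))
        items = _draw_items(total, rng)
        item_values: list[int | None] = [int(v) for v in items]
        if config.missing_item_rate > 0:
            for slot in range(N_ITEMS):
                if item_values[slot] == 0 and (
                    missing_rng.random() < config.missing_item_rate
                ):
                    item_values[slot] = None

        record = NarrativeRecord.build(
            subject_id=f"subj-{idx:05d}",
            narrative=narrative,
            pcl5=Pcl5Response(tuple(item_values)),
        )
        if record.label != cls_label:
            raise AssertionError("generator produced an inconsistent label")
        records.append(record)
    return records


def generate_embeddings(
    records: Sequence[NarrativeRecord],
    config: SynthConfig,
) -> dict[str, np.ndarray]:
    """Unit-norm class-separated Gaussian embeddings keyed by subject_id.

    Class mean directions are +/- (delta/2) along one random unit direction,
    so ||mu_1 - mu_0|| = delta; per-subject noise has expected norm about
    ``noise_scale``. Deterministic given config.seed and record order.
    """
    rng = np.random.default_rng([config.seed, 1])
    d = config.dimension
    direction = rng.standard_normal(d)
    direction /= np.linalg.norm(direction)
    mu = {
        1: (config.delta / 2.0) * direction,
        0: -(config.delta / 2.0) * direction,
    }
    vectors: dict[str, np.ndarray] = {}
    for rec in records:
        noise = rng.standard_normal(d) * (config.noise_scale / math.sqrt(d))
        vec = mu[rec.label] + noise
        norm = np.linalg.norm(vec)
        if norm == 0.0:  # measure-zero; keep the contract anyway
            vec = direction.copy()
            norm = 1.0
        vectors[rec.subject_id] = vec / norm
    return vectors
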