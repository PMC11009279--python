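"""Pairwise training-set augmentation with Hadamard-product features.

From a balanced train split of n narratives per class, three pair sets are
built:

* set1 — all C(n, 2) unordered within-class pairs of class 1 (label 1),
* set2 — all C(n, 2) unordered within-class pairs of class 0 (label 1),
* set3 — |set1| + |set2| distinct cross-class pairs sampled uniformly
  without replacement (label 0).

Each pair's feature is the elementwise (Hadamard) product of the two
narrative embeddings, so the total is 4*C(n, 2) label-balanced examples
(n = 170 gives 14,365 + 14,365 + 28,730 = 57,460).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import SplitPlan
from .errors import ValidationError

PROVENANCE_SET1 = "set1"
PROVENANCE_SET2 = "set2"
PROVENANCE_SET3 = "set3"

_POSITIVE_SETS = {PROVENANCE_SET1, PROVENANCE_SET2}


@dataclass(frozen=True)
class PairExample:
    """An (u, v) narrative pair with its Hadamard feature and pair label."""

    u_id: str
    v_id: str
    z: np.ndarray
    pair_label: int
    provenance: str

    def __post_init__(self) -> None:
        if self.u_id == self.v_id:
            raise ValidationError(f"self-pair for subject {self.u_id!r}")
        if not np.all(np.isfinite(self.z)):
            raise ValidationError(
                f"non-finite feature for pair ({self.u_id}, {self.v_id})"
            )
        expected = 1 if self.provenance in _POSITIVE_SETS else 0
        if self.pair_label != expected:
            raise ValidationError(
                f"provenance {self.provenance!r} implies label {expected}, "
                f"got {self.pair_label}"
            )


def hadamard_feature(u_vec: np.ndarray, v_vec: np.ndarray) -> np.ndarray:
    """Elementwise product of two equal-length vectors."""
    u_vec = np.asarray(u_vec)
    v_vec = np.asarray(v_vec)
    if u_vec.shape != v_vec.shape or u_vec.ndim != 1:
        raise ValidationError(
            f"vector shape mismatch: {u_vec.shape} vs {v_vec.shape}"
        )
    return u_vec * v_vec


def enumerate_within_pairs(ids: Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered distinct pairs, canonically ordered u < v."""
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate IDs in within-class pair enumeration")
    if len(ids) < 2:
        raise ValidationError(f"need at least 2 IDs, got {len(ids)}")
    return [(min(a, b), max(a, b)) for a, b in combinations(ids, 2)]


def sample_cross_pairs(
    ids_class1: Sequence[str],
    ids_class0: Sequence[str],
    k: int,
    seed: int,
) -> list[tuple[str, str]]:
    """k distinct (class-1, class-0) pairs, uniform without replacement."""
    n1, n0 = len(ids_class1), len(ids_class0)
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be non-empty")
    total = n1 * n0
    if not 0 < k <= total:
        raise ValidationError(
            f"requested {k} cross pairs but only {total} are possible"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=k, replace=False)
    return [(ids_class1[int(i) // n0], ids_class0[int(i) % n0]) for i in flat]


def build_training_set(
    split: SplitPlan,
    vectors: Mapping[str, np.ndarray],
    seed: int,
    set3_size: int | None = None,
) -> list[PairExample]:
    """Build sets #1-#3 over the train IDs of ``split``.

    ``set3_size`` defaults to |set1| + |set2|. Every train ID must have a
    vector in ``vectors``; the total is 2*C(n1,2) + 2*C(n0,2) examples,
    exactly label-balanced at the default size.
    """
    train1 = split.train_ids[1]
    train0 = split.train_ids[0]
    for subject_id in (*train1, *train0):
        if subject_id not in vectors:
            raise ValidationError(f"no embedding vector for ID {subject_id!r}")

    examples: list[PairExample] = []

    def _feature(u: str, v: str) -> np.ndarray:
        return hadamard_feature(vectors[u], vectors[v])

    set1 = enumerate_within_pairs(train1)
    set2 = enumerate_within_pairs(train0)
    for provenance, pair_list in (
        (PROVENANCE_SET1, set1),
        (PROVENANCE_SET2, set2),
    ):
        for u, v in pair_list:
            examples.append(
                PairExample(u, v, _feature(u, v), pair_label=1,
                            provenance=provenance)
            )

    if set3_size is None:
        set3_size = len(set1) + len(set2)
    for u, v in sample_cross_pairs(train1, train0, set3_size, seed):
        examples.append(
            PairExample(u, v, _feature(u, v), pair_label=0,
                        provenance=PROVENANCE_SET3)
        )
    return examples


def pairs_as_arrays(
    examples: Sequence[PairExample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair features and labels into (X, y) arrays."""
    if not examples:
        raise ValidationError("empty pair collection")
    X = np.vstack([ex.z for ex in examples])
    y = np.array([ex.pair_label for ex in examples], dtype=np.float64)
    return X, y


def write_pair_manifest(
    examples: Iterable[PairExample], path: str | Path
) -> None:
    """JSONL manifest of pair membership (features are not serialized)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for ex in examples:
            handle.write(
                json.dumps(
                    {
                        "u_id": ex.u_id,
                        "v_id": ex.v_id,
                        "pair_label": ex.pair_label,
                        "provenance": ex.provenance,
                    }
                )
                + "\n"
            )
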