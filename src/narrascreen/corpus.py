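"""Narrative corpus handling: loading, PCL-5 scoring, labeling, filtering,
class balancing and train/test splitting.

A record is one subject: a free-text childbirth narrative plus the 20 PCL-5
item responses. The total severity score (missing items coded as 0) defines
a provisional case label: total >= 31 -> class 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

N_ITEMS = 20
ITEM_MIN = 0
ITEM_MAX = 4
CUTOFF = 31
TOTAL_MAX = N_ITEMS * ITEM_MAX
DEFAULT_MIN_WORDS = 30

#: the paper's 190 -> 170 train ratio, generalized
DEFAULT_TRAIN_FRACTION = Fraction(17, 19)

_MISSING_TOKENS = {"", "na", "n/a", "nan", "none", "null", "missing"}

PCL5_COLUMNS = tuple(f"pcl5_{i:02d}" for i in range(1, N_ITEMS + 1))


def _normalize_item(value: object, slot: int) -> int | None:
    """Coerce one raw item response to an int in [0, 4] or None (missing)."""
    if value is None:
        return None
    if isinstance(value, float):
        if np.isnan(value):
            return None
        if not value.is_integer():
            raise ValidationError(
                f"PCL-5 item {slot + 1}: non-integer value {value!r}"
            )
        value = int(value)
    if isinstance(value, str):
        stripped = value.strip()
        if stripped.lower() in _MISSING_TOKENS:
            return None
        try:
            value = int(stripped)
        except ValueError:
            raise ValidationError(
                f"PCL-5 item {slot + 1}: unparseable value {stripped!r}"
            ) from None
    if isinstance(value, (int, np.integer)) and not isinstance(value, bool):
        value = int(value)
        if not ITEM_MIN <= value <= ITEM_MAX:
            raise ValidationError(
                f"PCL-5 item {slot + 1}: value {value} outside "
                f"[{ITEM_MIN}, {ITEM_MAX}]"
            )
        return value
    raise ValidationError(
        f"PCL-5 item {slot + 1}: unsupported type {type(value).__name__}"
    )


@dataclass(frozen=True)
class Pcl5Response:
    """Twenty item responses, each an int in {0..4} or None when missing."""

    items: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValidationError(
                f"PCL-5 response must have {N_ITEMS} items, got {len(self.items)}"
            )
        for slot, item in enumerate(self.items):
            if item is None:
                continue
            if not isinstance(item, int) or isinstance(item, bool):
                raise ValidationError(
                    f"PCL-5 item {slot + 1}: expected int or None, "
                    f"got {type(item).__name__}"
                )
            if not ITEM_MIN <= item <= ITEM_MAX:
                raise ValidationError(
                    f"PCL-5 item {slot + 1}: value {item} outside "
                    f"[{ITEM_MIN}, {ITEM_MAX}]"
                )

    @classmethod
    def from_raw(cls, values: Sequence[object]) -> "Pcl5Response":
        """Build from raw CSV/JSON values, normalizing missing markers."""
        if len(values) != N_ITEMS:
            raise ValidationError(
                f"PCL-5 response must have {N_ITEMS} items, got {len(values)}"
            )
        return cls(tuple(_normalize_item(v, i) for i, v in enumerate(values)))

    @property
    def n_missing(self) -> int:
        return sum(1 for item in self.items if item is None)


def score_pcl5(response: Pcl5Response) -> int:
    """Total severity score; missing items contribute 0."""
    return sum(item for item in response.items if item is not None)


def label_case(total: int) -> int:
    """Provisional case label: 1 iff total >= 31."""
    if not isinstance(total, (int, np.integer)) or isinstance(total, bool):
        raise ValidationError(f"total must be an integer, got {total!r}")
    if not 0 <= total <= TOTAL_MAX:
        raise ValidationError(f"total {total} outside [0, {TOTAL_MAX}]")
    return 1 if total >= CUTOFF else 0


def word_count(text: str) -> int:
    """Whitespace-delimited token count; punctuation stays attached."""
    return len(text.split())


@dataclass(frozen=True)
class NarrativeRecord:
    """One subject's narrative with derived score, label and word count."""

    subject_id: str
    narrative: str
    pcl5: Pcl5Response
    pcl5_total: int
    label: int
    word_count: int

    @classmethod
    def build(
        cls, subject_id: str, narrative: str, pcl5: Pcl5Response
    ) -> "NarrativeRecord":
        total = score_pcl5(pcl5)
        return cls(
            subject_id=str(subject_id),
            narrative=narrative,
            pcl5=pcl5,
            pcl5_total=total,
            label=label_case(total),
            word_count=word_count(narrative),
        )


@dataclass(frozen=True)
class SplitPlan:
    """Per-class train/test ID assignment from one balanced set."""

    train_ids: dict[int, tuple[str, ...]]
    test_ids: dict[int, tuple[str, ...]]
    seed: int
    train_per_class: int

    def __post_init__(self) -> None:
        for cls_label in (0, 1):
            train = set(self.train_ids.get(cls_label, ()))
            test = set(self.test_ids.get(cls_label, ()))
            if train & test:
                raise ValidationError(
                    f"class {cls_label}: train and test sets overlap"
                )
        n_train = {len(v) for v in self.train_ids.values()}
        n_test = {len(v) for v in self.test_ids.values()}
        if len(n_train) != 1 or len(n_test) != 1:
            raise ValidationError("per-class train/test counts are unequal")

    @property
    def all_train_ids(self) -> tuple[str, ...]:
        return self.train_ids[0] + self.train_ids[1]

    @property
    def all_test_ids(self) -> tuple[str, ...]:
        return self.test_ids[0] + self.test_ids[1]


def check_unique_ids(records: Sequence[NarrativeRecord]) -> None:
    """Duplicate subject IDs are a hard error (they would leak across splits)."""
    seen: set[str] = set()
    for rec in records:
        if rec.subject_id in seen:
            raise ValidationError(f"duplicate subject_id {rec.subject_id!r}")
        seen.add(rec.subject_id)


def filter_min_words(
    records: Sequence[NarrativeRecord], min_words: int = DEFAULT_MIN_WORDS
) -> list[NarrativeRecord]:
    """Keep records with word_count >= min_words, preserving order."""
    return [rec for rec in records if rec.word_count >= min_words]


def balance_downsample(
    records: Sequence[NarrativeRecord], seed: int
) -> list[NarrativeRecord]:
    """Down-sample the majority class to the minority class size.

    The minority class is kept in full; majority records are drawn uniformly
    without replacement. Output preserves the original record order among
    survivors. Deterministic given ``seed``.
    """
    by_class: dict[int, list[int]] = {0: [], 1: []}
    for idx, rec in enumerate(records):
        by_class[rec.label].append(idx)
    for cls_label, members in by_class.items():
        if not members:
            raise ValidationError(f"class {cls_label} has no members")
    minority = min(by_class, key=lambda c: len(by_class[c]))
    majority = 1 - minority
    n_keep = len(by_class[minority])
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(by_class[majority], size=n_keep, replace=False)
    keep = set(by_class[minority]) | set(int(i) for i in kept_majority)
    return [rec for idx, rec in enumerate(records) if idx in keep]


def default_train_per_class(per_class_count: int) -> int:
    """round(17/19 * n) — generalizes the 190 -> 170 train ratio."""
    return round(per_class_count * DEFAULT_TRAIN_FRACTION)


def make_split(
    balanced: Sequence[NarrativeRecord],
    train_per_class: int | None = None,
    seed: int = 0,
) -> SplitPlan:
    """Sample a per-class train/test split from a balanced record set."""
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for rec in balanced:
        by_class[rec.label].append(rec.subject_id)
    counts = {c: len(ids) for c, ids in by_class.items()}
    if counts[0] != counts[1]:
        raise ValidationError(
            f"records are not balanced: {counts[0]} vs {counts[1]} per class"
        )
    per_class = counts[0]
    if per_class == 0:
        raise ValidationError("empty record set")
    if train_per_class is None:
        train_per_class = default_train_per_class(per_class)
    if not 0 < train_per_class < per_class:
        raise ValidationError(
            f"train_per_class={train_per_class} must be in (0, {per_class})"
        )
    rng = np.random.default_rng(seed)
    train_ids: dict[int, tuple[str, ...]] = {}
    test_ids: dict[int, tuple[str, ...]] = {}
    for cls_label in (0, 1):
        ids = by_class[cls_label]
        chosen = rng.choice(len(ids), size=train_per_class, replace=False)
        chosen_set = {int(i) for i in chosen}
        train_ids[cls_label] = tuple(
            ids[i] for i in range(len(ids)) if i in chosen_set
        )
        test_ids[cls_label] = tuple(
            ids[i] for i in range(len(ids)) if i not in chosen_set
        )
    return SplitPlan(
        train_ids=train_ids,
        test_ids=test_ids,
        seed=seed,
        train_per_class=train_per_class,
    )


# ---------------------------------------------------------------------------
# I/O: CSV and JSONL corpora, split manifests
# ---------------------------------------------------------------------------

def _record_from_mapping(row: dict[str, object]) -> NarrativeRecord:
    try:
        subject_id = row["subject_id"]
        narrative = row["narrative"]
    except KeyError as exc:
        raise ValidationError(f"missing required column {exc.args[0]!r}") from None
    raw_items = []
    for col in PCL5_COLUMNS:
        if col not in row:
            raise ValidationError(f"missing required column {col!r}")
        raw_items.append(row[col])
    return NarrativeRecord.build(
        subject_id=str(subject_id),
        narrative=str(narrative),
        pcl5=Pcl5Response.from_raw(raw_items),
    )


def load_corpus(path: str | Path) -> list[NarrativeRecord]:
    """Load a corpus from CSV or JSONL (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        records = _load_csv(path)
    elif path.suffix.lower() in {".jsonl", ".ndjson"}:
        records = _load_jsonl(path)
    else:
        raise ValidationError(f"unsupported corpus format: {path.suffix!r}")
    check_unique_ids(records)
    return records


def _load_csv(path: Path) -> list[NarrativeRecord]:
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        return [_record_from_mapping(row) for row in reader]


def _load_jsonl(path: Path) -> list[NarrativeRecord]:
    records = []
    with path.open(encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line:
                records.append(_record_from_mapping(json.loads(line)))
    return records


def write_corpus_csv(records: Iterable[NarrativeRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["subject_id", "narrative", *PCL5_COLUMNS])
        for rec in records:
            items = ["" if v is None else v for v in rec.pcl5.items]
            writer.writerow([rec.subject_id, rec.narrative, *items])


def write_split_manifest(split: SplitPlan, path: str | Path) -> None:
    """JSONL manifest: one line per subject with label and split assignment."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for assignment, ids_by_class in (
            ("train", split.train_ids),
            ("test", split.test_ids),
        ):
            for cls_label in (0, 1):
                for subject_id in ids_by_class[cls_label]:
                    handle.write(
                        json.dumps(
                            {
                                "subject_id": subject_id,
                                "label": cls_label,
                                "split": assignment,
                            }
                        )
                        + "\n"
                    )
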