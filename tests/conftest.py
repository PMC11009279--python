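import numpy as np
import pytest

from narrascreen.corpus import NarrativeRecord, Pcl5Response

# PCL-5 item tuples that pin the label: ten 4s -> total 40 (class 1),
# all zeros -> total 0 (class 0)
_ITEMS_CLASS1 = tuple([4] * 10 + [0] * 10)
_ITEMS_CLASS0 = tuple([0] * 20)


def make_record(subject_id: str, label: int, n_words: int = 40) -> NarrativeRecord:
    """Record with exactly ``n_words`` whitespace tokens (first is the ID,
    so narratives are unique across subjects)."""
    items = _ITEMS_CLASS1 if label == 1 else _ITEMS_CLASS0
    if n_words <= 0:
        narrative = ""
    else:
        narrative = " ".join([subject_id] + [f"w{i}" for i in range(n_words - 1)])
    return NarrativeRecord.build(
        subject_id=subject_id,
        narrative=narrative,
        pcl5=Pcl5Response(items),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_balanced_records():
    """Six records, three per class, all above the word floor."""
    return [make_record(f"s{i}", label=i % 2) for i in range(6)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
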