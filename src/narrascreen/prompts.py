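"""Zero-shot and few-shot prompt classification against a chat backend.

The templates reproduce the study's best-performing prompts: a task
instruction addressed to a "psychiatrist" persona, optional labeled example
blocks separated by ``###``, and the target narrative last. Responses are
parsed strictly ("1"/"0" after stripping whitespace) with a logged lenient
first-character fallback; anything else is recorded as unparseable and
excluded from confusion counts, never silently dropped.

Backends are abstract and deterministic mocks are provided; live API access
is an explicit opt-in and is never required.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import NarrativeRecord
from .errors import BackendError, ValidationError

logger = logging.getLogger(__name__)

UNPARSEABLE = "unparseable"

MAX_FEW_SHOT_EXAMPLES = 4

_INSTRUCTION_ZERO = (
    "You are a psychiatrist specialized in diagnosing and treating "
    "Post-Traumatic Stress Disorder (PTSD). I will provide you with a "
    "narrative written by a woman describing her birth experience. Your "
    "task is to decide whether this woman is at high risk of PTSD (Label 1) "
    "or lower risk of PTSD (Label 0). Do not write anything but '1' or '0'."
)

_INSTRUCTION_FEW = (
    "You are a psychiatrist specialized in diagnosing and treating "
    "Post-Traumatic Stress Disorder (PTSD). I will provide you with a "
    "narrative written by a woman describing her birth experience. Your "
    "task is to decide whether this woman is at high risk of PTSD (Label 1), "
    "or lower risk of PTSD (Label 0). Do not write anything but '1' or '0'. "
    "Here are a few examples of text with their associated class labels as "
    "'1' (PTSD) or '0' (No-PTSD)."
)

ZERO_SHOT_TEMPLATE = _INSTRUCTION_ZERO + ' ### < Text > : "{text}"'


@dataclass(frozen=True)
class PromptSpec:
    """Prompt configuration for one classification run."""

    mode: str  # "zero_shot" | "few_shot"
    examples: tuple[tuple[str, int], ...] = ()  # (narrative, label) pairs
    temperature: float = 0.0
    model_name: str = "gpt-3.5-turbo-16k"

    def __post_init__(self) -> None:
        if self.mode not in ("zero_shot", "few_shot"):
            raise ValidationError(f"unknown prompt mode {self.mode!r}")
        if self.temperature != 0:
            raise ValidationError("temperature must be 0 (deterministic runs)")
        if self.mode == "zero_shot":
            if self.examples:
                raise ValidationError("zero_shot mode takes no examples")
        else:
            if not 1 <= len(self.examples) <= MAX_FEW_SHOT_EXAMPLES:
                raise ValidationError(
                    f"few_shot mode takes 1-{MAX_FEW_SHOT_EXAMPLES} examples"
                )
            labels = {label for _, label in self.examples}
            if not labels <= {0, 1}:
                raise ValidationError("example labels must be 0 or 1")
            if len(self.examples) >= 2 and labels != {0, 1}:
                raise ValidationError(
                    "few_shot with 2+ examples needs at least one of each label"
                )


def render_prompt(spec: PromptSpec, narrative: str) -> str:
    """Instantiate the prompt template for one target narrative.

    Pure: the same spec and narrative always render the same string.
    """
    if not narrative or not narrative.strip():
        raise ValidationError("narrative must be non-empty")
    if spec.mode == "zero_shot":
        return ZERO_SHOT_TEMPLATE.format(text=narrative)
    blocks = [
        f'< Text > : "{text}" < Label > : {label}'
        for text, label in spec.examples
    ]
    blocks.append(f'< Text > : "{narrative}"')
    return _INSTRUCTION_FEW + " " + " ### ".join(blocks)


def parse_label(raw_response: str) -> int | str:
    """Parse a chat response into 0, 1, or the UNPARSEABLE marker.

    Strict rule first (the whole stripped response is '1' or '0'); then a
    lenient first-character fallback with a logged warning; otherwise
    UNPARSEABLE.
    """
    stripped = raw_response.strip()
    if stripped in ("0", "1"):
        return int(stripped)
    if stripped and stripped[0] in ("0", "1"):
        logger.warning(
            "lenient parse: took leading %r from response %r",
            stripped[0], raw_response,
        )
        return int(stripped[0])
    return UNPARSEABLE


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

@runtime_checkable
class ChatBackend(Protocol):
    name: str

    def complete(self, prompt: str) -> str:  # pragma: no cover
        ...


def extract_target_text(prompt: str) -> str:
    """Recover the target narrative (the last quoted text block) from a
    rendered prompt. Used by mocks that react to the narrative itself."""
    start = prompt.rfind(': "')
    if start < 0 or not prompt.endswith('"'):
        raise ValidationError("prompt does not end with a quoted text block")
    return prompt[start + 3 : -1]


@dataclass
class ConstantBackend:
    """Always answers the same string."""

    response: str = "1"
    name: str = "mock-constant"

    def complete(self, prompt: str) -> str:
        return self.response


@dataclass
class FunctionBackend:
    """Answers via an arbitrary prompt -> response function."""

    fn: Callable[[str], str]
    name: str = "mock-function"

    def complete(self, prompt: str) -> str:
        return self.fn(prompt)


@dataclass
class ScriptedBackend:
    """Answers from a narrative-text -> response mapping.

    The target narrative is extracted from the rendered prompt, so the same
    script works for zero- and few-shot prompts. Unknown narratives get
    ``default`` (a backend error when None).
    """

    responses: Mapping[str, str]
    default: str | None = None
    name: str = "mock-scripted"

    def complete(self, prompt: str) -> str:
        target = extract_target_text(prompt)
        if target in self.responses:
            return self.responses[target]
        if self.default is None:
            raise BackendError("scripted backend has no response for prompt")
        return self.default


@dataclass
class KeywordBackend:
    """Answers '1' iff a keyword occurs in the target narrative.

    Pairs with the synthetic corpus generator, whose class-1 narratives
    carry a guaranteed marker token.
    """

    keyword: str = "flashbacks"
    name: str = "mock-keyword"

    def complete(self, prompt: str) -> str:
        return "1" if self.keyword in extract_target_text(prompt) else "0"


@dataclass
class OpenAIChatBackend:
    """Shape of a live chat-completions client; transport is injectable.

    Without a transport this backend refuses to run: tests and CI must use
    the mocks above. Credentials come only from the environment.
    """

    model_name: str = "gpt-3.5-turbo-16k"
    endpoint: str = "https://api.openai.com/v1/chat/completions"
    timeout: float = 60.0
    api_key_env: str = "OPENAI_API_KEY"
    transport: Callable[[str, str, float], str] | None = None

    @property
    def name(self) -> str:
        return self.model_name

    def complete(self, prompt: str) -> str:
        if self.transport is None:
            raise BackendError(
                "live chat access requires an explicit transport; "
                "use a mock backend for offline runs"
            )
        if not os.environ.get(self.api_key_env):
            raise BackendError(f"missing credentials in ${self.api_key_env}")
        return self.transport(self.model_name, prompt, 0.0)


# ---------------------------------------------------------------------------
# Classification runs
# ---------------------------------------------------------------------------

@dataclass
class PromptRunResult:
    """Parsed labels plus a full audit transcript."""

    labels: dict[str, int | str]  # subject_id -> 0 | 1 | UNPARSEABLE
    transcript: list[dict] = field(default_factory=list)
    n_lenient: int = 0
    n_unparseable: int = 0
    n_backend_errors: int = 0

    def write_transcript(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as handle:
            for entry in self.transcript:
                handle.write(json.dumps(entry) + "\n")


def classify_via_chat(
    spec: PromptSpec,
    narratives: Sequence[tuple[str, str]],
    backend: ChatBackend,
    max_retries: int = 1,
) -> PromptRunResult:
    """Classify (subject_id, narrative) pairs through the chat backend.

    Backend failures are retried ``max_retries`` times, then recorded as
    unparseable with the error message in the transcript.
    """
    result = PromptRunResult(labels={})
    for subject_id, narrative in narratives:
        prompt = render_prompt(spec, narrative)
        raw: str | None = None
        error: str | None = None
        for _attempt in range(max_retries + 1):
            try:
                raw = backend.complete(prompt)
                error = None
                break
            except BackendError as exc:
                error = str(exc)
        if raw is None:
            label: int | str = UNPARSEABLE
            result.n_backend_errors += 1
        else:
            stripped = raw.strip()
            label = parse_label(raw)
            if label in (0, 1) and stripped not in ("0", "1"):
                result.n_lenient += 1
        if label == UNPARSEABLE:
            result.n_unparseable += 1
        result.labels[subject_id] = label
        result.transcript.append(
            {
                "subject_id": subject_id,
                "prompt": prompt,
                "raw_response": raw,
                "parsed_label": label,
                "backend_error": error,
            }
        )
    return result


def select_few_shot_examples(
    records: Sequence[NarrativeRecord], seed: int, n_per_class: int = 1
) -> tuple[tuple[tuple[str, int], ...], tuple[str, ...]]:
    """Pick seeded few-shot examples (one or more per class) from the corpus.

    Returns (examples, used subject IDs); callers must exclude the used IDs
    from evaluation.
    """
    rng = np.random.default_rng(seed)
    examples: list[tuple[str, int]] = []
    used: list[str] = []
    for cls_label in (1, 0):
        members = [rec for rec in records if rec.label == cls_label]
        if len(members) < n_per_class:
            raise ValidationError(
                f"class {cls_label} has fewer than {n_per_class} records"
            )
        chosen = rng.choice(len(members), size=n_per_class, replace=False)
        for idx in chosen:
            rec = members[int(idx)]
            examples.append((rec.narrative, cls_label))
            used.append(rec.subject_id)
    return tuple(examples), tuple(used)
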