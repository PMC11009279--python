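"""Embedding backends: a uniform text -> fixed-dimension vector contract.

Three implementations:

* :class:`HashEmbedder` — deterministic offline embedder for tests and
  offline runs (hash of the text seeds a generator; unit-norm Gaussian).
* :class:`RemoteEmbedder` — the shape of an HTTP embedding API client.
  The transport is injectable so it is fully mockable; no network code runs
  unless a transport is supplied.
* :func:`cached_embed` — content-addressed JSONL cache in front of any
  embedder.

Cache file format (version 1): first line is a JSON header
``{"format": "narrascreen-embcache", "version": 1}``; each following line is
``{"model": <name>, "text_sha256": <hex>, "vector": [floats...]}``.
Keys are ``(model name, sha256 of the UTF-8 text)``; identical texts share
one entry.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import BackendError, ValidationError

DEFAULT_DIMENSION = 1536
#: whitespace-token budget mirroring a 16k-context model; exceeding it is an
#: error rather than a silent truncation
DEFAULT_TOKEN_BUDGET = 16384

_CACHE_FORMAT = "narrascreen-embcache"
_CACHE_VERSION = 1


@runtime_checkable
class Embedder(Protocol):
    """Contract every embedding backend satisfies."""

    name: str
    dimension: int
    deterministic: bool

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


def _text_hash(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def _check_texts(texts: Sequence[str], token_budget: int) -> None:
    for i, text in enumerate(texts):
        if not isinstance(text, str) or not text:
            raise ValidationError(f"text at index {i} is empty or not a string")
        n_tokens = len(text.split())
        if n_tokens > token_budget:
            raise ValidationError(
                f"text at index {i} has {n_tokens} tokens, exceeding the "
                f"budget of {token_budget}; refusing to truncate silently"
            )


@dataclass
class HashEmbedder:
    """Deterministic offline embedder.

    Each text's SHA-256 digest (combined with ``seed``) seeds a generator;
    the vector is a standard-normal draw scaled to unit norm. Output depends
    only on (text, seed, dimension) — pure by construction.
    """

    dimension: int = DEFAULT_DIMENSION
    seed: int = 0
    token_budget: int = DEFAULT_TOKEN_BUDGET
    deterministic: bool = field(default=True, init=False)

    @property
    def name(self) -> str:
        return f"hash-embedder-d{self.dimension}-s{self.seed}"

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        _check_texts(texts, self.token_budget)
        out = np.empty((len(texts), self.dimension), dtype=np.float64)
        for i, text in enumerate(texts):
            digest = hashlib.sha256(text.encode("utf-8")).digest()
            entropy = int.from_bytes(digest[:8], "little")
            rng = np.random.default_rng([self.seed, entropy])
            vec = rng.standard_normal(self.dimension)
            out[i] = vec / np.linalg.norm(vec)
        return out


Transport = Callable[[str, Sequence[str]], Sequence[Sequence[float]]]


@dataclass
class RemoteEmbedder:
    """Remote-API-shaped embedder with an injectable transport.

    ``transport(model_name, texts)`` must return one vector per text. With no
    transport configured, calls fail with a :class:`BackendError` — this class
    is the integration point, not a live client. Credentials are read from the
    environment variable named by ``api_key_env`` and never stored.
    """

    model_name: str = "text-embedding-ada-002"
    dimension: int = DEFAULT_DIMENSION
    endpoint: str = "https://api.openai.com/v1/embeddings"
    timeout: float = 30.0
    api_key_env: str = "OPENAI_API_KEY"
    token_budget: int = DEFAULT_TOKEN_BUDGET
    transport: Transport | None = None
    deterministic: bool = field(default=False, init=False)

    @property
    def name(self) -> str:
        return self.model_name

    @property
    def api_key(self) -> str | None:
        return os.environ.get(self.api_key_env)

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        _check_texts(texts, self.token_budget)
        if self.transport is None:
            raise BackendError(
                f"no transport configured for {self.model_name!r}; "
                "live API access requires an explicit transport",
                failed_indices=tuple(range(len(texts))),
            )
        try:
            rows = self.transport(self.model_name, texts)
        except Exception as exc:  # transport failures are retriable
            raise BackendError(
                f"embedding backend failed: {exc}",
                failed_indices=tuple(range(len(texts))),
            ) from exc
        return _validate_batch(rows, len(texts), self.dimension)


def _validate_batch(rows: object, n: int, dimension: int) -> np.ndarray:
    arr = np.asarray(rows, dtype=np.float64)
    if arr.shape != (n, dimension):
        raise ValidationError(
            f"backend returned shape {arr.shape}, expected ({n}, {dimension})"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("backend returned non-finite embedding values")
    return arr


def embed_batch(texts: Sequence[str], embedder: Embedder) -> np.ndarray:
    """Embed texts, returning an ``(n, d)`` array in input order."""
    vectors = embedder.embed(texts)
    return _validate_batch(vectors, len(texts), embedder.dimension)


# ---------------------------------------------------------------------------
# Content-addressed cache
# ---------------------------------------------------------------------------

def _read_cache(cache_path: Path) -> dict[tuple[str, str], np.ndarray]:
    entries: dict[tuple[str, str], np.ndarray] = {}
    if not cache_path.exists():
        return entries
    try:
        with cache_path.open(encoding="utf-8") as handle:
            header = json.loads(handle.readline())
            if (
                header.get("format") != _CACHE_FORMAT
                or header.get("version") != _CACHE_VERSION
            ):
                raise ValueError("unrecognized cache header")
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                vec = np.asarray(obj["vector"], dtype=np.float64)
                entries[(obj["model"], obj["text_sha256"])] = vec
    except (ValueError, KeyError, OSError) as exc:
        warnings.warn(
            f"embedding cache at {cache_path} is corrupt ({exc}); rebuilding",
            stacklevel=3,
        )
        return {}
    return entries


def _append_cache(
    cache_path: Path,
    new_entries: Mapping[tuple[str, str], np.ndarray],
    rewrite: bool = False,
) -> None:
    cache_path.parent.mkdir(parents=True, exist_ok=True)
    fresh = rewrite or not cache_path.exists()
    mode = "w" if fresh else "a"
    with cache_path.open(mode, encoding="utf-8") as handle:
        if fresh:
            handle.write(
                json.dumps({"format": _CACHE_FORMAT, "version": _CACHE_VERSION})
                + "\n"
            )
        for (model, text_sha), vec in new_entries.items():
            handle.write(
                json.dumps(
                    {
                        "model": model,
                        "text_sha256": text_sha,
                        "vector": vec.tolist(),
                    }
                )
                + "\n"
            )


def cached_embed(
    texts: Sequence[str], embedder: Embedder, cache_path: str | Path
) -> np.ndarray:
    """Like :func:`embed_batch`, backed by a content-addressed cache.

    Only cache misses reach the backend; results are bit-identical to a
    direct call for a deterministic embedder. A corrupt cache file is
    rebuilt with a warning.
    """
    cache_path = Path(cache_path)
    entries = _read_cache(cache_path)
    cache_was_corrupt = cache_path.exists() and not entries

    keys = [(embedder.name, _text_hash(t)) for t in texts]
    miss_positions = [i for i, key in enumerate(keys) if key not in entries]

    new_entries: dict[tuple[str, str], np.ndarray] = {}
    if miss_positions:
        miss_texts = [texts[i] for i in miss_positions]
        fresh = embed_batch(miss_texts, embedder)
        for pos, row in zip(miss_positions, fresh):
            new_entries[keys[pos]] = row
        _append_cache(cache_path, new_entries, rewrite=cache_was_corrupt)
        entries.update(new_entries)

    out = np.empty((len(texts), embedder.dimension), dtype=np.float64)
    for i, key in enumerate(keys):
        out[i] = entries[key]
    return out


def store_vectors(
    cache_path: str | Path,
    model_name: str,
    texts: Sequence[str],
    vectors: np.ndarray,
) -> None:
    """Seed a cache with externally produced vectors (e.g. synthetic ones)."""
    if len(texts) != len(vectors):
        raise ValidationError("texts and vectors length mismatch")
    cache_path = Path(cache_path)
    entries = _read_cache(cache_path)
    new_entries = {}
    for text, vec in zip(texts, vectors):
        key = (model_name, _text_hash(text))
        if key not in entries:
            new_entries[key] = np.asarray(vec, dtype=np.float64)
    if new_entries:
        _append_cache(cache_path, new_entries, rewrite=not entries)


def load_vectors(
    cache_path: str | Path, model_name: str, texts: Sequence[str]
) -> np.ndarray:
    """Read cached vectors for ``texts``; error if any are absent."""
    entries = _read_cache(Path(cache_path))
    rows = []
    for i, text in enumerate(texts):
        key = (model_name, _text_hash(text))
        if key not in entries:
            raise ValidationError(
                f"no cached vector for text at index {i} under model "
                f"{model_name!r}"
            )
        rows.append(entries[key])
    return np.vstack(rows) if rows else np.empty((0, 0))
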