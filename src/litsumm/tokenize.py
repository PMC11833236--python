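"""Token counting backends.

LLM context windows are measured in tokens, not words; a serviceable rule of
thumb for English prose is one token per 0.75 words.  The default backend is
the word-count estimator ``ceil(words / 0.75)``; an exact BPE backend can be
plugged in wherever a tokenizer for the target model is installed.
"""

from __future__ import annotations

import math
from typing import Callable, Protocol


class Tokenizer(Protocol):
    def count(self, text: str) -> int: ...


class WordEstimateTokenizer:
    """Estimate token counts as ``ceil(word_count / words_per_token)``.

    ``words_per_token`` defaults to 0.75, the standard English-prose rule of
    thumb (a 4096-token window holds roughly 3000 words).
    """

    def __init__(self, words_per_token: float = 0.75) -> None:
        if words_per_token <= 0:
            raise ValueError("words_per_token must be positive")
        self.words_per_token = words_per_token

    def count(self, text: str) -> int:
        words = len(text.split())
        if words == 0:
            return 0
        return math.ceil(words / self.words_per_token)


class BpeTokenizer:
    """Exact subword tokenizer for a named model, via ``tiktoken``.

    Requires ``tiktoken`` to be importable; raises at construction otherwise.
    """

    def __init__(self, model: str = "gpt-4") -> None:
        import tiktoken  # deferred: optional backend

        self._enc = tiktoken.encoding_for_model(model)

    def count(self, text: str) -> int:
        return len(self._enc.encode(text))


DEFAULT_TOKENIZER = WordEstimateTokenizer()


def count_tokens(text: str, tokenizer: Tokenizer | None = None) -> int:
    """Count tokens of ``text`` with ``tokenizer`` (default: word estimator)."""
    return (tokenizer or DEFAULT_TOKENIZER).count(text)


def get_tokenizer(name: str = "estimate", **kwargs) -> Tokenizer:
    factories: dict[str, Callable[..., Tokenizer]] = {
        "estimate": WordEstimateTokenizer,
        "bpe": BpeTokenizer,
    }
    try:
        return factories[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown tokenizer backend {name!r}") from None
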