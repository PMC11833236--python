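"""Rule-based sentence segmentation shared across the pipeline.

A sentence boundary is a run of ``.``, ``!`` or ``?`` followed by whitespace
and an uppercase letter or digit, unless the token preceding the punctuation
is a guarded abbreviation ("Fig.", "et al.", "e.g.", ...).  The segmenter is
deliberately deterministic; a statistical segmenter can be swapped in through
the :class:`Segmenter` protocol.
"""

from __future__ import annotations

import re
from typing import Protocol, Sequence

# Abbreviations that must not terminate a sentence.  Stored lowercase, with
# the trailing period; multiword entries are matched against the tail of the
# text before the candidate boundary.
ABBREVIATIONS = frozenset(
    {
        "fig.",
        "figs.",
        "et al.",
        "e.g.",
        "i.e.",
        "cf.",
        "vs.",
        "ca.",
        "approx.",
        "dr.",
        "no.",
        "nos.",
        "ref.",
        "refs.",
        "eq.",
        "eqs.",
        "spp.",
        "sp.",
    }
)

_BOUNDARY = re.compile(r"[.!?]+(?=(\s+)[\"'\(\[]?[A-Z0-9])")


class Segmenter(Protocol):
    def spans(self, text: str) -> list[tuple[int, int]]: ...


class RuleBasedSegmenter:
    """Deterministic splitter with an abbreviation guard list."""

    def __init__(self, abbreviations: Sequence[str] = ()) -> None:
        extra = {a.lower() for a in abbreviations}
        self._abbrev = ABBREVIATIONS | extra
        self._max_words = max(len(a.split()) for a in self._abbrev)

    def _guarded(self, text: str, punct_start: int, punct_end: int) -> bool:
        if text[punct_start:punct_end] != ".":
            return False  # '!' / '?' never end abbreviations
        head = text[:punct_end]
        words = head.split()
        if not words:
            return False
        for k in range(1, self._max_words + 1):
            tail = " ".join(words[-k:]).lower()
            if tail in self._abbrev:
                return True
        return False

    def spans(self, text: str) -> list[tuple[int, int]]:
        """Half-open ``[start, end)`` spans of each sentence, in order."""
        spans: list[tuple[int, int]] = []
        start = 0
        for m in _BOUNDARY.finditer(text):
            if self._guarded(text, m.start(), m.end()):
                continue
            spans.append((start, m.end()))
            start = m.end() + len(m.group(1))
        if start < len(text) and text[start:].strip():
            spans.append((start, len(text)))
        # trim leading/trailing whitespace inside each span
        out = []
        for s, e in spans:
            seg = text[s:e]
            lead = len(seg) - len(seg.lstrip())
            trail = len(seg) - len(seg.rstrip())
            if s + lead < e - trail:
                out.append((s + lead, e - trail))
        return out

    def split(self, text: str) -> list[str]:
        return [text[s:e] for s, e in self.spans(text)]


DEFAULT_SEGMENTER = RuleBasedSegmenter()


def split_sentences(text: str) -> list[str]:
    return DEFAULT_SEGMENTER.split(text)


def sentence_spans(text: str) -> list[tuple[int, int]]:
    return DEFAULT_SEGMENTER.spans(text)
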