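"""Independent brute-force re-implementations of the five reference checks.

Deliberately written with nothing but regular expressions and set
arithmetic, sharing no code with ``litsumm.audit``, so agreement between the
two routes is evidence rather than tautology.  Also: an exhaustive greedy
trace for farthest-point selection, and a naive round-robin simulator.
"""

from __future__ import annotations

import math
import re

_PMC = re.compile(r"PMC\d+")
_GROUP = re.compile(r"\[([^\[\]]*)\]")
_SPLIT = re.compile(r"(?<=[.!?])\s+(?=[\[\"'(]?[A-Z0-9])")


def oracle_sentence_count(summary: str) -> int:
    return len([s for s in _SPLIT.split(summary) if s.strip()])


def _oracle_instances(summary: str) -> list[tuple[int, int, list[str]]]:
    """(start, end, pmcids) for bracket groups with PMC ids and bare PMC tokens."""
    out = []
    covered = []
    for m in _GROUP.finditer(summary):
        ids = _PMC.findall(m.group(1))
        if ids:
            out.append((m.start(), m.end(), ids))
            covered.append((m.start(), m.end()))
    for m in _PMC.finditer(summary):
        if any(s <= m.start() < e for s, e in covered):
            continue
        if m.end() < len(summary) and summary[m.end()].isalnum():
            continue
        out.append((m.start(), m.end(), [m.group(0)]))
    return sorted(out)


def oracle_adequacy(summary: str, min_ratio: float = 0.5) -> bool:
    refs = sum(len(ids) for _, _, ids in _oracle_instances(summary))
    return refs >= min_ratio * oracle_sentence_count(summary)


def oracle_formatting(summary: str) -> bool:
    for m in _GROUP.finditer(summary):
        tokens = [t for t in re.split(r"[,;\s]+", m.group(1).strip()) if t]
        if not tokens or any(not re.fullmatch(r"PMC\d+", t) for t in tokens):
            return False
    if re.search(r"\bPMID\b|\bdoi\b", summary, re.IGNORECASE):
        return False
    if re.search(r"\bPMC(?!\d)", summary):
        return False
    if re.search(r"\(\s*PMC\d+[^)]*\)", summary):
        return False
    return True


def oracle_realness(summary: str, context_pmcids: set[str]) -> bool:
    return set(_PMC.findall(summary)) <= context_pmcids


def _oracle_terminal(tail: str) -> bool:
    """Terminal iff only closing punctuation separates the instance from the
    end of the text or from the start of the next sentence."""
    seen_ender = False
    j = 0
    while j < len(tail) and tail[j] in " \t.!?;:'\")]":
        if tail[j] in ".!?":
            seen_ender = True
        j += 1
    return j >= len(tail) or seen_ender


def oracle_placement(summary: str, max_nonterminal_fraction: float = 0.2) -> bool:
    inst = _oracle_instances(summary)
    if not inst:
        return True
    # trailing pure-reference block holding every citation of the summary
    m = re.search(r"((?:\s*\[[^\[\]]*\])+)\s*$", summary)
    if m and _PMC.search(m.group(1)):
        head = summary[: m.start()]
        if not _PMC.search(head) and re.search(r"[.!?]\s*$", head.rstrip()):
            return False
    nonterminal = sum(1 for _, end, _ in inst if not _oracle_terminal(summary[end:]))
    return nonterminal / len(inst) <= max_nonterminal_fraction


def oracle_concentration(summary: str, max_fraction: float = 0.5, min_total: int = 3) -> bool:
    sizes = [len(ids) for _, _, ids in _oracle_instances(summary)]
    total = sum(sizes)
    if total < min_total:
        return True
    return max(sizes) <= max_fraction * total


def oracle_greedy_trace(
    vectors, token_counts, context_limit: int, seed_index: int = 0
) -> list[int]:
    """Exhaustive min-max-cosine greedy trace, explicit loops throughout."""

    def cos(a, b) -> float:
        num = sum(x * y for x, y in zip(a, b))
        na = math.sqrt(sum(x * x for x in a)) or 1.0
        nb = math.sqrt(sum(x * x for x in b)) or 1.0
        return num / (na * nb)

    n = len(vectors)
    if n == 0 or token_counts[seed_index] > context_limit:
        return []
    selected = [seed_index]
    total = token_counts[seed_index]
    remaining = [i for i in range(n) if i != seed_index]
    while remaining:
        scored = []
        for i in remaining:
            worst = max(cos(vectors[i], vectors[j]) for j in selected)
            scored.append((worst, i))
        scored.sort()
        best = scored[0][1]
        if total + token_counts[best] > context_limit:
            break
        selected.append(best)
        total += token_counts[best]
        remaining.remove(best)
    return selected


def oracle_round_robin(queues: list[list[int]], token_counts, context_limit: int) -> list[int]:
    """Naive cyclic simulator: queues already ordered (exemplars first),
    clusters already sorted largest-first."""
    queues = [list(q) for q in queues]
    selected: list[int] = []
    total = 0
    while any(queues):
        for q in queues:
            if not q:
                continue
            cand = q[0]
            if total + token_counts[cand] > context_limit:
                return selected
            q.pop(0)
            selected.append(cand)
            total += token_counts[cand]
    return selected
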