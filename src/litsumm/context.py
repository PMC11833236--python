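"""Token-budgeted context construction.

From a per-RNA sentence corpus, assemble the block of literature sentences
handed to the LLM as its sole source of facts, under a hard token cap
(default 2560 of a 4096-token window, leaving room for the prompt, the
~255-token summary, and a ~1150-token revision round trip).

Selection dispatch, in order:

* fewer than five sentences            -> ``skipped_too_few`` (nothing to say)
* everything fits in the cap           -> ``all`` (no selection)
* too much text, clustering unusable   -> ``length_sort`` (longest sentences first)
* too much text, clusters found        -> ``topic_round_robin`` (one sentence per
  topic in turn, exemplars first, for broad coverage)
* even the cluster exemplars overflow  -> ``topic_greedy`` (farthest-point pick
  over exemplars by cosine similarity)

Topic structure comes from embedding each sentence (384-d), reducing to 20
dimensions with UMAP, and density-clustering with HDBSCAN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingBackend, HashedNgramEmbedder
from .harvest import SentenceRecord
from .tokenize import Tokenizer, count_tokens


class Strategy(str, Enum):
    ALL = "all"
    LENGTH_SORT = "length_sort"
    TOPIC_ROUND_ROBIN = "topic_round_robin"
    TOPIC_GREEDY = "topic_greedy"
    SKIPPED_TOO_FEW = "skipped_too_few"


@dataclass(frozen=True)
class TokenBudget:
    """Token accounting for a single summarisation call chain.

    ``context_limit`` is the hard cap on context sentences; the remaining
    window is reserved for the prompt (60-140 tokens), the output summary
    (~255 tokens) and a revision round (~1150 tokens).
    """

    model_window: int = 4096
    context_limit: int = 2560
    reserved_output: int = 255
    reserved_prompt: int = 140
    reserved_revision: int = 1150
    slack: int = 109  # documented allowance: reservations are estimates

    def __post_init__(self) -> None:
        if not self.context_limit < self.model_window:
            raise ValueError("context_limit must be smaller than the model window")
        committed = (
            self.context_limit
            + self.reserved_output
            + self.reserved_prompt
            + self.reserved_revision
        )
        if committed > self.model_window + self.slack:
            raise ValueError(
                f"budget over-committed: {committed} > window {self.model_window} "
                f"+ slack {self.slack}"
            )


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embed/reduce/cluster knobs for topic selection."""

    embed_dim: int = 384
    reduced_dim: int = 20
    min_cluster_size: int = 5
    exemplar_fraction: float = 0.1
    seed: int = 0
    backend: str = "hashed"  # "hashed" | "sentence-transformer"
    reducer: str = "umap"  # "umap" | "pca"
    min_sentences: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.reduced_dim <= self.embed_dim:
            raise ValueError("require 0 < reduced_dim <= embed_dim")


@dataclass
class Context:
    """The ordered, budgeted sentence set for one RNA, with provenance."""

    rna_id: str
    sentences: list[SentenceRecord]
    total_tokens: int
    strategy: Strategy
    cluster_labels: list[int] | None = None
    notes: tuple[str, ...] = ()

    @property
    def pmcids(self) -> set[str]:
        return {s.pmcid for s in self.sentences}

    def rendered(self) -> str:
        """Context block as fed to the LLM: one tagged sentence per line."""
        return "\n".join(f"[{s.pmcid}] {s.sentence}" for s in self.sentences)

    def to_json(self) -> dict:
        return {
            "rna_id": self.rna_id,
            "strategy": self.strategy.value,
            "total_tokens": self.total_tokens,
            "sentences": [{"pmcid": s.pmcid, "sentence": s.sentence} for s in self.sentences],
            "notes": list(self.notes),
        }

    @classmethod
    def from_json(cls, d: dict) -> "Context":
        return cls(
            rna_id=d["rna_id"],
            sentences=[
                SentenceRecord(rna_id=d["rna_id"], pmcid=s["pmcid"], sentence=s["sentence"])
                for s in d["sentences"]
            ],
            total_tokens=d["total_tokens"],
            strategy=Strategy(d["strategy"]),
            notes=tuple(d.get("notes", ())),
        )


def save_context(ctx: Context, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ctx.to_json(), indent=1) + "\n")


def load_context(path: str | Path) -> Context:
    return Context.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# embed / reduce / cluster


def embed(
    texts: Sequence[str],
    cfg: EmbeddingConfig = EmbeddingConfig(),
    backend: EmbeddingBackend | None = None,
) -> np.ndarray:
    """One ``embed_dim`` vector per sentence."""
    if len(texts) == 0:
        raise ValueError("cannot embed an empty corpus")
    if backend is None:
        if cfg.backend == "hashed":
            backend = HashedNgramEmbedder(dim=cfg.embed_dim, seed=cfg.seed)
        else:
            from .embedding import get_embedder

            backend = get_embedder(cfg.backend, dim=cfg.embed_dim, seed=cfg.seed)
    return backend.encode(texts)


def reduce(matrix: np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Seeded dimensionality reduction to ``reduced_dim`` columns.

    Below ``reduced_dim + 2`` rows the reduction is ill-posed and the input
    passes through unchanged with a warning.
    """
    n = matrix.shape[0]
    if n < cfg.reduced_dim + 2:
        warnings.warn(
            f"{n} rows is too few to reduce to {cfg.reduced_dim} dimensions; passing through",
            stacklevel=2,
        )
        return matrix
    if cfg.reducer == "pca":
        from sklearn.decomposition import PCA

        return PCA(n_components=cfg.reduced_dim, random_state=cfg.seed).fit_transform(matrix)
    import umap  # deferred: numba JIT import cost

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = umap.UMAP(
            n_components=cfg.reduced_dim,
            n_neighbors=min(15, n - 1),
            random_state=cfg.seed,
        )
        return np.asarray(model.fit_transform(matrix), dtype=np.float64)


def cluster(
    matrix: np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig()
) -> tuple[np.ndarray, dict[int, list[int]]]:
    """HDBSCAN labels plus per-cluster exemplar indices.

    Labels are ``-1`` (noise) or ``0..K-1``.  A cluster's exemplars are its
    density-core representatives: the top ``exemplar_fraction`` of members
    (at least one) ranked by cluster-membership strength, ties broken by
    index for determinism.  Clustering is *applicable* for selection
    purposes iff at least two clusters emerge; callers fall back to length
    sorting otherwise.
    """
    n = matrix.shape[0]
    if n < 2 * cfg.min_cluster_size:
        return np.full(n, -1, dtype=int), {}
    from sklearn.cluster import HDBSCAN

    model = HDBSCAN(min_cluster_size=cfg.min_cluster_size, copy=True)
    model.fit(matrix)
    labels = np.asarray(model.labels_, dtype=int)
    probs = np.asarray(model.probabilities_, dtype=float)
    exemplars: dict[int, list[int]] = {}
    for lab in sorted(set(labels.tolist()) - {-1}):
        members = [int(i) for i in np.flatnonzero(labels == lab)]
        k = max(1, int(len(members) * cfg.exemplar_fraction))
        ranked = sorted(members, key=lambda i: (-probs[i], i))
        exemplars[lab] = sorted(ranked[:k])
    return labels, exemplars


def clustering_applicable(labels: np.ndarray, exemplars: dict[int, list[int]]) -> bool:
    return len(exemplars) >= 2


# ---------------------------------------------------------------------------
# fills


def length_sort_fill(
    corpus: Sequence[SentenceRecord],
    budget: TokenBudget,
    tokenizer: Tokenizer | None = None,
) -> Context:
    """Longest-first greedy prefix: sort by token count descending and take
    sentences until the next one would overflow the cap."""
    records = _with_token_counts(corpus, tokenizer)
    notes: list[str] = []
    usable, dropped = _drop_oversized(records, budget)
    if dropped:
        notes.append(f"dropped {dropped} oversized sentence(s) exceeding the context cap")
    order = sorted(range(len(usable)), key=lambda i: (-usable[i].token_count, i))
    chosen: list[SentenceRecord] = []
    total = 0
    for i in order:
        if total + usable[i].token_count > budget.context_limit:
            break
        chosen.append(usable[i])
        total += usable[i].token_count
    if not chosen:
        notes.append("degenerate: no sentence fits the context cap")
    rna_id = corpus[0].rna_id if corpus else ""
    return Context(rna_id, chosen, total, Strategy.LENGTH_SORT, notes=tuple(notes))


def round_robin_fill(
    labels: Sequence[int],
    exemplars: dict[int, list[int]],
    token_counts: Sequence[int],
    budget: TokenBudget,
    seed: int = 0,
) -> list[int]:
    """Cyclic per-cluster sampling: one unused sentence per cluster per visit,
    exemplars before ordinary members, largest cluster first.

    Stops as soon as the next candidate would overflow the cap, so every
    cluster contributes one sentence before any contributes two (budget
    permitting).  Noise points become eligible only after every cluster is
    exhausted.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    sizes = {lab: int((labels == lab).sum()) for lab in exemplars}
    order = sorted(exemplars, key=lambda lab: (-sizes[lab], lab))
    queues: dict[int, list[int]] = {}
    for lab in order:
        ex = sorted(exemplars[lab])
        members = [int(i) for i in np.flatnonzero(labels == lab) if i not in set(ex)]
        members = list(rng.permutation(members)) if members else []
        queues[lab] = ex + [int(m) for m in members]

    selected: list[int] = []
    total = 0
    active = list(order)
    while active:
        progressed = []
        for lab in active:
            if not queues[lab]:
                continue
            cand = queues[lab][0]
            if total + token_counts[cand] > budget.context_limit:
                return selected
            queues[lab].pop(0)
            selected.append(cand)
            total += token_counts[cand]
            progressed.append(lab)
        active = [lab for lab in active if queues[lab]]
        if not progressed and active:
            break
    noise = [int(i) for i in np.flatnonzero(labels == -1)]
    for cand in rng.permutation(noise) if noise else []:
        cand = int(cand)
        if total + token_counts[cand] > budget.context_limit:
            return selected
        selected.append(cand)
        total += token_counts[cand]
    return selected


def greedy_dissimilar_fill(
    vectors: np.ndarray,
    token_counts: Sequence[int],
    budget: TokenBudget,
    seed_index: int = 0,
) -> list[int]:
    """Farthest-point selection over cluster exemplars.

    Starts from the largest cluster's exemplar and repeatedly adds the
    candidate whose *maximum* cosine similarity to the already-selected set
    is smallest (ties to the lowest index), until the next pick would
    overflow the token cap.
    """
    n = vectors.shape[0]
    if n == 0:
        return []
    sims = _cosine_matrix(vectors)
    selected: list[int] = []
    total = 0
    if token_counts[seed_index] > budget.context_limit:
        return []
    selected.append(seed_index)
    total += token_counts[seed_index]
    remaining = [i for i in range(n) if i != seed_index]
    while remaining:
        best = min(remaining, key=lambda i: (max(sims[i, j] for j in selected), i))
        if total + token_counts[best] > budget.context_limit:
            break
        selected.append(best)
        total += token_counts[best]
        remaining.remove(best)
    return selected


def _cosine_matrix(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vectors / norms
    return unit @ unit.T


# ---------------------------------------------------------------------------
# dispatch


def select(
    corpus: Sequence[SentenceRecord],
    budget: TokenBudget = TokenBudget(),
    cfg: EmbeddingConfig = EmbeddingConfig(),
    tokenizer: Tokenizer | None = None,
    embedder: EmbeddingBackend | None = None,
) -> Context:
    """Dispatch a corpus to the appropriate selection strategy (module docstring)."""
    if not corpus:
        return Context("", [], 0, Strategy.SKIPPED_TOO_FEW)
    rna_ids = {r.rna_id for r in corpus}
    if len(rna_ids) > 1:
        raise ValueError(f"corpus mixes RNA ids: {sorted(rna_ids)}")
    rna_id = corpus[0].rna_id

    records = _dedupe(_with_token_counts(corpus, tokenizer))
    if len(records) < cfg.min_sentences:
        return Context(rna_id, [], 0, Strategy.SKIPPED_TOO_FEW)

    total = sum(r.token_count for r in records)
    if total <= budget.context_limit:
        return Context(rna_id, list(records), total, Strategy.ALL)

    usable, dropped = _drop_oversized(records, budget)
    notes = (
        (f"dropped {dropped} oversized sentence(s) exceeding the context cap",)
        if dropped
        else ()
    )

    if len(usable) >= 2 * cfg.min_cluster_size:
        vectors = embed([r.sentence for r in usable], cfg, backend=embedder)
        reduced = reduce(vectors, cfg)
        labels, exemplars = cluster(reduced, cfg)
    else:
        labels, exemplars, reduced = np.array([]), {}, None

    if not clustering_applicable(np.asarray(labels), exemplars):
        ctx = length_sort_fill(usable, budget, tokenizer)
        return replace(ctx, rna_id=rna_id, notes=ctx.notes + notes)

    token_counts = [r.token_count for r in usable]
    exemplar_indices = sorted(i for idxs in exemplars.values() for i in idxs)
    exemplar_token_sum = sum(token_counts[i] for i in exemplar_indices)

    if exemplar_token_sum > budget.context_limit:
        sizes = {lab: int((np.asarray(labels) == lab).sum()) for lab in exemplars}
        largest = min(exemplars, key=lambda lab: (-sizes[lab], lab))
        seed_pos = exemplar_indices.index(min(exemplars[largest]))
        picked = greedy_dissimilar_fill(
            reduced[exemplar_indices],
            [token_counts[i] for i in exemplar_indices],
            budget,
            seed_index=seed_pos,
        )
        chosen = [exemplar_indices[i] for i in picked]
        strategy = Strategy.TOPIC_GREEDY
    else:
        chosen = round_robin_fill(labels, exemplars, token_counts, budget, seed=cfg.seed)
        strategy = Strategy.TOPIC_ROUND_ROBIN

    sentences = [usable[i] for i in chosen]
    return Context(
        rna_id,
        sentences,
        sum(s.token_count for s in sentences),
        strategy,
        cluster_labels=[int(np.asarray(labels)[i]) for i in chosen],
        notes=notes,
    )


def _with_token_counts(
    corpus: Sequence[SentenceRecord], tokenizer: Tokenizer | None
) -> list[SentenceRecord]:
    out = []
    for r in corpus:
        if r.token_count <= 0:
            r = replace(r, token_count=count_tokens(r.sentence, tokenizer))
        out.append(r)
    return out


def _dedupe(records: Sequence[SentenceRecord]) -> list[SentenceRecord]:
    seen: set[tuple[str, str]] = set()
    out = []
    for r in records:
        key = (r.pmcid, r.sentence)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def _drop_oversized(
    records: Sequence[SentenceRecord], budget: TokenBudget
) -> tuple[list[SentenceRecord], int]:
    usable = [r for r in records if r.token_count <= budget.context_limit]
    return usable, len(records) - len(usable)
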