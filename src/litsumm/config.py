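"""TOML configuration loading.

A single ``[litsumm]``-style TOML file configures budgets, thresholds,
selection knobs, sampling parameters, and the LLM backend.  Every key is
optional; omitted keys fall back to the documented defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .audit import CheckThresholds
from .context import EmbeddingConfig, TokenBudget
from .orchestrator import PipelineConfig
from .prompting import GenerationParams, HttpChatBackend, LlmBackend, ScriptedBackend


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    raw: dict = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text())

    budget = TokenBudget(
        model_window=raw.get("model_window", 4096),
        context_limit=raw.get("context_limit", 2560),
    )
    embedding = EmbeddingConfig(
        embed_dim=raw.get("embed_dim", 384),
        reduced_dim=raw.get("reduced_dim", 20),
        min_cluster_size=raw.get("min_cluster_size", 5),
        min_sentences=raw.get("min_sentences", 5),
        backend=raw.get("embedding_backend", "hashed"),
        reducer=raw.get("reducer", "umap"),
        seed=raw.get("seed", 0),
    )
    thresholds = CheckThresholds(
        min_refs_per_sentence=raw.get("min_refs_per_sentence", 0.5),
        max_fraction_per_instance=raw.get("max_fraction_per_instance", 0.5),
        min_total_for_concentration=raw.get("min_total_for_concentration", 3),
        max_nonterminal_fraction=raw.get("max_nonterminal_fraction", 0.2),
    )
    params = GenerationParams(
        temperature=raw.get("temperature", 0.1),
        presence_penalty=raw.get("presence_penalty", -2.0),
        frequency_penalty=raw.get("frequency_penalty", 1.0),
        max_output_tokens=raw.get("max_output_tokens", 255),
    )
    cfg_seed = seed if seed is not None else raw.get("seed", 0)
    return PipelineConfig(
        max_attempts=raw.get("max_attempts", 4),
        thresholds=thresholds,
        budget=budget,
        params=params,
        embedding=embedding,
        seed=cfg_seed,
        display_policy=raw.get("display_policy", "hide_flagged"),
    )


def load_backend(name: str, path: str | Path | None = None) -> LlmBackend:
    raw: dict = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text())
    if name == "scripted":
        return ScriptedBackend()
    if name == "http":
        return HttpChatBackend(
            endpoint=raw.get("endpoint", "http://localhost:8000/v1/chat/completions"),
            model=raw.get("model", "gpt-4-1106-preview"),
            api_key_env=raw.get("api_key_env", "LITSUMM_API_KEY"),
        )
    raise ValueError(f"unknown backend {name!r}")
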