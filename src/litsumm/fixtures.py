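"""Synthetic corpora, defective summaries, and scripted LLM transcripts.

Everything the pipeline consumes can be generated here deterministically, so
every selection regime, reference-check failure, and pipeline path is
testable offline.  Synthetic sentences are template-based English with a
controlled, disjoint vocabulary per topic (expression, disease association,
localization, interaction), which lets the hashed n-gram embedding backend
separate topics without any model download.  Invented PMCIDs come from a
numeric range disjoint from any generated corpus, so realness violations
are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .audit import Check, run_all
from .context import Context, EmbeddingConfig, TokenBudget, select
from .harvest import SentenceRecord
from .prompting import ScriptedBackend

TOPICS = ("expression", "disease", "localization", "interaction")

# Disjoint controlled vocabularies; sentences drawn from one topic share
# vocabulary only through the RNA ID and a few function words.
_TOPIC_VOCAB: dict[str, list[str]] = {
    "expression": (
        "expression upregulated downregulated transcript abundance northern blot "
        "qpcr induced suppressed levels fold-change overexpression knockdown "
        "promoter transcription enhancer silencing rna-seq microarray depletion "
        "transfection reporter luciferase stably transiently elevated reduced"
    ).split(),
    "disease": (
        "carcinoma tumor prognosis metastasis survival patients biomarker "
        "malignant benign cohort diagnosis staging recurrence chemotherapy "
        "resistance oncogenic suppressor proliferation invasion migration "
        "apoptosis xenograft clinical hepatocellular gastric colorectal glioma"
    ).split(),
    "localization": (
        "nucleus cytoplasm nuclear cytoplasmic localization exosome speckle "
        "chromatin nucleolus compartment shuttling fish hybridization fraction "
        "fractionation enriched membrane mitochondrial perinuclear foci puncta "
        "granules paraspeckle retained exported subcellular imaging confocal"
    ).split(),
    "interaction": (
        "binds interacts sponge scaffold complex pulldown immunoprecipitation "
        "rip clip crosslinking motif domain partner protein recruitment "
        "sequestration duplex hybridizes target site seed pairing axis "
        "competing endogenous decoy tethering association affinity"
    ).split(),
}

_INVENTED_PMC_BASE = 900_000_000  # disjoint from every generated corpus


class Defect(str, Enum):
    NONE = "none"
    TOO_FEW_REFS = "too_few_refs"
    NON_PMC_FORMAT = "non_pmc_format"
    INVENTED_PMCID = "invented_pmcid"
    TRAILING_REF_BLOCK = "trailing_ref_block"
    STACKED_REFS = "stacked_refs"
    UNSUPPORTED_CLAIM = "unsupported_claim"


#: which reference check each defect must trip (NONE / UNSUPPORTED_CLAIM: none)
DEFECT_TO_CHECK: dict[Defect, Check | None] = {
    Defect.NONE: None,
    Defect.TOO_FEW_REFS: Check.ADEQUACY,
    Defect.NON_PMC_FORMAT: Check.FORMATTING,
    Defect.INVENTED_PMCID: Check.REALNESS,
    Defect.TRAILING_REF_BLOCK: Check.PLACEMENT,
    Defect.STACKED_REFS: Check.CONCENTRATION,
    Defect.UNSUPPORTED_CLAIM: None,
}


class SpecError(ValueError):
    """The fixture specification is contradictory or unsatisfiable."""


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for one synthetic per-RNA sentence corpus."""

    rna_id: str = "hsa-mir-21"
    n_articles: int = 4
    sentences_per_article: tuple[int, int] = (2, 6)  # uniform inclusive range
    n_topics: int = 4
    token_length_range: tuple[int, int] = (20, 35)  # per-sentence tokens
    seed: int = 0
    pmc_base: int = 7_000_000

    def __post_init__(self) -> None:
        if not 1 <= self.n_topics <= len(TOPICS):
            raise SpecError(f"n_topics must be in [1, {len(TOPICS)}]")
        if self.sentences_per_article[0] < 1:
            raise SpecError("articles need at least one sentence")


def make_corpus(spec: CorpusSpec) -> list[SentenceRecord]:
    """Deterministic synthetic corpus with balanced planted topics.

    Sentences cycle through the first ``n_topics`` topics so the planted
    structure is balanced and recoverable by clustering; every sentence
    contains the RNA ID verbatim; PMCIDs are unique and PMC-formatted.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.sentences_per_article
    counts = rng.integers(lo, hi + 1, size=spec.n_articles)
    if spec.n_topics > int(counts.sum()):
        raise SpecError("n_topics exceeds the total sentence count")
    records: list[SentenceRecord] = []
    k = 0
    for a in range(spec.n_articles):
        pmcid = f"PMC{spec.pmc_base + a}"
        for _ in range(int(counts[a])):
            topic = TOPICS[k % spec.n_topics]
            records.append(
                SentenceRecord(
                    rna_id=spec.rna_id,
                    pmcid=pmcid,
                    sentence=_make_sentence(spec.rna_id, topic, spec.token_length_range, rng),
                )
            )
            k += 1
    return records


def _make_sentence(
    rna_id: str, topic: str, token_range: tuple[int, int], rng: np.random.Generator
) -> str:
    vocab = _TOPIC_VOCAB[topic]
    target_tokens = int(rng.integers(token_range[0], token_range[1] + 1))
    n_words = max(4, int(target_tokens * 0.75))  # estimator: 0.75 words/token
    words = [str(w) for w in rng.choice(vocab, size=n_words - 2)]
    body = " ".join(words)
    opener = str(rng.choice(["Notably,", "Here,", "Moreover,", "In addition,"]))
    return f"{opener} {rna_id} {body}."


# ---------------------------------------------------------------------------
# selection-regime presets


def corpus_for_regime(regime: str, seed: int = 0, rna_id: str = "hsa-mir-21") -> CorpusSpec:
    """Corpus specs sized to land in each of the four selection regimes
    (too-few, fits-budget, over-budget clustered, exemplars-over-budget)
    plus the length-sort fallback, under the default 2560-token cap."""
    presets = {
        # 4 sentences: below the five-sentence floor
        "skipped": CorpusSpec(
            rna_id, n_articles=1, sentences_per_article=(4, 4), n_topics=2, seed=seed
        ),
        # ~20 short sentences, well under the cap
        "all": CorpusSpec(
            rna_id,
            n_articles=4,
            sentences_per_article=(4, 6),
            token_length_range=(15, 25),
            seed=seed,
        ),
        # 8 very long sentences: over budget but below the clustering floor
        "length_sort": CorpusSpec(
            rna_id,
            n_articles=2,
            sentences_per_article=(4, 4),
            n_topics=2,
            token_length_range=(380, 420),
            seed=seed,
        ),
        # ~200 short sentences: over budget, exemplars fit
        "round_robin": CorpusSpec(
            rna_id,
            n_articles=10,
            sentences_per_article=(18, 22),
            token_length_range=(20, 30),
            seed=seed,
        ),
        # ~400 long sentences: even the exemplar cores overflow the cap
        "greedy": CorpusSpec(
            rna_id,
            n_articles=10,
            sentences_per_article=(38, 42),
            token_length_range=(110, 130),
            seed=seed,
        ),
    }
    try:
        return presets[regime]
    except KeyError:
        raise SpecError(f"unknown regime {regime!r}") from None


# ---------------------------------------------------------------------------
# defective summaries


@dataclass(frozen=True)
class DefectSpec:
    defect: Defect
    base_context: Context
    seed: int = 0


def make_defective_summary(spec: DefectSpec) -> str:
    """Summary violating exactly the named reference check (verified before return).

    ``none`` passes all five checks; ``unsupported_claim`` also passes all
    five (its flaw is semantic and only the consistency stage can see it).
    """
    ctx = spec.base_context
    if not ctx.sentences:
        raise SpecError("base context is empty")
    pmcids = sorted(ctx.pmcids)
    rng = np.random.default_rng(spec.seed)
    rna = ctx.rna_id or "the RNA"

    def claim(i: int) -> str:
        topic = TOPICS[i % len(TOPICS)]
        w = [str(x) for x in rng.choice(_TOPIC_VOCAB[topic], size=4)]
        return f"{rna.capitalize()} shows {w[0]} and {w[1]} linked to {w[2]} {w[3]}"

    def pmc(i: int) -> str:
        return pmcids[i % len(pmcids)]

    d = spec.defect
    if d is Defect.NONE or d is Defect.UNSUPPORTED_CLAIM:
        lines = [f"{claim(i)} [{pmc(i)}]." for i in range(4)]
        if d is Defect.UNSUPPORTED_CLAIM:
            lines.insert(
                2, f"{rna.capitalize()} expands DFU as diabetic foot ulcer [{pmc(0)}]."
            )
        summary = " ".join(lines)
    elif d is Defect.TOO_FEW_REFS:
        lines = [f"{claim(0)} [{pmc(0)}]."] + [f"{claim(i)}." for i in range(1, 4)]
        summary = " ".join(lines)
    elif d is Defect.NON_PMC_FORMAT:
        lines = [f"{claim(i)} [{pmc(i)}]." for i in range(3)] + [f"{claim(3)} [1]."]
        summary = " ".join(lines)
    elif d is Defect.INVENTED_PMCID:
        fake = f"PMC{_INVENTED_PMC_BASE + int(rng.integers(0, 10_000))}"
        lines = [f"{claim(i)} [{pmc(i)}]." for i in range(3)] + [f"{claim(3)} [{fake}]."]
        summary = " ".join(lines)
    elif d is Defect.TRAILING_REF_BLOCK:
        lines = [f"{claim(i)}." for i in range(3)]
        block = " ".join(f"[{pmc(i)}]" for i in range(3))
        summary = " ".join(lines) + " " + block
    elif d is Defect.STACKED_REFS:
        if len(pmcids) < 2:
            raise SpecError("stacked_refs needs at least two distinct context PMCIDs")
        lines = [f"{claim(i)} [{pmc(i)}]." for i in range(3)]
        stacked = ", ".join(pmc(i) for i in range(5))
        lines.append(f"{claim(3)} [{stacked}].")
        summary = " ".join(lines)
    else:  # pragma: no cover
        raise SpecError(f"unknown defect {d}")

    _verify_defect(summary, ctx, d)
    return summary


def _verify_defect(summary: str, ctx: Context, d: Defect) -> None:
    audit = run_all(summary, ctx)
    failed = {r.check for r in audit.reports if not r.passed}
    intended = DEFECT_TO_CHECK[d]
    expected = {intended} if intended else set()
    if failed != expected:
        raise SpecError(
            f"defect {d.value} produced failures {sorted(c.value for c in failed)}, "
            f"expected {sorted(c.value for c in expected)}"
        )


# ---------------------------------------------------------------------------
# scripted pipeline paths


PATHS = ("first_pass_clean", "rescue_then_clean", "exhaust_four", "consistency_revise")

#: path -> (terminal status name, expected generation calls)
PATH_EXPECTATIONS = {
    "first_pass_clean": ("consistency_clean", 1),
    "rescue_then_clean": ("consistency_clean", 2),
    "exhaust_four": ("flagged_refs_exhausted", 4),
    "consistency_revise": ("consistency_revised", 1),
}


def _all_true(summary: str) -> str:
    from .consistency import split_bullets

    n = len(split_bullets(summary))
    return "\n".join(f"{i}. TRUE — restated from the cited context sentence" for i in range(1, n + 1))


def _one_false(summary: str) -> str:
    from .consistency import split_bullets

    n = len(split_bullets(summary))
    lines = [f"1. FALSE — the context never mentions this expansion"]
    lines += [f"{i}. TRUE — restated from the cited context sentence" for i in range(2, n + 1)]
    return "\n".join(lines)


def make_script(path: str, context: Context, seed: int = 0) -> ScriptedBackend:
    """Scripted backend realizing one named pipeline path against ``context``."""
    clean = make_defective_summary(DefectSpec(Defect.NONE, context, seed=seed))
    revised = make_defective_summary(DefectSpec(Defect.NONE, context, seed=seed + 1))
    bad = make_defective_summary(DefectSpec(Defect.TOO_FEW_REFS, context, seed=seed))
    backend = ScriptedBackend()
    if path == "first_pass_clean":
        backend.queue("initial", clean)
        backend.queue("consistency_check", _all_true(clean))
    elif path == "rescue_then_clean":
        backend.queue("initial", bad)
        backend.queue("rescue_adequacy", clean)
        backend.queue("consistency_check", _all_true(clean))
    elif path == "exhaust_four":
        backend.queue("initial", bad)
        backend.queue(
            "rescue_adequacy",
            make_defective_summary(DefectSpec(Defect.TOO_FEW_REFS, context, seed=seed + 1)),
            make_defective_summary(DefectSpec(Defect.TOO_FEW_REFS, context, seed=seed + 2)),
            make_defective_summary(DefectSpec(Defect.TOO_FEW_REFS, context, seed=seed + 3)),
        )
    elif path == "consistency_revise":
        backend.queue("initial", clean)
        backend.queue("consistency_check", _one_false(clean))
        backend.queue("consistency_revise", revised)
    else:
        raise SpecError(f"unknown pipeline path {path!r}")
    return backend


def small_context(
    rna_id: str = "hsa-mir-21", n_sentences: int = 8, seed: int = 0
) -> Context:
    """Convenience: a fits-budget context for defect and script fixtures."""
    spec = CorpusSpec(
        rna_id,
        n_articles=4,
        sentences_per_article=(2, 2),
        token_length_range=(15, 25),
        seed=seed,
    )
    corpus = make_corpus(spec)[:n_sentences]
    return select(corpus, TokenBudget(), EmbeddingConfig(seed=seed))
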