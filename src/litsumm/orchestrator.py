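"""Per-RNA pipeline execution and batch statistics.

For each RNA: build the context, generate a summary, loop through the
reference checks with check-specific rescue prompts (at most four generation
attempts in total), then run the bullet-wise consistency pass and a final
reference check.  Results carry a full per-attempt provenance trail; items
that exhaust their attempts or fail the final check are *flagged* — retained
in the outputs but excluded from the displayable export.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .audit import AuditResult, CheckThresholds, run_all
from .consistency import ConsistencyReport, consistency_pass
from .context import Context, EmbeddingConfig, Strategy, TokenBudget, select
from .harvest import SentenceRecord
from .prompting import (
    CHECK_PARAMS,
    GenerationParams,
    LlmBackend,
    LlmExchange,
    TransportError,
    complete,
    get_template,
    render,
)


class Status(str, Enum):
    REFS_FIRST_PASS = "refs_first_pass"
    REFS_AFTER_REVISION = "refs_after_revision"
    FLAGGED_REFS_EXHAUSTED = "flagged_refs_exhausted"
    CONSISTENCY_CLEAN = "consistency_clean"
    CONSISTENCY_REVISED = "consistency_revised"
    FLAGGED_CONSISTENCY = "flagged_consistency"
    SKIPPED_TOO_FEW = "skipped_too_few"


@dataclass(frozen=True)
class PipelineConfig:
    max_attempts: int = 4
    thresholds: CheckThresholds = field(default_factory=CheckThresholds)
    budget: TokenBudget = field(default_factory=TokenBudget)
    params: GenerationParams = field(default_factory=GenerationParams)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    seed: int = 0
    display_policy: str = "hide_flagged"  # "hide_flagged" | "show_all"

    def __post_init__(self) -> None:
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    def fingerprint(self) -> str:
        blob = json.dumps(
            {
                "max_attempts": self.max_attempts,
                "context_limit": self.budget.context_limit,
                "min_refs_per_sentence": self.thresholds.min_refs_per_sentence,
                "params": [
                    self.params.temperature,
                    self.params.presence_penalty,
                    self.params.frequency_penalty,
                ],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class AttemptRecord:
    attempt_index: int  # 1-based
    summary_text: str
    audit: AuditResult
    rescue_used: str | None = None  # rescue template that produced this attempt
    exchanges: list[LlmExchange] = field(default_factory=list)


@dataclass
class PipelineResult:
    rna_id: str
    final_summary: str | None
    ref_status: Status | None
    consistency_status: Status | None
    status: Status
    attempts: list[AttemptRecord] = field(default_factory=list)
    consistency_report: ConsistencyReport | None = None
    final_audit: AuditResult | None = None
    displayable: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def generation_calls(self) -> int:
        return len(self.attempts)

    def pmcids_cited(self) -> list[str]:
        if self.final_audit is None:
            return []
        return sorted({p for i in self.final_audit.instances for p in i.pmcids})

    def to_json(self) -> dict:
        return {
            "rna_id": self.rna_id,
            "final_summary": self.final_summary,
            "ref_status": self.ref_status.value if self.ref_status else None,
            "consistency_status": (
                self.consistency_status.value if self.consistency_status else None
            ),
            "status": self.status.value,
            "displayable": self.displayable,
            "n_attempts": len(self.attempts),
            "pmcids_cited": self.pmcids_cited(),
            "consistency": (
                self.consistency_report.to_json() if self.consistency_report else None
            ),
            "metadata": self.metadata,
        }


def _metadata(config: PipelineConfig, backend: LlmBackend, context: Context) -> dict:
    return {
        "backend": type(backend).__name__,
        "model": getattr(backend, "model", "scripted"),
        "selection_strategy": context.strategy.value,
        "context_tokens": context.total_tokens,
        "config_fingerprint": config.fingerprint(),
    }


def run_one(
    rna_id: str,
    corpus: Sequence[SentenceRecord],
    backend: LlmBackend,
    config: PipelineConfig = PipelineConfig(),
    context: Context | None = None,
) -> PipelineResult:
    """Execute the full chain for one RNA (see module docstring)."""
    if context is None:
        cfg = replace(config.embedding, seed=config.seed)
        context = select(corpus, config.budget, cfg)
    if context.strategy is Strategy.SKIPPED_TOO_FEW:
        return PipelineResult(
            rna_id=rna_id,
            final_summary=None,
            ref_status=None,
            consistency_status=None,
            status=Status.SKIPPED_TOO_FEW,
            metadata={"selection_strategy": context.strategy.value},
        )

    result = PipelineResult(
        rna_id=rna_id,
        final_summary=None,
        ref_status=None,
        consistency_status=None,
        status=Status.FLAGGED_REFS_EXHAUSTED,
        metadata=_metadata(config, backend, context),
    )
    rescue_params = replace(CHECK_PARAMS, max_output_tokens=config.params.max_output_tokens)

    # --- reference-check / rescue loop (<= max_attempts generations) ---
    summary: str | None = None
    audit: AuditResult | None = None
    rescue: str | None = None
    try:
        for attempt in range(1, config.max_attempts + 1):
            exchanges: list[LlmExchange] = []
            if attempt == 1:
                prompt = render(
                    get_template("initial"),
                    {"rna_id": rna_id, "context": context.rendered()},
                )
                summary = complete(
                    backend,
                    prompt,
                    config.params,
                    model_window=config.budget.model_window,
                    template_name="initial",
                    log=exchanges,
                )
            else:
                assert audit is not None and rescue is not None
                failure = audit.first_failure
                prompt = render(
                    get_template(rescue),
                    {
                        "rna_id": rna_id,
                        "context": context.rendered(),
                        "summary": summary or "",
                        "issues": json.dumps(failure.detail) if failure else "",
                    },
                )
                summary = complete(
                    backend,
                    prompt,
                    rescue_params,
                    model_window=config.budget.model_window,
                    template_name=rescue,
                    log=exchanges,
                )
            audit = run_all(summary, context, config.thresholds)
            result.attempts.append(
                AttemptRecord(
                    attempt_index=attempt,
                    summary_text=summary,
                    audit=audit,
                    rescue_used=rescue if attempt > 1 else None,
                    exchanges=exchanges,
                )
            )
            if audit.passed:
                result.ref_status = (
                    Status.REFS_FIRST_PASS if attempt == 1 else Status.REFS_AFTER_REVISION
                )
                break
            rescue = audit.rescue_template
    except TransportError as exc:
        result.status = Status.FLAGGED_REFS_EXHAUSTED
        result.metadata["transport_error"] = str(exc)
        return result

    if result.ref_status is None:  # attempts exhausted
        result.status = Status.FLAGGED_REFS_EXHAUSTED
        result.final_summary = summary
        result.final_audit = audit
        return result

    # --- consistency pass + final reference check ---
    assert summary is not None
    try:
        exchanges = []
        report, final_text, revised = consistency_pass(
            summary,
            context,
            backend,
            model_window=config.budget.model_window,
            log=exchanges,
        )
        result.consistency_report = report
        if result.attempts:
            result.attempts[-1].exchanges.extend(exchanges)
        final_audit = run_all(final_text, context, config.thresholds)
        result.final_audit = final_audit
        result.final_summary = final_text
        if not revised:
            result.consistency_status = Status.CONSISTENCY_CLEAN
        elif final_audit.passed:
            result.consistency_status = Status.CONSISTENCY_REVISED
        else:
            result.consistency_status = Status.FLAGGED_CONSISTENCY
        result.status = result.consistency_status
    except TransportError as exc:
        result.consistency_status = Status.FLAGGED_CONSISTENCY
        result.status = Status.FLAGGED_CONSISTENCY
        result.final_summary = summary
        result.metadata["transport_error"] = str(exc)
        return result

    flagged = result.status in (Status.FLAGGED_CONSISTENCY, Status.FLAGGED_REFS_EXHAUSTED)
    result.displayable = (not flagged) or config.display_policy == "show_all"
    return result


@dataclass
class BatchStats:
    """Stage pass rates over one batch, computed from the batch's own results."""

    n_items: int = 0
    n_skipped: int = 0
    refs_first_pass: int = 0
    refs_after_revision: int = 0  # cumulative: passed the reference stage at all
    consistency_clean: int = 0
    consistency_after_revision: int = 0  # cumulative: clean or successfully revised
    mean_attempts: float = 0.0
    total_prompt_tokens: int = 0
    total_completion_tokens: int = 0

    @property
    def n_summarized(self) -> int:
        return self.n_items - self.n_skipped

    def rate(self, count: int) -> float:
        return 100.0 * count / self.n_summarized if self.n_summarized else 0.0

    def rows(self) -> list[tuple[str, float, int]]:
        return [
            ("References—first pass", self.rate(self.refs_first_pass), self.refs_first_pass),
            (
                "References—after revision",
                self.rate(self.refs_after_revision),
                self.refs_after_revision,
            ),
            (
                "Self-consistency—no problems found",
                self.rate(self.consistency_clean),
                self.consistency_clean,
            ),
            (
                "Self-consistency—no problems after revision",
                self.rate(self.consistency_after_revision),
                self.consistency_after_revision,
            ),
        ]

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["Failure mode", "Pass rate (%)", "Number of passing summaries"])
            for label, rate, count in self.rows():
                w.writerow([label, f"{rate:.1f}", count])


def run_batch(
    items: Iterable[tuple[str, Sequence[SentenceRecord]]],
    backend: LlmBackend,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[PipelineResult], BatchStats]:
    """Run the pipeline over many RNAs sequentially, isolating per-item failures.

    Output order is input order; a failing item yields a flagged result, never
    an exception that aborts the batch.
    """
    results: list[PipelineResult] = []
    for rna_id, corpus in items:
        try:
            results.append(run_one(rna_id, corpus, backend, config))
        except Exception as exc:  # per-item isolation
            results.append(
                PipelineResult(
                    rna_id=rna_id,
                    final_summary=None,
                    ref_status=None,
                    consistency_status=None,
                    status=Status.FLAGGED_REFS_EXHAUSTED,
                    metadata={"error": f"{type(exc).__name__}: {exc}"},
                )
            )
    return results, compute_stats(results)


def compute_stats(results: Sequence[PipelineResult]) -> BatchStats:
    stats = BatchStats(n_items=len(results))
    attempts_counts = []
    for r in results:
        if r.status is Status.SKIPPED_TOO_FEW:
            stats.n_skipped += 1
            continue
        attempts_counts.append(len(r.attempts))
        if r.ref_status is Status.REFS_FIRST_PASS:
            stats.refs_first_pass += 1
        if r.ref_status in (Status.REFS_FIRST_PASS, Status.REFS_AFTER_REVISION):
            stats.refs_after_revision += 1
        if r.consistency_status is Status.CONSISTENCY_CLEAN:
            stats.consistency_clean += 1
        if r.consistency_status in (Status.CONSISTENCY_CLEAN, Status.CONSISTENCY_REVISED):
            stats.consistency_after_revision += 1
        for a in r.attempts:
            for ex in a.exchanges:
                stats.total_prompt_tokens += ex.token_usage.get("prompt", 0)
                stats.total_completion_tokens += ex.token_usage.get("completion", 0)
    stats.mean_attempts = (
        sum(attempts_counts) / len(attempts_counts) if attempts_counts else 0.0
    )
    return stats


def export_displayable(results: Sequence[PipelineResult], path: str | Path) -> int:
    """Write displayable results as JSONL; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in results:
            if not r.displayable:
                continue
            fh.write(
                json.dumps(
                    {
                        "rna_id": r.rna_id,
                        "summary": r.final_summary,
                        "pmcids_cited": r.pmcids_cited(),
                        "status": r.status.value,
                        "metadata": r.metadata,
                    }
                )
                + "\n"
            )
            n += 1
    return n


def write_results_jsonl(results: Sequence[PipelineResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps(r.to_json()) + "\n")
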