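"""Bullet-wise self-consistency checking and revision.

After a summary passes the reference checks, it is decomposed into one
bullet per sentence and the model is asked — against the very context the
summary came from — for a TRUE/FALSE verdict plus an explanation for each
bullet.  Any FALSE (or unparseable) verdict triggers exactly one revision
call that feeds the verdicts back and asks the model to amend the summary.
This module never edits summary text itself: every edit comes from the
backend, so provenance stays with the model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .context import Context
from .prompting import (
    CHECK_PARAMS,
    LlmBackend,
    LlmExchange,
    complete,
    get_template,
    render,
)
from .segment import Segmenter, DEFAULT_SEGMENTER


class Verdict(str, Enum):
    TRUE = "TRUE"
    FALSE = "FALSE"
    UNPARSEABLE = "UNPARSEABLE"


@dataclass
class BulletVerdict:
    bullet_text: str
    verdict: Verdict
    explanation: str = ""
    support_span: str | None = None


@dataclass
class ConsistencyReport:
    verdicts: list[BulletVerdict]
    raw_response: str

    @property
    def any_false(self) -> bool:
        return any(v.verdict is not Verdict.TRUE for v in self.verdicts)

    def issues_text(self) -> str:
        lines = []
        for i, v in enumerate(self.verdicts, start=1):
            lines.append(f"{i}. {v.verdict.value} — {v.explanation or v.bullet_text}")
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "any_false": self.any_false,
            "verdicts": [
                {
                    "bullet": v.bullet_text,
                    "verdict": v.verdict.value,
                    "explanation": v.explanation,
                }
                for v in self.verdicts
            ],
            "raw_response": self.raw_response,
        }


def split_bullets(summary: str, segmenter: Segmenter | None = None) -> list[str]:
    """One bullet per segmented sentence, citation brackets retained."""
    if not summary.strip():
        raise ValueError("cannot split an empty summary into bullets")
    seg = segmenter or DEFAULT_SEGMENTER
    return seg.split(summary)


_VERDICT_LINE = re.compile(
    r"^\s*(\d+)[.):\-]?\s*(TRUE|FALSE)\b[\s\-–—:.]*(.*)$", re.IGNORECASE
)


def parse_verdicts(response: str, bullets: list[str]) -> ConsistencyReport:
    """Tolerant parse of ``<index>. TRUE|FALSE — <explanation>`` lines.

    Lines that are missing or malformed degrade to UNPARSEABLE, which counts
    as a failure (fail-closed): a verdict we cannot read must trigger
    revision, never silently pass.
    """
    found: dict[int, tuple[Verdict, str]] = {}
    for line in response.splitlines():
        m = _VERDICT_LINE.match(line)
        if not m:
            continue
        idx = int(m.group(1))
        verdict = Verdict(m.group(2).upper())
        if 1 <= idx <= len(bullets) and idx not in found:
            found[idx] = (verdict, m.group(3).strip())
    verdicts = []
    for i, bullet in enumerate(bullets, start=1):
        if i in found:
            v, expl = found[i]
            verdicts.append(BulletVerdict(bullet_text=bullet, verdict=v, explanation=expl))
        else:
            verdicts.append(BulletVerdict(bullet_text=bullet, verdict=Verdict.UNPARSEABLE))
    return ConsistencyReport(verdicts=verdicts, raw_response=response)


def consistency_pass(
    summary: str,
    context: Context,
    backend: LlmBackend,
    model_window: int = 4096,
    log: list[LlmExchange] | None = None,
) -> tuple[ConsistencyReport, str, bool]:
    """One check call, plus one revision call iff any verdict fails.

    Returns ``(report, summary_text, revised)`` where ``summary_text`` is
    the revised text when revision ran, else the input unchanged.
    """
    bullets = split_bullets(summary)
    numbered = "\n".join(f"{i}. {b}" for i, b in enumerate(bullets, start=1))
    check_prompt = render(
        get_template("consistency_check"),
        {"rna_id": context.rna_id, "context": context.rendered(), "bullets": numbered},
    )
    response = complete(
        backend,
        check_prompt,
        CHECK_PARAMS,
        model_window=model_window,
        template_name="consistency_check",
        log=log,
    )
    report = parse_verdicts(response, bullets)
    if not report.any_false:
        return report, summary, False
    revise_prompt = render(
        get_template("consistency_revise"),
        {
            "rna_id": context.rna_id,
            "context": context.rendered(),
            "summary": summary,
            "issues": report.issues_text(),
        },
    )
    revised = complete(
        backend,
        revise_prompt,
        CHECK_PARAMS,
        model_window=model_window,
        template_name="consistency_revise",
        log=log,
    )
    return report, revised, True
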