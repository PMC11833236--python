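"""Citation parsing and the five reference checks.

A referenced summary must (1) carry enough citations for its length, (2)
cite with well-formed PubMed Central identifiers, (3) cite only articles
actually present in its context, (4) attach citations to the sentences they
support rather than dumping them at the end, and (5) spread citations over
instances instead of stacking them into one bracket.  Any failing check
names the rescue prompt that asks the model to repair that specific mistake.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .context import Context
from .segment import Segmenter, DEFAULT_SEGMENTER

PMCID = re.compile(r"PMC[0-9]+")
_BRACKET_GROUP = re.compile(r"\[([^\[\]]*)\]")
_PAREN_GROUP = re.compile(r"\(([^()]*)\)")
_SEPARATORS = re.compile(r"[,;\s]+")
_TRAILING_PUNCT = " \t.!?;:'\")]"


class Check(str, Enum):
    ADEQUACY = "adequacy"
    FORMATTING = "formatting"
    REALNESS = "realness"
    PLACEMENT = "placement"
    CONCENTRATION = "concentration"


#: check -> rescue prompt template; formatting and realness share the
#: identifier-validity template, concentration shares the placement one.
RESCUE_FOR_CHECK = {
    Check.ADEQUACY: "rescue_adequacy",
    Check.FORMATTING: "rescue_format",
    Check.REALNESS: "rescue_realness",
    Check.PLACEMENT: "rescue_placement",
    Check.CONCENTRATION: "rescue_placement",
}

CHECK_ORDER = (
    Check.ADEQUACY,
    Check.FORMATTING,
    Check.REALNESS,
    Check.PLACEMENT,
    Check.CONCENTRATION,
)


@dataclass(frozen=True)
class CheckThresholds:
    """Numeric bounds of the reference checks.

    ``min_refs_per_sentence``: at least this many citations per summary
    sentence (counted with multiplicity).  ``max_fraction_per_instance``: no
    citation instance may hold more than this fraction of all citations.
    ``min_total_for_concentration``: below this many total citations the
    concentration check is vacuous (a single-citation summary would
    otherwise always fail).  ``max_nonterminal_fraction`` operationalises
    "references go at the end of sentences, usually".
    """

    min_refs_per_sentence: float = 0.5
    max_fraction_per_instance: float = 0.5
    min_total_for_concentration: int = 3
    max_nonterminal_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.min_refs_per_sentence <= 1:
            raise ValueError("min_refs_per_sentence must lie in (0, 1]")
        if not 0 < self.max_fraction_per_instance <= 1:
            raise ValueError("max_fraction_per_instance must lie in (0, 1]")


@dataclass
class CitationInstance:
    """One citation occurrence: a bracketed group or a bare PMC token."""

    pmcids: list[str]
    char_span: tuple[int, int]  # [start, end) in the summary
    sentence_index: int = 0
    terminal: bool = False

    @property
    def size(self) -> int:
        return len(self.pmcids)


@dataclass
class CheckReport:
    check: Check
    passed: bool
    detail: dict = field(default_factory=dict)
    rescue_template: str | None = None

    def __post_init__(self) -> None:
        if self.passed:
            self.rescue_template = None
        elif self.rescue_template is None:
            self.rescue_template = RESCUE_FOR_CHECK[self.check]

    def to_json(self) -> dict:
        return {
            "check": self.check.value,
            "passed": self.passed,
            "detail": self.detail,
            "rescue_template": self.rescue_template,
        }


def parse_citations(
    summary: str,
    segmenter: Segmenter | None = None,
    lenient_parentheses: bool = False,
) -> list[CitationInstance]:
    """Extract citation instances in reading order.

    Bracketed groups containing one or more ``PMC<digits>`` tokens become one
    instance with ordered identifiers; bare ``PMC<digits>`` tokens outside
    any group become singleton instances.  Parenthesised groups are parsed
    only in lenient mode (strict mode leaves them to the formatting check).
    Malformed tokens (``PMCabc``, numeric markers) yield no instance.
    """
    seg = segmenter or DEFAULT_SEGMENTER
    instances: list[CitationInstance] = []
    covered: list[tuple[int, int]] = []
    group_patterns = [_BRACKET_GROUP]
    if lenient_parentheses:
        group_patterns.append(_PAREN_GROUP)
    for pat in group_patterns:
        for m in pat.finditer(summary):
            ids = PMCID.findall(m.group(1))
            if ids:
                instances.append(CitationInstance(pmcids=ids, char_span=(m.start(), m.end())))
                covered.append((m.start(), m.end()))
    for m in PMCID.finditer(summary):
        if any(s <= m.start() < e for s, e in covered):
            continue
        # require a true bare token (not PMC123x)
        end = m.end()
        if end < len(summary) and (summary[end].isalnum()):
            continue
        instances.append(CitationInstance(pmcids=[m.group(0)], char_span=(m.start(), end)))
    instances.sort(key=lambda i: i.char_span)

    spans = seg.spans(summary)
    for inst in instances:
        idx = 0
        for k, (s, e) in enumerate(spans):
            if s <= inst.char_span[0] < e or inst.char_span[0] >= s:
                idx = k
        inst.sentence_index = idx
        if spans:
            s, e = spans[idx]
            tail = summary[inst.char_span[1] : e]
            inst.terminal = tail.strip(_TRAILING_PUNCT) == ""
    return instances


def check_adequacy(
    summary: str,
    instances: list[CitationInstance],
    thresholds: CheckThresholds = CheckThresholds(),
    segmenter: Segmenter | None = None,
) -> CheckReport:
    """Enough references for the summary length: >= 0.5 citations/sentence,
    counting cited identifiers with multiplicity."""
    seg = segmenter or DEFAULT_SEGMENTER
    n_sentences = len(seg.spans(summary))
    if n_sentences == 0:
        raise ValueError("summary has no sentences")
    n_refs = sum(inst.size for inst in instances)
    ratio = n_refs / n_sentences
    return CheckReport(
        Check.ADEQUACY,
        passed=ratio >= thresholds.min_refs_per_sentence,
        detail={"ratio": ratio, "n_refs": n_refs, "n_sentences": n_sentences},
    )


def check_formatting(
    summary: str,
    instances: list[CitationInstance],
    lenient_parentheses: bool = False,
) -> CheckReport:
    """Every citation-like token must be a well-formed PMCID citation.

    Flags: bracket groups whose content is not purely PMC identifiers (this
    catches numeric ``[1]`` markers and typos like ``[PMCabc]``), PMID or
    DOI style references, malformed bare PMC tokens, and - in strict mode -
    parenthesised citation groups.
    """
    offending: list[dict] = []
    for m in _BRACKET_GROUP.finditer(summary):
        tokens = [t for t in _SEPARATORS.split(m.group(1).strip()) if t]
        if not tokens or not all(re.fullmatch(r"PMC[0-9]+", t) for t in tokens):
            offending.append({"span": [m.start(), m.end()], "text": m.group(0)})
    for m in _PAREN_GROUP.finditer(summary):
        if PMCID.search(m.group(1)) and not lenient_parentheses:
            offending.append(
                {"span": [m.start(), m.end()], "text": m.group(0), "reason": "parenthesized"}
            )
    for m in re.finditer(r"\bPMID\b|\bdoi\b", summary, re.IGNORECASE):
        offending.append({"span": [m.start(), m.end()], "text": m.group(0)})
    for m in re.finditer(r"\bPMC(?![0-9])[A-Za-z0-9]*", summary):
        offending.append({"span": [m.start(), m.end()], "text": m.group(0)})
    return CheckReport(
        Check.FORMATTING, passed=not offending, detail={"offending": offending}
    )


def check_realness(instances: list[CitationInstance], context: Context) -> CheckReport:
    """All cited identifiers must exist in the context (no invented PMCIDs)."""
    cited = {p for inst in instances for p in inst.pmcids}
    available = context.pmcids
    offending = sorted(cited - available)
    return CheckReport(Check.REALNESS, passed=not offending, detail={"offending": offending})


def check_placement(
    instances: list[CitationInstance],
    summary: str,
    thresholds: CheckThresholds = CheckThresholds(),
    segmenter: Segmenter | None = None,
) -> CheckReport:
    """Citations belong at the end of the sentences they support.

    Fails when the summary ends in a pure reference block holding every
    citation, or when too many instances sit mid-sentence.
    """
    seg = segmenter or DEFAULT_SEGMENTER
    if not instances:
        return CheckReport(Check.PLACEMENT, passed=True, detail={"n_instances": 0})
    spans = seg.spans(summary)
    last_idx = len(spans) - 1
    trailing_block = False
    if spans:
        in_last = [i for i in instances if i.sentence_index == last_idx]
        if len(in_last) == len(instances):
            s, e = spans[last_idx]
            stripped = summary[s:e]
            for inst in instances:
                a, b = inst.char_span
                stripped = stripped.replace(summary[a:b], "")
            if not re.search(r"[A-Za-z0-9]", stripped) and last_idx > 0:
                trailing_block = True
    nonterminal = sum(1 for i in instances if not i.terminal)
    frac = nonterminal / len(instances)
    return CheckReport(
        Check.PLACEMENT,
        passed=not trailing_block and frac <= thresholds.max_nonterminal_fraction,
        detail={"trailing_block": trailing_block, "nonterminal_fraction": frac},
    )


def check_concentration(
    instances: list[CitationInstance],
    thresholds: CheckThresholds = CheckThresholds(),
) -> CheckReport:
    """No instance may stack more than half of all citations.

    Summaries with fewer than ``min_total_for_concentration`` citations are
    exempt — with one or two citations the bound is unsatisfiable without
    being informative about reference dumping.
    """
    total = sum(inst.size for inst in instances)
    if total < thresholds.min_total_for_concentration:
        return CheckReport(
            Check.CONCENTRATION, passed=True, detail={"total": total, "exempt": True}
        )
    largest = max(inst.size for inst in instances)
    offending = [k for k, inst in enumerate(instances) if inst.size == largest]
    passed = largest <= thresholds.max_fraction_per_instance * total
    return CheckReport(
        Check.CONCENTRATION,
        passed=passed,
        detail={
            "total": total,
            "max_instance": largest,
            "offending_instance": None if passed else offending[0],
        },
    )


@dataclass
class AuditResult:
    reports: list[CheckReport]
    instances: list[CitationInstance]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.reports)

    @property
    def first_failure(self) -> CheckReport | None:
        return next((r for r in self.reports if not r.passed), None)

    @property
    def rescue_template(self) -> str | None:
        f = self.first_failure
        return f.rescue_template if f else None

    def to_json(self) -> dict:
        return {"passed": self.passed, "reports": [r.to_json() for r in self.reports]}


def run_all(
    summary: str,
    context: Context,
    thresholds: CheckThresholds = CheckThresholds(),
    segmenter: Segmenter | None = None,
    lenient_parentheses: bool = False,
) -> AuditResult:
    """Run the five checks in fixed order; the first failure selects the
    rescue prompt for the next generation attempt."""
    instances = parse_citations(summary, segmenter, lenient_parentheses)
    reports = [
        check_adequacy(summary, instances, thresholds, segmenter),
        check_formatting(summary, instances, lenient_parentheses),
        check_realness(instances, context),
        check_placement(instances, summary, thresholds, segmenter),
        check_concentration(instances, thresholds),
    ]
    return AuditResult(reports=reports, instances=instances)
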