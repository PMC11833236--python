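"""Local emulation of LitScan sentence acquisition.

Given article full text, build the EuropePMC query string for an RNA
identifier, validate that the identifier is mentioned, and extract every
sentence mentioning it.  Matching is case-insensitive with word boundaries
defined as any character that is not alphanumeric and not a hyphen (or the
string edge), so serial identifiers do not match inside their extensions:
``hsa-mir-21`` never matches inside ``hsa-mir-210``.

Network retrieval is out of scope; articles arrive as plain-text files named
``<PMCID>.txt`` or as JSONL ``{pmcid, body}`` records via :class:`LocalArticleStore`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .segment import Segmenter, DEFAULT_SEGMENTER

_PMCID_RE = re.compile(r"^PMC[0-9]+$")

# The six RNA-type disambiguation terms and the three flags of the EuropePMC
# query, kept verbatim.
_QUERY_TEMPLATE = (
    '("{id}" AND ("rna" OR "mrna" OR "ncrna" OR "lncrna" OR "rrna" OR "sncrna")'
    " AND IN_EPMC:Y AND OPEN_ACCESS:Y AND NOT SRC:PPR)"
)


class InvalidIdentifierError(ValueError):
    """The RNA identifier cannot be used to build a safe quoted query."""


@dataclass(frozen=True)
class RnaIdentifier:
    """An RNA name plus the cross-reference aliases that denote the same RNA."""

    primary_id: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "\n" in self.primary_id:
            raise InvalidIdentifierError("primary_id must not contain newlines")
        object.__setattr__(
            self, "aliases", tuple(a for a in self.aliases if a != self.primary_id)
        )

    @property
    def surface_forms(self) -> tuple[str, ...]:
        return (self.primary_id, *self.aliases)


@dataclass(frozen=True)
class ArticleText:
    """Full text of one open-access article, tagged with its PMCID."""

    pmcid: str
    body: str

    def __post_init__(self) -> None:
        if not _PMCID_RE.match(self.pmcid):
            raise ValueError(f"not a PMC identifier: {self.pmcid!r}")


@dataclass
class SentenceRecord:
    """One literature sentence mentioning one RNA, tagged with its source."""

    rna_id: str
    pmcid: str
    sentence: str
    token_count: int = 0  # filled lazily by the context builder
    matched_form: str | None = None  # which surface form (id or alias) matched

    def to_json(self) -> dict:
        return {"rna_id": self.rna_id, "pmcid": self.pmcid, "sentence": self.sentence}


def build_query(identifier: RnaIdentifier | str) -> str:
    """Render the EuropePMC full-text query for one RNA identifier.

    The identifier is double-quoted and combined with six RNA-type terms to
    suppress articles that mention the ID but no kind of RNA, restricted to
    the open-access EuropePMC subset, excluding preprints.
    """
    primary = identifier.primary_id if isinstance(identifier, RnaIdentifier) else identifier
    if not primary:
        raise InvalidIdentifierError("empty RNA identifier")
    if '"' in primary:
        raise InvalidIdentifierError(
            f"identifier {primary!r} contains a double quote and cannot be quoted"
        )
    return _QUERY_TEMPLATE.format(id=primary)


def _mention_pattern(form: str) -> re.Pattern[str]:
    # Word boundary: string edge or any char that is neither alphanumeric nor
    # a hyphen.  Hyphens are ID-internal, so an ID never matches inside a
    # longer serial identifier.
    return re.compile(
        r"(?<![A-Za-z0-9-])" + re.escape(form) + r"(?![A-Za-z0-9-])",
        re.IGNORECASE,
    )


def find_mention(text: str, identifier: RnaIdentifier) -> str | None:
    """Return the first surface form of ``identifier`` mentioned in ``text``."""
    for form in identifier.surface_forms:
        if form and _mention_pattern(form).search(text):
            return form
    return None


def validate_mention(article: ArticleText, identifier: RnaIdentifier) -> bool:
    """True iff the article body mentions the ID or any alias."""
    return find_mention(article.body, identifier) is not None


def extract_sentences(
    article: ArticleText,
    identifier: RnaIdentifier,
    segmenter: Segmenter | None = None,
) -> list[SentenceRecord]:
    """Extract every sentence of ``article`` mentioning the RNA, in document order."""
    seg = segmenter or DEFAULT_SEGMENTER
    records: list[SentenceRecord] = []
    for start, end in seg.spans(article.body):
        sentence = article.body[start:end]
        form = find_mention(sentence, identifier)
        if form is None:
            continue
        records.append(
            SentenceRecord(
                rna_id=identifier.primary_id,
                pmcid=article.pmcid,
                sentence=" ".join(sentence.split()),  # collapse internal newlines
                matched_form=form,
            )
        )
    return records


class LocalArticleStore:
    """Serves :class:`ArticleText` from local files (the shipped transport stub).

    Accepts either a directory of ``<PMCID>.txt`` files or a JSONL file of
    ``{"pmcid": ..., "body": ...}`` records.
    """

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)

    def __iter__(self) -> Iterator[ArticleText]:
        seen: set[str] = set()
        if self.path.is_dir():
            for f in sorted(self.path.glob("PMC*.txt")):
                pmcid = f.stem
                if pmcid in seen:
                    raise ValueError(f"duplicate article {pmcid}")
                seen.add(pmcid)
                yield ArticleText(pmcid=pmcid, body=f.read_text())
        else:
            with open(self.path) as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    rec = json.loads(line)
                    if rec["pmcid"] in seen:
                        raise ValueError(f"duplicate article {rec['pmcid']}")
                    seen.add(rec["pmcid"])
                    yield ArticleText(pmcid=rec["pmcid"], body=rec["body"])


def harvest_corpus(
    articles: Iterable[ArticleText],
    identifier: RnaIdentifier,
    segmenter: Segmenter | None = None,
) -> list[SentenceRecord]:
    """Run mention validation + sentence extraction over a set of articles."""
    corpus: list[SentenceRecord] = []
    for article in articles:
        if not validate_mention(article, identifier):
            continue
        corpus.extend(extract_sentences(article, identifier, segmenter))
    return corpus


def write_sentences_jsonl(records: Iterable[SentenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json()) + "\n")


def read_sentences_jsonl(path: str | Path) -> list[SentenceRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            records.append(
                SentenceRecord(rna_id=d["rna_id"], pmcid=d["pmcid"], sentence=d["sentence"])
            )
    return records
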