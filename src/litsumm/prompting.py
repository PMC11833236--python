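"""Prompt templates, generation parameters, and the LLM backend contract.

Templates live as editable text files (``templates/*.txt``) with a small
front-matter block naming their placeholders.  Rendering is literal
substitution — context text is never escaped, because the LLM must see the
sentences verbatim to cite them.

Two backends satisfy the chat-completion contract: an HTTP client for a real
endpoint, and :class:`ScriptedBackend`, a deterministic stand-in that replays
queued responses keyed by template name, which makes every pipeline path
replayable in tests.
"""

from __future__ import annotations

import json
import os
import re
import time
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Protocol

from .tokenize import Tokenizer, count_tokens

TEMPLATE_NAMES = (
    "initial",
    "rescue_adequacy",
    "rescue_format",
    "rescue_realness",
    "rescue_placement",
    "consistency_check",
    "consistency_revise",
)

# formatting and realness failures are both identifier-validity problems and
# share one rescue template; concentration shares the citation-placement one.
TEMPLATE_FILES = {
    "initial": "initial.txt",
    "rescue_adequacy": "rescue_adequacy.txt",
    "rescue_format": "rescue_identifier.txt",
    "rescue_realness": "rescue_identifier.txt",
    "rescue_placement": "rescue_placement.txt",
    "consistency_check": "consistency_check.txt",
    "consistency_revise": "consistency_revise.txt",
}


class TemplateError(ValueError):
    """A placeholder required by the template is missing from the bindings."""


class BudgetError(ValueError):
    """The prompt plus reserved output would overflow the model window."""


class TransportError(RuntimeError):
    """The backend failed after bounded retries."""


@dataclass(frozen=True)
class GenerationParams:
    """Sampling parameters for one LLM call.

    The initial summary generation uses a negative presence penalty (-2) to
    *encourage* restating context tokens, balanced by a frequency penalty of
    1 against verbatim repetition; temperature stays low (0.1) to curb
    hallucination while allowing rephrasing.
    """

    temperature: float = 0.1
    presence_penalty: float = -2.0
    frequency_penalty: float = 1.0
    max_output_tokens: int = 255

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        for p in (self.presence_penalty, self.frequency_penalty):
            if not -2.0 <= p <= 2.0:
                raise ValueError("penalties must lie in [-2, 2]")


#: conservative parameters for rescue / consistency / revision calls
CHECK_PARAMS = GenerationParams(
    temperature=0.1, presence_penalty=0.0, frequency_penalty=0.0, max_output_tokens=1150
)

_PLACEHOLDER = re.compile(r"\{([a-z_]+)\}")


@dataclass(frozen=True)
class PromptTemplate:
    name: str
    text: str
    placeholders: tuple[str, ...]

    @classmethod
    def from_file(cls, name: str, path: Path | None = None) -> "PromptTemplate":
        if path is None:
            ref = resources.files("litsumm") / "templates" / TEMPLATE_FILES[name]
            raw = ref.read_text()
        else:
            raw = Path(path).read_text()
        meta, text = _parse_front_matter(raw)
        return cls(name=name, text=text, placeholders=tuple(meta["placeholders"]))


def _parse_front_matter(raw: str) -> tuple[dict, str]:
    if not raw.startswith("---"):
        return {"placeholders": sorted(set(_PLACEHOLDER.findall(raw)))}, raw
    _, fm, body = raw.split("---", 2)
    meta: dict = {}
    for line in fm.strip().splitlines():
        key, _, val = line.partition(":")
        meta[key.strip()] = [v.strip() for v in val.split(",") if v.strip()]
    if "name" in meta:
        meta["name"] = meta["name"][0]
    return meta, body.lstrip("\n")


_TEMPLATE_CACHE: dict[str, PromptTemplate] = {}


def get_template(name: str) -> PromptTemplate:
    if name not in TEMPLATE_FILES:
        raise KeyError(f"unknown template {name!r}")
    if name not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[name] = PromptTemplate.from_file(name)
    return _TEMPLATE_CACHE[name]


def render(template: PromptTemplate, bindings: dict[str, str]) -> str:
    """Literal substitution of every ``{placeholder}``; no escaping."""
    missing = [p for p in template.placeholders if p not in bindings]
    if missing:
        raise TemplateError(f"missing bindings for template {template.name!r}: {missing}")

    def sub(m: re.Match) -> str:
        key = m.group(1)
        if key not in bindings:
            raise TemplateError(f"missing bindings for template {template.name!r}: [{key!r}]")
        return str(bindings[key])

    return _PLACEHOLDER.sub(sub, template.text)


@dataclass
class LlmExchange:
    """Audit record of exactly one backend call."""

    template_name: str
    rendered_prompt: str
    params: GenerationParams
    response_text: str
    token_usage: dict[str, int] = field(default_factory=dict)


class LlmBackend(Protocol):
    def chat(self, prompt: str, params: GenerationParams) -> str: ...


class ScriptedBackend:
    """Deterministic backend replaying queued responses keyed by template name.

    ``complete`` passes the template name through, so queues for different
    stages never interleave; an exhausted queue raises, which surfaces as a
    transport failure in the orchestrator.
    """

    def __init__(self, queues: dict[str, list[str]] | None = None) -> None:
        self._queues: dict[str, deque[str]] = {
            k: deque(v) for k, v in (queues or {}).items()
        }
        self.transcript: list[LlmExchange] = []

    def queue(self, template_name: str, *responses: str) -> "ScriptedBackend":
        self._queues.setdefault(template_name, deque()).extend(responses)
        return self

    def chat(self, prompt: str, params: GenerationParams, template_name: str = "") -> str:
        q = self._queues.get(template_name)
        if not q:
            raise TransportError(f"scripted backend has no response queued for {template_name!r}")
        return q.popleft()


class HttpChatBackend:
    """Minimal chat-completion client for an OpenAI-style endpoint.

    Uses the standard library HTTP machinery; the API key is read from the
    environment variable named in the constructor, never stored.
    """

    def __init__(
        self,
        endpoint: str,
        model: str,
        api_key_env: str = "LITSUMM_API_KEY",
        max_retries: int = 3,
        timeout: float = 60.0,
    ) -> None:
        self.endpoint = endpoint
        self.model = model
        self.api_key_env = api_key_env
        self.max_retries = max_retries
        self.timeout = timeout

    def payload(self, prompt: str, params: GenerationParams) -> dict:
        return {
            "model": self.model,
            "messages": [{"role": "user", "content": prompt}],
            "temperature": params.temperature,
            "presence_penalty": params.presence_penalty,
            "frequency_penalty": params.frequency_penalty,
            "max_tokens": params.max_output_tokens,
        }

    def chat(self, prompt: str, params: GenerationParams) -> str:
        import urllib.error
        import urllib.request

        body = json.dumps(self.payload(prompt, params)).encode()
        key = os.environ.get(self.api_key_env, "")
        req = urllib.request.Request(
            self.endpoint,
            data=body,
            headers={"Content-Type": "application/json", "Authorization": f"Bearer {key}"},
        )
        last: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    data = json.loads(resp.read())
                return data["choices"][0]["message"]["content"]
            except (urllib.error.URLError, OSError, KeyError, json.JSONDecodeError) as exc:
                last = exc
                time.sleep(min(2**attempt, 8))
        raise TransportError(f"backend failed after {self.max_retries} retries: {last}")


def complete(
    backend: LlmBackend,
    prompt: str,
    params: GenerationParams,
    model_window: int = 4096,
    tokenizer: Tokenizer | None = None,
    template_name: str = "",
    log: list[LlmExchange] | None = None,
) -> str:
    """Send ``prompt`` to ``backend`` after enforcing the window budget.

    Raises :class:`BudgetError` *before* any network traffic if the prompt
    plus the reserved output would not fit the model window.  Every call is
    recorded as one :class:`LlmExchange` when ``log`` is supplied.
    """
    prompt_tokens = count_tokens(prompt, tokenizer)
    if prompt_tokens + params.max_output_tokens > model_window:
        raise BudgetError(
            f"prompt ({prompt_tokens} tokens) + max output ({params.max_output_tokens}) "
            f"exceeds the {model_window}-token window"
        )
    if isinstance(backend, ScriptedBackend):
        text = backend.chat(prompt, params, template_name=template_name)
    else:
        text = backend.chat(prompt, params)
    exchange = LlmExchange(
        template_name=template_name,
        rendered_prompt=prompt,
        params=params,
        response_text=text,
        token_usage={"prompt": prompt_tokens, "completion": count_tokens(text, tokenizer)},
    )
    if log is not None:
        log.append(exchange)
    if isinstance(backend, ScriptedBackend):
        backend.transcript.append(exchange)
    return text
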