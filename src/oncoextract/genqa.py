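"""Generative-model baseline plumbing: prompt assembly and output parsing.

A generative baseline answers the same clinical questions by free text
rather than by span extraction, so its output is untrusted and must be
post-parsed: the text following the first biomarker mention is taken as the
candidate value (up to the end of the sentence or line), the sentinel
``NaN`` or an output without any biomarker mention maps to unanswerable
(routed to ``not_present``), and the candidate is classified with the
prototype cosine classifier.

No language model ships with the package: :class:`GenerativeBackend` is a
contract (any callable hook, e.g. a subprocess wrapper around a locally
installed model), and :class:`EchoBackend` is a deterministic mock used to
exercise the plumbing end to end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

from .classify import (
    NOT_PRESENT,
    OutputRecord,
    PipelineConfig,
    PrototypeModel,
    classify_prototype,
)
from .qa import Report, _compiled
from .schema import FeatureSchema

#: sentinel a generative model is instructed to produce when it cannot answer
UNANSWERABLE_SENTINEL = "NaN"

DEFAULT_SYSTEM_TEMPLATE = (
    "You are a careful clinical information extraction assistant. You read "
    "pathology reports and report the recorded value of {biomarker} exactly "
    "as written, without inventing information."
)

DEFAULT_INSTRUCTION_TEMPLATE = (
    "Context:\n{context}\n\n"
    "Question: {question}\n"
    "Answer with the value of {biomarker} exactly as it appears in the "
    'context, in the form "{biomarker}: <value>". If the context does not '
    f'contain the answer, reply "{UNANSWERABLE_SENTINEL}".'
)

_PLACEHOLDER_RE = re.compile(r"\{(question|context|biomarker)\}")


class PromptError(ValueError):
    pass


@dataclass(frozen=True)
class PromptPair:
    """A resolved system + instruction prompt (context kept for mock backends)."""

    system_prompt: str
    instruction_prompt: str
    context: str = ""
    question: str = ""


@runtime_checkable
class GenerativeBackend(Protocol):
    def generate(self, prompt: PromptPair) -> str:
        ...


def build_prompt(
    feature: FeatureSchema,
    context: str,
    system_template: str = DEFAULT_SYSTEM_TEMPLATE,
    instruction_template: str = DEFAULT_INSTRUCTION_TEMPLATE,
) -> PromptPair:
    """Fill the question/context/biomarker placeholders of both templates.

    The instruction template must reference all three placeholders (the
    system template may reference any subset); a template leaving a
    placeholder unresolved raises :class:`PromptError`.
    """
    needed = {"question", "context", "biomarker"}
    have = set(_PLACEHOLDER_RE.findall(instruction_template)) | set(
        _PLACEHOLDER_RE.findall(system_template)
    )
    missing = needed - have
    if missing:
        raise PromptError(f"prompt templates missing placeholders: {sorted(missing)}")
    fields = {
        "question": feature.question,
        "context": context,
        "biomarker": feature.display_name,
    }
    try:
        return PromptPair(
            system_prompt=system_template.format(**fields),
            instruction_prompt=instruction_template.format(**fields),
            context=context,
            question=feature.question,
        )
    except (KeyError, IndexError) as exc:
        raise PromptError(f"unresolved placeholder in prompt template: {exc}") from exc


_SENTENCE_END_RE = re.compile(r"[.\n\r]")
_LEAD_SEP_RE = re.compile(r"^(?:\s|[:=\-–]|\bis\b|\bwas\b|\bare\b)+", re.IGNORECASE)


def parse_generation(output: str, feature: FeatureSchema) -> str | None:
    """Extract the candidate value from generated text (None = unanswerable).

    The text following the first biomarker-alias occurrence is taken up to
    the end of the sentence or line, with leading separators ("is", ":", "-")
    stripped. The sentinel ``NaN``, an empty output, or an output containing
    no biomarker mention all map to None. Never raises.
    """
    out = (output or "").strip()
    if not out or out.lower() == UNANSWERABLE_SENTINEL.lower():
        return None
    alias_re, _, _ = _compiled(feature)
    m = alias_re.search(out)
    if m is None:
        return None
    tail = out[m.end() :]
    end = _SENTENCE_END_RE.search(tail)
    if end is not None:
        tail = tail[: end.start()]
    tail = _LEAD_SEP_RE.sub("", tail).strip()
    return tail or None


def run_generative(
    report: Report,
    feature: FeatureSchema,
    backend: GenerativeBackend,
    classifier_model: PrototypeModel | None,
    config: PipelineConfig | None = None,
    system_template: str = DEFAULT_SYSTEM_TEMPLATE,
    instruction_template: str = DEFAULT_INSTRUCTION_TEMPLATE,
) -> OutputRecord:
    """Prompt -> generate -> parse -> prototype-classify one report/feature.

    Generative baselines carry no usable span confidence, so the QA
    confidence is reported as 1.0 for parsed candidates and 0.0 for
    unanswerable outputs.
    """
    config = config or PipelineConfig()
    prompt = build_prompt(feature, report.text, system_template, instruction_template)
    candidate = parse_generation(backend.generate(prompt), feature)
    if candidate is None or classifier_model is None:
        return OutputRecord(
            report_id=report.report_id,
            feature_id=feature.feature_id,
            predicted_class=NOT_PRESENT,
            qa_confidence=0.0,
            classifier_confidence=1.0,
        )
    pred = classify_prototype(
        classifier_model, candidate, config.softmax_temperature, config.prototype_score
    )
    return OutputRecord(
        report_id=report.report_id,
        feature_id=feature.feature_id,
        predicted_class=pred.label,
        qa_confidence=1.0,
        classifier_confidence=pred.classifier_confidence,
        span_text=candidate,
    )


class EchoBackend:
    """Deterministic mock backend echoing ``"<biomarker>: <value>"``.

    ``value_for_context`` maps a report text to the surface form that should
    be echoed (None -> the unanswerable sentinel). Used to close the
    generative loop in tests without any real model.
    """

    def __init__(self, feature: FeatureSchema, value_for_context: Callable[[str], str | None]):
        self.feature = feature
        self.value_for_context = value_for_context

    def generate(self, prompt: PromptPair) -> str:
        value = self.value_for_context(prompt.context)
        if value is None:
            return UNANSWERABLE_SENTINEL
        return f"{self.feature.aliases[0]}: {value}."


class CallableBackend:
    """Adapter for a user-supplied ``PromptPair -> str`` hook."""

    def __init__(self, fn: Callable[[PromptPair], str]):
        self._fn = fn

    def generate(self, prompt: PromptPair) -> str:
        return self._fn(prompt)
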