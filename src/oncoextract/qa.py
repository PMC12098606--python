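"""Stage 1 — extractive question answering over free-text reports.

Given a report (context) and a feature's clinical question, a backend
returns an :class:`AnswerSpan`: a substring of the context with character
offsets and a confidence in [0, 1], or the empty span when the answer is not
present. Because the answer is always a verbatim substring (start/end
offsets, never generated text), the stage cannot hallucinate; the
:func:`ask` wrapper enforces this substring invariant against any backend.

Two backends are provided:

* :class:`RuleBasedBackend` / :func:`rule_based_extract` — a deterministic
  lexicon-window extractor that locates a feature alias and scans a bounded
  window after it for a value written in one of the feature's known surface
  forms. It serves as the reference backend and an honest baseline.
* :func:`transformer_adapter` — an optional adapter around a local
  span-predicting QA model (or any callable with the same contract).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

from .schema import FeatureSchema

#: characters scanned after an alias for a value surface form
DEFAULT_WINDOW = 60

_NUMERIC_RE = re.compile(r"\d+(?:\.\d+)?(?:\s?%)?")


class ExtractionError(RuntimeError):
    """Backend failure, tagged with the report and feature it occurred on."""

    def __init__(self, message: str, report_id: str = "", feature_id: str = ""):
        super().__init__(message)
        self.report_id = report_id
        self.feature_id = feature_id


class SpanIntegrityError(ExtractionError):
    """A backend returned text that is not a substring of the context."""


@dataclass(frozen=True)
class Report:
    """A free-text clinical report (may contain ``[redacted]`` tokens)."""

    report_id: str
    text: str


@dataclass(frozen=True)
class AnswerSpan:
    """An extracted substring with 0-based half-open character offsets.

    The empty span (unanswerable) is encoded as ``text=""`` with
    ``start == end == -1``.
    """

    text: str
    start: int
    end: int
    confidence: float

    @property
    def is_empty(self) -> bool:
        return self.text == "" and self.start == -1 and self.end == -1

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


def empty_span(confidence: float = 0.0) -> AnswerSpan:
    return AnswerSpan("", -1, -1, confidence)


@runtime_checkable
class ExtractiveBackend(Protocol):
    """Contract for stage-1 backends.

    ``answer`` must return a span whose text is a substring of *context* at
    the reported offsets, or the empty span for unanswerable contexts.
    Backends may additionally implement ``answer_all`` returning every
    candidate span (one per mention) for downstream severity resolution.
    """

    def answer(self, context: str, question: str, feature: FeatureSchema) -> AnswerSpan:
        ...


def _word_bounded(pattern: str) -> str:
    # \b misbehaves next to non-word characters ("+", "/"); use lookarounds
    return r"(?<!\w)" + re.escape(pattern) + r"(?!\w)"


_PATTERN_CACHE: dict = {}


def _compiled(feature: FeatureSchema):
    """Per-feature compiled alias and surface-form patterns (cached)."""
    key = (feature.feature_id, feature.aliases, feature.classes)
    hit = _PATTERN_CACHE.get(key)
    if hit is not None:
        return hit
    alias_re = re.compile(
        "|".join(_word_bounded(a) for a in sorted(feature.aliases, key=len, reverse=True)),
        re.IGNORECASE,
    )
    lexicon = feature.surface_lexicon()
    # group-free alternation, longest surface first: at any position the
    # longest matching surface wins, and finditer yields the earliest match
    surfaces = sorted({s for s, _ in lexicon}, key=len, reverse=True)
    surface_re = re.compile("|".join(_word_bounded(s) for s in surfaces), re.IGNORECASE)
    class_of = {s.lower(): c for s, c in lexicon}
    _PATTERN_CACHE[key] = (alias_re, surface_re, class_of)
    return alias_re, surface_re, class_of


def surface_match_class(feature: FeatureSchema, text: str) -> str | None:
    """Class whose surface form exactly covers *text* (None if no match)."""
    _, surface_re, class_of = _compiled(feature)
    if surface_re.fullmatch(text.strip()) is None:
        return None
    return class_of.get(text.strip().lower())


def extract_candidates(
    context: str, feature: FeatureSchema, window: int = DEFAULT_WINDOW
) -> list[AnswerSpan]:
    """All candidate value spans, one per alias mention (may be empty).

    For each occurrence of a feature alias, the *window* characters after it
    are scanned for the earliest (ties: longest) surface form of any class in
    the feature's lexicon — confidence 0.95 — falling back to a loose numeric
    pattern at confidence 0.5. Mentions with no value in the window yield
    nothing.
    """
    alias_re, surface_re, _ = _compiled(feature)
    spans: list[AnswerSpan] = []
    seen: set[tuple[int, int]] = set()
    for am in alias_re.finditer(context):
        lo = am.end()
        hi = min(len(context), lo + window)
        m = surface_re.search(context, lo, hi)
        conf = 0.95
        if m is None:
            m = _NUMERIC_RE.search(context, lo, hi)
            conf = 0.5
        if m is not None:
            start, end = m.start(), m.end()
            if (start, end) not in seen:
                seen.add((start, end))
                spans.append(AnswerSpan(context[start:end], start, end, conf))
    return spans


def rule_based_extract(
    context: str, feature: FeatureSchema, window: int = DEFAULT_WINDOW
) -> AnswerSpan:
    """First candidate span of :func:`extract_candidates`, or the empty span."""
    spans = extract_candidates(context, feature, window)
    return spans[0] if spans else empty_span()


class RuleBasedBackend:
    """Deterministic lexicon-window backend implementing the stage-1 contract."""

    def __init__(self, window: int = DEFAULT_WINDOW):
        self.window = window

    def answer(self, context: str, question: str, feature: FeatureSchema) -> AnswerSpan:
        return rule_based_extract(context, feature, self.window)

    def answer_all(
        self, context: str, question: str, feature: FeatureSchema
    ) -> list[AnswerSpan]:
        return extract_candidates(context, feature, self.window)


def verify_span(span: AnswerSpan, context: str, report_id: str = "", feature_id: str = "") -> AnswerSpan:
    """Enforce the no-hallucination invariant ``span.text == context[start:end]``."""
    if span.is_empty:
        return span
    if span.start < 0 or span.end > len(context) or context[span.start : span.end] != span.text:
        raise SpanIntegrityError(
            f"backend span {span.text!r} is not the context substring at "
            f"[{span.start}, {span.end})",
            report_id=report_id,
            feature_id=feature_id,
        )
    return span


def ask(backend: ExtractiveBackend, report: Report, feature: FeatureSchema) -> AnswerSpan:
    """Run a backend on one report/feature and verify the substring invariant."""
    try:
        span = backend.answer(report.text, feature.question, feature)
    except ExtractionError:
        raise
    except Exception as exc:  # tag arbitrary backend failures
        raise ExtractionError(
            f"backend failed: {exc}", report_id=report.report_id,
            feature_id=feature.feature_id,
        ) from exc
    return verify_span(span, report.text, report.report_id, feature.feature_id)


def ask_all(backend: ExtractiveBackend, report: Report, feature: FeatureSchema) -> list[AnswerSpan]:
    """All candidate spans from a backend (falls back to the single answer)."""
    if hasattr(backend, "answer_all"):
        spans = backend.answer_all(report.text, feature.question, feature)
    else:
        spans = [ask(backend, report, feature)]
    out = []
    for s in spans:
        verify_span(s, report.text, report.report_id, feature.feature_id)
        if not s.is_empty:
            out.append(s)
    return out


class _CallableBackend:
    def __init__(self, fn: Callable[[str, str, FeatureSchema], AnswerSpan]):
        self._fn = fn

    def answer(self, context: str, question: str, feature: FeatureSchema) -> AnswerSpan:
        return verify_span(self._fn(context, question, feature), context,
                           feature_id=feature.feature_id)


def transformer_adapter(model_ref) -> ExtractiveBackend:
    """Wrap a local span-predicting QA model as an :class:`ExtractiveBackend`.

    *model_ref* may be a callable ``(context, question, feature) -> AnswerSpan``
    (wrapped with substring verification) or a local path/name of a
    transformers question-answering model. The adapter's confidence is the
    product of the start- and end-token probabilities renormalized against
    the model's no-answer score; unanswerable contexts yield the empty span.

    The transformers dependency is optional and never required by the
    package's own test suite; a missing installation raises a clear error.
    """
    if callable(model_ref):
        return _CallableBackend(model_ref)
    try:
        from transformers import pipeline as hf_pipeline  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "transformer_adapter requires the optional 'transformers' package "
            "and a locally available QA model; install both offline, e.g. "
            "`pip install transformers torch` with a pre-downloaded model "
            f"directory (got model_ref={model_ref!r})"
        ) from exc

    qa = hf_pipeline("question-answering", model=model_ref, tokenizer=model_ref)

    class _HFBackend:  # pragma: no cover - exercised only with a local model
        def answer(self, context: str, question: str, feature: FeatureSchema) -> AnswerSpan:
            if not context.strip():
                return empty_span()
            res = qa(question=question, context=context, handle_impossible_answer=True)
            if not res.get("answer"):
                return empty_span(float(res.get("score", 0.0)))
            start, end = int(res["start"]), int(res["end"])
            return AnswerSpan(context[start:end], start, end,
                              max(0.0, min(1.0, float(res["score"]))))

    return _HFBackend()
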