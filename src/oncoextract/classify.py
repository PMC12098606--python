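"""Stage 2 — confidence routing and closed-vocabulary span classification.

Extracted spans are first routed: blank answers and answers whose QA
confidence falls below a threshold (default 10%) are assigned the
``not_present`` class directly. Surviving span texts are classified into the
feature's closed vocabulary by one of two few-shot classifiers fitted on a
handful of labelled example texts per class:

* **prototype** — nearest labelled example by cosine similarity of sentence
  embeddings; the per-class score is the maximum similarity over that
  class's examples (a ``centroid`` scoring mode is also available) and the
  reported confidence is a softmax over per-class scores.
* **contrastive** — a SetFit-style two-stage model: a linear refinement map
  over the base embeddings is trained with a contrastive pair loss on
  sampled same-class/different-class pairs, then a multinomial logistic head
  is fitted on the refined embeddings.

Embeddings come from any :class:`EmbeddingBackend`; the bundled
:class:`HashingNgramEmbedder` (character 3–5-grams hashed into 1,024
buckets, L2-normalized) is deterministic and dependency-free. The emitted
:class:`OutputRecord` carries only a vocabulary label and the two confidence
scores — never report text — so the pipeline output cannot leak PII.
"""

from __future__ import annotations

import hashlib
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from sklearn.linear_model import LogisticRegression

from .qa import AnswerSpan, ExtractiveBackend, Report, ask_all
from .schema import NOT_PRESENT, FeatureSchema, normalize_label, resolve_most_severe

_WS_RE = re.compile(r"\s+")
_STRIP = " \t.,;:!?'\"()[]{}"


def normalize_text(text: str) -> str:
    """Lower-case, collapse whitespace, strip edge punctuation."""
    return _WS_RE.sub(" ", text.lower()).strip().strip(_STRIP)


class PipelineConfig(BaseModel):
    """Tunables of the two-stage pipeline."""

    model_config = ConfigDict(frozen=True)

    qa_confidence_threshold: float = Field(default=0.10, ge=0.0, le=1.0)
    classifier_kind: str = "prototype"  # or "contrastive"
    softmax_temperature: float = Field(default=1.0, gt=0.0)
    prototype_score: str = "max"  # or "centroid"
    seed: int = 0


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Deterministic text -> unit-norm vector of fixed dimension."""

    dim: int

    def embed(self, text: str) -> np.ndarray:
        ...


class HashingNgramEmbedder:
    """Character n-gram hashing embedder (3–5-grams, 1,024 buckets).

    The normalized text is padded with boundary markers, its character
    n-grams are hashed (BLAKE2b, stable across processes) into ``dim``
    buckets, and the count vector is L2-normalized. Identical text always
    maps to the identical vector; the empty string maps to the zero vector.
    """

    def __init__(self, dim: int = 1024, ngram_range: tuple[int, int] = (3, 5)):
        self.dim = dim
        self.ngram_range = ngram_range
        self.name = f"hashing-ngram-{ngram_range[0]}-{ngram_range[1]}-d{dim}"

    def embed(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        t = normalize_text(text)
        if not t:
            return v
        padded = f"<{t}>"
        lo, hi = self.ngram_range
        for n in range(lo, hi + 1):
            for i in range(max(0, len(padded) - n + 1)):
                gram = padded[i : i + n]
                h = int.from_bytes(
                    hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest(), "big"
                )
                v[h % self.dim] += 1.0
        norm = float(np.linalg.norm(v))
        return v / norm if norm > 0 else v

    def embed_many(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([self.embed(t) for t in texts]) if texts else np.zeros((0, self.dim))


@dataclass(frozen=True)
class LabeledExample:
    """A short labelled text used to fit a classifier (label != not_present)."""

    text: str
    label: str


@dataclass(frozen=True)
class Prediction:
    label: str
    classifier_confidence: float


@dataclass
class PrototypeModel:
    """Per-class labelled example embeddings for nearest-example classification."""

    feature_id: str
    classes: tuple[str, ...]  # schema order, restricted to fitted classes
    embeddings: dict[str, np.ndarray]  # class -> (n_c, d) unit-norm rows
    texts: dict[str, list[str]]
    embedder: EmbeddingBackend

    @property
    def n_examples(self) -> int:
        return sum(e.shape[0] for e in self.embeddings.values())


class ClassifierError(ValueError):
    pass


def _check_examples(examples: Sequence[LabeledExample], feature: FeatureSchema) -> None:
    if not examples:
        raise ClassifierError(f"{feature.feature_id}: no training examples")
    for ex in examples:
        label = normalize_label(ex.label)
        if label == NOT_PRESENT:
            raise ClassifierError(
                f"{feature.feature_id}: {NOT_PRESENT!r} cannot be a training class "
                "(it is assigned by routing, not by the classifier)"
            )
        if label not in feature.classes:
            raise ClassifierError(
                f"{feature.feature_id}: example label {label!r} not in vocabulary"
            )


def fit_prototype(
    examples: Sequence[LabeledExample],
    embedder: EmbeddingBackend,
    feature: FeatureSchema,
) -> PrototypeModel:
    """Store normalized example embeddings grouped by class (schema order)."""
    _check_examples(examples, feature)
    grouped: dict[str, list[str]] = {}
    for ex in examples:
        grouped.setdefault(normalize_label(ex.label), []).append(ex.text)
    classes = tuple(c for c in feature.classes if c in grouped)
    embeddings = {c: embedder.embed_many(grouped[c]) for c in classes}
    return PrototypeModel(
        feature_id=feature.feature_id,
        classes=classes,
        embeddings=embeddings,
        texts={c: list(grouped[c]) for c in classes},
        embedder=embedder,
    )


def _softmax(scores: np.ndarray, temperature: float) -> np.ndarray:
    z = scores / temperature
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def classify_prototype(
    model: PrototypeModel,
    text: str,
    temperature: float = 1.0,
    score_mode: str = "max",
) -> Prediction:
    """Assign the class of the most cosine-similar labelled example.

    Per-class score is the max cosine similarity over that class's example
    embeddings (``score_mode="centroid"`` uses the similarity to the
    normalized class centroid instead). The label is the argmax class, ties
    broken by schema class order; the confidence is the softmax of the
    per-class scores at the given temperature.
    """
    v = model.embedder.embed(text)
    scores = np.empty(len(model.classes))
    for i, c in enumerate(model.classes):
        E = model.embeddings[c]
        if score_mode == "centroid":
            centroid = E.mean(axis=0)
            n = np.linalg.norm(centroid)
            scores[i] = float(centroid @ v / n) if n > 0 else 0.0
        else:
            scores[i] = float((E @ v).max())
    probs = _softmax(scores, temperature)
    idx = int(np.argmax(scores))  # np.argmax takes the first max: schema order
    return Prediction(model.classes[idx], float(probs[idx]))


# ---------------------------------------------------------------------------
# contrastive (SetFit-style) few-shot classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastiveConfig:
    margin: float = 0.25
    pairs_per_example: int = 20
    epochs: int = 10
    learning_rate: float = 0.01
    seed: int = 0


@dataclass
class ContrastiveFewShotModel:
    """Linear embedding refiner ``W`` plus a multinomial logistic head."""

    feature_id: str
    classes: tuple[str, ...]
    W: np.ndarray  # (d, d) refinement map applied as W @ v
    head: LogisticRegression
    embedder: EmbeddingBackend
    config: ContrastiveConfig
    loss_history: list[float] = field(default_factory=list)

    def refine(self, v: np.ndarray) -> np.ndarray:
        u = self.W @ v
        n = np.linalg.norm(u)
        return u / n if n > 0 else u


def sample_pairs(
    examples: Sequence[LabeledExample],
    pairs_per_example: int,
    seed: int,
) -> list[tuple[str, str, int]]:
    """Seeded same-class (y=1) / different-class (y=0) text pairs.

    Each example anchors ``R/2`` positive and ``R/2`` negative pairs sampled
    uniformly. A class with a single example cannot anchor positive pairs and
    contributes only its negative pairs (with a warning).
    """
    labels = [normalize_label(ex.label) for ex in examples]
    if len(set(labels)) < 2:
        raise ClassifierError("contrastive pairs need at least two classes")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, l in enumerate(labels):
        by_class.setdefault(l, []).append(i)
    singletons = sorted(c for c, idx in by_class.items() if len(idx) == 1)
    if singletons:
        warnings.warn(
            f"classes with a single example contribute only negative pairs: "
            f"{', '.join(singletons)}",
            stacklevel=2,
        )
    pairs: list[tuple[str, str, int]] = []
    n_pos = pairs_per_example // 2
    n_neg = pairs_per_example - n_pos
    for i, ex in enumerate(examples):
        same = [j for j in by_class[labels[i]] if j != i]
        diff = [j for j in range(len(examples)) if labels[j] != labels[i]]
        if same:
            for j in rng.choice(same, size=n_pos):
                pairs.append((ex.text, examples[j].text, 1))
        for j in rng.choice(diff, size=n_neg):
            pairs.append((ex.text, examples[j].text, 0))
    return pairs


def _pair_loss_and_grad(
    W: np.ndarray, A: np.ndarray, B: np.ndarray, y: np.ndarray, margin: float
) -> tuple[float, np.ndarray]:
    """Mean contrastive loss over pairs and its gradient w.r.t. W.

    L(a, b, y) = y (1 - cos(Wa, Wb))^2 + (1 - y) max(0, cos(Wa, Wb) - m)^2
    """
    eps = 1e-12
    U = A @ W.T
    V = B @ W.T
    nu = np.maximum(np.linalg.norm(U, axis=1), eps)
    nv = np.maximum(np.linalg.norm(V, axis=1), eps)
    c = np.sum(U * V, axis=1) / (nu * nv)
    hinge = np.maximum(0.0, c - margin)
    loss = float(np.mean(y * (1.0 - c) ** 2 + (1 - y) * hinge**2))
    # dL/dc per pair
    g = np.where(y == 1, -2.0 * (1.0 - c), 2.0 * hinge)
    dc_dU = V / (nu * nv)[:, None] - (c / nu**2)[:, None] * U
    dc_dV = U / (nu * nv)[:, None] - (c / nv**2)[:, None] * V
    gU = g[:, None] * dc_dU
    gV = g[:, None] * dc_dV
    dW = (gU.T @ A + gV.T @ B) / len(y)
    return loss, dW


def fit_contrastive(
    examples: Sequence[LabeledExample],
    embedder: EmbeddingBackend,
    feature: FeatureSchema,
    config: ContrastiveConfig | None = None,
) -> ContrastiveFewShotModel:
    """Fit the two-stage few-shot classifier.

    Stage A learns the linear refinement map ``W`` (initialized to the
    identity) by full-batch gradient descent on the contrastive pair loss;
    stage B fits a multinomial logistic head on the refined, re-normalized
    example embeddings. Both stages are deterministic given the seed.
    """
    config = config or ContrastiveConfig()
    _check_examples(examples, feature)
    labels = [normalize_label(ex.label) for ex in examples]
    if len(set(labels)) < 2:
        raise ClassifierError(
            f"{feature.feature_id}: contrastive classifier needs >= 2 classes"
        )
    d = embedder.dim
    W = np.eye(d)
    pairs = sample_pairs(examples, config.pairs_per_example, config.seed)
    A = embedder.embed_many([p[0] for p in pairs])
    B = embedder.embed_many([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])

    history: list[float] = []
    loss, dW = _pair_loss_and_grad(W, A, B, y, config.margin)
    history.append(loss)
    for _ in range(config.epochs):
        W = W - config.learning_rate * dW
        loss, dW = _pair_loss_and_grad(W, A, B, y, config.margin)
        if not math.isfinite(loss):
            raise ClassifierError(
                f"{feature.feature_id}: non-finite contrastive loss "
                f"(lr={config.learning_rate}, margin={config.margin}, "
                f"epoch={len(history)}, pairs={len(y)})"
            )
        history.append(loss)

    classes = tuple(c for c in feature.classes if c in set(labels))
    class_index = {c: i for i, c in enumerate(classes)}
    X = embedder.embed_many([ex.text for ex in examples]) @ W.T
    norms = np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
    X = X / norms
    head = LogisticRegression(max_iter=1000, random_state=config.seed)
    head.fit(X, np.array([class_index[l] for l in labels]))
    return ContrastiveFewShotModel(
        feature_id=feature.feature_id,
        classes=classes,
        W=W,
        head=head,
        embedder=embedder,
        config=config,
        loss_history=history,
    )


def classify_fewshot(model: ContrastiveFewShotModel, text: str) -> Prediction:
    """Head probability argmax on the refined embedding (ties: schema order)."""
    x = model.refine(model.embedder.embed(text))
    probs = model.head.predict_proba(x[None, :])[0]
    # head classes are integer indices into model.classes, already sorted,
    # so argmax-first resolves ties in schema class order
    idx = int(np.argmax(probs))
    return Prediction(model.classes[model.head.classes_[idx]], float(probs[idx]))


# ---------------------------------------------------------------------------
# routing and the end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutputRecord:
    """The only thing the pipeline emits: a closed-vocabulary label plus the
    stage confidences. Contains no report text by default (PII safety);
    ``span_text`` is populated only when explicitly requested."""

    report_id: str
    feature_id: str
    predicted_class: str
    qa_confidence: float
    classifier_confidence: float
    span_text: str | None = None

    def to_dict(self, unsafe_spans: bool = False) -> dict:
        d = {
            "report_id": self.report_id,
            "feature_id": self.feature_id,
            "predicted_class": self.predicted_class,
            "qa_confidence": round(self.qa_confidence, 6),
            "classifier_confidence": round(self.classifier_confidence, 6),
        }
        if unsafe_spans and self.span_text is not None:
            d["span_text"] = self.span_text
        return d


def route(span: AnswerSpan, config: PipelineConfig) -> str | None:
    """Return ``not_present`` for blank/low-confidence spans, else ``None``.

    Blank answers and answers with QA confidence below the threshold are
    assigned the not-present class without consulting the classifier.
    """
    if span.is_empty or span.confidence < config.qa_confidence_threshold:
        return NOT_PRESENT
    return None


def _classify(model, text: str, config: PipelineConfig) -> Prediction:
    if isinstance(model, PrototypeModel):
        return classify_prototype(
            model, text, config.softmax_temperature, config.prototype_score
        )
    if isinstance(model, ContrastiveFewShotModel):
        return classify_fewshot(model, text)
    raise ClassifierError(f"unsupported classifier model {type(model).__name__}")


def run_pipeline(
    report: Report,
    feature: FeatureSchema,
    backend: ExtractiveBackend,
    classifier_model: PrototypeModel | ContrastiveFewShotModel | None,
    config: PipelineConfig | None = None,
) -> OutputRecord:
    """Extract -> route -> classify -> severity-resolve one report/feature.

    All candidate spans from the backend are routed individually; surviving
    spans are classified and, when several mentions yield different classes,
    the most severe class wins (multi-mention rule). With no surviving span
    (or no classifier) the record is ``not_present`` with classifier
    confidence 1.0, since routing — not the classifier — decided it.
    """
    config = config or PipelineConfig()
    spans = ask_all(backend, report, feature)
    max_qa = max((s.confidence for s in spans), default=0.0)
    survivors = [s for s in spans if route(s, config) is None]
    if not survivors or classifier_model is None:
        return OutputRecord(
            report_id=report.report_id,
            feature_id=feature.feature_id,
            predicted_class=NOT_PRESENT,
            qa_confidence=max_qa,
            classifier_confidence=1.0,
        )
    predictions = [(s, _classify(classifier_model, s.text, config)) for s in survivors]
    winner = resolve_most_severe(feature, [p.label for _, p in predictions])
    span, pred = max(
        ((s, p) for s, p in predictions if p.label == winner),
        key=lambda sp: sp[1].classifier_confidence,
    )
    return OutputRecord(
        report_id=report.report_id,
        feature_id=feature.feature_id,
        predicted_class=pred.label,
        qa_confidence=span.confidence,
        classifier_confidence=pred.classifier_confidence,
        span_text=span.text,
    )


def run_batch(
    reports: Iterable[Report],
    feature: FeatureSchema,
    backend: ExtractiveBackend,
    classifier_model,
    config: PipelineConfig | None = None,
) -> list[OutputRecord]:
    return [run_pipeline(r, feature, backend, classifier_model, config) for r in reports]
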