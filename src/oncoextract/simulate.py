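"""Synthetic labelled pathology-report corpora.

Real NHS pathology reports cannot be redistributed, so this module emulates
their statistical and stylistic structure for fully self-contained testing:
right-skewed word counts (log-normal, clipped to the 7–3,213-word range with
mean ≈ 340), ``[redacted]`` tokens from an upstream de-identification step,
biomarker mentions written in varied surface forms ("positive", "+ve",
"g3", "high grade" ...), multi-mention reports where the most severe value
is the ground truth, and three kinds of impossible-answer report: the
feature is absent, only requested ("... p53 has been requested ..."), or
its value was redacted.

Every generated report carries ground-truth labels per feature plus the
provenance of the surface forms actually inserted, so any stage of the
pipeline can be scored without external data. At ``style_noise=0`` every
positive mention uses the canonical surface form and re-parsing a report
with the feature's full lexicon recovers the ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .classify import LabeledExample
from .qa import Report
from .schema import (
    NOT_PRESENT,
    FeatureSchema,
    SchemaRegistry,
    resolve_most_severe,
)

#: word-count envelope of the emulated corpus
MIN_WORDS, MAX_WORDS, MEAN_WORDS = 7, 3213, 339.9

# log-normal parameters solved so that exp(mu + sigma^2/2) = MEAN_WORDS with
# a right skew that keeps essentially all mass inside [MIN_WORDS, MAX_WORDS]
_LENGTH_LOG_SD = 0.9
_LENGTH_LOG_MEAN = float(np.log(MEAN_WORDS) - _LENGTH_LOG_SD**2 / 2)

REDACTED_TOKEN = "[redacted]"

IMPOSSIBLE_KINDS = ("absent", "requested", "redacted_value")


class SyntheticConfig(BaseModel):
    """Knobs of the generator; defaults emulate the reference corpus."""

    model_config = ConfigDict(frozen=True)

    features: tuple[str, ...]
    n_reports: int = Field(ge=1)
    positive_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    style_noise: float = Field(default=0.3, ge=0.0, le=1.0)
    redaction_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    impossible_kinds: Mapping[str, float] = {
        "absent": 0.5,
        "requested": 0.3,
        "redacted_value": 0.2,
    }
    multi_mention_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    length_log_mean: float = _LENGTH_LOG_MEAN
    length_log_sd: float = Field(default=_LENGTH_LOG_SD, gt=0.0)
    seed: int = 0


@dataclass(frozen=True)
class LabeledReport:
    """A synthetic report with per-feature ground truth and provenance."""

    report: Report
    labels: Mapping[str, str]  # feature_id -> class (or not_present)
    provenance: Mapping[str, tuple[tuple[str, str], ...]]  # feature -> ((label, surface), ...)


class CorpusError(ValueError):
    pass


# Filler sentences: plain laboratory narrative containing no digits, no
# feature aliases and no class surface forms, so they can never collide with
# a mention window. Synthetic corpora are PII-free by construction.
_FILLERS = (
    "The specimen was received in formalin and processed routinely.",
    "Sections were examined at multiple levels.",
    "The sample was reviewed at the weekly multidisciplinary meeting.",
    "Clinical details were provided on the request form.",
    "The tissue was embedded in paraffin for further assessment.",
    "Macroscopic description was recorded at the time of dissection.",
    "Representative blocks were taken for microscopy.",
    "The margins were inked prior to sectioning.",
    "Further levels were cut to clarify the appearances.",
    "A supplementary report will follow if additional findings emerge.",
    "The case was discussed with the reporting consultant.",
    "Immunohistochemical panels were performed on selected blocks.",
    "The previous biopsy material was reviewed for comparison.",
    "The specimen was transported according to standard protocol.",
    "Histological examination was undertaken on all submitted tissue.",
    "No additional material was received with this request.",
    "Correlation with imaging and clinical findings is recommended.",
    "The report was issued following internal quality review.",
    "Ancillary studies were arranged as part of the diagnostic workup.",
    "The referring clinician was informed of the preliminary findings.",
    "Controls reacted appropriately throughout the run.",
    "Fixation time was within the accepted laboratory range.",
    "The block was returned to the archive after processing.",
    "Orientation of the specimen was maintained during embedding.",
)

_POSITIVE_TEMPLATES = (
    "{alias}: {value}.",
    "{alias} is {value}.",
    "The {alias} result is {value}.",
    "{alias} status: {value}.",
    "Assessment shows {alias} {value}.",
)

_SECOND_MENTION_TEMPLATES = (
    "A previous report described {alias} as {value}.",
    "Review of the earlier specimen gave {alias} {value}.",
)

# Value-less mention sentences are padded past the extractor's scan window so
# that a neighbouring sentence can never be misread as this feature's value.
_REQUESTED_TEMPLATES = (
    "{alias} staining has been requested and the result will follow in a supplementary message.",
    "{alias} testing is awaited and will be reported separately by the laboratory in due course.",
    "{alias} analysis has been requested from the referring laboratory and remains outstanding at this time.",
)

_REDACTED_TEMPLATES = (
    "{alias}: [redacted] according to the supplementary addendum issued separately.",
    "{alias} result recorded as [redacted] in the source document and withheld from this summary.",
)


def _pick(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def _style_alias(rng: np.random.Generator, feature: FeatureSchema) -> str:
    alias = _pick(rng, feature.aliases)
    form = int(rng.integers(3))
    if form == 0:
        return alias.upper() if len(alias) <= 5 else alias.capitalize()
    if form == 1:
        return alias.capitalize()
    return alias


def _typo(rng: np.random.Generator, s: str) -> str:
    # swap two adjacent interior characters
    if len(s) < 5 or not s.isalpha():
        return s
    i = int(rng.integers(1, len(s) - 2))
    return s[:i] + s[i + 1] + s[i] + s[i + 2 :]


def choose_surface(
    rng: np.random.Generator, feature: FeatureSchema, label: str, style_noise: float
) -> str:
    """Surface form for *label*: canonical at noise 0, styled variants above."""
    surfaces = feature.surfaces_for(label)
    canonical = surfaces[0]
    variants = surfaces[1:]
    s = canonical
    if variants and rng.random() < style_noise:
        s = _pick(rng, variants)
    if rng.random() < 0.3 * style_noise:
        s = _typo(rng, s)
    return s


def _sample_length(rng: np.random.Generator, config: SyntheticConfig) -> int:
    w = rng.lognormal(config.length_log_mean, config.length_log_sd)
    return int(np.clip(round(w), MIN_WORDS, MAX_WORDS))


def _mention_sentences(
    rng: np.random.Generator,
    feature: FeatureSchema,
    config: SyntheticConfig,
) -> tuple[str, list[str], list[tuple[str, str]]]:
    """(truth label, mention sentences, (label, surface) provenance)."""
    if rng.random() < config.positive_fraction:
        label = _pick(rng, feature.positive_classes)
        surface = choose_surface(rng, feature, label, config.style_noise)
        sentences = [
            _pick(rng, _POSITIVE_TEMPLATES).format(
                alias=_style_alias(rng, feature), value=surface
            )
        ]
        inserted = [(label, surface)]
        if rng.random() < config.multi_mention_rate and len(feature.positive_classes) > 1:
            other = _pick(rng, [c for c in feature.positive_classes if c != label])
            surface2 = choose_surface(rng, feature, other, config.style_noise)
            sentences.append(
                _pick(rng, _SECOND_MENTION_TEMPLATES).format(
                    alias=_style_alias(rng, feature), value=surface2
                )
            )
            inserted.append((other, surface2))
        truth = resolve_most_severe(feature, [l for l, _ in inserted])
        return truth, sentences, inserted

    kinds = list(config.impossible_kinds)
    weights = np.array([config.impossible_kinds[k] for k in kinds], dtype=float)
    if weights.sum() <= 0:
        raise CorpusError("impossible_kinds weights must sum to a positive value")
    kind = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]
    if kind == "absent":
        return NOT_PRESENT, [], []
    templates = _REQUESTED_TEMPLATES if kind == "requested" else _REDACTED_TEMPLATES
    sentence = _pick(rng, templates).format(alias=_style_alias(rng, feature))
    return NOT_PRESENT, [sentence], []


def _redact(rng: np.random.Generator, sentence: str) -> str:
    words = sentence.split()
    i = int(rng.integers(1, len(words) + 1))
    return " ".join(words[:i] + [REDACTED_TOKEN] + words[i:])


def generate_corpus(
    config: SyntheticConfig, registry: SchemaRegistry
) -> list[LabeledReport]:
    """Seeded, reproducible corpus of labelled synthetic reports.

    Each report draws its target word count from the configured log-normal
    (clipped to [7, 3213]); each requested feature is independently positive
    with probability ``positive_fraction`` (mention sentences embedded in
    filler narrative) or impossible (absent / requested / redacted value).
    Unknown features raise :class:`CorpusError`.
    """
    for fid in config.features:
        if fid not in registry:
            raise CorpusError(f"unknown feature {fid!r}")
    features = [registry[fid] for fid in config.features]
    rng = np.random.default_rng(config.seed)
    corpus: list[LabeledReport] = []
    for i in range(config.n_reports):
        target_words = _sample_length(rng, config)
        labels: dict[str, str] = {}
        provenance: dict[str, tuple[tuple[str, str], ...]] = {}
        mentions: list[str] = []
        for feature in features:
            truth, sentences, inserted = _mention_sentences(rng, feature, config)
            labels[feature.feature_id] = truth
            provenance[feature.feature_id] = tuple(inserted)
            mentions.extend(sentences)
        mention_words = sum(len(s.split()) for s in mentions)
        fillers: list[str] = []
        words = mention_words
        while words < target_words:
            s = _pick(rng, _FILLERS)
            if rng.random() < config.redaction_rate:
                s = _redact(rng, s)
            fillers.append(s)
            words += len(s.split())
        # scatter mention sentences among the fillers
        sentences = fillers
        for m in mentions:
            pos = int(rng.integers(len(sentences) + 1))
            sentences = sentences[:pos] + [m] + sentences[pos:]
        corpus.append(
            LabeledReport(
                report=Report(report_id=f"r{i:06d}", text=" ".join(sentences)),
                labels=labels,
                provenance=provenance,
            )
        )
    return corpus


def build_eval_split(
    corpus: Sequence[LabeledReport],
    feature_id: str,
    n_pos: int = 50,
    n_neg: int = 50,
    seed: int = 0,
) -> list[LabeledReport]:
    """Sample a test set of exactly *n_pos* positively identifiable and
    *n_neg* impossible-answer reports for one feature, without replacement.

    Mirrors the evaluation protocol of a 50/50 split between reports with a
    positively identifiable mention and reports where the feature is absent
    or not positively identifiable.
    """
    pos = [r for r in corpus if r.labels.get(feature_id, NOT_PRESENT) != NOT_PRESENT]
    neg = [r for r in corpus if r.labels.get(feature_id, NOT_PRESENT) == NOT_PRESENT]
    if len(pos) < n_pos or len(neg) < n_neg:
        raise CorpusError(
            f"{feature_id}: need {n_pos} positive and {n_neg} impossible reports, "
            f"corpus has {len(pos)} and {len(neg)}"
        )
    rng = np.random.default_rng(seed)
    picked = [pos[i] for i in rng.choice(len(pos), size=n_pos, replace=False)]
    picked += [neg[i] for i in rng.choice(len(neg), size=n_neg, replace=False)]
    order = rng.permutation(len(picked))
    return [picked[i] for i in order]


def make_examples(
    registry: SchemaRegistry,
    feature_id: str,
    k_per_class: int,
    seed: int = 0,
    style_noise: float = 0.3,
) -> list[LabeledExample]:
    """``k_per_class`` labelled surface-form texts per non-``not_present``
    class, drawn deterministically from the feature's style lexicon.

    The canonical form of each class is always included first; remaining
    slots cycle through the shuffled variant surface forms (repeating when
    the lexicon is smaller than *k*).
    """
    if k_per_class < 1:
        raise CorpusError("k_per_class must be >= 1")
    feature = registry[feature_id]
    rng = np.random.default_rng(seed)
    examples: list[LabeledExample] = []
    for label in feature.positive_classes:
        surfaces = list(feature.surfaces_for(label))
        canonical, variants = surfaces[0], surfaces[1:]
        if variants and style_noise > 0:
            variants = [variants[i] for i in rng.permutation(len(variants))]
            pool = [canonical] + variants
        else:
            pool = [canonical]
        for j in range(k_per_class):
            examples.append(LabeledExample(text=pool[j % len(pool)], label=label))
    return examples


def truth_table(corpus: Sequence[LabeledReport], feature_id: str) -> dict[str, str]:
    """``report_id -> ground-truth label`` for one feature."""
    return {r.report.report_id: r.labels[feature_id] for r in corpus}
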