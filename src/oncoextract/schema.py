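"""Feature schemas: closed class vocabularies, questions, aliases and severity.

Each clinical feature (biomarker, stage, grade ...) is described by a
:class:`FeatureSchema` holding the natural-language question asked of a
report, the surface forms used to locate mentions, the closed vocabulary of
class labels the pipeline may emit, and a total severity order used to
resolve conflicting mentions within one report ("the most severe result
wins"). A :class:`SchemaRegistry` collects features; the packaged default
registry covers 23 features: 18 endometrial/breast/TNM/haematology features
plus 5 lung features (ALK, CgA, EGFR, synaptophysin, TTF1).

Every vocabulary contains the reserved label ``not_present`` — the class for
reports in which the feature is absent or not positively identifiable — and
``not_present`` is always the least severe class.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

NOT_PRESENT = "not_present"

#: sentinel in a config severity list expanded to the ascending numeric family
NUMERIC_SENTINEL = "__numeric__"

_VALUE_KINDS = ("categorical", "ordinal", "bounded_numeric")


class SchemaError(ValueError):
    """Raised when a schema document fails validation."""


def normalize_label(value: object) -> str:
    """Canonicalize a class label: lower-case, trimmed, inner spaces -> ``_``.

    Leading/trailing punctuation is stripped so that ``"Positive."`` and
    ``"positive"`` map to the same token; ``"No Excess"`` -> ``"no_excess"``.
    """
    s = unicodedata.normalize("NFKC", str(value)).lower().strip()
    s = re.sub(r"\s+", " ", s)
    s = s.strip(" \t.,;:!?'\"()[]{}")
    return s.replace(" ", "_")


class FeatureSchema(BaseModel):
    """One clinical feature: question, mention lexicon and closed vocabulary.

    ``classes`` always includes :data:`NOT_PRESENT`; ``severity_rank`` is a
    permutation of ``classes`` minus ``not_present``, ordered least to most
    severe. ``surface_forms`` maps each non-``not_present`` class to the
    strings it may be written as in free text (the class token itself is
    always an implicit canonical surface form).
    """

    model_config = ConfigDict(frozen=True)

    feature_id: str
    display_name: str
    question: str
    aliases: tuple[str, ...]
    classes: tuple[str, ...]
    severity_rank: tuple[str, ...]
    value_kind: str = "categorical"
    surface_forms: Mapping[str, tuple[str, ...]] = {}
    numeric_range: tuple[int, int] | None = None

    @field_validator("value_kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        if v not in _VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {_VALUE_KINDS}, got {v!r}")
        return v

    @field_validator("aliases")
    @classmethod
    def _aliases_nonempty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v or any(not a.strip() for a in v):
            raise ValueError("aliases must be a non-empty list of non-empty strings")
        return v

    @model_validator(mode="after")
    def _check_vocabulary(self) -> "FeatureSchema":
        fid = self.feature_id
        if not fid:
            raise ValueError("feature_id must be non-empty")
        seen: set[str] = set()
        for c in self.classes:
            if c != normalize_label(c) or not c:
                raise ValueError(f"{fid}: class {c!r} is not in canonical form")
            if c in seen:
                raise ValueError(f"{fid}: duplicate class {c!r}")
            seen.add(c)
        if NOT_PRESENT not in seen:
            raise ValueError(f"{fid}: vocabulary must contain {NOT_PRESENT!r}")
        expected = seen - {NOT_PRESENT}
        if set(self.severity_rank) != expected or len(self.severity_rank) != len(expected):
            raise ValueError(
                f"{fid}: severity_rank must be a permutation of the classes "
                f"excluding {NOT_PRESENT!r}"
            )
        for c in self.surface_forms:
            if c not in seen:
                raise ValueError(f"{fid}: surface_forms for unknown class {c!r}")
        return self

    # -- severity ---------------------------------------------------------

    def severity_index(self, label: str) -> int:
        """Rank of *label*; ``not_present`` is below every other class."""
        label = normalize_label(label)
        if label == NOT_PRESENT:
            return -1
        try:
            return self.severity_rank.index(label)
        except ValueError:
            raise SchemaError(f"{self.feature_id}: unknown label {label!r}") from None

    # -- lexicon ----------------------------------------------------------

    def surfaces_for(self, label: str) -> tuple[str, ...]:
        """All surface forms of *label*, canonical form first."""
        label = normalize_label(label)
        if label not in self.classes:
            raise SchemaError(f"{self.feature_id}: unknown label {label!r}")
        canonical = label.replace("_", " ")
        extra = tuple(s for s in self.surface_forms.get(label, ()) if s != canonical)
        return (canonical, *extra)

    def surface_lexicon(self) -> tuple[tuple[str, str], ...]:
        """``(surface, class)`` pairs for every non-``not_present`` class."""
        pairs: list[tuple[str, str]] = []
        for c in self.classes:
            if c == NOT_PRESENT:
                continue
            for s in self.surfaces_for(c):
                pairs.append((s, c))
        return tuple(pairs)

    @property
    def positive_classes(self) -> tuple[str, ...]:
        return tuple(c for c in self.classes if c != NOT_PRESENT)


class SchemaRegistry(BaseModel):
    """Immutable mapping of ``feature_id`` to :class:`FeatureSchema`."""

    model_config = ConfigDict(frozen=True)

    features: Mapping[str, FeatureSchema]

    def __getitem__(self, feature_id: str) -> FeatureSchema:
        try:
            return self.features[feature_id]
        except KeyError:
            raise SchemaError(f"unknown feature {feature_id!r}") from None

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.features

    def __iter__(self):
        return iter(self.features.values())

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.features)


def _expand_numeric(entry: Mapping) -> tuple[list[str], dict[str, list[str]]]:
    """Integer class family and surface forms for a bounded_numeric feature."""
    lo, hi = entry["numeric_range"]
    patterns = entry.get("numeric_surface_patterns", ["{v}"])
    labels = [str(v) for v in range(int(lo), int(hi) + 1)]
    surfaces = {
        str(v): [p.format(v=v) for p in patterns if p.format(v=v) != str(v)]
        for v in range(int(lo), int(hi) + 1)
    }
    return labels, surfaces


def _build_feature(entry: Mapping) -> FeatureSchema:
    fid = normalize_label(entry.get("feature_id", ""))
    if not fid:
        raise SchemaError("feature entry missing feature_id")
    if "classes" not in entry or "question" not in entry:
        raise SchemaError(f"{fid}: every feature must declare classes and a question")

    classes = [normalize_label(c) for c in entry["classes"]]
    severity = [normalize_label(c) for c in entry.get("severity", entry["classes"])]
    surface_forms = {
        normalize_label(k): [str(s).strip() for s in v]
        for k, v in (entry.get("surface_forms") or {}).items()
    }
    numeric_range = None
    if entry.get("value_kind") == "bounded_numeric":
        if "numeric_range" not in entry:
            raise SchemaError(f"{fid}: bounded_numeric feature needs numeric_range")
        numeric_range = tuple(int(x) for x in entry["numeric_range"])
        num_labels, num_surfaces = _expand_numeric(entry)
        classes = classes + [c for c in num_labels if c not in classes]
        for k, v in num_surfaces.items():  # keep explicit overrides on round-trip
            surface_forms.setdefault(k, v)
        new_numeric = [c for c in num_labels if c not in severity]
        if NUMERIC_SENTINEL in severity:
            i = severity.index(NUMERIC_SENTINEL)
            severity = severity[:i] + new_numeric + severity[i + 1 :]
        else:
            severity = severity + new_numeric
    elif NUMERIC_SENTINEL in severity:
        raise SchemaError(f"{fid}: {NUMERIC_SENTINEL} only valid for bounded_numeric")

    if NOT_PRESENT not in classes:
        classes = classes + [NOT_PRESENT]
    severity = [c for c in severity if c != NOT_PRESENT]

    try:
        return FeatureSchema(
            feature_id=fid,
            display_name=str(entry.get("display_name", fid)),
            question=str(entry["question"]),
            aliases=tuple(str(a).strip() for a in entry.get("aliases", ())),
            classes=tuple(classes),
            severity_rank=tuple(severity),
            value_kind=str(entry.get("value_kind", "categorical")),
            surface_forms={k: tuple(v) for k, v in surface_forms.items()},
            numeric_range=numeric_range,
        )
    except ValueError as exc:
        raise SchemaError(f"invalid feature {fid!r}: {exc}") from exc


def load_registry(config: Mapping | str) -> SchemaRegistry:
    """Build a validated :class:`SchemaRegistry` from a schema document.

    *config* is either an already-parsed mapping with a ``features`` list or
    a YAML string of the same shape. ``not_present`` is injected into any
    vocabulary lacking it. Duplicate feature ids, duplicate classes within a
    feature, or a severity list that is not a permutation of the classes all
    raise :class:`SchemaError` naming the offending feature.
    """
    if isinstance(config, str):
        config = yaml.safe_load(config) or {}
    entries = config.get("features", [])
    features: dict[str, FeatureSchema] = {}
    for entry in entries:
        feat = _build_feature(entry)
        if feat.feature_id in features:
            raise SchemaError(f"duplicate feature_id {feat.feature_id!r}")
        features[feat.feature_id] = feat
    return SchemaRegistry(features=features)


@lru_cache(maxsize=1)
def default_registry() -> SchemaRegistry:
    """The packaged 23-feature registry (loaded once per process)."""
    text = resources.files("oncoextract.data").joinpath("default_schema.yaml").read_text()
    registry = load_registry(text)
    if len(registry) != 23:  # packaging sanity check
        raise SchemaError(f"packaged registry has {len(registry)} features, expected 23")
    return registry


#: feature ids of the 18-feature endometrial/breast/TNM/haematology panel
EXPERIMENT1_FEATURES: tuple[str, ...] = (
    "figo", "grade", "p53", "mmr", "mlh1", "msh2", "msh6", "pms2",
    "myometrial_invasion", "lymphovascular_invasion", "her2", "er", "pr",
    "tnm_t", "tnm_n", "tnm_m", "tnm_edition", "blast_percentage",
)

#: feature ids of the 5-feature lung panel used in the adaptability study
LUNG_FEATURES: tuple[str, ...] = ("alk", "cga", "egfr", "synaptophysin", "ttf1")


def resolve_most_severe(feature: FeatureSchema, labels: Sequence[str]) -> str:
    """Return the most severe label of a non-empty list.

    Implements the annotation rule for multi-mention reports: when a feature
    is reported several times, the clinically most severe value stands.
    ``not_present`` never wins over any other label. Unknown labels raise
    :class:`SchemaError`.
    """
    if not labels:
        raise SchemaError(f"{feature.feature_id}: cannot resolve an empty label list")
    normalized = [normalize_label(l) for l in labels]
    for l in normalized:
        if l != NOT_PRESENT and l not in feature.classes:
            raise SchemaError(f"{feature.feature_id}: unknown label {l!r}")
    return max(normalized, key=feature.severity_index)


def registry_to_config(registry: SchemaRegistry) -> dict:
    """Inverse of :func:`load_registry` (round-trippable plain mapping)."""
    out = []
    for f in registry:
        entry: dict = {
            "feature_id": f.feature_id,
            "display_name": f.display_name,
            "question": f.question,
            "value_kind": f.value_kind,
            "aliases": list(f.aliases),
            "classes": [c for c in f.classes if c != NOT_PRESENT],
            "severity": list(f.severity_rank),
            "surface_forms": {k: list(v) for k, v in f.surface_forms.items()},
        }
        if f.numeric_range is not None:
            entry["numeric_range"] = list(f.numeric_range)
        out.append(entry)
    return {"features": out}


def iter_features(registry: SchemaRegistry, ids: Iterable[str] | None = None):
    """Yield schemas for *ids* (default: all), validating membership."""
    if ids is None:
        yield from registry
    else:
        for fid in ids:
            yield registry[fid]
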