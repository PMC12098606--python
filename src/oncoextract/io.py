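"""JSONL/CSV interchange and model serialization.

JSONL (one record per line) is the canonical interchange: report batches
are ``{"report_id", "text"}``, ground truth is ``{"report_id",
"feature_id", "label"}``, classifier example sets are ``{"text", "label"}``
and pipeline output is ``{"report_id", "feature_id", "predicted_class",
"qa_confidence", "classifier_confidence"}``. CSV with the same columns is
accepted for report input. Fitted models are serialized to a versioned
on-disk format recording the embedder identity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .classify import (
    ContrastiveConfig,
    ContrastiveFewShotModel,
    HashingNgramEmbedder,
    LabeledExample,
    OutputRecord,
    PrototypeModel,
)
from .qa import Report

FORMAT_VERSION = 1


class IOFormatError(ValueError):
    pass


def _read_jsonl(path: Path) -> list[dict]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise IOFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
    return rows


def write_jsonl(rows: Iterable[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(json.dumps(row, ensure_ascii=False, sort_keys=True) + "\n")


def read_reports(path: str | Path) -> list[Report]:
    """Read a report batch from JSONL or CSV (``report_id``, ``text``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str).fillna("")
        rows = df.to_dict("records")
    else:
        rows = _read_jsonl(path)
    reports = []
    seen = set()
    for row in rows:
        if "report_id" not in row or "text" not in row:
            raise IOFormatError(f"{path}: records need 'report_id' and 'text' fields")
        rid = str(row["report_id"])
        if rid in seen:
            raise IOFormatError(f"{path}: duplicate report_id {rid!r}")
        seen.add(rid)
        reports.append(Report(report_id=rid, text=str(row["text"])))
    return reports


def write_reports(reports: Iterable[Report], path: str | Path) -> None:
    write_jsonl(({"report_id": r.report_id, "text": r.text} for r in reports), path)


def read_examples(path: str | Path) -> list[LabeledExample]:
    rows = _read_jsonl(Path(path))
    out = []
    for row in rows:
        if "text" not in row or "label" not in row:
            raise IOFormatError(f"{path}: example records need 'text' and 'label'")
        out.append(LabeledExample(text=str(row["text"]), label=str(row["label"])))
    return out


def write_examples(examples: Iterable[LabeledExample], path: str | Path) -> None:
    write_jsonl(({"text": e.text, "label": e.label} for e in examples), path)


def write_records(
    records: Sequence[OutputRecord], path: str | Path, unsafe_spans: bool = False
) -> None:
    """Write pipeline output; span text is withheld unless *unsafe_spans*."""
    write_jsonl((r.to_dict(unsafe_spans=unsafe_spans) for r in records), path)


def read_truth(path: str | Path) -> dict[str, dict[str, str]]:
    """``feature_id -> {report_id -> label}`` from a truth JSONL file."""
    out: dict[str, dict[str, str]] = {}
    for row in _read_jsonl(Path(path)):
        out.setdefault(str(row["feature_id"]), {})[str(row["report_id"])] = str(row["label"])
    return out


def read_predictions(path: str | Path) -> dict[str, dict[str, str]]:
    """``feature_id -> {report_id -> predicted_class}`` from output JSONL."""
    out: dict[str, dict[str, str]] = {}
    for row in _read_jsonl(Path(path)):
        out.setdefault(str(row["feature_id"]), {})[str(row["report_id"])] = str(
            row["predicted_class"]
        )
    return out


# -- model serialization ----------------------------------------------------


def _embedder_identity(embedder) -> dict:
    return {
        "name": getattr(embedder, "name", type(embedder).__name__),
        "dim": embedder.dim,
    }


def _check_embedder(meta: dict, embedder) -> None:
    identity = _embedder_identity(embedder)
    if meta != identity:
        raise IOFormatError(
            f"model was fitted with embedder {meta}, cannot load with {identity}"
        )


def save_prototype(model: PrototypeModel, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "prototype",
        "feature_id": model.feature_id,
        "embedder": _embedder_identity(model.embedder),
        "classes": list(model.classes),
        "texts": {c: model.texts[c] for c in model.classes},
        "embeddings": {c: model.embeddings[c].tolist() for c in model.classes},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_prototype(path: str | Path, embedder: HashingNgramEmbedder) -> PrototypeModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("kind") != "prototype":
        raise IOFormatError(f"{path}: not a prototype model file")
    _check_embedder(payload["embedder"], embedder)
    return PrototypeModel(
        feature_id=payload["feature_id"],
        classes=tuple(payload["classes"]),
        embeddings={c: np.array(v) for c, v in payload["embeddings"].items()},
        texts={c: list(v) for c, v in payload["texts"].items()},
        embedder=embedder,
    )


def save_contrastive(model: ContrastiveFewShotModel, path: str | Path) -> None:
    np.savez_compressed(
        path,
        format_version=FORMAT_VERSION,
        kind="contrastive",
        feature_id=model.feature_id,
        embedder=json.dumps(_embedder_identity(model.embedder)),
        classes=np.array(model.classes),
        W=model.W,
        coef=model.head.coef_,
        intercept=model.head.intercept_,
        head_classes=model.head.classes_,
        config=json.dumps(vars(model.config)),
        loss_history=np.array(model.loss_history),
    )


def load_contrastive(path: str | Path, embedder: HashingNgramEmbedder) -> ContrastiveFewShotModel:
    with np.load(path, allow_pickle=False) as data:
        if str(data["kind"]) != "contrastive":
            raise IOFormatError(f"{path}: not a contrastive model file")
        _check_embedder(json.loads(str(data["embedder"])), embedder)
        head = LogisticRegression()
        head.coef_ = data["coef"]
        head.intercept_ = data["intercept"]
        head.classes_ = data["head_classes"]
        return ContrastiveFewShotModel(
            feature_id=str(data["feature_id"]),
            classes=tuple(str(c) for c in data["classes"]),
            W=data["W"],
            head=head,
            embedder=embedder,
            config=ContrastiveConfig(**json.loads(str(data["config"]))),
            loss_history=list(data["loss_history"]),
        )
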