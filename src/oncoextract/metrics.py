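"""Evaluation: accuracy/F1 scoring, t-intervals, agreement, error breakdowns
and the training-set-size (adaptability) experiment.

Per-feature accuracy is the percentage of reports whose predicted class
equals the annotated ground truth; precision/recall/F1 are macro-averaged
over the classes present in the truth. Scores are summarized across
features with a Student-t 95% interval (mean ± t_{n-1,0.975} · sd/√n, sample
standard deviation across the n per-feature scores). Interrater agreement
uses Cohen's kappa. The misclassification breakdown decomposes errors by
truth group (impossible vs positively identifiable) and by assigned group.
The learning curve refits the classifier on nested training subsets of
sizes 5/10/20/50/100 over seeded permutations of the test/train split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    HashingNgramEmbedder,
    LabeledExample,
    OutputRecord,
    PipelineConfig,
    fit_prototype,
    run_pipeline,
)
from .qa import Report, RuleBasedBackend
from .schema import NOT_PRESENT, FeatureSchema, SchemaRegistry, normalize_label
from .simulate import LabeledReport, build_eval_split

ConfusionTable = pd.DataFrame  # truth classes x predicted classes


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class MetricsSummary:
    accuracy: float  # percent
    macro_precision: float
    macro_recall: float
    macro_f1: float


@dataclass(frozen=True)
class SummaryCI:
    mean: float
    sd: float
    n: int
    lower: float
    upper: float


@dataclass(frozen=True)
class AgreementResult:
    p_o: float
    p_e: float
    kappa: float


@dataclass(frozen=True)
class MisclassBreakdown:
    misclassified_impossible: int  # truth impossible, predicted a positive class
    misclassified_positive: int  # truth positive, predicted wrongly
    assigned_impossible: int  # errors whose predicted class is not_present
    assigned_positive: int  # errors whose predicted class is a positive class

    @property
    def total_errors(self) -> int:
        return self.misclassified_impossible + self.misclassified_positive


def _as_label_map(predictions) -> dict[str, str]:
    if isinstance(predictions, Mapping):
        return {str(k): normalize_label(v) for k, v in predictions.items()}
    out: dict[str, str] = {}
    for rec in predictions:
        if isinstance(rec, OutputRecord):
            out[rec.report_id] = normalize_label(rec.predicted_class)
        else:
            rid, label = rec
            out[str(rid)] = normalize_label(label)
    return out


def _aligned(predictions, truths) -> tuple[dict[str, str], dict[str, str]]:
    pred = _as_label_map(predictions)
    truth = _as_label_map(truths)
    if not pred:
        raise EvaluationError("empty prediction set")
    if set(pred) != set(truth):
        missing = sorted(set(truth) - set(pred))[:3]
        extra = sorted(set(pred) - set(truth))[:3]
        raise EvaluationError(
            f"predictions and truths are not aligned by report_id "
            f"(missing={missing}, unexpected={extra})"
        )
    return pred, truth


def score(
    predictions, truths, feature: FeatureSchema
) -> tuple[ConfusionTable, MetricsSummary]:
    """Confusion table over the closed vocabulary plus summary metrics.

    Accuracy is 100·trace/total. Precision/recall/F1 are macro-averaged over
    the classes present in the truth, with empty denominators scored 0.
    """
    pred, truth = _aligned(predictions, truths)
    vocab = list(feature.classes)
    for rid in truth:
        for label, kind in ((truth[rid], "truth"), (pred[rid], "predicted")):
            if label not in feature.classes:
                raise EvaluationError(
                    f"{feature.feature_id}: {kind} label {label!r} not in vocabulary"
                )
    table = pd.DataFrame(0, index=vocab, columns=vocab, dtype=int)
    for rid in truth:
        table.loc[truth[rid], pred[rid]] += 1
    total = int(table.values.sum())
    accuracy = 100.0 * float(np.trace(table.values)) / total
    precisions, recalls, f1s = [], [], []
    for c in vocab:
        if table.loc[c].sum() == 0:  # class absent from truth
            continue
        tp = int(table.loc[c, c])
        fp = int(table[c].sum()) - tp
        fn = int(table.loc[c].sum()) - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return table, MetricsSummary(
        accuracy=accuracy,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
    )


def ci_from_summary(mean: float, sd: float, n: int) -> tuple[float, float]:
    """95% Student-t interval from summary statistics, at 2 decimals.

    ``mean ± t_{n-1, 0.975} · sd / sqrt(n)`` — the interval formula used to
    summarize per-feature scores.
    """
    if n < 2:
        raise EvaluationError(f"interval needs n >= 2 scores, got {n}")
    if sd < 0:
        raise EvaluationError("standard deviation must be non-negative")
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return round(mean - half, 2), round(mean + half, 2)


def ci_across_features(per_feature_scores: Sequence[float]) -> SummaryCI:
    """Mean, sample sd and t-interval of per-feature scores."""
    scores = np.asarray(per_feature_scores, dtype=float)
    if scores.size < 2:
        raise EvaluationError("need at least 2 per-feature scores")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    lower, upper = ci_from_summary(mean, sd, scores.size)
    return SummaryCI(mean=mean, sd=sd, n=int(scores.size), lower=lower, upper=upper)


def misclass_breakdown(predictions, truths) -> MisclassBreakdown:
    """Decompose errors by truth group and by assigned group.

    The two decompositions reconcile: errors among truth-impossible reports
    plus errors among truth-positive reports equal errors assigned the
    impossible class plus errors assigned a positive class.
    """
    pred, truth = _aligned(predictions, truths)
    mis_imp = mis_pos = asg_imp = asg_pos = 0
    for rid in truth:
        if pred[rid] == truth[rid]:
            continue
        if truth[rid] == NOT_PRESENT:
            mis_imp += 1
        else:
            mis_pos += 1
        if pred[rid] == NOT_PRESENT:
            asg_imp += 1
        else:
            asg_pos += 1
    return MisclassBreakdown(mis_imp, mis_pos, asg_imp, asg_pos)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Cohen's chance-corrected agreement between two raters.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` and
    chance agreement ``p_e = Σ_c p_a(c)·p_b(c)``. When ``p_e = 1`` (both
    raters constant on the same label) kappa is defined as 1 if agreement is
    perfect and 0 otherwise.
    """
    if len(labels_a) != len(labels_b):
        raise EvaluationError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if not labels_a:
        raise EvaluationError("label vectors must be non-empty")
    a = [normalize_label(x) for x in labels_a]
    b = [normalize_label(x) for x in labels_b]
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = set(a) | set(b)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(p_o=p_o, p_e=p_e, kappa=kappa)


# ---------------------------------------------------------------------------
# adaptability experiment (learning curve over training-set sizes)
# ---------------------------------------------------------------------------


@dataclass
class LearningCurveResult:
    """Accuracy per (training size, permutation, feature) plus aggregates."""

    table: pd.DataFrame  # columns: size, permutation, feature, accuracy

    def summary(self) -> pd.DataFrame:
        """Per size: mean accuracy and 95% CI across per-feature means."""
        rows = []
        for size, group in self.table.groupby("size"):
            per_feature = group.groupby("feature")["accuracy"].mean()
            if len(per_feature) >= 2:
                ci = ci_across_features(per_feature.to_list())
                rows.append(
                    {"size": size, "mean_accuracy": ci.mean, "sd": ci.sd,
                     "lower": ci.lower, "upper": ci.upper}
                )
            else:
                m = float(per_feature.mean())
                rows.append(
                    {"size": size, "mean_accuracy": m, "sd": 0.0,
                     "lower": m, "upper": m}
                )
        return pd.DataFrame(rows).sort_values("size").reset_index(drop=True)


PipelineFactory = Callable[[FeatureSchema, Sequence[LabeledExample], int],
                           Callable[[Report], str]]


def default_pipeline_factory(
    embedder: HashingNgramEmbedder | None = None,
    config: PipelineConfig | None = None,
) -> PipelineFactory:
    """Rule-based extraction + prototype classifier fitted on the examples.

    With no training examples the classifier is absent and every report is
    routed to ``not_present``.
    """
    embedder = embedder or HashingNgramEmbedder()
    config = config or PipelineConfig()
    backend = RuleBasedBackend()

    def factory(feature: FeatureSchema, examples: Sequence[LabeledExample], seed: int):
        model = fit_prototype(examples, embedder, feature) if examples else None

        def predict(report: Report) -> str:
            return run_pipeline(report, feature, backend, model, config).predicted_class

        return predict

    return factory


def examples_from_reports(
    reports: Sequence[LabeledReport], feature_id: str
) -> list[LabeledExample]:
    """Labelled span-text examples from the provenance of training reports."""
    out: list[LabeledExample] = []
    for r in reports:
        for label, surface in r.provenance.get(feature_id, ()):
            out.append(LabeledExample(text=surface, label=label))
    return out


def learning_curve(
    corpus: Sequence[LabeledReport],
    feature_ids: Sequence[str],
    registry: SchemaRegistry,
    sizes: Sequence[int] = (5, 10, 20, 50, 100),
    permutations: int = 5,
    pipeline_factory: PipelineFactory | None = None,
    seed: int = 0,
    n_pos: int = 50,
    n_neg: int = 50,
) -> LearningCurveResult:
    """Accuracy vs training-set size over seeded split permutations.

    For each permutation a fixed test set (``n_pos`` positive / ``n_neg``
    impossible reports) is drawn per feature; training subsets of the
    requested sizes are nested random samples of the remaining reports, the
    classifier is refitted per size from the surface forms occurring in the
    subset, and the test accuracy recorded.
    """
    factory = pipeline_factory or default_pipeline_factory()
    largest = max(sizes)
    rows = []
    root = np.random.SeedSequence(seed)
    perm_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(permutations)]
    for p, pseed in enumerate(perm_seeds):
        for fid in feature_ids:
            feature = registry[fid]
            test = build_eval_split(corpus, fid, n_pos, n_neg, seed=pseed)
            test_ids = {r.report.report_id for r in test}
            pool = [r for r in corpus if r.report.report_id not in test_ids]
            if len(pool) < largest:
                raise EvaluationError(
                    f"{fid}: permutation {p} needs {largest} training reports, "
                    f"only {len(pool)} remain outside the test split"
                )
            rng = np.random.default_rng(pseed + 1)
            order = rng.permutation(len(pool))
            truths = {r.report.report_id: r.labels[fid] for r in test}
            for size in sizes:
                subset = [pool[i] for i in order[:size]]  # nested subsets
                examples = examples_from_reports(subset, fid)
                predict = factory(feature, examples, pseed)
                preds = {r.report.report_id: predict(r.report) for r in test}
                _, summary = score(preds, truths, feature)
                rows.append(
                    {"size": size, "permutation": p, "feature": fid,
                     "accuracy": summary.accuracy}
                )
    return LearningCurveResult(table=pd.DataFrame(rows))
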