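"""Stage 2: embeddings, routing, prototype and contrastive classifiers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oncoextract import (
    ClassifierError,
    ContrastiveConfig,
    FeatureSchema,
    LabeledExample,
    NOT_PRESENT,
    PipelineConfig,
    Report,
    RuleBasedBackend,
    classify_fewshot,
    classify_prototype,
    empty_span,
    fit_contrastive,
    fit_prototype,
    route,
    run_pipeline,
    sample_pairs,
)
from oncoextract.qa import AnswerSpan


def toy_feature(classes=("alpha", "beta", "gamma")):
    return FeatureSchema(
        feature_id="toy",
        display_name="Toy",
        question="What is the toy status?",
        aliases=("toy",),
        classes=(*classes, NOT_PRESENT),
        severity_rank=tuple(classes),
    )


class FixedEmbedder:
    """Stub embedder mapping known texts to fixed unit vectors."""

    def __init__(self, mapping, dim):
        self.mapping = mapping
        self.dim = dim
        self.name = "fixed"

    def embed(self, text):
        return np.array(self.mapping[text], dtype=float)

    def embed_many(self, texts):
        return np.vstack([self.embed(t) for t in texts])


class TestEmbedder:
    def test_deterministic_and_unit_norm(self, embedder):
        v1, v2 = embedder.embed("strongly positive"), embedder.embed("strongly positive")
        np.testing.assert_array_equal(v1, v2)
        assert np.linalg.norm(v1) == pytest.approx(1.0)

    def test_normalization_collapses_case_and_whitespace(self, embedder):
        np.testing.assert_array_equal(
            embedder.embed("  Wild-Type.  "), embedder.embed("wild-type")
        )

    def test_empty_text_maps_to_zero_vector(self, embedder):
        assert np.linalg.norm(embedder.embed("")) == 0.0


class TestRoute:
    def test_blank_answer_routes_to_not_present(self):
        assert route(empty_span(0.99), PipelineConfig()) == NOT_PRESENT

    def test_low_confidence_routes_to_not_present(self):
        span = AnswerSpan("positive", 0, 8, 0.05)
        assert route(span, PipelineConfig()) == NOT_PRESENT

    def test_confident_span_passes(self):
        span = AnswerSpan("wild-type", 0, 9, 0.985)
        assert route(span, PipelineConfig()) is None

    @given(conf=st.floats(0, 1), lo=st.floats(0, 1), hi=st.floats(0, 1))
    def test_routing_monotone_in_threshold(self, conf, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        span = AnswerSpan("v", 0, 1, conf)
        at_lo = route(span, PipelineConfig(qa_confidence_threshold=lo))
        at_hi = route(span, PipelineConfig(qa_confidence_threshold=hi))
        if at_lo == NOT_PRESENT:  # raising the threshold can only add routing
            assert at_hi == NOT_PRESENT


class TestPrototype:
    def test_stores_one_vector_per_example(self, embedder):
        feature = toy_feature(("alpha", "beta"))
        examples = [LabeledExample(f"a{i}", "alpha") for i in range(5)] + [
            LabeledExample(f"b{i}", "beta") for i in range(5)
        ]
        model = fit_prototype(examples, embedder, feature)
        assert model.n_examples == 10

    def test_not_present_examples_rejected(self, embedder):
        with pytest.raises(ClassifierError, match="not_present"):
            fit_prototype(
                [LabeledExample("x", NOT_PRESENT)], embedder, toy_feature()
            )

    def test_single_class_single_example_is_valid(self, embedder):
        model = fit_prototype(
            [LabeledExample("only", "alpha")], embedder, toy_feature()
        )
        assert classify_prototype(model, "only").label == "alpha"

    def test_identical_text_scores_cosine_one(self, embedder):
        feature = toy_feature(("alpha", "beta"))
        model = fit_prototype(
            [LabeledExample("first phrase", "alpha"),
             LabeledExample("second phrase", "beta")],
            embedder,
            feature,
        )
        pred = classify_prototype(model, "first phrase")
        assert pred.label == "alpha"
        assert float((model.embeddings["alpha"] @ embedder.embed("first phrase")).max()) == pytest.approx(1.0)

    def test_orthogonal_query_falls_back_to_first_class_uniformly(self):
        e = np.eye(4)
        emb = FixedEmbedder(
            {"a": e[0], "b": e[1], "c": e[2], "query": e[3]}, dim=4
        )
        model = fit_prototype(
            [LabeledExample("a", "alpha"), LabeledExample("b", "beta"),
             LabeledExample("c", "gamma")],
            emb,
            toy_feature(),
        )
        pred = classify_prototype(model, "query")
        assert pred.label == "alpha"  # first class in schema order
        assert pred.classifier_confidence == pytest.approx(1 / 3)

    @given(data=st.data())
    def test_matches_bruteforce_on_random_instances(self, data):
        """argmax of per-class max cosine, computed by exhaustive loops."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        k = data.draw(st.integers(2, 4))
        classes = [f"c{i}" for i in range(k)]
        feature = toy_feature(tuple(classes))
        mapping, examples = {}, []
        for c in classes:
            for j in range(int(rng.integers(1, 4))):
                v = rng.normal(size=6)
                v /= np.linalg.norm(v)
                mapping[f"{c}x{j}"] = v
                examples.append(LabeledExample(f"{c}x{j}", c))
        q = rng.normal(size=6)
        q /= np.linalg.norm(q)
        mapping["query"] = q
        emb = FixedEmbedder(mapping, dim=6)
        model = fit_prototype(examples, emb, feature)
        pred = classify_prototype(model, "query")
        # independent brute force
        best_label, best_score, scores = None, -np.inf, []
        for c in classes:
            s = max(float(mapping[e.text] @ q) for e in examples if e.label == c)
            scores.append(s)
            if s > best_score:
                best_label, best_score = c, s
        assert pred.label == best_label
        expected_conf = np.exp(scores - np.max(scores))
        expected_conf /= expected_conf.sum()
        assert pred.classifier_confidence == pytest.approx(
            float(expected_conf[classes.index(best_label)])
        )


class TestSamplePairs:
    def test_pair_count(self):
        examples = [LabeledExample("a1", "alpha"), LabeledExample("a2", "alpha"),
                    LabeledExample("b1", "beta"), LabeledExample("b2", "beta")]
        assert len(sample_pairs(examples, 2, seed=0)) == 8

    def test_same_seed_same_pairs(self):
        examples = [LabeledExample(f"t{i}", "alpha" if i % 2 else "beta")
                    for i in range(6)]
        assert sample_pairs(examples, 4, 42) == sample_pairs(examples, 4, 42)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError, match="two classes"):
            sample_pairs([LabeledExample("a", "alpha"), LabeledExample("b", "alpha")], 2, 0)

    def test_singleton_class_contributes_only_negatives(self):
        examples = [LabeledExample("a", "alpha"),
                    LabeledExample("b1", "beta"), LabeledExample("b2", "beta")]
        with pytest.warns(UserWarning, match="alpha"):
            pairs = sample_pairs(examples, 4, 0)
        assert all(y == 0 for a, b, y in pairs if a == "a")


SEPARABLE = [
    LabeledExample("red crimson scarlet", "alpha"),
    LabeledExample("crimson ruby red", "alpha"),
    LabeledExample("scarlet ruby tint", "alpha"),
    LabeledExample("blue azure navy", "beta"),
    LabeledExample("azure cobalt blue", "beta"),
    LabeledExample("navy cobalt shade", "beta"),
]


class TestContrastive:
    def test_separable_toy_data_reaches_perfect_training_accuracy(self, embedder):
        feature = toy_feature(("alpha", "beta"))
        model = fit_contrastive(SEPARABLE, embedder, feature, ContrastiveConfig(seed=1))
        for ex in SEPARABLE:
            assert classify_fewshot(model, ex.text).label == ex.label

    def test_zero_epochs_keeps_identity_map(self, embedder):
        model = fit_contrastive(
            SEPARABLE, embedder, toy_feature(("alpha", "beta")),
            ContrastiveConfig(epochs=0, seed=1),
        )
        np.testing.assert_array_equal(model.W, np.eye(embedder.dim))
        assert len(model.loss_history) == 1

    def test_same_seed_gives_identical_model(self, embedder):
        cfg = ContrastiveConfig(seed=7, epochs=3)
        feature = toy_feature(("alpha", "beta"))
        m1 = fit_contrastive(SEPARABLE, embedder, feature, cfg)
        m2 = fit_contrastive(SEPARABLE, embedder, feature, cfg)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.head.coef_, m2.head.coef_)

    def test_training_decreases_mean_pair_loss(self, embedder):
        model = fit_contrastive(
            SEPARABLE, embedder, toy_feature(("alpha", "beta")),
            ContrastiveConfig(seed=3),
        )
        assert model.loss_history[-1] < model.loss_history[0]

    def test_probabilities_sum_to_one(self, embedder):
        model = fit_contrastive(
            SEPARABLE, embedder, toy_feature(("alpha", "beta")),
            ContrastiveConfig(seed=3, epochs=2),
        )
        x = model.refine(embedder.embed("ruby navy"))
        probs = model.head.predict_proba(x[None, :])[0]
        assert probs.sum() == pytest.approx(1.0)

    def test_single_class_rejected(self, embedder):
        with pytest.raises(ClassifierError):
            fit_contrastive(
                [LabeledExample("a", "alpha"), LabeledExample("b", "alpha")],
                embedder,
                toy_feature(),
            )


class TestRunPipeline:
    def test_report_without_mention_routes_to_not_present(self, registry, embedder):
        from oncoextract import make_examples

        feature = registry["p53"]
        model = fit_prototype(
            make_examples(registry, "p53", 4, seed=0), embedder, feature
        )
        record = run_pipeline(
            Report("r1", "The specimen was received in formalin."),
            feature, RuleBasedBackend(), model,
        )
        assert record.predicted_class == NOT_PRESENT
        assert record.classifier_confidence == 1.0

    def test_multi_mention_resolves_to_most_severe(self, registry, embedder):
        from oncoextract import make_examples

        feature = registry["figo"]
        model = fit_prototype(
            make_examples(registry, "figo", 4, seed=0), embedder, feature
        )
        record = run_pipeline(
            Report("r1", "FIGO: 1a. A previous report described FIGO as 3a."),
            feature, RuleBasedBackend(), model,
        )
        assert record.predicted_class == "3a"

    def test_raising_threshold_never_moves_prediction_away_from_not_present(
        self, registry, embedder
    ):
        from oncoextract import make_examples

        feature = registry["p53"]
        model = fit_prototype(
            make_examples(registry, "p53", 4, seed=0), embedder, feature
        )
        report = Report("r1", "p53: positive.")
        previous = None
        for threshold in (0.0, 0.3, 0.6, 0.96, 1.0):
            record = run_pipeline(
                report, feature, RuleBasedBackend(), model,
                PipelineConfig(qa_confidence_threshold=threshold),
            )
            if previous == NOT_PRESENT:
                assert record.predicted_class == NOT_PRESENT
            previous = record.predicted_class

    def test_output_record_withholds_span_text_by_default(self, registry, embedder):
        from oncoextract import make_examples

        feature = registry["p53"]
        model = fit_prototype(
            make_examples(registry, "p53", 4, seed=0), embedder, feature
        )
        record = run_pipeline(Report("r1", "p53: positive."), feature,
                              RuleBasedBackend(), model)
        assert "span_text" not in record.to_dict()
        assert "span_text" in record.to_dict(unsafe_spans=True)

    @given(text=st.text(max_size=200))
    def test_closed_vocabulary_on_arbitrary_text(self, registry, embedder, text):
        from oncoextract import make_examples

        feature = registry["her2"]
        model = fit_prototype(
            make_examples(registry, "her2", 3, seed=0), embedder, feature
        )
        record = run_pipeline(Report("r", text), feature, RuleBasedBackend(), model)
        assert record.predicted_class in feature.classes
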