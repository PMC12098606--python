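# Methods

This note documents the models and procedures implemented in
`oncoextract`, the parameter choices that matter, what the synthetic data
generator does and does not emulate, and the numerical conventions used
throughout.

## Pipeline model

The pipeline treats clinical feature extraction as *extractive question
answering with impossible answers*, followed by *closed-vocabulary
classification of the extracted span*. The design premise is that a span
extractor cannot hallucinate (its output is a substring of the input by
construction) and that a classifier restricted to a fixed vocabulary
cannot leak free text. `run_pipeline` composes four steps per report and
feature:

1. **Extraction.** The backend returns candidate spans with confidences.
   The `ask`/`ask_all` wrappers enforce
   `span.text == context[start:end]` and reject any backend that violates
   it — this is the no-hallucination guarantee, checked at run time rather
   than assumed.
2. **Routing.** The empty span, and any span with QA confidence strictly
   below `qa_confidence_threshold` (default **0.10**), is assigned
   `not_present` without consulting the classifier. The threshold applies
   only to the QA confidence; the classifier confidence is emitted
   unthresholded so users can apply their own cut-offs.
3. **Classification.** Surviving span texts are normalized (lower-case,
   whitespace collapsed, edge punctuation stripped — a deliberate
   mitigation for spelling/style variability) and classified.
4. **Severity resolution.** If several mentions yield different classes,
   the most severe wins, mirroring the annotation rule that multi-mention
   reports are labelled with the most clinically severe result.
   `not_present` never beats a positive class.

### Rule-based extractive backend

The bundled backend finds each feature-alias occurrence (word-bounded,
case-insensitive) and scans the following **60 characters** for the
earliest — ties broken longest — surface form of any vocabulary class,
returning it at confidence 0.95; if no surface form is found, a loose
numeric pattern is accepted at confidence 0.5; otherwise the mention
yields nothing. The 60-character window covers "is strongly positive
(3+)"-style phrasing without crossing a sentence; it is a constructor
argument. This backend is simultaneously the deterministic test double
and an honest baseline; a fine-tuned transformer QA model can be wrapped
by `transformer_adapter`, whose confidence is defined as the product of
the start- and end-token probabilities renormalized against the no-answer
score (a documented choice — monotone in model certainty — since no
canonical definition exists).

### Embeddings

`HashingNgramEmbedder` hashes character 3–5-grams of the padded,
normalized text into 1,024 buckets (BLAKE2b, stable across processes and
platforms) and L2-normalizes the counts. It is deterministic,
dependency-free, and honours the `EmbeddingBackend` contract (fixed
dimension, unit norm for non-empty text, empty text → zero vector). Any
sentence-transformer can be substituted behind the same contract; results
in this repository use the hashing embedder throughout.

### Prototype classifier

Per class, the score is the **maximum** cosine similarity over that
class's example embeddings — nearest labelled example, not centroid.
Max preserves multi-modal surface families ("g3" and "high grade" both
mean grade 3) that a centroid would blur; a `centroid` scoring mode is
available via `PipelineConfig.prototype_score`. The label is the argmax
(ties broken by schema class order, which makes the degenerate
all-orthogonal case deterministic: first class, confidence 1/K), and the
confidence is a softmax over per-class scores at
`softmax_temperature` (default 1.0).

### Contrastive few-shot classifier

The SetFit-style classifier is realized as a **learned linear map** `W`
(d×d, initialized to the identity) over the frozen base embeddings rather
than deep-network weight updates: full-batch gradient descent on

```
L(a, b, y) = y (1 − cos(Wa, Wb))² + (1 − y) max(0, cos(Wa, Wb) − m)²
```

over pairs sampled per example (R/2 same-class, R/2 different-class,
seeded; singleton classes contribute only negative pairs, with a
warning), followed by a multinomial logistic head on the re-normalized
refined embeddings. Defaults: margin m = 0.25, R = 20 pairs per example,
10 epochs, learning rate 0.01. The linear refiner keeps the method
desk-scale and dependency-free while preserving the two-stage structure
(embedding refinement, then head). The gradient of the pair loss is
derived analytically and computed as two d×d matrix products per epoch.
Both stages are deterministic given the seed; the loss history is stored
on the model, and training is required to decrease the mean pair loss on
separable data (tested).

## Schema registry and severity orders

The packaged registry covers 23 features. Class labels are canonicalized
(lower-case, edge punctuation stripped, inner spaces → `_`);
`not_present` is injected into any vocabulary lacking it and is always
the severity minimum. Severity orders are not fully dictated by the
source material beyond "most severe wins", so the packaged defaults
follow clinical convention and are fully overridable in the YAML config:

* staging/grade orders ascend (FIGO 1 < 1a < … < 4b; grade 1<2<3<4;
  TNM T/N/M ascend with X least severe after `not_present`);
* binary markers rank the disease-indicating class highest: invasion
  present > absent, MMR deficient > intact, receptor/IHC positive >
  negative with equivocal in between (HER2: negative < 1 < 2 < equivocal
  < 3 < positive);
* the four MMR constituent proteins rank **absent above present**,
  because loss of expression is the abnormal, disease-indicating result —
  the one place where the generic "present > absent" convention would
  contradict the disease-indicating principle it is meant to encode;
* bounded-numeric families (blast percentage 0–100, ER/PR Allred 0–8)
  keep the integer value as the label and sit between the flanking
  categorical classes in severity (e.g. negative < 0 … 8 < positive).
  Integers are kept verbatim rather than binned, since the vocabulary
  definition gives ranges, not bins.

## Synthetic corpus generator

The generator's defaults encode the corpus conditions the pipeline is
meant to face: word counts drawn from a log-normal with
`exp(μ + σ²/2) = 339.9` and σ = 0.9, clipped to [7, 3213] (σ chosen so
that the clipped tail mass is negligible and the skew is typical of
clinical text); `[redacted]` tokens inserted into filler sentences at
rate 0.1; each requested feature independently positive with probability
0.5; multi-mention reports at rate 0.1 (two classes inserted, the more
severe labelled); impossible-answer reports split absent/requested/
redacted-value at 0.5/0.3/0.2 (the true prevalence of each kind in real
corpora is unknown; these weights are exposed in `SyntheticConfig`).
`style_noise` interpolates from canonical surface forms ("positive",
"3a") to styled variants ("+ve", "g3", roman-numeral stages) with
occasional adjacent-character typos, exercising the sensitivity of
span-lifting extractors to spelling variability; the package default is
0.3.

Two structural guarantees are built in and tested: at `style_noise = 0`,
re-parsing any generated report with the feature's full lexicon recovers
the severity-resolved ground truth exactly (filler sentences contain no
digits, aliases or surface forms, and value-less mention sentences are
padded past the extractor's scan window so neighbouring sentences cannot
be misread); and generated text is drawn entirely from a fixed template
vocabulary, so synthetic corpora are PII-free by construction.

**What passing on synthetic data does and does not show.** The generator
reproduces mention patterns, surface-form variety, redaction tokens and
length statistics — not real report structure, headers, negation scope,
discourse ("no evidence of…"), OCR noise, or clinical plausibility.
Perfect noise-free accuracy therefore validates the *pipeline contracts*
(extraction window, routing, severity resolution, closed vocabulary),
not expected performance on hospital data; noisy-corpus and
learning-curve numbers demonstrate relative behaviour (classifier
comparisons, plateau shape), not absolute clinical accuracy.

## Evaluation protocol

* **Accuracy** is the percentage of reports whose predicted class equals
  the ground truth, on test splits of 50 positively identifiable + 50
  impossible reports per feature.
* **Precision/recall/F1** are macro-averaged over classes present in the
  truth (macro chosen because the class imbalance of the 50/50 design
  otherwise hides minority-class errors; empty denominators score 0).
* **Across-feature summaries** use the Student-t interval
  `mean ± t_{n−1, 0.975} · sd / √n` with the *sample* standard deviation
  across per-feature scores, reported at 2 decimals. With n = 18
  features this formula reproduces independently printed accuracy
  intervals exactly, which pins the interpretation to the t distribution
  (a normal-z interval does not reproduce them).
* **Cohen's kappa** `(p_o − p_e)/(1 − p_e)` with
  `p_e = Σ_c p_a(c) p_b(c)`; the degenerate case `p_e = 1` is defined as
  1 for perfect agreement and 0 otherwise.
* **Misclassification breakdowns** decompose errors by truth group
  (impossible vs positively identifiable) and by assigned group; the two
  decompositions must reconcile to the total error count on every
  instance.
* **Learning curve**: per permutation, a fixed 50/50 test split is drawn;
  training subsets of sizes 5/10/20/50/100 are *nested* random samples of
  the remaining reports (nesting reduces between-size variance relative
  to independent resampling); the classifier is refitted per size from
  the surface forms occurring in the subset, and accuracies are
  aggregated across features with the t-interval above. A subset with no
  positive examples yields no classifier and routes everything to
  `not_present` (50% accuracy on a 50/50 split), which is the honest
  floor of the experiment.

## Problem sizes used in the bundled runs

The packaged test suite and `scripts/acceptance.py` use: 160-report
corpora per feature for the 50/50 splits (all 18 panel features
noise-free; 6 representative features — p53, HER2, grade, FIGO, MMR,
ER — for the prototype-vs-contrastive comparison at `style_noise = 0.3`);
a 240-report corpus over 3 lung features × 5 permutations for the
learning curve; 10,000 reports (6,000 synthetic at `style_noise = 0.5`
plus 4,000 adversarial: random codepoints and shuffled trigger tokens)
for the closed-vocabulary/PII property; and 1,000/500 random instances
for the classifier/metric oracle checks. These sizes give stable
statistics on a single CPU in well under a minute.

## Known limitations

* The rule-based extractor has no negation or hedge handling ("no
  evidence of lymphovascular invasion" extracts nothing only because
  "evidence" is not in the lexicon window — "lymphovascular invasion:
  not identified" is handled by the explicit "not identified" surface
  form, not by a negation model).
* The hashing embedder captures character-level similarity only; it has
  no semantics ("wild-type" and "normal" are similar only insofar as
  they co-occur as labelled examples of the same class).
* The contrastive refiner is linear; it cannot learn interactions a
  fine-tuned deep sentence encoder could.
* Severity orders for vocabularies without a clinical total order (TNM
  edition) are conventions needed only to make multi-mention resolution
  deterministic, not clinical claims.
* Generative-baseline scores depend on an external model supplied by the
  user; the package validates only the prompt/parse plumbing (a mock
  echo backend closes the loop at 100% on noise-free data).
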