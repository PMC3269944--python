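"""End-to-end pipeline: gene tagging -> feature extraction -> vocabulary
fit -> vectorization -> data-derived regularization -> Huber training ->
optional higher-order induction -> prediction and evaluation.

The five submitted-run presets toggle the feature families:

=======  ========  ============  =====  ===========  ===========  ============
preset   extra     multi-word    MeSH   stemmed GRs  feature cut  higher order
         corpus    (uni/bi/tri)
=======  ========  ============  =====  ===========  ===========  ============
run1     no        uni+bi        yes    no           no           no
run2     yes       uni+bi        yes    no           no           no
run3     no        uni+bi+tri    yes    yes          DF >= 4      no
run4     yes       uni+bi+tri    yes    yes          DF >= 4      no
run5     no        uni+bi+tri    yes    yes          DF >= 4      yes
=======  ========  ============  =====  ===========  ===========  ============

Substring (character 6-gram) features and gene anonymization are part of
the baseline in every preset.  The "extra corpus" flag merges a second
labeled corpus into training (standing in for an additional development
set); it changes data, not features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from . import corpus_io, evaluation, gene_ner
from . import higher_order as higher_order_mod
from . import huber as huber_mod
from .corpus_io import LabeledCorpus, ParseRecord
from .features import (
    FeatureConfig,
    FeatureVocabulary,
    extract_document_features,
    fit_vocabulary,
    vectorize,
)
from .gene_ner import GeneMention, PriorityModel
from .huber import HuberModel, TrainSettings

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PRESETS", "preset", "train_run", "predict", "evaluate_scores"]


@dataclass(frozen=True)
class RunConfig:
    """Feature toggles plus training hyperparameters for one run."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    train_settings: TrainSettings = field(default_factory=TrainSettings)
    lam_prime: float = huber_mod.DEFAULT_LAMBDA_PRIME
    use_extra_corpus: bool = False
    higher_order: bool = False
    higher_order_min_count: int = higher_order_mod.DEFAULT_MIN_COUNT
    higher_order_min_derivative: float = higher_order_mod.DEFAULT_MIN_DERIVATIVE

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


PRESETS: dict[str, RunConfig] = {
    "run1": RunConfig(
        features=FeatureConfig(use_trigram=False, stem_dependency=False, min_doc_freq=1)
    ),
    "run2": RunConfig(
        features=FeatureConfig(use_trigram=False, stem_dependency=False, min_doc_freq=1),
        use_extra_corpus=True,
    ),
    "run3": RunConfig(
        features=FeatureConfig(use_trigram=True, stem_dependency=True, min_doc_freq=4)
    ),
    "run4": RunConfig(
        features=FeatureConfig(use_trigram=True, stem_dependency=True, min_doc_freq=4),
        use_extra_corpus=True,
    ),
    "run5": RunConfig(
        features=FeatureConfig(use_trigram=True, stem_dependency=True, min_doc_freq=4),
        higher_order=True,
    ),
}


def preset(name: str) -> RunConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


@dataclass
class RunReport:
    """Everything a run produced, serializable to JSON."""

    preset: str
    vocabulary_size: int
    n_train: int
    n_positive: int
    n_negative: int
    lam: float
    n_iterations: int
    final_cost: float
    induced_pairs: int
    metrics: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class TrainedArtifacts:
    config: RunConfig
    vocabulary: FeatureVocabulary
    model: HuberModel
    priority_model: PriorityModel | None
    report: RunReport


def _group_parses(parses: Sequence[ParseRecord]) -> dict[str, list[ParseRecord]]:
    grouped: dict[str, list[ParseRecord]] = {}
    for rec in parses:
        grouped.setdefault(rec.doc_id, []).append(rec)
    return grouped


def _tag_corpus(
    corpus: LabeledCorpus, priority_model: PriorityModel
) -> dict[str, list[GeneMention]]:
    from .features import tokenize_sentences

    mentions: dict[str, list[GeneMention]] = {}
    for doc in corpus.documents:
        text = (doc.title + " " + doc.abstract).strip()
        sentences = tokenize_sentences(text, lowercase=False)
        candidates = gene_ner.regex_candidate_phrases(sentences)
        mentions[doc.doc_id] = gene_ner.tag_document(priority_model, doc, candidates)
    return mentions


def _doc_features(
    corpus: LabeledCorpus,
    config: RunConfig,
    parses: Sequence[ParseRecord],
    mentions: dict[str, list[GeneMention]] | None,
) -> dict[str, set[str]]:
    grouped = _group_parses(parses)
    feats: dict[str, set[str]] = {}
    for doc in corpus.documents:
        feats[doc.doc_id] = extract_document_features(
            doc,
            config.features,
            parses=grouped.get(doc.doc_id, ()),
            mentions=(mentions or {}).get(doc.doc_id, ()),
        )
    return feats


def train_run(
    corpus: LabeledCorpus,
    config: RunConfig,
    parses: Sequence[ParseRecord] = (),
    mentions: dict[str, list[GeneMention]] | None = None,
    priority_model: PriorityModel | None = None,
    extra_corpus: LabeledCorpus | None = None,
    extra_parses: Sequence[ParseRecord] = (),
    preset_name: str = "custom",
) -> TrainedArtifacts:
    """Execute the full training pipeline on a labeled corpus.

    Gene mentions may be supplied directly (e.g. gold mentions from the
    synthetic generator) or produced by tagging with a Priority Model and
    the regex candidate chunker.  Parses are required only when
    dependency features are enabled.
    """
    if config.features.use_dependency and not parses:
        raise ValueError("dependency features enabled but no parses supplied")
    if config.use_extra_corpus and extra_corpus is not None:
        merged_docs = corpus.documents + extra_corpus.documents
        merged_labels = dict(corpus.labels)
        merged_labels.update(extra_corpus.labels)
        corpus = LabeledCorpus(merged_docs, merged_labels)
        parses = list(parses) + list(extra_parses)

    if mentions is None and priority_model is not None:
        mentions = _tag_corpus(corpus, priority_model)

    feats = _doc_features(corpus, config, parses, mentions)
    vocab = fit_vocabulary([feats[d.doc_id] for d in corpus.documents], config.features)
    vectors = [
        vectorize(feats[d.doc_id], vocab, d.doc_id).indices for d in corpus.documents
    ]
    labels = [corpus.labels[d.doc_id] for d in corpus.documents]

    model = huber_mod.train(
        vectors,
        labels,
        config.train_settings,
        lam_prime=config.lam_prime,
        n_features=len(vocab),
    )

    induced = []
    if config.higher_order:
        model, _X_aug, induced = higher_order_mod.induce_and_retrain(
            model,
            vectors,
            labels,
            config.train_settings,
            min_count=config.higher_order_min_count,
            min_derivative=config.higher_order_min_derivative,
            vocabulary=vocab,
        )

    scores, preds = predict(model, vocab, corpus, parses, mentions, config)
    metrics = evaluation.metrics_report(scores, preds, corpus.labels)
    report = RunReport(
        preset=preset_name,
        vocabulary_size=len(vocab),
        n_train=len(corpus),
        n_positive=corpus.n_positive,
        n_negative=corpus.n_negative,
        lam=model.lam,
        n_iterations=model.n_iterations,
        final_cost=model.final_cost,
        induced_pairs=len(induced),
        metrics=metrics,
    )
    return TrainedArtifacts(config, vocab, model, priority_model, report)


def _expand_higher_order(indices: tuple[int, ...], vocab: FeatureVocabulary) -> tuple[int, ...]:
    """Activate H|i&j conjunctions whose constituents are both active."""
    active = set(indices)
    extra = []
    for feat, idx in vocab.index.items():
        if feat.startswith("H|"):
            i, j = feat[2:].split("&")
            if int(i) in active and int(j) in active:
                extra.append(idx)
    return tuple(sorted(active | set(extra)))


def predict(
    model: HuberModel,
    vocab: FeatureVocabulary,
    corpus: LabeledCorpus,
    parses: Sequence[ParseRecord] = (),
    mentions: dict[str, list[GeneMention]] | None = None,
    config: RunConfig | None = None,
) -> tuple[dict[str, float], dict[str, int]]:
    """Score and binarize every document; returns (scores, sign labels)."""
    config = config or RunConfig()
    if len(model.w) != len(vocab):
        raise ValueError(
            f"model has {len(model.w)} weights but vocabulary has {len(vocab)} features"
        )
    feats = _doc_features(corpus, config, parses, mentions)
    scores: dict[str, float] = {}
    preds: dict[str, int] = {}
    has_higher = any(f.startswith("H|") for f in vocab.index)
    for doc in corpus.documents:
        vec = vectorize(feats[doc.doc_id], vocab, doc.doc_id).indices
        if has_higher:
            vec = _expand_higher_order(vec, vocab)
        s = huber_mod.score(model, vec)
        scores[doc.doc_id] = s
        preds[doc.doc_id] = +1 if s > 0 else -1
    return scores, preds


def evaluate_scores(
    scores: dict[str, float], gold: dict[str, int]
) -> dict[str, float]:
    """Metric suite from raw scores, binarizing by sign."""
    preds = {d: (+1 if s > 0 else -1) for d, s in scores.items()}
    return evaluation.metrics_report(scores, preds, gold)


def write_scores(scores: dict[str, float], path: Path) -> None:
    order = sorted(scores, key=lambda d: (-scores[d], d))
    with open(path, "w") as fh:
        for doc_id in order:
            s = scores[doc_id]
            label = 1 if s > 0 else -1
            fh.write(f"{doc_id}\t{s:.10g}\t{label}\n")


def read_scores(path: Path) -> dict[str, float]:
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            doc_id, s, _label = line.rstrip("\n").split("\t")
            scores[doc_id] = float(s)
    return scores
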