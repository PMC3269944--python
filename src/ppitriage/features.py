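"""Feature extraction: word n-grams, character substrings, MeSH terms and
dependency-relation features, with gene anonymization and a document-
frequency cut.

Feature strings are namespaced by family prefix so families can never
collide:

========  =====================================
prefix    family
========  =====================================
``W1|``   word unigram
``W2|``   word bigram (within sentence)
``W3|``   word trigram (within sentence)
``S|``    character k-gram of a token (k = 6)
``M1|``   MeSH descriptor unigram
``M2|``   MeSH descriptor bigram
``D|``    dependency relation ``rel(head,dep)``
``H|``    induced higher-order conjunction
========  =====================================

All features are binary presence indicators; a document's vector is the
set of vocabulary indices of its features.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

from .corpus_io import Document, ParseRecord
from .gene_ner import GeneMention
from .porter import porter_stem

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "FeatureVocabulary",
    "FeatureVector",
    "split_sentences",
    "tokenize",
    "tokenize_sentences",
    "anonymize_tokens",
    "word_ngram_features",
    "substring_features",
    "mesh_features",
    "dependency_features",
    "extract_document_features",
    "fit_vocabulary",
    "vectorize",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Toggles for the feature families used by the submitted-run presets."""

    use_unigram: bool = True
    use_bigram: bool = True
    use_trigram: bool = False
    use_substrings: bool = True
    substring_k: int = 6
    use_mesh: bool = True
    use_dependency: bool = True
    stem_dependency: bool = False
    anonymize_genes: bool = True
    anonymous_tag: str = "PTNWORD"
    min_doc_freq: int = 1

    def __post_init__(self) -> None:
        if self.substring_k < 2:
            raise ValueError("substring_k must be >= 2")
        if self.min_doc_freq < 1:
            raise ValueError("min_doc_freq must be >= 1")

    def with_(self, **kwargs) -> "FeatureConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_SENT_BOUNDARY = re.compile(r"(?<=[.?!])\s+(?=[A-Z0-9])")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")


def split_sentences(text: str) -> list[str]:
    """Split on ``[.?!]`` followed by whitespace and an upper-case letter."""
    text = text.strip()
    if not text:
        return []
    return [s for s in _SENT_BOUNDARY.split(text) if s.strip()]


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Word tokens; internal hyphens and digits survive (``MEK-1``, ``p53``)."""
    tokens = _TOKEN_RE.findall(text)
    if lowercase:
        tokens = [t.lower() for t in tokens]
    return tokens


def tokenize_sentences(text: str, lowercase: bool = True) -> list[list[str]]:
    return [tokenize(s, lowercase=lowercase) for s in split_sentences(text)]


def anonymize_tokens(
    sentences: Sequence[Sequence[str]],
    mentions: Iterable[GeneMention],
    tag: str = "PTNWORD",
) -> list[list[str]]:
    """Replace each mention's token span with the anonymous tag (one token).

    Multi-word mentions collapse to a single tag token, so a mention
    behaves as one unit in every downstream feature family.
    """
    out = [list(s) for s in sentences]
    by_sentence: dict[int, list[GeneMention]] = {}
    for m in mentions:
        by_sentence.setdefault(m.sentence_index, []).append(m)
    for s, ms in by_sentence.items():
        if s >= len(out):
            continue
        for m in sorted(ms, key=lambda m: -m.start):
            if m.end <= len(out[s]):
                out[s][m.start : m.end] = [tag]
    return out


# ---------------------------------------------------------------------------
# Feature families
# ---------------------------------------------------------------------------

def word_ngram_features(
    sentences: Sequence[Sequence[str]], config: FeatureConfig
) -> set[str]:
    """Word unigram/bigram/trigram features; n-grams never cross a
    sentence boundary (only neighboring words are combined)."""
    feats: set[str] = set()
    for tokens in sentences:
        if config.use_unigram:
            feats.update(f"W1|{t}" for t in tokens)
        if config.use_bigram:
            feats.update(
                f"W2|{a}_{b}" for a, b in zip(tokens, tokens[1:])
            )
        if config.use_trigram:
            feats.update(
                f"W3|{a}_{b}_{c}"
                for a, b, c in zip(tokens, tokens[1:], tokens[2:])
            )
    return feats


def substring_features(tokens: Iterable[str], k: int = 6) -> set[str]:
    """All contiguous character k-grams per token; short tokens emit the
    whole token.  Tokens are lowercased first."""
    feats: set[str] = set()
    for tok in tokens:
        tok = tok.lower()
        if not tok:
            continue
        if len(tok) <= k:
            feats.add(f"S|{tok}")
        else:
            feats.update(f"S|{tok[i : i + k]}" for i in range(len(tok) - k + 1))
    return feats


_MESH_SPLIT = re.compile(r"[\s,]+")


def mesh_features(mesh_terms: Iterable[str]) -> set[str]:
    """Unigram and bigram subphrases of each MeSH descriptor.

    Qualifiers after ``/`` are treated as separate descriptors.
    """
    feats: set[str] = set()
    for raw in mesh_terms:
        for descriptor in raw.split("/"):
            tokens = [t for t in _MESH_SPLIT.split(descriptor.lower().strip()) if t]
            feats.update(f"M1|{t}" for t in tokens)
            feats.update(f"M2|{a}_{b}" for a, b in zip(tokens, tokens[1:]))
    return feats


def _mention_surface_keys(mentions: Iterable[GeneMention]) -> set[str]:
    keys: set[str] = set()
    for m in mentions:
        surface = m.surface.lower()
        keys.add(surface)
        keys.add(surface.replace(" ", "_"))
        keys.update(surface.split())
    return keys


def dependency_features(
    parses: Iterable[ParseRecord],
    mentions: Iterable[GeneMention],
    config: FeatureConfig,
) -> set[str]:
    """``D|rel(head,dep)`` features from dependency relations.

    Gene names in the *dependent* position are replaced by the anonymous
    tag when anonymization is on; head words are kept verbatim even when
    they are genes.  With stemming on, the Porter stemmer is applied to
    the head and to non-anonymized dependents; the tag itself is never
    stemmed or lowercased.
    """
    mention_keys = _mention_surface_keys(mentions) if config.anonymize_genes else set()
    feats: set[str] = set()
    for record in parses:
        for rel, head, dep in record.relations:
            head = head.lower()
            if config.stem_dependency:
                head = porter_stem(head)
            if config.anonymize_genes and dep.lower() in mention_keys:
                dep_out = config.anonymous_tag
            else:
                dep_out = dep.lower()
                if config.stem_dependency:
                    dep_out = porter_stem(dep_out)
            feats.add(f"D|{rel}({head},{dep_out})")
    return feats


def extract_document_features(
    document: Document,
    config: FeatureConfig,
    parses: Iterable[ParseRecord] = (),
    mentions: Iterable[GeneMention] = (),
) -> set[str]:
    """All enabled feature families for one document.

    Title and abstract are concatenated with a sentence boundary between
    them.  When anonymization is on, mention spans are collapsed to the
    anonymous tag before word-family extraction, so two documents that
    differ only in gene surface forms yield identical features.
    """
    mentions = list(mentions)
    sentences = tokenize_sentences(
        (document.title + " " + document.abstract).strip(), lowercase=False
    )
    if config.anonymize_genes and mentions:
        sentences = anonymize_tokens(sentences, mentions, config.anonymous_tag)
    # lowercase everything except the anonymous tag
    sentences = [
        [t if t == config.anonymous_tag else t.lower() for t in s] for s in sentences
    ]
    feats: set[str] = set()
    feats |= word_ngram_features(sentences, config)
    if config.use_substrings:
        tokens = [t for s in sentences for t in s if t != config.anonymous_tag]
        feats |= substring_features(tokens, config.substring_k)
    if config.use_mesh:
        feats |= mesh_features(document.mesh_terms)
    if config.use_dependency:
        feats |= dependency_features(parses, mentions, config)
    return feats


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclass
class FeatureVocabulary:
    """Frozen mapping feature-string -> contiguous 1-based index."""

    index: dict[str, int]
    doc_freq: dict[str, int]

    def __len__(self) -> int:
        return len(self.index)

    def family(self, feature: str) -> str:
        return feature.split("|", 1)[0]

    def add_feature(self, feature: str, doc_freq: int = 0) -> int:
        """Append a feature (used by higher-order induction); returns its index."""
        if feature in self.index:
            return self.index[feature]
        idx = len(self.index) + 1
        self.index[feature] = idx
        self.doc_freq[feature] = doc_freq
        return idx

    def save(self, stream: TextIO) -> None:
        for feat, idx in sorted(self.index.items(), key=lambda kv: kv[1]):
            stream.write(f"{feat}\t{idx}\t{self.doc_freq.get(feat, 0)}\t{self.family(feat)}\n")

    @classmethod
    def load(cls, stream: TextIO) -> "FeatureVocabulary":
        index: dict[str, int] = {}
        doc_freq: dict[str, int] = {}
        for line in stream:
            if not line.strip():
                continue
            feat, idx, df, _family = line.rstrip("\n").split("\t")
            index[feat] = int(idx)
            doc_freq[feat] = int(df)
        return cls(index, doc_freq)


@dataclass
class FeatureVector:
    """Sorted binary indicator indices for one document."""

    doc_id: str
    indices: tuple[int, ...]


def fit_vocabulary(
    per_doc_features: Sequence[set[str]], config: FeatureConfig
) -> FeatureVocabulary:
    """Count document frequencies and build the index.

    Features with document frequency below ``min_doc_freq`` are removed
    (the feature cut applies to every family alike); survivors are indexed
    1..V in lexicographic order.
    """
    df: dict[str, int] = {}
    for feats in per_doc_features:
        for f in feats:
            df[f] = df.get(f, 0) + 1
    surviving = sorted(f for f, n in df.items() if n >= config.min_doc_freq)
    if not surviving:
        raise ValueError("feature cut removed every feature; lower min_doc_freq")
    index = {f: i + 1 for i, f in enumerate(surviving)}
    return FeatureVocabulary(index, {f: df[f] for f in surviving})


def vectorize(
    features: Iterable[str], vocabulary: FeatureVocabulary, doc_id: str = ""
) -> FeatureVector:
    """Map feature strings to sorted vocabulary indices, dropping unknowns."""
    idx = []
    dropped = 0
    for f in set(features):
        i = vocabulary.index.get(f)
        if i is None:
            dropped += 1
        else:
            idx.append(i)
    if dropped:
        logger.debug("dropped %d out-of-vocabulary features for %s", dropped, doc_id)
    return FeatureVector(doc_id, tuple(sorted(idx)))
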