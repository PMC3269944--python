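"""Corpus input/output and synthetic-corpus generation.

Readers and writers for the small set of external formats the triage
pipeline consumes: Medline-style tagged abstract records (PMID/TI/AB/MH
fields only) or an equivalent TSV dialect, two-column label files,
dependency-parse tables (flat TSV or CoNLL-X), and SVMlight-style sparse
binary vectors with a vocabulary sidecar.

The synthetic-corpus generator builds fully labeled abstract collections
with planted gene mentions, interaction trigger phrases, label-conditional
MeSH terms and template dependency parses, so that every downstream stage
(gene tagging, feature extraction, classification, evaluation) can be
exercised without any external corpus.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, TextIO

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "LabeledCorpus",
    "DependencyRelation",
    "ParseRecord",
    "SyntheticSpec",
    "read_medline",
    "write_medline",
    "read_labels",
    "write_labels",
    "read_parses",
    "write_parses",
    "read_sparse_vectors",
    "write_sparse_vectors",
    "read_vocabulary_sidecar",
    "write_vocabulary_sidecar",
    "generate_synthetic_corpus",
    "synthetic_gene_lexicon",
    "DEFAULT_TRIGGER_PHRASES",
]


@dataclass
class Document:
    """One abstract record.

    Only title and abstract feed word/syntactic features; ``mesh_terms``
    feed MeSH features exclusively.
    """

    doc_id: str
    title: str
    abstract: str
    mesh_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("Document requires a non-empty doc_id")


@dataclass
class LabeledCorpus:
    """Documents plus one binary relevance label (+1 PPI / -1 non-PPI) each."""

    documents: list[Document]
    labels: dict[str, int]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_id in corpus")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"documents without labels: {missing[:5]}")
        bad = {i: l for i, l in self.labels.items() if l not in (+1, -1)}
        if bad:
            raise ValueError(f"labels must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def n_positive(self) -> int:
        return sum(1 for d in self.documents if self.labels[d.doc_id] == +1)

    @property
    def n_negative(self) -> int:
        return sum(1 for d in self.documents if self.labels[d.doc_id] == -1)


class DependencyRelation(NamedTuple):
    """(grammar relation label, head word, dependent word) from a parse."""

    relation: str
    head: str
    dependent: str


@dataclass
class ParseRecord:
    """Dependency relations for one sentence of one document."""

    doc_id: str
    sentence_index: int
    relations: list[DependencyRelation]


def _as_stream(stream: TextIO | str) -> TextIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


# ---------------------------------------------------------------------------
# Medline-style records
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"^([A-Z][A-Z0-9]{1,3})\s*- ?(.*)$")


def _parse_tagged_records(lines: list[str]) -> list[Document]:
    docs: list[Document] = []
    seen: set[str] = set()
    record: list[tuple[str, str]] = []

    def flush(ordinal: int) -> None:
        if not record:
            return
        fields: dict[str, list[str]] = {}
        for tag, value in record:
            fields.setdefault(tag, []).append(value)
        if "PMID" not in fields:
            raise ValueError(f"record {ordinal} has no PMID field")
        doc_id = fields["PMID"][0].strip()
        if not doc_id:
            raise ValueError(f"record {ordinal} has an empty PMID")
        if doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        docs.append(
            Document(
                doc_id=doc_id,
                title=" ".join(fields.get("TI", [])).strip(),
                abstract=" ".join(fields.get("AB", [])).strip(),
                mesh_terms=[m for m in fields.get("MH", []) if m],
            )
        )
        record.clear()

    ordinal = 0
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip():
            flush(ordinal)
            ordinal += 1
            continue
        m = _TAG_RE.match(line)
        if m:
            record.append((m.group(1), m.group(2)))
        elif line.startswith(" ") and record:
            # continuation line of the previous field, joined by one space
            tag, value = record[-1]
            record[-1] = (tag, (value + " " + line.strip()).strip())
        else:
            raise ValueError(f"unparseable Medline line: {line!r}")
    flush(ordinal)
    return docs


def _parse_tsv_records(lines: list[str]) -> list[Document]:
    docs: list[Document] = []
    seen: set[str] = set()
    for i, raw in enumerate(lines):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"TSV record {i} has fewer than 2 columns")
        parts += [""] * (4 - len(parts))
        doc_id, title, abstract, mesh = parts[:4]
        if not doc_id:
            raise ValueError(f"record {i} has an empty doc_id")
        if doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        mesh_terms = [m.strip() for m in mesh.split(";") if m.strip()]
        docs.append(Document(doc_id, title, abstract, mesh_terms))
    return docs


def read_medline(stream: TextIO | str) -> list[Document]:
    """Read Medline tagged records (PMID/TI/AB/MH) or the 4-column TSV dialect.

    The dialect is auto-detected from the first non-blank line.  Records
    lacking an abstract yield an empty abstract; a missing or duplicated
    doc_id raises ``ValueError``.
    """
    lines = _as_stream(stream).readlines()
    for raw in lines:
        if raw.strip():
            if _TAG_RE.match(raw.rstrip("\n")):
                return _parse_tagged_records(lines)
            return _parse_tsv_records(lines)
    return []


def write_medline(documents: Iterable[Document], stream: TextIO, dialect: str = "tagged") -> None:
    """Write documents in the tagged Medline subset or the TSV dialect."""
    if dialect == "tagged":
        for doc in documents:
            stream.write(f"PMID- {doc.doc_id}\n")
            stream.write(f"TI  - {doc.title}\n")
            stream.write(f"AB  - {doc.abstract}\n")
            for mh in doc.mesh_terms:
                stream.write(f"MH  - {mh}\n")
            stream.write("\n")
    elif dialect == "tsv":
        for doc in documents:
            mesh = ";".join(doc.mesh_terms)
            stream.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}\t{mesh}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

_LABEL_ALIASES = {
    "1": +1, "+1": +1, "true": +1, "p": +1,
    "-1": -1, "false": -1, "n": -1,
}


def read_labels(stream: TextIO | str) -> dict[str, int]:
    """Read a two-column TSV of doc_id and label (1/-1, true/false, P/N)."""
    labels: dict[str, int] = {}
    for i, raw in enumerate(_as_stream(stream)):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"label line {i} does not have 2 columns: {line!r}")
        doc_id, token = parts[0].strip(), parts[1].strip().lower()
        if token not in _LABEL_ALIASES:
            raise ValueError(f"unknown label token {parts[1]!r} on line {i}")
        value = _LABEL_ALIASES[token]
        if doc_id in labels and labels[doc_id] != value:
            raise ValueError(f"conflicting labels for doc_id {doc_id!r}")
        labels[doc_id] = value
    return labels


def write_labels(labels: dict[str, int], stream: TextIO) -> None:
    for doc_id, value in labels.items():
        stream.write(f"{doc_id}\t{value}\n")


# ---------------------------------------------------------------------------
# Dependency parses
# ---------------------------------------------------------------------------

def _parse_conllx(lines: list[str]) -> list[ParseRecord]:
    records: list[ParseRecord] = []
    doc_id = "0"
    sent_index: dict[str, int] = {}
    sentence: list[list[str]] = []

    def flush() -> None:
        nonlocal sentence
        if not sentence:
            return
        idx = sent_index.get(doc_id, 0)
        sent_index[doc_id] = idx + 1
        forms = {int(row[0]): row[1] for row in sentence}
        relations: list[DependencyRelation] = []
        for row in sentence:
            head = int(row[6])
            deprel = row[7]
            if head == 0:
                continue  # root links are not features
            if head not in forms:
                logger.warning(
                    "skipping token %r in %s/%d: dangling head index %d",
                    row[1], doc_id, idx, head,
                )
                continue
            relations.append(DependencyRelation(deprel, forms[head], row[1]))
        records.append(ParseRecord(doc_id, idx, relations))
        sentence = []

    for raw in lines:
        line = raw.rstrip("\n")
        if line.startswith("#"):
            m = re.match(r"#\s*doc(?:_id)?\s*[=:]?\s*(\S+)", line)
            if m:
                flush()
                doc_id = m.group(1)
            continue
        if not line.strip():
            flush()
            continue
        sentence.append(line.split("\t"))
    flush()
    return records


def read_parses(stream: TextIO | str) -> list[ParseRecord]:
    """Read dependency relations in flat TSV or CoNLL-X form.

    Flat TSV columns: doc_id, sentence_index, relation, head, dependent.
    CoNLL-X token tables (>= 8 columns, integer token ids) are converted
    using (DEPREL, head FORM, dependent FORM); root attachments are dropped
    and a dangling head index skips that token with a warning.  A comment
    line ``# doc_id = X`` sets the document for subsequent sentences.
    """
    lines = _as_stream(stream).readlines()
    body = [l for l in lines if l.strip() and not l.startswith("#")]
    if not body:
        return []
    first = body[0].rstrip("\n").split("\t")
    if len(first) >= 8 and first[0].isdigit():
        return _parse_conllx(lines)

    grouped: dict[tuple[str, int], ParseRecord] = {}
    order: list[tuple[str, int]] = []
    for i, raw in enumerate(lines):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"parse line {i} does not have 5 columns: {line!r}")
        doc_id, sent, rel, head, dep = parts
        key = (doc_id, int(sent))
        if key not in grouped:
            grouped[key] = ParseRecord(doc_id, int(sent), [])
            order.append(key)
        grouped[key].relations.append(DependencyRelation(rel, head, dep))
    return [grouped[k] for k in order]


def write_parses(records: Iterable[ParseRecord], stream: TextIO) -> None:
    for rec in records:
        for rel in rec.relations:
            stream.write(
                f"{rec.doc_id}\t{rec.sentence_index}\t{rel.relation}\t{rel.head}\t{rel.dependent}\n"
            )


# ---------------------------------------------------------------------------
# SVMlight-style sparse binary vectors
# ---------------------------------------------------------------------------

def write_sparse_vectors(
    vectors: Iterable[Iterable[int]], labels: Iterable[int], stream: TextIO
) -> None:
    """Write binary vectors as ``<label> <idx>:1 ...`` with 1-based indices."""
    for vec, label in zip(vectors, labels):
        idx = sorted(set(int(i) for i in vec))
        if idx and idx[0] < 1:
            raise ValueError("sparse vector indices must be 1-based")
        head = "+1" if label > 0 else "-1"
        if idx:
            stream.write(head + " " + " ".join(f"{i}:1" for i in idx) + "\n")
        else:
            stream.write(head + "\n")


def read_sparse_vectors(stream: TextIO | str) -> tuple[list[tuple[int, ...]], list[int]]:
    vectors: list[tuple[int, ...]] = []
    labels: list[int] = []
    for lineno, raw in enumerate(_as_stream(stream), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        labels.append(+1 if parts[0] in ("+1", "1") else -1)
        idx: list[int] = []
        for tok in parts[1:]:
            i_str, v_str = tok.split(":")
            if v_str != "1":
                raise ValueError(f"line {lineno}: non-binary value {v_str!r}")
            i = int(i_str)
            if idx and i <= idx[-1]:
                raise ValueError(f"line {lineno}: indices not strictly increasing")
            idx.append(i)
        vectors.append(tuple(idx))
    return vectors, labels


def write_vocabulary_sidecar(vocab: dict[str, int], stream: TextIO) -> None:
    for feat, idx in sorted(vocab.items(), key=lambda kv: kv[1]):
        stream.write(f"{feat}\t{idx}\n")


def read_vocabulary_sidecar(stream: TextIO | str) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for raw in _as_stream(stream):
        if not raw.strip():
            continue
        feat, idx = raw.rstrip("\n").split("\t")
        vocab[feat] = int(idx)
    return vocab


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

DEFAULT_TRIGGER_PHRASES = [
    "interacts with",
    "binds",
    "phosphorylates",
    "associates with",
    "activates",
    "forms a complex with",
    "coimmunoprecipitates with",
    "dimerizes with",
]

_NEGATIVE_VERB_PHRASES = [
    "is expressed in",
    "localizes to",
    "is mutated in",
    "is conserved in",
    "was sequenced from",
]

_POSITIVE_MESH = [
    "Protein Binding",
    "Protein Interaction Mapping",
    "Signal Transduction",
    "Two-Hybrid System Techniques",
]
_NEGATIVE_MESH = [
    "Mice",
    "Humans",
    "Cell Line",
    "Gene Expression Profiling",
]
_COMMON_MESH = ["Proteins", "Molecular Sequence Data"]

_GREEK = ["alpha", "beta", "gamma", "kappa"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic labeled-abstract generator.

    Identical spec (seed included) produces a byte-identical corpus.
    Labels are assigned deterministically by document index: the first
    ``ceil(pos_fraction * n_docs)`` documents are positive, so class
    counts are exact rather than sampled.
    """

    n_docs: int = 200
    pos_fraction: float = 0.5
    vocab_size: int = 120
    n_trigger_phrases: int = 5
    gene_token_rate: float = 1.0
    noise_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pos_fraction <= 1.0:
            raise ValueError("pos_fraction must lie in [0, 1]")
        if self.n_docs < 0 or self.vocab_size < 1:
            raise ValueError("n_docs must be >= 0 and vocab_size >= 1")


_CONSONANTS = "bcdfghjklmnprstvw"
_VOWELS = "aeiou"


def _random_word(rng: np.random.Generator, min_syl: int = 2, max_syl: int = 4) -> str:
    n = int(rng.integers(min_syl, max_syl + 1))
    parts = []
    for _ in range(n):
        parts.append(_CONSONANTS[int(rng.integers(len(_CONSONANTS)))])
        parts.append(_VOWELS[int(rng.integers(len(_VOWELS)))])
    return "".join(parts)


def _background_vocab(rng: np.random.Generator, size: int) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < size:
        w = _random_word(rng)
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _gene_lexicon(rng: np.random.Generator, size: int = 40) -> list[str]:
    """Gene-like names: capitalized stem + digit suffix, ~20% two-word."""
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < size:
        stem = _random_word(rng, 1, 2).capitalize()
        name = f"{stem}{int(rng.integers(1, 10))}"
        if rng.random() < 0.2:
            name = f"{name} {_GREEK[int(rng.integers(len(_GREEK)))]}"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def synthetic_gene_lexicon(spec: SyntheticSpec, size: int = 40) -> list[str]:
    """The gene lexicon a given spec's corpus draws its mentions from.

    Derived from the same seed stream position as inside
    :func:`generate_synthetic_corpus`, so the returned names are exactly
    the ones planted in that corpus.
    """
    rng = np.random.default_rng(spec.seed)
    _background_vocab(rng, spec.vocab_size)
    return _gene_lexicon(rng, size)


def generate_synthetic_corpus(
    spec: SyntheticSpec,
) -> tuple[LabeledCorpus, list[ParseRecord], dict[str, list]]:
    """Generate a labeled synthetic corpus with planted PPI structure.

    Positive documents embed at least one trigger-template sentence
    ``<GENE> <trigger> <GENE>``; negative documents use non-trigger verb
    templates with the same gene-token rate, so gene mentions alone carry
    no label signal.  Background tokens are label-independent noise.
    Template parses emit (subj, verb, gene1) and (obj, verb, gene2)
    relations for every template sentence.  The returned mention map
    records every planted gene token span as a
    :class:`~ppitriage.gene_ner.GeneMention`.
    """
    from .gene_ner import GeneMention  # local import: gene_ner depends on this module

    rng = np.random.default_rng(spec.seed)
    vocab = _background_vocab(rng, spec.vocab_size)
    genes = _gene_lexicon(rng)
    triggers = list(DEFAULT_TRIGGER_PHRASES)
    while len(triggers) < spec.n_trigger_phrases:
        triggers.append(f"{_random_word(rng)}ates")
    triggers = triggers[: max(1, spec.n_trigger_phrases)]

    n_pos = math.ceil(spec.pos_fraction * spec.n_docs)
    documents: list[Document] = []
    labels: dict[str, int] = {}
    parses: list[ParseRecord] = []
    mentions: dict[str, list] = {}

    def pick(seq: list[str]) -> str:
        return seq[int(rng.integers(len(seq)))]

    def noisy_tail() -> list[str]:
        extra = []
        while rng.random() < spec.noise_rate:
            extra.append(pick(vocab))
        return extra

    def finish_sentence(words: list[str]) -> str:
        # every sentence starts uppercase and ends with a period so the
        # feature tokenizer recovers the same sentence boundaries
        words = list(words)
        words[0] = words[0][0].upper() + words[0][1:]
        return " ".join(words) + "."

    for d in range(spec.n_docs):
        doc_id = f"SYN{d:05d}"
        label = +1 if d < n_pos else -1
        labels[doc_id] = label
        doc_mentions: list = []
        doc_parses: list[ParseRecord] = []

        n_sentences = int(rng.integers(3, 6))  # title + 2..4 abstract sentences
        sentences: list[str] = []
        # decide per sentence whether it carries a gene template
        is_template = [
            spec.gene_token_rate > 0 and rng.random() < min(1.0, spec.gene_token_rate)
            for _ in range(n_sentences)
        ]
        if label == +1 and spec.gene_token_rate > 0 and not any(is_template):
            is_template[int(rng.integers(n_sentences))] = True
        # positives: at least one template sentence uses a trigger phrase
        uses_trigger = [False] * n_sentences
        if label == +1:
            template_ids = [i for i, t in enumerate(is_template) if t]
            if template_ids:
                for i in template_ids:
                    uses_trigger[i] = rng.random() < 0.7
                if not any(uses_trigger[i] for i in template_ids):
                    uses_trigger[template_ids[int(rng.integers(len(template_ids)))]] = True

        for s in range(n_sentences):
            if not is_template[s]:
                n = int(rng.integers(4, 9))
                words = [pick(vocab) for _ in range(n)] + noisy_tail()
                sentences.append(finish_sentence(words))
                continue
            gene1 = pick(genes)
            verb = pick(triggers) if uses_trigger[s] else pick(_NEGATIVE_VERB_PHRASES)
            if uses_trigger[s]:
                gene2 = pick(genes)
                obj: str | None = gene2
            else:
                gene2 = None
                obj = pick(vocab)
            lead = [pick(vocab) for _ in range(int(rng.integers(0, 3)))]
            tail = noisy_tail()
            words = lead + gene1.split() + verb.split() + (obj.split() if obj else []) + tail
            sentences.append(finish_sentence(words))

            g1_start = len(lead)
            g1_len = len(gene1.split())
            doc_mentions.append(
                GeneMention(doc_id, s, g1_start, g1_start + g1_len, gene1)
            )
            verb_head = verb.split()[0]
            g1_unit = gene1.replace(" ", "_")
            relations = [DependencyRelation("subj", verb_head, g1_unit)]
            if gene2 is not None:
                g2_start = g1_start + g1_len + len(verb.split())
                g2_len = len(gene2.split())
                doc_mentions.append(
                    GeneMention(doc_id, s, g2_start, g2_start + g2_len, gene2)
                )
                relations.append(
                    DependencyRelation("obj", verb_head, gene2.replace(" ", "_"))
                )
            doc_parses.append(ParseRecord(doc_id, s, relations))

        # label-conditional MeSH terms plus a shared common pool
        mesh: list[str] = []
        pool = _POSITIVE_MESH if label == +1 else _NEGATIVE_MESH
        for _ in range(int(rng.integers(1, 3))):
            term = pick(pool)
            if term not in mesh:
                mesh.append(term)
        if rng.random() < 0.5:
            common = pick(_COMMON_MESH)
            if common not in mesh:
                mesh.append(common)

        title = sentences[0]
        abstract = " ".join(sentences[1:])
        documents.append(Document(doc_id, title, abstract, mesh))
        parses.extend(doc_parses)
        mentions[doc_id] = doc_mentions

    corpus = LabeledCorpus(documents, labels)
    return corpus, parses, mentions
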