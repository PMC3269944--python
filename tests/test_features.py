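"""Feature extraction: tokenization, the five families, vocabulary cut."""

import pytest

from ppitriage.corpus_io import Document, ParseRecord, DependencyRelation
from ppitriage.features import (
    FeatureConfig,
    dependency_features,
    extract_document_features,
    fit_vocabulary,
    mesh_features,
    split_sentences,
    substring_features,
    tokenize,
    tokenize_sentences,
    vectorize,
    word_ngram_features,
)
from ppitriage.gene_ner import GeneMention


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("A binds B.", ["a", "binds", "b"]),
            ("MEK-1 interacts", ["mek-1", "interacts"]),
            ("", []),
            ("p53 and IL-2R activate.", ["p53", "and", "il-2r", "activate"]),
        ],
    )
    def test_tokens(self, text, expected):
        assert tokenize(text) == expected

    def test_sentence_boundary_needs_space_and_uppercase(self):
        assert len(split_sentences("A binds B. C rises.")) == 2
        assert len(split_sentences("E. coli grows")) == 1  # no uppercase after
        assert len(split_sentences("pH 7.4 buffer")) == 1  # no space after dot


class TestWordNgrams:
    def test_uni_bi(self):
        cfg = FeatureConfig(use_trigram=False)
        feats = word_ngram_features([["a", "binds", "b"]], cfg)
        assert feats == {
            "W1|a", "W1|binds", "W1|b", "W2|a_binds", "W2|binds_b",
        }

    def test_trigram_added(self):
        cfg = FeatureConfig(use_trigram=True)
        feats = word_ngram_features([["a", "binds", "b"]], cfg)
        assert "W3|a_binds_b" in feats

    def test_ngrams_do_not_cross_sentences(self):
        cfg = FeatureConfig()
        feats = word_ngram_features([["a", "binds", "b"], ["c"]], cfg)
        assert "W2|b_c" not in feats
        assert "W1|c" in feats


class TestSubstrings:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("kinase", {"S|kinase"}),
            ("kinases", {"S|kinase", "S|inases"}),
            ("p53", {"S|p53"}),
        ],
    )
    def test_windows(self, token, expected):
        assert substring_features([token], k=6) == expected


class TestMesh:
    def test_descriptor_subphrases(self):
        assert mesh_features(["Protein Binding"]) == {
            "M1|protein", "M1|binding", "M2|protein_binding",
        }

    def test_single_word_descriptor(self):
        assert mesh_features(["Mice"]) == {"M1|mice"}

    def test_qualifier_is_separate_descriptor(self):
        feats = mesh_features(["Proteins/metabolism"])
        assert "M1|proteins" in feats and "M1|metabolism" in feats
        assert "M2|proteins_metabolism" not in feats

    def test_empty(self):
        assert mesh_features([]) == set()


def parse(rel, head, dep, doc="d", sent=0):
    return ParseRecord(doc, sent, [DependencyRelation(rel, head, dep)])


def mention(surface, doc="d", sent=0, start=0):
    n = len(surface.split())
    return GeneMention(doc, sent, start, start + n, surface)


class TestDependencyFeatures:
    def test_anonymized_and_stemmed(self):
        cfg = FeatureConfig(stem_dependency=True, anonymize_genes=True)
        feats = dependency_features(
            [parse("dobj", "binds", "MEK1")], [mention("MEK1")], cfg
        )
        assert feats == {"D|dobj(binds,MEK1)".replace("binds", "bind").replace("MEK1", "PTNWORD")}

    def test_plain_relation(self):
        cfg = FeatureConfig(stem_dependency=False, anonymize_genes=True)
        feats = dependency_features([parse("dobj", "binds", "lamp")], [], cfg)
        assert feats == {"D|dobj(binds,lamp)"}

    def test_stemming_without_anonymization(self):
        cfg = FeatureConfig(stem_dependency=True, anonymize_genes=False)
        feats = dependency_features(
            [parse("dobj", "binds", "lamp")], [mention("lamp")], cfg
        )
        assert feats == {"D|dobj(bind,lamp)"}

    def test_head_position_genes_not_anonymized(self):
        cfg = FeatureConfig(anonymize_genes=True)
        feats = dependency_features(
            [parse("subj", "MEK1", "binds")], [mention("MEK1")], cfg
        )
        assert feats == {"D|subj(mek1,binds)"}

    def test_multiword_mention_unit(self):
        cfg = FeatureConfig(anonymize_genes=True)
        feats = dependency_features(
            [parse("subj", "binds", "Tnf_alpha")], [mention("Tnf alpha")], cfg
        )
        assert feats == {"D|subj(binds,PTNWORD)"}


class TestVocabulary:
    def per_doc(self):
        return [
            {"W1|a", "W1|b"},
            {"W1|a", "W1|c"},
            {"W1|a", "W1|b"},
            {"W1|a", "W1|b", "W1|c"},
            {"W1|a", "W1|b"},
        ]

    def test_feature_cut_removes_below_threshold(self):
        vocab = fit_vocabulary(self.per_doc(), FeatureConfig(min_doc_freq=4))
        # hand-tabulated DFs: a=5, b=4, c=2
        assert set(vocab.index) == {"W1|a", "W1|b"}
        assert vocab.doc_freq == {"W1|a": 5, "W1|b": 4}

    def test_min_doc_freq_1_is_identity(self):
        vocab = fit_vocabulary(self.per_doc(), FeatureConfig(min_doc_freq=1))
        assert set(vocab.index) == {"W1|a", "W1|b", "W1|c"}

    def test_indices_contiguous_lexicographic(self):
        vocab = fit_vocabulary(self.per_doc(), FeatureConfig(min_doc_freq=1))
        assert vocab.index == {"W1|a": 1, "W1|b": 2, "W1|c": 3}

    def test_cut_monotone_in_threshold(self):
        sizes = [
            len(fit_vocabulary(self.per_doc(), FeatureConfig(min_doc_freq=k)))
            for k in (1, 2, 4, 5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_vocabulary_is_hard_error(self):
        with pytest.raises(ValueError):
            fit_vocabulary([{"W1|x"}], FeatureConfig(min_doc_freq=2))

    def test_vectorize_drops_unknown_and_dedups(self):
        vocab = fit_vocabulary(self.per_doc(), FeatureConfig(min_doc_freq=4))
        vec = vectorize({"W1|a", "W1|zzz", "W1|b"}, vocab)
        assert vec.indices == (1, 2)
        assert vectorize({"W1|zzz"}, vocab).indices == ()


class TestDocumentExtraction:
    def test_reduces_to_bag_of_words(self):
        """Unigrams only + no cut == plain bag-of-words presence."""
        cfg = FeatureConfig(
            use_bigram=False, use_substrings=False, use_mesh=False,
            use_dependency=False, anonymize_genes=False,
        )
        doc = Document("1", "A binds B.", "B binds C.", ["Mice"])
        feats = extract_document_features(doc, cfg)
        words = set(tokenize("A binds B. B binds C."))
        assert feats == {f"W1|{w}" for w in words}

    def test_anonymization_invariance(self):
        """Documents differing only in gene surfaces give identical features."""
        cfg = FeatureConfig(use_mesh=False, use_dependency=True)
        d1 = Document("1", "Kinase MEK1 binds AKT2 now.", "")
        d2 = Document("2", "Kinase RAF9 binds ERK7 now.", "")
        ms1 = [mention("MEK1", "1", 0, 1), mention("AKT2", "1", 0, 3)]
        ms2 = [mention("RAF9", "2", 0, 1), mention("ERK7", "2", 0, 3)]
        p1 = [ParseRecord("1", 0, [DependencyRelation("obj", "binds", "AKT2")])]
        p2 = [ParseRecord("2", 0, [DependencyRelation("obj", "binds", "ERK7")])]
        f1 = extract_document_features(d1, cfg, p1, ms1)
        f2 = extract_document_features(d2, cfg, p2, ms2)
        assert f1 == f2
        assert any(f.startswith("D|") for f in f1)

    def test_title_and_abstract_both_contribute(self):
        cfg = FeatureConfig(use_bigram=False, use_substrings=False,
                            use_mesh=False, use_dependency=False)
        doc = Document("1", "Alpha rises.", "Beta falls.")
        feats = extract_document_features(doc, cfg)
        assert {"W1|alpha", "W1|beta"} <= feats
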