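"""Priority Model: scoring recursion, likelihood training, tagging rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppitriage.corpus_io import Document, SyntheticSpec, synthetic_gene_lexicon
from ppitriage.gene_ner import (
    PriorityModel,
    TokenStat,
    regex_candidate_phrases,
    score_name,
    tag_document,
    train_priority_model,
)


def model_from(pq: dict[str, tuple[float, float]]) -> PriorityModel:
    return PriorityModel(stats={t: TokenStat(t, p, q) for t, (p, q) in pq.items()})


def oracle_score(model: PriorityModel, tokens) -> float:
    """Independent oracle: explicit right-priority weight expansion
    lambda_i = q'_i * prod_{j>i}(1 - q_j) with q'_1 = 1."""
    k = len(tokens)
    ps = [model.lookup(t)[0] for t in tokens]
    qs = [model.lookup(t)[1] for t in tokens]
    total = 0.0
    for i in range(k):
        weight = 1.0 if i == 0 else qs[i]
        for j in range(i + 1, k):
            weight *= 1.0 - qs[j]
        total += weight * ps[i]
    return total


class TestScoreName:
    def test_single_token_reduces_to_p(self):
        m = model_from({"kinase": (0.9, 0.1)})
        assert score_name(m, ["kinase"]) == pytest.approx(0.9)

    def test_two_token_closed_form(self):
        m = model_from({"a": (0.2, 0.5), "b": (0.9, 0.7)})
        assert score_name(m, ["a", "b"]) == pytest.approx(0.7 * 0.9 + 0.3 * 0.2)

    def test_equal_p_gives_p_for_any_q(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            qs = rng.random(4)
            m = model_from({f"t{i}": (0.37, q) for i, q in enumerate(qs)})
            assert score_name(m, [f"t{i}" for i in range(4)]) == pytest.approx(0.37)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            score_name(model_from({}), [])

    def test_unseen_token_uses_defaults(self):
        m = PriorityModel(default_p=0.5, default_q=0.5)
        assert score_name(m, ["never-seen"]) == pytest.approx(0.5)

    def test_matches_weight_expansion_oracle_up_to_length_4(self):
        rng = np.random.default_rng(1)
        alphabet = {t: (rng.random(), rng.random()) for t in "xyz"}
        m = model_from(alphabet)
        for k in range(1, 5):
            for seq in itertools.product("xyz", repeat=k):
                assert score_name(m, seq) == pytest.approx(oracle_score(m, seq))

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        for k in range(1, 7):
            qs = rng.random(k)
            m = model_from({f"t{i}": (1.0, q) for i, q in enumerate(qs)})
            # with all p = 1 the score IS the weight sum
            assert score_name(m, [f"t{i}" for i in range(k)]) == pytest.approx(1.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1),
                st.floats(min_value=0, max_value=1),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_score_bounded_by_token_ps(self, pqs):
        m = model_from({f"t{i}": pq for i, pq in enumerate(pqs)})
        tokens = [f"t{i}" for i in range(len(pqs))]
        s = score_name(m, tokens)
        ps = [pq[0] for pq in pqs]
        assert min(ps) - 1e-12 <= s <= max(ps) + 1e-12

    def test_monotone_in_token_p(self):
        base = {"a": (0.3, 0.4), "b": (0.6, 0.7)}
        lo = score_name(model_from(base), ["a", "b"])
        base["a"] = (0.5, 0.4)
        hi = score_name(model_from(base), ["a", "b"])
        assert hi > lo


class TestTraining:
    def test_single_token_classes_separate(self):
        m = train_priority_model([["kinase"]] * 5, [["table"]] * 5)
        assert m.stats["kinase"].p > 0.9
        assert m.stats["table"].p < 0.1

    def test_symmetric_content_gives_half(self):
        names = [["shared", "token"]] * 4
        m = train_priority_model(names, names)
        assert score_name(m, ["shared", "token"]) == pytest.approx(0.5, abs=0.05)

    def test_parameters_stay_in_open_unit_interval(self):
        m = train_priority_model([["only-pos"]] * 3, [["only-neg"]] * 3)
        for st_ in m.stats.values():
            assert 0.0 < st_.p < 1.0
            assert 0.0 < st_.q < 1.0

    def test_synthetic_lexicon_recovery_auc(self):
        spec = SyntheticSpec(seed=1)
        lexicon = synthetic_gene_lexicon(spec)
        common = (
            "the of protein cell expression analysis binding mouse tissue "
            "sample result method table figure study level gene assay control"
        ).split()
        pos = [n.split() for n in lexicon[:25]]
        neg = [[w] for w in common] + [["gene", "expression"], ["the", "cell"]]
        model = train_priority_model(pos, neg)
        # held-out: remaining lexicon names vs. held-out common bigrams
        held_pos = [n.split() for n in lexicon[25:]]
        held_neg = [["protein", "level"], ["control", "sample"], ["assay"], ["study"]]
        pos_scores = [score_name(model, n) for n in held_pos]
        neg_scores = [score_name(model, n) for n in held_neg]
        pairs = [(p > n) + 0.5 * (p == n) for p in pos_scores for n in neg_scores]
        auc = sum(pairs) / len(pairs)
        assert auc > 0.95

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            train_priority_model([], [["x"]])


class TestTagging:
    def doc(self, title):
        return Document("d1", title, "")

    def strong_model(self, tokens):
        return PriorityModel(
            stats={t: TokenStat(t, 1.0, 0.9) for t in tokens}, default_p=0.0
        )

    def test_all_numeric_candidate_rejected(self):
        m = self.strong_model(["1234"])
        doc = self.doc("Value 1234 rises.")
        assert tag_document(m, doc, [(0, 1, 2)]) == []

    def test_high_scoring_candidate_accepted(self):
        m = self.strong_model(["MEK1"])
        doc = self.doc("Kinase MEK1 binds.")
        (mention,) = tag_document(m, doc, [(0, 1, 2)])
        assert mention.surface == "MEK1"
        assert (mention.start, mention.end) == (1, 2)

    def test_leftmost_longest_overlap_resolution(self):
        m = self.strong_model(["A1", "B2", "C3"])
        doc = self.doc("A1 B2 C3 rise.")
        mentions = tag_document(m, doc, [(0, 0, 2), (0, 1, 3)])
        assert [(mn.start, mn.end) for mn in mentions] == [(0, 2)]

    def test_empty_candidates(self):
        m = self.strong_model(["X1"])
        assert tag_document(m, self.doc("X1 binds."), []) == []

    def test_regex_chunker_finds_gene_like_runs(self):
        sentences = [["The", "protein", "MEK-1", "alpha", "binds", "p53", "today"]]
        spans = regex_candidate_phrases(sentences)
        surfaces = [" ".join(sentences[s][a:b]) for s, a, b in spans]
        assert "MEK-1 alpha" in surfaces
        assert "p53" in surfaces
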