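"""Gene/protein name detection with a Priority Model.

The Priority Model is a statistical language model for named-entity
classification built on the observation that, in English entity names,
tokens further to the right tend to determine the nature of the entity
("receptor" in "epidermal growth factor receptor").  Each token ``t`` has
two probabilities:

* ``p`` — the probability that seeing ``t`` in a name indicates the
  gene/protein class;
* ``q`` — the probability that ``t`` is a more reliable indicator of the
  name's class than any token to its left.

For a name ``t_1 ... t_k`` the class probability is the right-priority
mixture

    score = sum_i  lambda_i * p_i,
    lambda_i = q'_i * prod_{j>i} (1 - q_j),   q'_1 = 1,

i.e. the rightmost token decides with probability ``q_k``, otherwise the
decision recurses on the prefix.  Fixing the leftmost reliability to one
makes the weights a convex combination, so the score always lies between
the smallest and largest ``p`` in the name.

Training maximizes the Bernoulli log-likelihood of gene / non-gene name
lists over the token parameters in logit space with L-BFGS.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.optimize import minimize

from .corpus_io import Document

__all__ = [
    "TokenStat",
    "PriorityModel",
    "GeneMention",
    "score_name",
    "train_priority_model",
    "tag_document",
    "regex_candidate_phrases",
]

_EPS = 1e-6


@dataclass
class TokenStat:
    """Per-token class probability ``p`` and reliability ``q``."""

    token: str
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError(f"p and q must lie in [0,1]: {self}")


@dataclass
class PriorityModel:
    """Token statistics plus defaults for unseen tokens and a decision cutoff."""

    stats: dict[str, TokenStat] = field(default_factory=dict)
    default_p: float = 0.5
    default_q: float = 0.5
    decision_threshold: float = 0.5

    def lookup(self, token: str) -> tuple[float, float]:
        st = self.stats.get(token)
        if st is None:
            st = self.stats.get(token.lower())
        if st is None:
            return self.default_p, self.default_q
        return st.p, st.q

    def save(self, stream: TextIO) -> None:
        stream.write(
            f"#default_p={self.default_p}\tdefault_q={self.default_q}"
            f"\tthreshold={self.decision_threshold}\n"
        )
        for token in sorted(self.stats):
            st = self.stats[token]
            stream.write(f"{token}\t{st.p:.10g}\t{st.q:.10g}\n")

    @classmethod
    def load(cls, stream: TextIO) -> "PriorityModel":
        header = stream.readline().strip()
        if not header.startswith("#"):
            raise ValueError("priority model file lacks a header line")
        kv = dict(part.split("=") for part in header[1:].split("\t"))
        model = cls(
            default_p=float(kv["default_p"]),
            default_q=float(kv["default_q"]),
            decision_threshold=float(kv["threshold"]),
        )
        for line in stream:
            if not line.strip():
                continue
            token, p, q = line.rstrip("\n").split("\t")
            model.stats[token] = TokenStat(token, float(p), float(q))
        return model


@dataclass
class GeneMention:
    """A detected gene name: token span (half-open) within one sentence."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("mention span must be non-empty")


def score_name(model: PriorityModel, tokens: Sequence[str]) -> float:
    """Probability that a token sequence is a gene/protein name.

    Evaluated by the forward recursion ``s_1 = p_1``,
    ``s_i = q_i p_i + (1 - q_i) s_{i-1}``, which expands to the
    right-priority weights described in the module docstring.
    """
    if len(tokens) == 0:
        raise ValueError("cannot score an empty token sequence")
    p, _ = model.lookup(tokens[0])
    score = p
    for tok in tokens[1:]:
        p, q = model.lookup(tok)
        score = q * p + (1.0 - q) * score
    return score


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_priority_model(
    positive_names: Iterable[Sequence[str]],
    negative_names: Iterable[Sequence[str]],
    max_iter: int = 200,
    decision_threshold: float = 0.5,
) -> PriorityModel:
    """Fit per-token ``(p, q)`` by maximum likelihood on labeled name lists.

    Parameters are optimized in logit space (all logits initialized to 0,
    i.e. p = q = 0.5) with L-BFGS-B and an analytic gradient obtained by
    back-propagating through the scoring recursion.  Fitted probabilities
    are clipped to ``[1e-6, 1 - 1e-6]`` so tokens seen in only one class
    cannot drive the likelihood to a degenerate optimum.
    """
    pos = [list(n) for n in positive_names]
    neg = [list(n) for n in negative_names]
    if not pos or not neg:
        raise ValueError("both name lists must be non-empty")

    vocab: dict[str, int] = {}
    for name in pos + neg:
        if not name:
            raise ValueError("names must contain at least one token")
        for tok in name:
            vocab.setdefault(tok, len(vocab))
    V = len(vocab)
    names = [(np.array([vocab[t] for t in n], dtype=np.intp), 1.0) for n in pos]
    names += [(np.array([vocab[t] for t in n], dtype=np.intp), 0.0) for n in neg]

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        p = _sigmoid(params[:V])
        q = _sigmoid(params[V:])
        grad_p = np.zeros(V)
        grad_q = np.zeros(V)
        nll = 0.0
        for idx, y in names:
            k = len(idx)
            # forward recursion, keeping prefix scores
            s = np.empty(k)
            s[0] = p[idx[0]]
            for i in range(1, k):
                qi = q[idx[i]]
                s[i] = qi * p[idx[i]] + (1.0 - qi) * s[i - 1]
            sk = min(max(s[-1], _EPS), 1.0 - _EPS)
            nll -= y * math.log(sk) + (1.0 - y) * math.log(1.0 - sk)
            # d(nll)/d(score)
            ds = -(y / sk) + (1.0 - y) / (1.0 - sk)
            # backward: c = d s_k / d s_i
            c = 1.0
            for i in range(k - 1, 0, -1):
                qi = q[idx[i]]
                grad_p[idx[i]] += ds * c * qi
                grad_q[idx[i]] += ds * c * (p[idx[i]] - s[i - 1])
                c *= 1.0 - qi
            grad_p[idx[0]] += ds * c
        # chain rule through the logits
        g = np.concatenate([grad_p * p * (1.0 - p), grad_q * q * (1.0 - q)])
        return nll, g

    x0 = np.zeros(2 * V)
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    p_hat = np.clip(_sigmoid(res.x[:V]), _EPS, 1.0 - _EPS)
    q_hat = np.clip(_sigmoid(res.x[V:]), _EPS, 1.0 - _EPS)
    stats = {
        tok: TokenStat(tok, float(p_hat[i]), float(q_hat[i]))
        for tok, i in vocab.items()
    }
    return PriorityModel(stats=stats, decision_threshold=decision_threshold)


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

_ALL_NUMERIC_RE = re.compile(r"^[0-9]+$")


def _is_all_numeric(tokens: Sequence[str]) -> bool:
    return all(_ALL_NUMERIC_RE.match(t) for t in tokens)


_CANDIDATE_TOKEN_RE = re.compile(r"[A-Z]|[0-9]")
_STOP_TOKENS = {"the", "a", "an", "and", "or", "of", "in", "to", "with"}


def regex_candidate_phrases(
    sentences: Sequence[Sequence[str]],
) -> list[tuple[int, int, int]]:
    """Fallback candidate chunker: maximal runs of capitalized or
    digit-bearing tokens (plus greek-letter suffix words).

    Returns ``(sentence_index, start, end)`` spans.  Real deployments
    should plug in a noun-phrase chunker; tests usually pass explicit
    candidate spans instead.
    """
    greek = {"alpha", "beta", "gamma", "delta", "kappa"}

    def qualifies(tok: str) -> bool:
        if tok.lower() in _STOP_TOKENS:
            return False
        return bool(_CANDIDATE_TOKEN_RE.search(tok)) or tok.lower() in greek

    spans: list[tuple[int, int, int]] = []
    for s, tokens in enumerate(sentences):
        start = None
        for i, tok in enumerate(tokens):
            if qualifies(tok):
                if start is None:
                    start = i
            else:
                if start is not None:
                    spans.append((s, start, i))
                    start = None
        if start is not None:
            spans.append((s, start, len(tokens)))
    return spans


def tag_document(
    model: PriorityModel,
    document: Document,
    candidate_phrases: Sequence[tuple[int, int, int]],
) -> list[GeneMention]:
    """Score candidate phrases and return accepted gene mentions.

    A candidate becomes a mention iff its Priority-Model score exceeds the
    decision threshold and its surface string is not all-numeric (an
    all-digit string is never a gene name).  Overlapping accepted spans in
    one sentence are resolved leftmost-longest.  Multi-word mentions are
    single units for downstream parsing/anonymization.
    """
    from .features import tokenize_sentences

    sentences = tokenize_sentences(
        document.title + " " + document.abstract if document.abstract else document.title,
        lowercase=False,
    )
    accepted: list[GeneMention] = []
    for s, start, end in candidate_phrases:
        if s >= len(sentences):
            continue
        tokens = sentences[s][start:end]
        if not tokens or _is_all_numeric(tokens):
            continue
        if score_name(model, tokens) > model.decision_threshold:
            accepted.append(
                GeneMention(document.doc_id, s, start, end, " ".join(tokens))
            )

    # leftmost-longest overlap resolution within each sentence
    accepted.sort(key=lambda m: (m.sentence_index, m.start, -(m.end - m.start)))
    result: list[GeneMention] = []
    last_end: dict[int, int] = {}
    for m in accepted:
        if m.start >= last_end.get(m.sentence_index, 0):
            result.append(m)
            last_end[m.sentence_index] = m.end
    return result
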