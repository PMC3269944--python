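"""The original Porter stemming algorithm (1980).

Implements the five-step suffix-stripping procedure exactly as published,
with no later extensions or revisions.  Stemming is applied only to words
inside dependency-relation features; the gene anonymization tag is never
stemmed.

Notation used in the rule conditions:

* ``m``  — the measure of a stem: the number of vowel-consonant sequences
  ``[C](VC)^m[V]``.
* ``*v*`` — the stem contains a vowel.
* ``*d`` — the stem ends with a double consonant.
* ``*o`` — the stem ends consonant-vowel-consonant where the final
  consonant is not ``w``, ``x`` or ``y``.

``y`` counts as a vowel when preceded by a consonant.
"""

from __future__ import annotations

__all__ = ["porter_stem"]


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in "aeiou":
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(stem: str) -> bool:
    return (
        len(stem) >= 2
        and stem[-1] == stem[-2]
        and _is_consonant(stem, len(stem) - 1)
    )


def _ends_cvc(stem: str) -> bool:
    if len(stem) < 3:
        return False
    if not (
        _is_consonant(stem, len(stem) - 3)
        and not _is_consonant(stem, len(stem) - 2)
        and _is_consonant(stem, len(stem) - 1)
    ):
        return False
    return stem[-1] not in "wxy"


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        stem = w[:-3]
        return w[:-1] if _measure(stem) > 0 else w
    removed = None
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        removed = w[:-2]
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        removed = w[:-3]
    if removed is None:
        return w
    if removed.endswith(("at", "bl", "iz")):
        return removed + "e"
    if _ends_double_consonant(removed) and removed[-1] not in "lsz":
        return removed[:-1]
    if _measure(removed) == 1 and _ends_cvc(removed):
        return removed + "e"
    return removed


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _apply_rules(w: str, rules: list[tuple[str, str]], min_measure: int) -> str:
    for suffix, replacement in rules:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > min_measure:
                return stem + replacement
            return w
    return w


def _step4(w: str) -> str:
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if suffix == "ion" and not stem.endswith(("s", "t")):
                return w
            if _measure(stem) > 1:
                return stem
            return w
    return w


def _step5a(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return w


def _step5b(w: str) -> str:
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        return w[:-1]
    return w


def porter_stem(word: str) -> str:
    """Stem a lowercase word with the original Porter algorithm.

    Words of length <= 2 are returned unchanged, as in the published
    procedure.
    """
    if len(word) <= 2:
        return word
    w = word
    w = _step1a(w)
    w = _step1b(w)
    w = _step1c(w)
    w = _apply_rules(w, _STEP2, 0)
    w = _apply_rules(w, _STEP3, 0)
    w = _step4(w)
    w = _step5a(w)
    w = _step5b(w)
    return w
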