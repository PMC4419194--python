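"""A lightweight rule-based part-of-speech tagger (Penn Treebank tagset).

Informal forum prose is short and lexically repetitive, and the downstream
features need only a handful of tag distinctions (proper nouns, adjectives,
cardinal numbers, verbs after "please").  The tagger therefore combines a
closed-class lexicon, a small open-class word list, and suffix heuristics.
It is deterministic and dependency-free; it is not a general-purpose tagger.
"""

from __future__ import annotations

from . import lexicons as lx

_PRONOUNS = frozenset("i you he she it we they me him her us them myself yourself".split())
_POSSESSIVES = frozenset("my your his its our their mine yours ours theirs".split())
_DETERMINERS = frozenset("the a an this that these those some no every each all".split())
_PREPOSITIONS = frozenset(
    """of in on at by for with from to about over under after before during
    into through between against""".split()
)
_CONJUNCTIONS = frozenset("and or but nor so yet".split())
_NUMBER_WORDS = frozenset(
    "one two three four five six seven eight nine ten hundred thousand".split()
)
_WH_WORDS = frozenset("who what when where why how which whose whom".split())

#: base-form verbs the featurizer and generator care about
_VERBS = frozenset(
    """tell give take go get come make ask call check help agree explain
    rest share post read write say see find start stop keep let bring
    suggest recommend advise try consider wish love hate know believe feel
    want need hope remember understand miss think wonder pray thank""".split()
)

_ADJECTIVES = lx.POSITIVE_ADJECTIVES | lx.NEGATIVE_ADJECTIVES | frozenset(
    "new old big small long short easy hard early late".split()
)

_ADJ_SUFFIXES = ("ful", "ous", "less", "able", "ible", "ish")

_BE_TAGS = {
    "am": "VBP", "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "be": "VB", "been": "VBN", "being": "VBG",
}
_AUX_TAGS = {"do": "VBP", "does": "VBZ", "did": "VBD", "have": "VBP",
             "has": "VBZ", "had": "VBD"}


def _is_number(tok: str) -> bool:
    t = tok.replace(",", "").replace(".", "")
    return t.isdigit() or tok in _NUMBER_WORDS


def tag_token(surface: str, sentence_initial: bool = False) -> str:
    """Return the Penn Treebank tag for a single token."""
    low = surface.lower()
    if _is_number(low):
        return "CD"
    if low in _BE_TAGS:
        return _BE_TAGS[low]
    if low in _AUX_TAGS:
        return _AUX_TAGS[low]
    if low in lx.MODAL_VERBS:
        return "MD"
    if low in _PRONOUNS:
        return "PRP"
    if low in _POSSESSIVES:
        return "PRP$"
    if low in _DETERMINERS or low in lx.INDEFINITE_PRONOUNS:
        return "DT"
    if low in _PREPOSITIONS:
        return "IN"
    if low in _CONJUNCTIONS:
        return "CC"
    if low in _WH_WORDS:
        return "WP"
    if low == "not" or low.endswith("n't"):
        return "RB"
    # proper noun: capitalized surface form away from the sentence start,
    # or a capitalized word the lexicon does not know
    if surface[:1].isupper() and (not sentence_initial or low not in _known_words()):
        return "NNP"
    if low in _ADJECTIVES:
        return "JJ"
    if low in _VERBS:
        return "VB"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("ing"):
        return "VBG"
    if low.endswith("ed"):
        return "VBD"
    if any(low.endswith(s) for s in _ADJ_SUFFIXES):
        return "JJ"
    if low.endswith("s") and not low.endswith("ss"):
        return "NNS"
    return "NN"


_KNOWN: frozenset | None = None


def _known_words() -> frozenset:
    global _KNOWN
    if _KNOWN is None:
        _KNOWN = frozenset(
            set(_PRONOUNS) | set(_POSSESSIVES) | set(_DETERMINERS)
            | set(_PREPOSITIONS) | set(_CONJUNCTIONS) | set(_WH_WORDS)
            | set(_VERBS) | set(_ADJECTIVES) | set(_BE_TAGS) | set(_AUX_TAGS)
            | set(lx.MODAL_VERBS) | set(lx.INDEFINITE_PRONOUNS)
            | set(lx.NEGATION) | set(lx.STATIVE_VERBS) | set(lx.ADVICE_VERBS)
        )
    return _KNOWN


def tag(tokens: list[str]) -> list[str]:
    """Tag a tokenized sentence; returns one tag per token."""
    return [tag_token(tok, sentence_initial=(i == 0)) for i, tok in enumerate(tokens)]


def tag_pairs(tokens: list[str]) -> list[tuple[str, str]]:
    return [(tok, tag_token(tok, sentence_initial=(i == 0))) for i, tok in enumerate(tokens)]
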