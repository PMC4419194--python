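"""Built-in lexicon pack and fixture category dictionaries.

The syntactic/sentiment features need small closed word lists (negation
words, advice verbs, subjectivity cues, ...).  The proprietary
psycholinguistic dictionaries used in production analyses cannot be
shipped, so this module provides openly licensed stand-in lists: they are
small, explicitly non-canonical, and intended for testing and for the
synthetic community generator.  Real deployments pass their own dictionary
files instead.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

from .exceptions import ConfigError

# --- closed-class word lists used by the feature extractors -----------------

NEGATION = frozenset(
    """not no never nothing none cannot can't don't didn't doesn't won't
    wouldn't couldn't shouldn't isn't aren't wasn't weren't without""".split()
)

ADVICE_VERBS = frozenset("suggest recommend advise tell try consider wish make".split())

STATIVE_VERBS = frozenset(
    "love hate know believe feel want need hope remember understand miss".split()
)

BE_VERBS = frozenset("am is are was were be been being".split())

AUXILIARY_VERBS = frozenset("do does did have has had".split()) | BE_VERBS

MODAL_VERBS = frozenset("can could may might must shall should will would".split())

INDEFINITE_PRONOUNS = frozenset(
    """any anyone anybody anything someone somebody something everyone
    everybody everything""".split()
)

POSITIVE_ADJECTIVES = frozenset(
    """happy glad grateful lucky hopeful strong good great fine better
    wonderful blessed""".split()
)

NEGATIVE_ADJECTIVES = frozenset(
    """sad scared afraid worried anxious terrified depressed angry tired
    upset frightened awful""".split()
)

STRONG_SUBJECTIVITY = frozenset(
    """terrified devastated reject nervous awful horrible amazing furious
    hate love scared desperate""".split()
)

WEAK_SUBJECTIVITY = frozenset(
    "idea suggest maybe perhaps possibly seem somewhat guess probably likely".split()
)

DRUGS = frozenset(
    """tamoxifen herceptin arimidex taxol cytoxan adriamycin femara
    zoladex lorazepam ibuprofen""".split()
)

INDIRECT_QUESTION_PATTERNS = (
    "i am wondering if",
    "i am wondering whether",
    "i wonder",
    "wondering if",
    "looking for any",
)


@dataclass(frozen=True)
class LexiconPack:
    """The word lists required by the syntactic feature extractor."""

    negation: frozenset = NEGATION
    advice_verbs: frozenset = ADVICE_VERBS
    stative_verbs: frozenset = STATIVE_VERBS
    positive_adjectives: frozenset = POSITIVE_ADJECTIVES
    negative_adjectives: frozenset = NEGATIVE_ADJECTIVES
    strong_subjectivity: frozenset = STRONG_SUBJECTIVITY
    weak_subjectivity: frozenset = WEAK_SUBJECTIVITY
    drugs: frozenset = DRUGS
    indefinite_pronouns: frozenset = INDEFINITE_PRONOUNS
    modal_verbs: frozenset = MODAL_VERBS
    indirect_question_patterns: Sequence[str] = INDIRECT_QUESTION_PATTERNS

    @classmethod
    def from_dict(cls, mapping: dict) -> "LexiconPack":
        missing = [f.name for f in fields(cls) if f.name not in mapping]
        if missing:
            raise ConfigError(f"missing required lexicon(s): {', '.join(missing)}")
        kwargs = {
            name: (tuple(mapping[name]) if name == "indirect_question_patterns"
                   else frozenset(w.lower() for w in mapping[name]))
            for name in (f.name for f in fields(cls))
        }
        return cls(**kwargs)


def default_lexicons() -> LexiconPack:
    return LexiconPack()


# --- fixture category dictionaries ------------------------------------------
#
# Disjoint content-word pools, one per measured construct.  The synthetic
# generator samples message bodies from these pools at rates tied to the
# latent construct intensities, so a dictionary-count feature built from the
# matching pool is an informative (but noisy) measure of the construct.

CONSTRUCT_POOLS: dict[str, tuple[str, ...]] = {
    "pos_emo_disclosure": (
        "joyful", "relieved", "thankful", "cheerful", "delighted", "uplifted",
        "overjoyed", "content", "serene", "elated", "comforted", "peaceful",
    ),
    "neg_emo_disclosure": (
        "miserable", "heartbroken", "hopeless", "dreading", "panicked",
        "tearful", "distraught", "despairing", "overwhelmed", "shaken",
        "fearful", "gloomy",
    ),
    "pos_info_disclosure": (
        "vacation", "celebration", "wedding", "graduation", "promotion",
        "anniversary", "picnic", "holiday", "remission", "milestone",
        "festival", "reunion",
    ),
    "neg_info_disclosure": (
        "lump", "biopsy", "tumor", "swelling", "recurrence", "metastasis",
        "mammogram", "pathology", "diagnosis", "relapse", "infection",
        "lesion",
    ),
    "question_asking": (
        "dosage", "timeline", "prognosis", "options", "experiences",
        "opinions", "recommendations", "insight", "guidance", "pointers",
        "clarification", "specifics",
    ),
    "elicit_emotional": (
        "reassurance", "venting", "listening", "empathy", "solace",
        "consolation",
    ),
    "elicit_informational": (
        "answers", "facts", "details", "information", "explanation",
        "sources",
    ),
    "provide_emotional": (
        "hugs", "prayers", "courage", "comfort", "sympathy", "encouragement",
        "caring", "warmth", "blessings", "strength", "compassion", "kindness",
    ),
    "provide_informational": (
        "oncologist", "protocol", "reference", "guideline", "pubmed",
        "dosing", "studies", "citation", "referral", "specialist", "clinic",
        "resource",
    ),
}

#: generic LIWC-style stand-in categories (literal words and stem wildcards)
GENERIC_DICTIONARIES: dict[str, tuple[str, ...]] = {
    "pronoun_i": ("i", "me", "my", "mine", "myself"),
    "pronoun_we": ("we", "us", "our", "ours", "ourselves"),
    "pronoun_you": ("you", "your", "yours", "yourself"),
    "posemo": ("love", "nice", "sweet", "happi*", "hope*"),
    "negemo": ("hurt", "nasty", "sad*", "cry*", "grief"),
    "anx": ("worri*", "nervous*", "afraid", "panic*"),
    "religion": ("pray*", "god", "bless*", "faith", "church"),
    "body_terms": ("arm", "breast", "skin", "bone", "chest"),
    "time_terms": ("today", "tomorrow", "yesterday", "week", "month", "year"),
}

#: filler vocabulary guaranteed to match no dictionary, lexicon, or pattern
FILLER_WORDS: tuple[str, ...] = (
    "the", "and", "then", "with", "from", "about", "over", "under", "after",
    "before", "during", "into", "again", "also", "still", "quite", "rather",
    "just", "really", "went", "came", "looked", "turned", "stayed", "walked",
    "morning", "evening", "afternoon", "kitchen", "window", "street", "house",
    "road", "coffee", "tea", "letter", "table", "chair", "garden",
)
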