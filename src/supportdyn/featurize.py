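"""Language features for support-exchange messages.

Three feature families feed the construct-measurement models:

1. *Category-dictionary counts* — how many tokens of a message match a
   word list (literal words plus trailing-``*`` stem wildcards), one count
   per loaded dictionary;
2. *Topic-dictionary counts* — the same mechanism over dictionaries built
   from the top words of an LDA topic model trained on the corpus itself;
3. *Syntactic, pattern and sentiment features* — sentence counts, negation,
   part-of-speech counts, advice/question patterns (``<Please+VERB>``,
   ``<If+you>``, ``<You+MODAL>``, verb-subject inversion, indirect
   questions), state features (be/stative verbs, sentences opening with
   "I"), subjectivity and drug-term counts, plus an optional binary
   story-telling flag produced by a trained classifier.

All matching is lowercase; counts are raw token/sentence counts so that the
features of a concatenation are the sums of the features of the parts.  A
per-100-words normalized view is available via ``normalize="per100"``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import tagger
from .exceptions import ConfigError, SchemaError, ValidationError
from .lexicons import AUXILIARY_VERBS, BE_VERBS, LexiconPack, default_lexicons

TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)?", re.UNICODE)

#: syntactic/pattern feature names, in output order
SYNTACTIC_FEATURES = (
    "sentence_count", "words_per_sentence", "negation", "proper_nouns",
    "adjectives", "cardinal_numbers", "advice_verbs", "please_verb",
    "if_you", "you_modal", "question_marks", "any_pronouns", "verb_subject",
    "indirect_questions", "be_verbs", "stative_verbs", "subject_i",
    "subject_i_pos_adj", "subject_i_neg_adj", "strong_subjectivity",
    "weak_subjectivity", "drug_terms",
)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens (unicode word chars, internal apostrophes kept)."""
    return TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class CategoryDictionary:
    """A named word list of literal entries and trailing-``*`` stems."""

    name: str
    entries: tuple[str, ...]
    literals: frozenset = field(init=False)
    stems: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"dictionary {self.name!r} is empty")
        seen, literals, stems = [], set(), []
        for raw in self.entries:
            e = raw.lower()
            if not e or any(c.isspace() for c in e):
                raise ValidationError(f"dictionary {self.name!r}: bad entry {raw!r}")
            if "*" in e[:-1]:
                raise ValidationError(
                    f"dictionary {self.name!r}: '*' only allowed in final position ({raw!r})"
                )
            if e in seen:
                continue
            seen.append(e)
            if e.endswith("*"):
                stems.append(e[:-1])
            else:
                literals.add(e)
        object.__setattr__(self, "entries", tuple(seen))
        object.__setattr__(self, "literals", frozenset(literals))
        object.__setattr__(self, "stems", tuple(sorted(stems)))

    def matches(self, token: str) -> bool:
        return token in self.literals or any(token.startswith(s) for s in self.stems)


def load_dictionary(path: str | Path) -> CategoryDictionary:
    """Load a single-category dictionary file (two-column TSV or ``.dic``)."""
    dicts = load_dictionary_file(path)
    if len(dicts) != 1:
        raise SchemaError(
            f"{path}: expected one category, found {len(dicts)}; use load_dictionary_file"
        )
    return dicts[0]


def load_dictionary_file(path: str | Path) -> list[CategoryDictionary]:
    """Load all categories from a TSV (category<TAB>entry) or ``%``-header ``.dic`` file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    entries: dict[str, list[str]] = {}
    if lines and lines[0] == "%":
        # .dic convention: %, id<TAB>name lines, %, then word<TAB>id... lines
        try:
            close = lines.index("%", 1)
        except ValueError as exc:
            raise SchemaError(f"{path}: unterminated .dic header") from exc
        id2name = {}
        for ln in lines[1:close]:
            cat_id, name = ln.split("\t")[:2]
            id2name[cat_id] = name
        for ln in lines[close + 1:]:
            parts = ln.split("\t")
            word, ids = parts[0], parts[1:]
            for cat_id in ids:
                if cat_id not in id2name:
                    raise SchemaError(f"{path}: unknown category id {cat_id!r}")
                entries.setdefault(id2name[cat_id], []).append(word)
    else:
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{path}: expected 2 tab-separated columns, got {ln!r}")
            entries.setdefault(parts[0], []).append(parts[1])
    if not entries:
        raise ValidationError(f"{path}: empty dictionary file")
    return [CategoryDictionary(name=k, entries=tuple(v)) for k, v in entries.items()]


def load_dictionary_pack(directory: str | Path) -> list[CategoryDictionary]:
    """Load every ``*.tsv``/``*.dic`` dictionary file in a directory (sorted)."""
    directory = Path(directory)
    out: list[CategoryDictionary] = []
    for p in sorted(directory.glob("*")):
        if p.suffix.lower() in (".tsv", ".dic", ".txt"):
            out.extend(load_dictionary_file(p))
    if not out:
        raise ValidationError(f"no dictionary files found in {directory}")
    return out


def count_matches(tokens: Sequence[str], dictionary: CategoryDictionary) -> int:
    """Number of tokens matching the dictionary (each token counts once)."""
    return sum(1 for tok in tokens if dictionary.matches(tok))


# --- sentence segmentation and tagging --------------------------------------

_ABBREVIATIONS = ("dr.", "mr.", "mrs.", "e.g.", "i.e.", "etc.")
_SENTENCE_RE = re.compile(r"[^.!?]*[.!?]+|[^.!?]+")
_PLACEHOLDER = "\x00"


@dataclass(frozen=True)
class TaggedSentence:
    """Tokens of one sentence with Penn Treebank tags and the terminator."""

    tokens: tuple[tuple[str, str], ...]
    terminator: str  # one of '.', '!', '?', 'none'

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t[0].lower() for t in self.tokens)


def segment_and_tag(body: str) -> list[TaggedSentence]:
    """Split a message into sentences on ``.!?`` (with an abbreviation guard)
    and POS-tag the tokens of each sentence."""
    if not body or not body.strip():
        return []
    protected = body
    for abbr in _ABBREVIATIONS:
        pattern = re.compile(re.escape(abbr), re.IGNORECASE)
        protected = pattern.sub(lambda m: m.group(0).replace(".", _PLACEHOLDER), protected)
    sentences: list[TaggedSentence] = []
    for chunk in _SENTENCE_RE.findall(protected):
        run = re.search(r"[.!?]+\s*$", chunk)
        if run:
            punct = run.group(0).strip()
            terminator = "?" if "?" in punct else ("!" if "!" in punct else ".")
            text = chunk[: run.start()]
        else:
            terminator = "none"
            text = chunk
        text = text.replace(_PLACEHOLDER, ".")
        surfaces = TOKEN_RE.findall(text)
        if not surfaces:
            continue
        tags = tagger.tag(surfaces)
        sentences.append(
            TaggedSentence(tokens=tuple(zip(surfaces, tags)), terminator=terminator)
        )
    return sentences


# --- syntactic / pattern / sentiment features --------------------------------

def syntactic_features(
    sentences: Sequence[TaggedSentence], lexicons: Optional[LexiconPack] = None
) -> dict[str, float]:
    """Sentence-level pattern counts and token-level lexicon counts."""
    lex = lexicons or default_lexicons()
    f = {name: 0.0 for name in SYNTACTIC_FEATURES}
    f["sentence_count"] = float(len(sentences))
    n_tokens = 0
    for sent in sentences:
        toks = sent.surfaces
        tags = tuple(t[1] for t in sent.tokens)
        n_tokens += len(toks)
        tokset = set(toks)
        if tokset & lex.negation:
            f["negation"] += 1
        f["proper_nouns"] += sum(t in ("NNP", "NNPS") for t in tags)
        f["adjectives"] += sum(t in ("JJ", "JJR", "JJS") for t in tags)
        f["cardinal_numbers"] += sum(t == "CD" for t in tags)
        f["advice_verbs"] += sum(t in lex.advice_verbs for t in toks)
        if toks[0] == "please" and len(toks) > 1 and tags[1].startswith("VB"):
            f["please_verb"] += 1
        if toks[0] == "if" and len(toks) > 1 and toks[1] == "you":
            f["if_you"] += 1
        if toks[0] == "you" and len(toks) > 1 and toks[1] in lex.modal_verbs:
            f["you_modal"] += 1
        if sent.terminator == "?":
            f["question_marks"] += 1
        f["any_pronouns"] += sum(t in lex.indefinite_pronouns for t in toks)
        if toks[0] in lex.modal_verbs or toks[0] in AUXILIARY_VERBS:
            f["verb_subject"] += 1
        joined = " ".join(toks)
        if any(pat in joined for pat in lex.indirect_question_patterns):
            f["indirect_questions"] += 1
        f["be_verbs"] += sum(t in BE_VERBS for t in toks)
        f["stative_verbs"] += sum(t in lex.stative_verbs for t in toks)
        if toks[0] == "i":
            f["subject_i"] += 1
            if tokset & lex.positive_adjectives:
                f["subject_i_pos_adj"] += 1
            if tokset & lex.negative_adjectives:
                f["subject_i_neg_adj"] += 1
        f["strong_subjectivity"] += sum(t in lex.strong_subjectivity for t in toks)
        f["weak_subjectivity"] += sum(t in lex.weak_subjectivity for t in toks)
        f["drug_terms"] += sum(t in lex.drugs for t in toks)
    f["words_per_sentence"] = n_tokens / len(sentences) if sentences else 0.0
    return f


def extract_features(
    body: str,
    dictionaries: Sequence[CategoryDictionary],
    lexicons: Optional[LexiconPack] = None,
    story_model=None,
    normalize: Optional[str] = None,
) -> dict[str, float]:
    """Full feature vector for one message body.

    Dictionary counts are emitted as ``dict_<name>``; ``is_story`` is 0 when
    no story model is supplied.  With ``normalize="per100"`` the pure count
    features are rescaled to counts per 100 words.
    """
    sentences = segment_and_tag(body)
    tokens = [tok for s in sentences for tok in s.surfaces]
    feats: dict[str, float] = {}
    for d in dictionaries:
        feats[f"dict_{d.name}"] = float(count_matches(tokens, d))
    feats.update(syntactic_features(sentences, lexicons))
    if story_model is not None:
        from .models import score_story

        row = pd.DataFrame([{k: v for k, v in feats.items()}])
        feats["is_story"] = float(score_story(story_model, row)[0])
    else:
        feats["is_story"] = 0.0
    if normalize == "per100":
        n_words = max(len(tokens), 1)
        skip = {"sentence_count", "words_per_sentence", "is_story"}
        feats = {
            k: (v * 100.0 / n_words if k not in skip else v) for k, v in feats.items()
        }
    elif normalize is not None:
        raise ConfigError(f"unknown normalization {normalize!r}")
    return feats


def featurize_corpus(
    messages: Iterable,
    dictionaries: Sequence[CategoryDictionary],
    lexicons: Optional[LexiconPack] = None,
    story_model=None,
    normalize: Optional[str] = None,
) -> pd.DataFrame:
    """Feature matrix (rows = message_id) for a sequence of Messages."""
    rows, index = [], []
    for msg in messages:
        rows.append(extract_features(msg.body, dictionaries, lexicons, story_model, normalize))
        index.append(msg.message_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="message_id"))


# --- LDA topic dictionaries ---------------------------------------------------

def build_topic_dictionaries(
    texts: Sequence[str],
    n_topics: int = 20,
    top_n: int = 500,
    seed: int = 0,
    extra_stopwords: Sequence[str] = (),
    max_iter: int = 50,
) -> tuple[list[CategoryDictionary], list[tuple[str, list[str]]]]:
    """Train an LDA topic model and emit one dictionary per topic.

    Each topic dictionary holds the ``top_n`` words with the highest
    topic-word probability; the report lists the top-10 words per topic for
    manual labelling.  Deterministic for a fixed seed.
    """
    from sklearn.decomposition import LatentDirichletAllocation
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS, CountVectorizer

    stop = set(ENGLISH_STOP_WORDS) | {w.lower() for w in extra_stopwords}

    def analyzer(doc: str) -> list[str]:
        return [t for t in tokenize(doc) if t not in stop and len(t) > 1]

    vec = CountVectorizer(analyzer=analyzer)
    X = vec.fit_transform(texts)
    if X.shape[0] < n_topics:
        raise ValidationError(
            f"need at least n_topics={n_topics} non-empty documents, got {X.shape[0]}"
        )
    vocab = np.asarray(vec.get_feature_names_out())
    if len(vocab) < top_n:
        warnings.warn(
            f"vocabulary ({len(vocab)} words) smaller than top_n={top_n}; "
            "dictionaries truncated to vocabulary size"
        )
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        # symmetric Dirichlet prior 50/n_topics, capped at the variational
        # implementation's upper bound of 1
        doc_topic_prior=min(1.0, 50.0 / n_topics),
        topic_word_prior=0.01,
        random_state=seed,
        learning_method="batch",
        max_iter=max_iter,
    )
    lda.fit(X)
    dicts, report = [], []
    width = max(2, len(str(n_topics - 1)))
    for k in range(n_topics):
        weights = lda.components_[k]
        # rank by probability, ties broken alphabetically for determinism
        order = np.lexsort((vocab, -weights))
        top = vocab[order[: min(top_n, len(vocab))]]
        name = f"topic_{k:0{width}d}"
        dicts.append(CategoryDictionary(name=name, entries=tuple(top)))
        report.append((name, [str(w) for w in top[:10]]))
    return dicts, report
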