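"""Dictionaries, segmentation/tagging, pattern detectors, LDA topics."""

import re
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supportdyn.exceptions import SchemaError, ValidationError
from supportdyn.featurize import (
    CategoryDictionary,
    build_topic_dictionaries,
    count_matches,
    extract_features,
    load_dictionary,
    load_dictionary_file,
    segment_and_tag,
    syntactic_features,
    tokenize,
)
from supportdyn.lexicons import CONSTRUCT_POOLS, MODAL_VERBS, NEGATION
from supportdyn.simulate import SimConfig, simulate_corpus

COUNT_FEATURES = (
    "sentence_count", "negation", "proper_nouns", "adjectives",
    "cardinal_numbers", "advice_verbs", "please_verb", "if_you", "you_modal",
    "question_marks", "any_pronouns", "verb_subject", "indirect_questions",
    "be_verbs", "stative_verbs", "subject_i", "subject_i_pos_adj",
    "subject_i_neg_adj", "strong_subjectivity", "weak_subjectivity",
    "drug_terms",
)


# --- dictionary loading ------------------------------------------------------

def test_load_tsv_dictionary(tmp_path):
    p = tmp_path / "emo.tsv"
    p.write_text("emo_pos\tlove\nemo_pos\thappi*\n", encoding="utf-8")
    d = load_dictionary(p)
    assert d.name == "emo_pos"
    assert set(d.entries) == {"love", "happi*"}


def test_duplicate_entries_stored_once(tmp_path):
    p = tmp_path / "d.tsv"
    p.write_text("cat\tword\ncat\tword\ncat\tWORD\n", encoding="utf-8")
    assert load_dictionary(p).entries == ("word",)


def test_dic_convention_file(tmp_path):
    p = tmp_path / "pack.dic"
    p.write_text("%\n1\tposemo\n2\tnegemo\n%\nlove\t1\nhate\t2\nok\t1\t2\n",
                 encoding="utf-8")
    dicts = {d.name: d for d in load_dictionary_file(p)}
    assert set(dicts["posemo"].entries) == {"love", "ok"}
    assert set(dicts["negemo"].entries) == {"hate", "ok"}


def test_dictionary_validation_errors(tmp_path):
    with pytest.raises(ValidationError):
        CategoryDictionary(name="x", entries=())
    with pytest.raises(ValidationError):
        CategoryDictionary(name="x", entries=("ha*py",))
    p = tmp_path / "bad.tsv"
    p.write_text("onlyonecolumn\n", encoding="utf-8")
    with pytest.raises(SchemaError):
        load_dictionary(p)


# --- matching ----------------------------------------------------------------

def test_stem_prefix_semantics():
    d = CategoryDictionary(name="x", entries=("happi*",))
    assert count_matches(["happy", "happiness"], d) == 1  # only the prefix match
    assert count_matches(["happiness", "happily"], d) == 2
    assert count_matches([], d) == 0


def test_count_matches_equals_brute_force(dictionaries):
    rng = np.random.default_rng(0)
    vocab = [w for pool in CONSTRUCT_POOLS.values() for w in pool]
    vocab += ["zzz", "love", "happiness", "the", "prayers"]
    tokens = [vocab[i] for i in rng.integers(0, len(vocab), size=1000)]
    for d in dictionaries:
        brute = 0
        for tok in tokens:
            hit = tok in {e for e in d.entries if not e.endswith("*")}
            for e in d.entries:
                if e.endswith("*") and tok.startswith(e[:-1]):
                    hit = True
            brute += hit
        assert count_matches(tokens, d) == brute


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from(sorted(CONSTRUCT_POOLS["neg_info_disclosure"]) + ["zzz"]),
                max_size=30),
       st.sampled_from(sorted(CONSTRUCT_POOLS["neg_info_disclosure"])))
def test_count_matches_monotone_and_additive(tokens, extra):
    d = CategoryDictionary(name="n", entries=CONSTRUCT_POOLS["neg_info_disclosure"])
    base = count_matches(tokens, d)
    assert count_matches(tokens + [extra], d) == base + 1
    assert count_matches(tokens + tokens, d) == 2 * base


# --- segmentation and tagging ------------------------------------------------

def test_segment_basic_terminators():
    sents = segment_and_tag("I am fine. Are you?")
    assert len(sents) == 2
    assert [s.terminator for s in sents] == [".", "?"]
    assert sents[0].surfaces == ("i", "am", "fine")


def test_segment_empty_body():
    assert segment_and_tag("") == []
    assert segment_and_tag("   ") == []


def test_abbreviation_guard():
    sents = segment_and_tag("Dr. Smith called me. I was glad!")
    assert len(sents) == 2
    assert sents[0].surfaces[0] == "dr"


def test_segmenter_recovers_generator_sentence_counts(small_community):
    threads, truth = small_community
    msgs = [m for t in threads for m in t.messages][:50]
    for m in msgs:
        planted = truth.planted_counts[m.message_id]["sentence_count"]
        assert len(segment_and_tag(m.body)) == planted


def test_tagger_marks_proper_nouns_and_numbers():
    sents = segment_and_tag("Then Tamara took 10 pills.")
    tags = dict(sents[0].tokens)
    assert tags["Tamara"] == "NNP"
    assert tags["10"] == "CD"


# --- syntactic features ------------------------------------------------------

def test_please_verb_pattern(lexicons):
    f = syntactic_features(segment_and_tag("Please give me advice."), lexicons)
    assert f["please_verb"] == 1
    assert f["sentence_count"] == 1


def test_question_prompt_example(lexicons):
    """An indirect advice-seeking question hits all four question cues."""
    body = "I am wondering if anyone has any advice on what I should do?"
    f = syntactic_features(segment_and_tag(body), lexicons)
    assert f["question_marks"] == 1
    assert f["indirect_questions"] == 1
    assert f["any_pronouns"] == 2  # anyone, any
    assert f["subject_i"] == 1


def test_generator_pattern_counts_exact(small_community, dictionaries, lexicons):
    """Every planted pattern and dictionary count is recovered exactly."""
    threads, truth = small_community
    msgs = [m for t in threads for m in t.messages]
    assert len(msgs) >= 100
    for m in msgs:
        feats = extract_features(m.body, dictionaries, lexicons)
        for key, planted in truth.planted_counts[m.message_id].items():
            assert feats[key] == planted, (m.message_id, key)


def test_detectors_agree_with_regex_oracle(small_community, lexicons):
    """Sentence-level detectors vs an independent regex oracle on >=1000
    generator sentences."""
    threads, _ = small_community
    verbs = {"give", "tell", "take", "go", "help", "explain", "agree", "rest"}
    n_checked = 0
    for m in [m for t in threads for m in t.messages]:
        for sent in segment_and_tag(m.body):
            text = " ".join(sent.surfaces)
            words = text.split()
            oracle = {
                "subject_i": int(bool(re.match(r"^i\b", text))),
                "if_you": int(bool(re.match(r"^if\s+you\b", text))),
                "you_modal": int(bool(re.match(
                    r"^you\s+(%s)\b" % "|".join(sorted(MODAL_VERBS)), text))),
                "please_verb": int(len(words) > 1 and words[0] == "please"
                                   and words[1] in verbs),
                "verb_subject": int(words[0] in MODAL_VERBS
                                    or words[0] in {"am", "is", "are", "was", "were",
                                                    "be", "been", "being", "do",
                                                    "does", "did", "have", "has",
                                                    "had"}),
                "question_marks": int(sent.terminator == "?"),
                "negation": int(any(w in NEGATION for w in words)),
                "indirect_questions": int(any(
                    p in text for p in lexicons.indirect_question_patterns)),
            }
            f = syntactic_features([sent], lexicons)
            for key, want in oracle.items():
                assert f[key] == want, (text, key)
            n_checked += 1
    assert n_checked >= 1000


def test_empty_message_gives_zero_vector(dictionaries, lexicons):
    f = extract_features("", dictionaries, lexicons)
    assert f["sentence_count"] == 0
    assert f["words_per_sentence"] == 0
    assert all(v == 0 for k, v in f.items())


def test_stopword_only_message(dictionaries, lexicons):
    f = extract_features("and then over there.", dictionaries, lexicons)
    assert all(f[f"dict_{d.name}"] == 0 for d in dictionaries)
    assert f["sentence_count"] >= 1


def test_count_features_additive_over_concatenation(small_community, dictionaries, lexicons):
    threads, _ = small_community
    bodies = [t.starter.body for t in threads[:10]]
    for a, b in zip(bodies[:-1], bodies[1:]):
        fa = extract_features(a, dictionaries, lexicons)
        fb = extract_features(b, dictionaries, lexicons)
        fab = extract_features(a + " " + b, dictionaries, lexicons)
        for key in list(COUNT_FEATURES) + [f"dict_{d.name}" for d in dictionaries]:
            assert fab[key] == fa[key] + fb[key], key


def test_per100_normalization(dictionaries, lexicons):
    body = "the lump biopsy . the tumor swelling ."
    raw = extract_features(body, dictionaries, lexicons)
    norm = extract_features(body, dictionaries, lexicons, normalize="per100")
    n_words = 6  # terminators are not tokens
    assert norm["dict_neg_info_disclosure"] == pytest.approx(
        raw["dict_neg_info_disclosure"] * 100 / n_words)
    assert norm["sentence_count"] == raw["sentence_count"]


# --- LDA topic dictionaries --------------------------------------------------

def _three_topic_corpus(n_docs=150, seed=0):
    rng = np.random.default_rng(seed)
    vocabs = [
        [f"alpha{i}" for i in range(25)],
        [f"beta{i}" for i in range(25)],
        [f"gamma{i}" for i in range(25)],
    ]
    docs = []
    for i in range(n_docs):
        pool = vocabs[i % 3]
        docs.append(" ".join(pool[j] for j in rng.integers(0, 25, size=40)))
    return docs, vocabs


def test_lda_recovers_planted_vocabularies():
    docs, vocabs = _three_topic_corpus()
    dicts, report = build_topic_dictionaries(docs, n_topics=3, top_n=25, seed=0)
    pools = [set(v) for v in vocabs]
    for d in dicts:
        best = max(len(set(d.entries) & pool) for pool in pools)
        assert best >= 0.9 * len(d.entries)
    assert len(report) == 3 and all(len(words) == 10 for _, words in report)


def test_lda_single_topic_matches_frequency_ranking():
    docs, _ = _three_topic_corpus(n_docs=60)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dicts, _ = build_topic_dictionaries(docs, n_topics=1, top_n=30, seed=0)
    counts = {}
    for doc in docs:
        for tok in tokenize(doc):
            counts[tok] = counts.get(tok, 0) + 1
    top_by_freq = set(sorted(counts, key=lambda w: -counts[w])[:30])
    assert len(set(dicts[0].entries) & top_by_freq) >= 27


def test_lda_deterministic_under_seed():
    docs, _ = _three_topic_corpus()
    a, _ = build_topic_dictionaries(docs, n_topics=3, top_n=20, seed=5)
    b, _ = build_topic_dictionaries(docs, n_topics=3, top_n=20, seed=5)
    assert [d.entries for d in a] == [d.entries for d in b]


def test_lda_truncates_small_vocabulary_with_warning():
    docs, _ = _three_topic_corpus(n_docs=30)
    with pytest.warns(UserWarning, match="vocabulary"):
        dicts, _ = build_topic_dictionaries(docs, n_topics=2, top_n=500, seed=0)
    assert all(len(d.entries) <= 75 for d in dicts)
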