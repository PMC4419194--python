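"""Synthetic support-community generator with ground truth.

The forum data the analysis pipeline targets cannot be redistributed, so
this module generates a community with the same statistical structure at
every stage, together with the ground truth each stage is supposed to
recover:

* per-exchange latent construct intensities drawn from a correlated
  truncated-normal model on the 1-7 Likert scale (means/SDs and the sign
  structure of the inter-construct correlations follow the descriptive
  statistics typical of such communities);
* message bodies assembled from disjoint per-construct vocabulary pools at
  token rates monotone in the latents, plus sentence templates that plant
  exact pattern counts (question marks, indirect questions, "I"-subject
  sentences, advice patterns, negation);
* first-reply support latents generated as a configured linear map of the
  starter latents plus noise, so path-model fits have a known target;
* crowd-rater panels with known variance components;
* user-level posting schedules whose dropout times follow a Weibull
  proportional-hazards model with configured hazard ratios.

Text generation is template/vocabulary-pool based, not a language model:
the downstream features are counts, so controllable counts matter more
than fluency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import RatingRecord
from .corpus import Message, Thread, thread_descriptives, write_corpus
from .exceptions import ConfigError
from .featurize import CategoryDictionary
from .lexicons import (
    CONSTRUCT_POOLS,
    FILLER_WORDS,
    GENERIC_DICTIONARIES,
    LexiconPack,
    default_lexicons,
)

STARTER_CONSTRUCTS = (
    "pos_emo_disclosure",
    "neg_emo_disclosure",
    "pos_info_disclosure",
    "neg_info_disclosure",
    "question_asking",
    "elicit_emotional",
    "elicit_informational",
)
STRATEGY_CONSTRUCTS = STARTER_CONSTRUCTS[:5]
REPLY_CONSTRUCTS = ("provide_emotional", "provide_informational")

_DEFAULT_MEANS = {
    "pos_emo_disclosure": 1.55,
    "neg_emo_disclosure": 2.39,
    "pos_info_disclosure": 1.89,
    "neg_info_disclosure": 3.58,
    "question_asking": 4.94,
    "elicit_emotional": 2.75,
    "elicit_informational": 4.21,
    "provide_emotional": 2.68,
    "provide_informational": 2.93,
}
_DEFAULT_SDS = {
    "pos_emo_disclosure": 0.96,
    "neg_emo_disclosure": 1.52,
    "pos_info_disclosure": 1.09,
    "neg_info_disclosure": 1.72,
    "question_asking": 2.17,
    "elicit_emotional": 1.66,
    "elicit_informational": 2.01,
    "provide_emotional": 1.43,
    "provide_informational": 1.47,
}


def _default_correlation() -> np.ndarray:
    # sign structure of the inter-construct correlations seen in hand-coded
    # community data (values rounded to .05); order = STARTER_CONSTRUCTS
    lower = {
        (1, 0): -0.10,
        (2, 0): 0.75, (2, 1): -0.10,
        (3, 0): -0.20, (3, 1): 0.65, (3, 2): -0.25,
        (4, 0): -0.35, (4, 1): 0.05, (4, 2): -0.35, (4, 3): 0.30,
        (5, 0): 0.15, (5, 1): 0.75, (5, 2): 0.10, (5, 3): 0.55, (5, 4): -0.10,
        (6, 0): -0.35, (6, 1): -0.05, (6, 2): -0.35, (6, 3): 0.25, (6, 4): 0.85,
    }
    C = np.eye(7)
    for (i, j), v in lower.items():
        C[i, j] = C[j, i] = v
    return C


_DEFAULT_REPLY_COEF = {
    "provide_emotional": {
        "pos_emo_disclosure": 0.07,
        "neg_emo_disclosure": 0.24,
        "pos_info_disclosure": 0.10,
        "neg_info_disclosure": 0.25,
        "question_asking": -0.21,
    },
    "provide_informational": {
        "question_asking": 0.38,
        "pos_info_disclosure": -0.09,
        "neg_info_disclosure": 0.03,
    },
}


@dataclass
class SurvivalTruth:
    """Planted Weibull proportional-hazards truth for the community."""

    shape: float = 0.85
    baseline_rate: float = 0.06  # lambda0: h0(t) = lambda0 * p * t^(p-1)
    log_hr: dict = dc_field(default_factory=lambda: {
        "has_profile": float(np.log(0.6)),
        "pct_starters": float(np.log(0.85)),
        "post_count": float(np.log(0.7)),
        "emo_support": float(np.log(0.7)),
        "info_support": float(np.log(1.2)),
        "post_x_emo": 0.0,
        "post_x_info": 0.0,
    })
    p_profile: float = 0.3119
    gap_weeks: int = 12
    end_week: int = 52
    entry_spread_weeks: int = 8


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_threads: int = 1000
    p_no_reply: float = 0.114
    extra_replies_mean: float = 1.0
    reply_delay_mean_hours: float = 12.0
    construct_means: dict = dc_field(default_factory=lambda: dict(_DEFAULT_MEANS))
    construct_sds: dict = dc_field(default_factory=lambda: dict(_DEFAULT_SDS))
    correlation: np.ndarray = dc_field(default_factory=_default_correlation)
    reply_coefficients: dict = dc_field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_REPLY_COEF.items()}
    )
    min_reply_noise_var: float = 0.15
    signal_rate: float = 3.0  # pool tokens per latent unit above 1
    filler_rate: float = 6.0
    story_prob: float = 0.25
    sigma_rater: float = 0.3
    sigma_err: float = 1.0
    k_raters: int = 10
    rater_pool: int = 50
    n_users: int = 800
    survival: SurvivalTruth = dc_field(default_factory=SurvivalTruth)

    def __post_init__(self) -> None:
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (len(STARTER_CONSTRUCTS),) * 2:
            raise ConfigError(f"correlation matrix must be {len(STARTER_CONSTRUCTS)}x"
                              f"{len(STARTER_CONSTRUCTS)}")
        if not np.allclose(C, C.T):
            raise ConfigError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ConfigError("correlation matrix is not positive semi-definite")
        if any(sd <= 0 for sd in self.construct_sds.values()):
            raise ConfigError("construct sds must be positive")
        if self.k_raters < 2:
            raise ConfigError("k_raters must be >= 2")
        self.correlation = C


@dataclass
class GroundTruth:
    """Everything the generator knows about what it planted."""

    latents: pd.DataFrame            # message_id x construct (NaN when n/a)
    starter_z: pd.DataFrame          # thread_id x starter construct, gaussian scale
    planted_counts: dict             # message_id -> feature -> exact count
    story_labels: dict               # starter message_id -> 0/1
    roles: dict                      # message_id -> starter | first_reply | extra
    config: SimConfig
    users: Optional[pd.DataFrame] = None    # survival: per-user covariates/times
    scores: Optional[pd.DataFrame] = None   # survival: per-message support scores


# --------------------------------------------------------------------------
# message text assembly (with exact bookkeeping)

_TEMPLATES = {
    "indirect_q": ("i am wondering if anyone could help ?",
                   {"subject_i": 1, "indirect_questions": 1, "question_marks": 1,
                    "any_pronouns": 1, "sentence_count": 1}),
    "verb_subject_q": ("could you explain this ?",
                       {"verb_subject": 1, "question_marks": 1, "sentence_count": 1}),
    "please_verb": ("please tell me .",
                    {"please_verb": 1, "advice_verbs": 1, "sentence_count": 1}),
    "if_you": ("if you agree .", {"if_you": 1, "sentence_count": 1}),
    "you_modal": ("you should rest .", {"you_modal": 1, "sentence_count": 1}),
    "i_pos_adj": ("i am glad today .",
                  {"subject_i": 1, "subject_i_pos_adj": 1, "sentence_count": 1}),
    "i_neg_adj": ("i was scared yesterday .",
                  {"subject_i": 1, "subject_i_neg_adj": 1, "sentence_count": 1}),
    "negation": ("it was not easy .", {"negation": 1, "sentence_count": 1}),
    "story": ("i went %s %s .", {"subject_i": 1, "sentence_count": 1}),
}


def _compose_message(
    rng: np.random.Generator, intensities: dict[str, float], config: SimConfig,
    is_story: bool = False,
) -> tuple[str, dict[str, float]]:
    """Assemble a message body; return it with the exact planted counts."""
    counts: dict[str, float] = {f"dict_{c}": 0.0 for c in CONSTRUCT_POOLS}
    for key in ("sentence_count", "question_marks", "indirect_questions",
                "verb_subject", "subject_i", "subject_i_pos_adj",
                "subject_i_neg_adj", "please_verb", "advice_verbs", "if_you",
                "you_modal", "negation", "any_pronouns"):
        counts[key] = 0.0
    sentences: list[str] = []

    def add_template(name: str, times: int) -> None:
        text, delta = _TEMPLATES[name]
        for _ in range(times):
            if name == "story":
                words = rng.choice(FILLER_WORDS, size=2, replace=True)
                sentences.append(text % tuple(words))
            else:
                sentences.append(text)
            for k, v in delta.items():
                counts[k] += v

    def pool_tokens(construct: str, value: float) -> list[str]:
        lam = config.signal_rate * max(value - 1.0, 0.0)
        k = int(rng.poisson(lam))
        if k == 0:
            return []
        pool = CONSTRUCT_POOLS[construct]
        counts[f"dict_{construct}"] += k
        return [pool[i] for i in rng.integers(0, len(pool), size=k)]

    q_val = intensities.get("question_asking", 1.0)
    for construct, value in intensities.items():
        toks = pool_tokens(construct, value)
        is_question = construct == "question_asking"
        for i in range(0, len(toks), 3):
            chunk = toks[i : i + 3]
            if is_question:
                sentences.append("the " + " ".join(chunk) + " ?")
                counts["question_marks"] += 1
            else:
                sentences.append("the " + " ".join(chunk) + " .")
            counts["sentence_count"] += 1

    add_template("indirect_q", int(rng.poisson(0.30 * max(q_val - 1, 0))))
    add_template("verb_subject_q", int(rng.poisson(0.20 * max(q_val - 1, 0))))
    add_template("please_verb", int(rng.poisson(0.15 * max(q_val - 1, 0))))
    pe_val = intensities.get("pos_emo_disclosure", 1.0)
    ne_val = intensities.get("neg_emo_disclosure", 1.0)
    add_template("i_pos_adj", int(rng.poisson(0.30 * max(pe_val - 1, 0))))
    add_template("i_neg_adj", int(rng.poisson(0.30 * max(ne_val - 1, 0))))
    pi_val = intensities.get("provide_informational", 1.0)
    add_template("if_you", int(rng.poisson(0.20 * max(pi_val - 1, 0))))
    add_template("you_modal", int(rng.poisson(0.20 * max(pi_val - 1, 0))))
    add_template("negation", int(rng.poisson(0.3)))
    if is_story:
        add_template("story", 3)

    n_fill = int(rng.poisson(config.filler_rate))
    fills = [FILLER_WORDS[i] for i in rng.integers(0, len(FILLER_WORDS), size=n_fill)]
    for i in range(0, len(fills), 4):
        sentences.append(" ".join(fills[i : i + 4]) + " .")
        counts["sentence_count"] += 1
    if not sentences:
        sentences.append("the morning .")
        counts["sentence_count"] += 1
    order = rng.permutation(len(sentences))
    return " ".join(sentences[i] for i in order), counts


# --------------------------------------------------------------------------

def simulate_corpus(config: Optional[SimConfig] = None) -> tuple[list[Thread], GroundTruth]:
    """Generate a threaded exchange corpus with known latent constructs."""
    config = config or SimConfig()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_threads
    k = len(STARTER_CONSTRUCTS)
    chol = np.linalg.cholesky(config.correlation + 1e-12 * np.eye(k))
    Z = rng.standard_normal((n, k)) @ chol.T
    means = np.array([config.construct_means[c] for c in STARTER_CONSTRUCTS])
    sds = np.array([config.construct_sds[c] for c in STARTER_CONSTRUCTS])
    raw = means + Z * sds
    values = np.clip(raw, 1.0, 7.0)

    # reply support latents: configured linear map of starter gaussians
    strat_idx = {c: i for i, c in enumerate(STARTER_CONSTRUCTS)}
    reply_z = {}
    for target, coefs in config.reply_coefficients.items():
        b = np.zeros(k)
        for src, w in coefs.items():
            b[strat_idx[src]] = w
        explained = float(b @ config.correlation @ b)
        noise_sd = float(np.sqrt(max(1.0 - explained, config.min_reply_noise_var)))
        reply_z[target] = Z @ b + rng.standard_normal(n) * noise_sd
    reply_values = {
        t: np.clip(
            config.construct_means[t] + config.construct_sds[t] * z, 1.0, 7.0
        )
        for t, z in reply_z.items()
    }

    base_time = datetime(2009, 1, 1, tzinfo=timezone.utc)
    threads: list[Thread] = []
    latent_rows: dict[str, dict[str, float]] = {}
    planted: dict[str, dict[str, float]] = {}
    stories: dict[str, int] = {}
    roles: dict[str, str] = {}
    has_reply = rng.random(n) >= config.p_no_reply
    for i in range(n):
        tid = f"t{i:05d}"
        t0 = base_time + timedelta(hours=3.0 * i) + timedelta(
            minutes=float(rng.integers(0, 60))
        )
        intensities = {c: float(values[i, j]) for j, c in enumerate(STARTER_CONSTRUCTS)}
        is_story = bool(rng.random() < config.story_prob)
        body, counts = _compose_message(rng, intensities, config, is_story=is_story)
        sid = f"{tid}_m0"
        starter = Message(sid, tid, f"u{i:05d}", t0, body, position=0)
        msgs = [starter]
        latent_rows[sid] = intensities
        planted[sid] = counts
        stories[sid] = int(is_story)
        roles[sid] = "starter"
        if has_reply[i]:
            delay = rng.exponential(config.reply_delay_mean_hours)
            rid = f"{tid}_m1"
            reply_int = {t: float(reply_values[t][i]) for t in REPLY_CONSTRUCTS}
            rbody, rcounts = _compose_message(rng, reply_int, config)
            msgs.append(
                Message(rid, tid, f"r{i:05d}", t0 + timedelta(hours=float(delay)),
                        rbody, position=1)
            )
            latent_rows[rid] = reply_int
            planted[rid] = rcounts
            roles[rid] = "first_reply"
            for j in range(int(rng.poisson(config.extra_replies_mean))):
                mid = f"{tid}_m{j + 2}"
                ebody, ecounts = _compose_message(rng, {}, config)
                msgs.append(
                    Message(
                        mid, tid, f"x{i:05d}_{j}",
                        t0 + timedelta(hours=float(delay) + 2.0 * (j + 1)),
                        ebody, position=j + 2,
                    )
                )
                planted[mid] = ecounts
                roles[mid] = "extra"
        threads.append(Thread(thread_id=tid, messages=msgs))

    all_constructs = list(STARTER_CONSTRUCTS) + list(REPLY_CONSTRUCTS)
    latents = pd.DataFrame.from_dict(latent_rows, orient="index").reindex(
        columns=all_constructs
    )
    latents.index.name = "message_id"
    starter_z = pd.DataFrame(
        Z, index=pd.Index([f"t{i:05d}" for i in range(n)], name="thread_id"),
        columns=list(STARTER_CONSTRUCTS),
    )
    truth = GroundTruth(
        latents=latents,
        starter_z=starter_z,
        planted_counts=planted,
        story_labels=stories,
        roles=roles,
        config=config,
    )
    return threads, truth


def simulate_ratings(
    latents: pd.DataFrame, config: Optional[SimConfig] = None, seed_offset: int = 7
) -> list[RatingRecord]:
    """Crowd-rater panels over latent values: k integer Likert judgments per
    (message, construct), with a shared rater-effect pool."""
    config = config or SimConfig()
    rng = np.random.default_rng([config.seed, seed_offset])
    rater_effects = rng.normal(0.0, config.sigma_rater, size=config.rater_pool)
    records: list[RatingRecord] = []
    for mid, row in latents.iterrows():
        for construct, value in row.items():
            if pd.isna(value):
                continue
            raters = rng.choice(config.rater_pool, size=config.k_raters, replace=False)
            noise = rng.normal(0.0, config.sigma_err, size=config.k_raters)
            for r, eps in zip(raters, noise):
                score = int(np.clip(np.rint(value + rater_effects[r] + eps), 1, 7))
                records.append(
                    RatingRecord(
                        message_id=str(mid),
                        construct=str(construct),
                        rater_id=f"w{r:03d}",
                        score=score,
                    )
                )
    return records


# --------------------------------------------------------------------------
# survival community

def simulate_survival_community(
    config: Optional[SimConfig] = None, build_corpus: bool = True
) -> tuple[list[Thread], dict[str, int], GroundTruth]:
    """Community with weekly posting schedules and Weibull PH dropout.

    Returns (threads, profiles, truth).  ``profiles`` covers only the study
    members; supporter accounts that inject replies are context only.
    ``truth.users`` holds the per-user covariates and exact event times;
    ``truth.scores`` holds per-message support scores for exposure
    construction.  With ``build_corpus=False`` only the user-level truth is
    generated (threads and scores are empty), which is much cheaper when
    only :func:`weibull_truth_spells` output is needed.
    """
    config = config or SimConfig()
    sv = config.survival
    rng = np.random.default_rng([config.seed, 2])
    n = config.n_users

    z = {
        "post_count": rng.standard_normal(n),
        "emo_support": rng.standard_normal(n),
        "info_support": rng.standard_normal(n),
        "pct_starters": rng.standard_normal(n),
    }
    has_profile = (rng.random(n) < sv.p_profile).astype(int)
    eta = np.log(sv.baseline_rate) + (
        sv.log_hr["has_profile"] * has_profile
        + sv.log_hr["pct_starters"] * z["pct_starters"]
        + sv.log_hr["post_count"] * z["post_count"]
        + sv.log_hr["emo_support"] * z["emo_support"]
        + sv.log_hr["info_support"] * z["info_support"]
        + sv.log_hr["post_x_emo"] * z["post_count"] * z["emo_support"]
        + sv.log_hr["post_x_info"] * z["post_count"] * z["info_support"]
    )
    T = (rng.exponential(1.0, size=n) / np.exp(eta)) ** (1.0 / sv.shape)
    entry = rng.integers(0, sv.entry_spread_weeks + 1, size=n)
    available = sv.end_week - entry

    base_time = datetime(2009, 1, 5, tzinfo=timezone.utc)
    threads: list[Thread] = []
    score_rows = []
    profiles: dict[str, int] = {}
    # stable per-user starter propensity: tertiles of the latent starter
    # covariate map to 1, 2 or 3 thread starters per active week
    tertile = np.digitize(z["pct_starters"], [-0.4307, 0.4307])
    for i in range(n if build_corpus else 0):
        uid = f"su{i:05d}"
        profiles[uid] = int(has_profile[i])
        t_entry = base_time + timedelta(weeks=int(entry[i]))
        last_week = int(min(np.floor(T[i]), available[i]))
        n_inject = max(int(np.rint(3.0 * np.exp(0.5 * z["post_count"][i]))), 0)
        for w in range(last_week + 1):
            wt = t_entry + timedelta(weeks=w)
            tid = f"s{i:05d}_w{w}"
            starter = Message(f"{tid}_m0", tid, uid, wt, "the morning .", position=0)
            msgs = [starter]
            score_rows.append((f"{tid}_m0",
                               float(np.clip(rng.normal(2.6, 0.8), 1, 7)),
                               float(np.clip(rng.normal(2.6, 0.8), 1, 7))))
            # 3 posts per active week: 1..3 of them thread starters, the
            # rest replies into the user's first thread of the week
            n_starters = 1 + int(tertile[i])
            for j in range(2):
                ts_j = wt + timedelta(hours=1 + j)
                if j < n_starters - 1:
                    tid_j = f"s{i:05d}_w{w}{'bc'[j]}"
                    m_j = Message(f"{tid_j}_m0", tid_j, uid, ts_j,
                                  "the evening .", position=0)
                    threads.append(Thread(thread_id=tid_j, messages=[m_j]))
                    mid_j = f"{tid_j}_m0"
                else:
                    mid_j = f"{tid}_m{len(msgs)}"
                    msgs.append(Message(mid_j, tid, uid, ts_j,
                                        "the evening .", position=len(msgs)))
                score_rows.append((mid_j,
                                   float(np.clip(rng.normal(2.6, 0.8), 1, 7)),
                                   float(np.clip(rng.normal(2.6, 0.8), 1, 7))))
            emo_vals = np.clip(
                4.0 + 0.9 * z["emo_support"][i] + rng.normal(0, 0.4, size=n_inject), 1, 7
            )
            info_vals = np.clip(
                4.0 + 0.9 * z["info_support"][i] + rng.normal(0, 0.4, size=n_inject), 1, 7
            )
            for j in range(n_inject):
                mid = f"{tid}_a{j}"
                msgs.append(
                    Message(mid, tid, f"angel{j:02d}",
                            wt + timedelta(hours=2 + j), "the coffee .",
                            position=len(msgs))
                )
                score_rows.append((mid, float(emo_vals[j]), float(info_vals[j])))
            threads.append(Thread(thread_id=tid, messages=msgs))

    if not build_corpus:
        profiles = {f"su{i:05d}": int(has_profile[i]) for i in range(n)}
    scores = pd.DataFrame(
        score_rows, columns=["message_id", "provide_emotional", "provide_informational"]
    ).set_index("message_id")
    users = pd.DataFrame(
        {
            "user_id": [f"su{i:05d}" for i in range(n)],
            "has_profile": has_profile,
            "pct_starters_z": z["pct_starters"],
            "post_count_z": z["post_count"],
            "emo_support_z": z["emo_support"],
            "info_support_z": z["info_support"],
            "eta": eta,
            "event_time": T,
            "entry_week": entry,
            "available_weeks": available,
        }
    ).set_index("user_id")
    truth = GroundTruth(
        latents=pd.DataFrame(), starter_z=pd.DataFrame(), planted_counts={},
        story_labels={}, roles={}, config=config, users=users, scores=scores,
    )
    return threads, profiles, truth


def weibull_truth_spells(truth: GroundTruth) -> pd.DataFrame:
    """Exact counting-process intervals from the survival ground truth.

    Each user is right-censored at their available follow-up; intervals are
    split at integer weeks (splitting leaves the likelihood unchanged) with
    the user's constant covariates on every interval.
    """
    users = truth.users
    rows = []
    for uid, u in users.iterrows():
        time = float(min(u["event_time"], u["available_weeks"]))
        event = int(u["event_time"] < u["available_weeks"])
        if time <= 0:
            time = 1e-3  # event essentially at entry
        w = 0.0
        while w < time:
            stop = min(w + 1.0, time)
            rows.append(
                {
                    "user_id": uid, "start": w, "stop": stop,
                    "event": event if stop == time else 0,
                    "has_profile": u["has_profile"],
                    "pct_starters": u["pct_starters_z"],
                    "post_count": u["post_count_z"],
                    "emo_support": u["emo_support_z"],
                    "info_support": u["info_support_z"],
                    "post_x_emo": u["post_count_z"] * u["emo_support_z"],
                    "post_x_info": u["post_count_z"] * u["info_support_z"],
                }
            )
            w = stop
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fixture pack

def make_fixture_pack(out_dir: str | Path) -> dict:
    """Write deterministic fixture dictionaries, lexicons, and a demo corpus.

    Returns (and writes as JSON) a manifest recording every planted count so
    loaders and featurizers can be verified against it byte-for-byte.
    """
    out = Path(out_dir)
    (out / "dictionaries").mkdir(parents=True, exist_ok=True)
    (out / "lexicons").mkdir(parents=True, exist_ok=True)

    dict_counts = {}
    for name, words in sorted(CONSTRUCT_POOLS.items()):
        path = out / "dictionaries" / f"construct_{name}.tsv"
        path.write_text(
            "".join(f"{name}\t{w}\n" for w in words), encoding="utf-8"
        )
        dict_counts[name] = len(set(words))
    for name, words in sorted(GENERIC_DICTIONARIES.items()):
        path = out / "dictionaries" / f"generic_{name}.tsv"
        path.write_text("".join(f"{name}\t{w}\n" for w in words), encoding="utf-8")
        dict_counts[name] = len(set(words))

    lex = default_lexicons()
    for fname in (
        "negation", "advice_verbs", "stative_verbs", "positive_adjectives",
        "negative_adjectives", "strong_subjectivity", "weak_subjectivity",
        "drugs", "indefinite_pronouns", "modal_verbs",
    ):
        words = sorted(getattr(lex, fname))
        (out / "lexicons" / f"{fname}.txt").write_text(
            "".join(w + "\n" for w in words), encoding="utf-8"
        )
    (out / "lexicons" / "indirect_question_patterns.txt").write_text(
        "".join(p + "\n" for p in lex.indirect_question_patterns), encoding="utf-8"
    )

    demo_cfg = SimConfig(seed=202401, n_threads=10)
    threads, truth = simulate_corpus(demo_cfg)
    write_corpus(threads, out / "demo_corpus.jsonl")
    desc = thread_descriptives(threads)
    n_pairs_with_reply = sum(1 for t in threads if len(t) > 1)
    planted_totals: dict[str, float] = {}
    for counts in truth.planted_counts.values():
        for k, v in counts.items():
            planted_totals[k] = planted_totals.get(k, 0.0) + v
    manifest = {
        "dictionary_entry_counts": dict_counts,
        "demo_corpus": {
            "n_threads": desc.n_threads,
            "n_messages": desc.n_messages,
            "n_pairs_with_reply": n_pairs_with_reply,
            "pct_never_replied": round(desc.pct_never_replied, 6),
            "pct_reply_24h": round(desc.pct_reply_24h, 6),
        },
        "planted_feature_totals": {k: planted_totals[k] for k in sorted(planted_totals)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest


def fixture_dictionaries() -> list[CategoryDictionary]:
    """The in-memory fixture dictionary pack (construct pools + generic)."""
    dicts = [
        CategoryDictionary(name=name, entries=tuple(words))
        for name, words in CONSTRUCT_POOLS.items()
    ]
    dicts += [
        CategoryDictionary(name=name, entries=tuple(words))
        for name, words in GENERIC_DICTIONARIES.items()
    ]
    return dicts
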