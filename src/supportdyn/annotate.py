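"""Multi-rater construct scores: aggregation, reliability, validity.

Crowd raters judge each message on 7-point Likert scales for nine
support-related constructs (four kinds of self-disclosure, question asking,
two support-elicitation judgments, and provision of emotional/informational
support).  Per-message scores are the arithmetic mean over the rater panel;
reliability is quantified with one-way random-effects intraclass
correlations, validity with Pearson correlation against a reference panel,
and binary agreement with Cohen's kappa.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError, ValidationError

CONSTRUCTS = (
    "pos_emo_disclosure",
    "neg_emo_disclosure",
    "pos_info_disclosure",
    "neg_info_disclosure",
    "question_asking",
    "elicit_emotional",
    "elicit_informational",
    "provide_emotional",
    "provide_informational",
)

#: the seven constructs measured by machine models (elicitation judgments
#: are human-coded only)
MACHINE_CONSTRUCTS = tuple(c for c in CONSTRUCTS if not c.startswith("elicit"))


@dataclass(frozen=True)
class RatingRecord:
    """One rater's 1-7 judgment of one construct in one message."""

    message_id: str
    construct: str
    rater_id: str
    score: int

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValidationError(f"unknown construct {self.construct!r}")
        if not float(self.score).is_integer() or not 1 <= self.score <= 7:
            raise ValidationError(
                f"rating for message {self.message_id!r} by {self.rater_id!r}: "
                f"score {self.score!r} not an integer in 1..7"
            )


@dataclass(frozen=True)
class ConstructScore:
    """Mean construct intensity for one message on the 1-7 scale."""

    message_id: str
    construct: str
    value: float
    n_raters: int


@dataclass(frozen=True)
class ReliabilityReport:
    construct: str
    icc_single: float
    icc_average: float
    n_messages: int
    mean_raters_per_message: float


def load_ratings(path: str | Path) -> list[RatingRecord]:
    """Read a ratings CSV (message_id, construct, rater_id, score)."""
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            RatingRecord(
                message_id=row["message_id"],
                construct=row["construct"],
                rater_id=row["rater_id"],
                score=int(row["score"]),
            )
            for row in reader
        ]


def aggregate_ratings(records: Sequence[RatingRecord]) -> list[ConstructScore]:
    """Average ratings per (message, construct) group.

    Order of first appearance is preserved; rater order within a group is
    irrelevant.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.message_id, rec.construct)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec.score)
    return [
        ConstructScore(
            message_id=mid,
            construct=construct,
            value=float(np.mean(groups[(mid, construct)])),
            n_raters=len(groups[(mid, construct)]),
        )
        for mid, construct in order
    ]


def icc_oneway(records: Sequence[RatingRecord], construct: str) -> ReliabilityReport:
    """One-way random-effects ICC for one construct.

    The rated message is the random grouping factor; raters are
    interchangeable subsets, so rater identity carries no variance term of
    its own.  With between/within mean squares MSB and MSW and the
    unbalanced-design effective panel size

        k0 = (N - sum(k_i^2)/N) / (n - 1),

    the single-measure ICC is (MSB - MSW) / (MSB + (k0 - 1) MSW) and the
    average-measure (panel-mean) ICC is (MSB - MSW) / MSB, the
    Spearman-Brown step-up of the single-measure value at k0.
    """
    groups: dict[str, list[int]] = {}
    for rec in records:
        if rec.construct == construct:
            groups.setdefault(rec.message_id, []).append(rec.score)
    if len(groups) < 2:
        raise DomainError("ICC requires ratings on at least 2 messages")
    if any(len(v) < 2 for v in groups.values()):
        raise DomainError("ICC requires at least 2 ratings per message")

    sizes = np.array([len(v) for v in groups.values()], dtype=float)
    n = len(groups)
    N = sizes.sum()
    grand = sum(sum(v) for v in groups.values()) / N
    means = np.array([np.mean(v) for v in groups.values()])
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values()))
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    if msb == 0 and msw == 0:
        raise DomainError("ICC undefined: ratings are constant everywhere")
    k0 = (N - (sizes**2).sum() / N) / (n - 1)
    icc_single = (msb - msw) / (msb + (k0 - 1) * msw)
    icc_average = (msb - msw) / msb if msb > 0 else float("-inf")
    return ReliabilityReport(
        construct=construct,
        icc_single=float(icc_single),
        icc_average=float(icc_average),
        n_messages=n,
        mean_raters_per_message=float(N / n),
    )


def validate_scores(a: Sequence[ConstructScore], b: Sequence[ConstructScore]) -> float:
    """Pearson r between two panels' mean scores over shared message ids."""
    map_a = {s.message_id: s.value for s in a}
    map_b = {s.message_id: s.value for s in b}
    shared = sorted(set(map_a) & set(map_b))
    if len(shared) < 3:
        raise DomainError(f"need >=3 shared message ids, got {len(shared)}")
    xa = np.array([map_a[m] for m in shared])
    xb = np.array([map_b[m] for m in shared])
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise DomainError("validation requires non-constant scores on both sides")
    return float(np.corrcoef(xa, xb)[0, 1])


def cohen_kappa(pred: Sequence[int], gold: Sequence[int]) -> float:
    """Unweighted Cohen's kappa for binary labels.

    kappa = (p_obs - p_exp) / (1 - p_exp) with chance agreement p_exp from
    the marginal label frequencies of the two label sequences.
    """
    if len(pred) != len(gold) or len(pred) == 0:
        raise DomainError("label sequences must be non-empty and equal length")
    p = np.asarray(pred)
    g = np.asarray(gold)
    n = len(p)
    p_obs = float((p == g).mean())
    labels = np.union1d(p, g)
    p_exp = float(sum((p == lab).mean() * (g == lab).mean() for lab in labels))
    if math.isclose(p_exp, 1.0):
        raise DomainError("kappa undefined: both label sets constant and equal")
    return (p_obs - p_exp) / (1 - p_exp)


def write_scores(scores: Sequence[ConstructScore], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["message_id", "construct", "value", "n_raters"])
        for s in scores:
            writer.writerow([s.message_id, s.construct, repr(s.value), s.n_raters])


def load_scores(path: str | Path) -> list[ConstructScore]:
    with open(path, encoding="utf-8", newline="") as fh:
        return [
            ConstructScore(
                message_id=row["message_id"],
                construct=row["construct"],
                value=float(row["value"]),
                n_raters=int(row["n_raters"]),
            )
            for row in csv.DictReader(fh)
        ]


def scores_to_frame(scores: Sequence[ConstructScore]):
    """Pivot ConstructScores into a message x construct pandas DataFrame."""
    import pandas as pd

    df = pd.DataFrame(
        {"message_id": [s.message_id for s in scores],
         "construct": [s.construct for s in scores],
         "value": [s.value for s in scores]}
    )
    return df.pivot(index="message_id", columns="construct", values="value")
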