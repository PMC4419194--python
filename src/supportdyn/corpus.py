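"""Data model and I/O for threaded forum corpora.

Messages belong to discussion threads.  The position-0 message of a thread is
the *thread starter*; the position-1 message is its *first reply*.  The
starter/first-reply pair is the unit of analysis for the support-exchange
models, and thread-level descriptive statistics (length, lifespan, reply
latency) characterise the community as a whole.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .exceptions import DomainError, IntegrityError, SchemaError

MESSAGE_FIELDS = ("message_id", "thread_id", "author_id", "timestamp", "body")


@dataclass
class Message:
    """A single forum post.

    ``position`` is the 0-based order of the message within its thread;
    position 0 marks the thread starter.
    """

    message_id: str
    thread_id: str
    author_id: str
    timestamp: datetime
    body: str
    position: int = 0

    def __post_init__(self) -> None:
        if self.body is None:
            raise SchemaError(f"message {self.message_id}: body may be empty but not null")
        if self.timestamp.tzinfo is None:
            # naive timestamps are taken to be UTC
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)


@dataclass
class Thread:
    """An ordered discussion thread (>= 1 message, exactly one starter)."""

    thread_id: str
    messages: list[Message] = field(default_factory=list)

    @property
    def starter(self) -> Message:
        return self.messages[0]

    @property
    def first_reply(self) -> Optional[Message]:
        return self.messages[1] if len(self.messages) > 1 else None

    def __len__(self) -> int:
        return len(self.messages)


@dataclass
class ExchangePair:
    """A thread starter and (when the thread got any reply) its first reply."""

    starter: Message
    first_reply: Optional[Message] = None


@dataclass
class ThreadDescriptives:
    """Community-level descriptive statistics over a set of threads."""

    n_threads: int
    n_messages: int
    thread_length_median: float
    thread_length_mean: float
    thread_length_sd: float
    lifespan_median_days: float
    lifespan_mean_days: float
    lifespan_sd_days: float
    pct_reply_24h: float
    pct_never_replied: float


def _parse_timestamp(raw: object, row_no: int) -> datetime:
    if isinstance(raw, datetime):
        ts = raw
    else:
        try:
            ts = datetime.fromisoformat(str(raw))
        except ValueError as exc:
            raise SchemaError(f"row {row_no}: bad timestamp {raw!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _rows_to_threads(rows: Iterable[dict], source: str) -> list[Thread]:
    seen_ids: set[str] = set()
    by_thread: dict[str, list[Message]] = {}
    order: list[str] = []
    for row_no, row in enumerate(rows, start=1):
        missing = [f for f in MESSAGE_FIELDS if f not in row or row[f] is None]
        if missing:
            raise SchemaError(f"{source} row {row_no}: missing field(s) {', '.join(missing)}")
        mid = str(row["message_id"])
        if mid in seen_ids:
            raise IntegrityError(f"{source}: duplicate message_id {mid!r}")
        seen_ids.add(mid)
        msg = Message(
            message_id=mid,
            thread_id=str(row["thread_id"]),
            author_id=str(row["author_id"]),
            timestamp=_parse_timestamp(row["timestamp"], row_no),
            body=str(row["body"]),
        )
        if msg.thread_id not in by_thread:
            by_thread[msg.thread_id] = []
            order.append(msg.thread_id)
        by_thread[msg.thread_id].append(msg)

    threads = []
    for tid in order:
        msgs = sorted(by_thread[tid], key=lambda m: (m.timestamp, m.message_id))
        for pos, m in enumerate(msgs):
            m.position = pos
        threads.append(Thread(thread_id=tid, messages=msgs))
    return threads


def load_corpus(path: str | Path, format: Optional[str] = None) -> list[Thread]:
    """Load a threaded corpus from JSONL or CSV.

    Messages are grouped by ``thread_id`` and ordered by timestamp (ties
    broken by lexicographic ``message_id``); positions are assigned 0..n-1.
    The format is inferred from the file suffix unless given explicitly.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path} line {line_no}: invalid JSON") from exc
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        raise SchemaError(f"unknown corpus format {format!r}")
    return _rows_to_threads(rows, str(path))


def write_corpus(threads: Sequence[Thread], path: str | Path, format: Optional[str] = None) -> None:
    """Write threads back to JSONL or CSV (round-trips with :func:`load_corpus`)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [
        {
            "message_id": m.message_id,
            "thread_id": m.thread_id,
            "author_id": m.author_id,
            "timestamp": m.timestamp.astimezone(timezone.utc).isoformat(),
            "body": m.body,
        }
        for t in threads
        for m in t.messages
    ]
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(MESSAGE_FIELDS))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise SchemaError(f"unknown corpus format {format!r}")


def extract_exchange_pairs(threads: Sequence[Thread]) -> list[ExchangePair]:
    """One :class:`ExchangePair` per thread, in input order.

    ``first_reply`` is absent for threads that never received a reply.
    """
    return [ExchangePair(starter=t.starter, first_reply=t.first_reply) for t in threads]


def thread_descriptives(
    threads: Sequence[Thread], reply_window: timedelta = timedelta(hours=24)
) -> ThreadDescriptives:
    """Descriptive statistics over threads.

    ``pct_reply_24h`` is the percentage of threads whose first reply arrived
    within ``reply_window`` of the starter (half-open window: a reply exactly
    at the boundary does not count).  ``pct_never_replied`` is the percentage
    of single-message threads.  Lifespans are last-minus-first timestamps in
    days.
    """
    if not threads:
        raise DomainError("thread_descriptives requires at least one thread")
    lengths = [len(t) for t in threads]
    lifespans = [
        (t.messages[-1].timestamp - t.messages[0].timestamp).total_seconds() / 86400.0
        for t in threads
    ]
    n = len(threads)
    replied_fast = sum(
        1
        for t in threads
        if t.first_reply is not None
        and (t.first_reply.timestamp - t.starter.timestamp) < reply_window
    )
    never = sum(1 for t in threads if t.first_reply is None)
    return ThreadDescriptives(
        n_threads=n,
        n_messages=sum(lengths),
        thread_length_median=float(statistics.median(lengths)),
        thread_length_mean=float(statistics.fmean(lengths)),
        thread_length_sd=float(statistics.stdev(lengths)) if n > 1 else 0.0,
        lifespan_median_days=float(statistics.median(lifespans)),
        lifespan_mean_days=float(statistics.fmean(lifespans)),
        lifespan_sd_days=float(statistics.stdev(lifespans)) if n > 1 else 0.0,
        pct_reply_24h=100.0 * replied_fast / n,
        pct_never_replied=100.0 * never / n,
    )
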