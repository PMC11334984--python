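"""Data model and I/O for call-event corpora.

A *session* is a fixed-length recording (default 1800 s) of one to three
callers; a *call* is a phee vocalization with an onset and offset in seconds
from session start.  All timing analyses in the package run on this
point-process representation.  Time is float seconds, 0-based; call intervals
are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default gap threshold (s) closing a conversation / qualifying a response.
#: The self/partner response curves return to baseline by ~4.6 s after a call
#: offset, so 10 s is a conservative upper bound on an exchange gap.
DEFAULT_RESPONSE_WINDOW = 10.0

REQUIRED_COLUMNS = ("session_id", "caller_id", "onset_s", "offset_s")


class SchemaError(ValueError):
    """A call table is missing required columns."""


@dataclass(frozen=True)
class CallRecord:
    """One vocalization: who called, when, and (optionally) pulse structure."""

    session_id: str
    caller_id: str
    onset: float
    offset: float
    pulse_onsets: tuple[float, ...] | None = None
    features: dict | None = None

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.offset <= self.onset:
            raise ValueError(
                f"offset must exceed onset, got [{self.onset}, {self.offset})"
            )
        if self.pulse_onsets is not None:
            p = np.asarray(self.pulse_onsets, float)
            if p.size and (
                np.any(np.diff(p) <= 0)
                or p[0] < self.onset
                or p[-1] > self.offset
            ):
                raise ValueError("pulse_onsets must be strictly increasing "
                                 "and lie within [onset, offset]")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class Session:
    """A recording session: roster of callers plus their sorted call train."""

    session_id: str
    duration: float = 1800.0
    context: str = "pair"
    roster: list[str] = field(default_factory=list)
    calls: list[CallRecord] = field(default_factory=list)

    _CONTEXT_SIZE = {"solo": 1, "pair": 2, "trio": 3}

    def __post_init__(self):
        if self.context not in self._CONTEXT_SIZE:
            raise ValueError(f"unknown context {self.context!r}")
        if self.roster and len(self.roster) != self._CONTEXT_SIZE[self.context]:
            raise ValueError(
                f"context {self.context!r} requires "
                f"{self._CONTEXT_SIZE[self.context]} callers, "
                f"roster has {len(self.roster)}"
            )
        for c in self.calls:
            if self.roster and c.caller_id not in self.roster:
                raise ValueError(f"caller {c.caller_id!r} not in roster")
            if c.offset > self.duration:
                raise ValueError(
                    f"call [{c.onset}, {c.offset}) extends past session "
                    f"duration {self.duration}"
                )
        self.calls = sorted(self.calls, key=lambda c: (c.onset, c.caller_id))

    def onsets(self, caller_id: str | None = None) -> np.ndarray:
        return np.array(
            [c.onset for c in self.calls
             if caller_id is None or c.caller_id == caller_id],
            dtype=float,
        )

    def calls_by(self, caller_id: str) -> list[CallRecord]:
        return [c for c in self.calls if c.caller_id == caller_id]

    def call_rate(self, caller_id: str) -> float:
        """Calls per session by one caller (volubility)."""
        return float(len(self.calls_by(caller_id)))


@dataclass(frozen=True)
class ConversationSegment:
    """A maximal run of calls with successive gaps <= the response window."""

    call_indices: tuple[int, ...]
    participants: frozenset[str]

    @property
    def n_calls(self) -> int:
        return len(self.call_indices)


@dataclass(frozen=True)
class RateSeries:
    """Rolling calling rate: calls per ``window_length`` s, stepped by ``step`` s."""

    caller_id: str
    window_length: float
    step: float
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# I/O


def corpus_to_frame(corpus: list[Session]) -> pd.DataFrame:
    rows = []
    for s in corpus:
        for c in s.calls:
            rows.append(
                {"session_id": s.session_id, "caller_id": c.caller_id,
                 "onset_s": c.onset, "offset_s": c.offset}
            )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_call_table(corpus: list[Session], path, manifest_path=None) -> None:
    """Write a corpus as a call-table CSV plus an optional sessions manifest."""
    corpus_to_frame(corpus).to_csv(path, index=False)
    if manifest_path is not None:
        pd.DataFrame(
            [{"session_id": s.session_id, "duration": s.duration,
              "context": s.context, "roster": "|".join(s.roster)}
             for s in corpus]
        ).to_csv(manifest_path, index=False)


def read_call_table(path, manifest_path=None,
                    default_duration: float = 1800.0) -> list[Session]:
    """Read a call-table CSV (and optional manifest) into Session objects.

    Without a manifest, the roster is inferred from the callers observed in
    each session and the context from the roster size.  Malformed rows raise
    a ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"call table missing required columns: {missing}")
    meta = None
    if manifest_path is not None:
        meta = pd.read_csv(manifest_path).set_index("session_id")
    sessions = []
    for sid, grp in df.groupby("session_id", sort=True):
        calls = []
        for idx, row in grp.iterrows():
            try:
                calls.append(
                    CallRecord(str(sid), str(row["caller_id"]),
                               float(row["onset_s"]), float(row["offset_s"]))
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"row {idx}: {exc}") from exc
        if meta is not None and sid in meta.index:
            m = meta.loc[sid]
            roster = [r for r in str(m["roster"]).split("|") if r]
            sessions.append(Session(str(sid), float(m["duration"]),
                                    str(m["context"]), roster, calls))
        else:
            roster = sorted({c.caller_id for c in calls})
            context = {1: "solo", 2: "pair", 3: "trio"}.get(len(roster))
            if context is None:
                raise ValueError(
                    f"session {sid!r}: {len(roster)} callers observed and no "
                    "manifest supplied"
                )
            sessions.append(
                Session(str(sid), default_duration, context, roster, calls)
            )
    return sessions


# ---------------------------------------------------------------------------
# Event labelling


def label_events(session: Session,
                 response_window: float = DEFAULT_RESPONSE_WINDOW,
                 ) -> pd.DataFrame:
    """Label each call as response and/or interruption.

    A call is *interrupting* when its onset lies inside another caller's
    ongoing call ``[onset, offset)``; the later-starting call carries the
    flag, and simultaneous onsets flag both.  A call is a *response* when the
    gap from the most recent other-caller offset to its onset lies in
    ``(0, response_window]``; ``responder_delay`` is that gap (NaN otherwise).
    """
    if response_window <= 0:
        raise ValueError("response_window must be > 0")
    calls = session.calls
    n = len(calls)
    is_resp = np.zeros(n, bool)
    delay = np.full(n, np.nan)
    is_int = np.zeros(n, bool)
    for i, c in enumerate(calls):
        prev_off = -np.inf
        for j, o in enumerate(calls):
            if o.caller_id == c.caller_id:
                continue
            # interruption: onset inside the other's call (tie flags both)
            if (o.onset < c.onset < o.offset) or (o.onset == c.onset and j != i):
                is_int[i] = True
            if o.offset < c.onset:
                prev_off = max(prev_off, o.offset)
        gap = c.onset - prev_off
        if 0 < gap <= response_window:
            is_resp[i] = True
            delay[i] = gap
    return pd.DataFrame(
        {"caller_id": [c.caller_id for c in calls],
         "onset": [c.onset for c in calls],
         "offset": [c.offset for c in calls],
         "is_response": is_resp,
         "responder_delay": delay,
         "is_interrupting": is_int}
    )


def segment_conversations(session: Session,
                          response_window: float = DEFAULT_RESPONSE_WINDOW,
                          ) -> list[ConversationSegment]:
    """Split a session into conversation segments.

    A segment is a maximal run of calls (any caller, self-runs included)
    in which each call starts no more than ``response_window`` s after the
    previous call's offset.  Singleton calls form no segment.
    """
    calls = session.calls
    segments: list[ConversationSegment] = []
    run: list[int] = []
    for i, c in enumerate(calls):
        if run and c.onset - calls[run[-1]].offset <= response_window:
            run.append(i)
        else:
            if len(run) >= 2:
                segments.append(_make_segment(calls, run))
            run = [i]
    if len(run) >= 2:
        segments.append(_make_segment(calls, run))
    return segments


def _make_segment(calls, run):
    return ConversationSegment(
        call_indices=tuple(run),
        participants=frozenset(calls[i].caller_id for i in run),
    )


def rolling_rate(session: Session, caller_id: str,
                 window_length: float = 180.0, step: float = 30.0,
                 ) -> RateSeries:
    """Rolling calling rate: calls per window, windows stepped through the
    session.  For an 1800 s session with the 180 s / 30 s defaults this yields
    55 windows."""
    if session.duration < window_length:
        raise ValueError("session shorter than rate window")
    n_windows = int(np.floor((session.duration - window_length) / step)) + 1
    onsets = session.onsets(caller_id)
    starts = np.arange(n_windows) * step
    values = np.array(
        [np.count_nonzero((onsets >= t0) & (onsets < t0 + window_length))
         for t0 in starts],
        dtype=float,
    )
    return RateSeries(caller_id, window_length, step, values)


# ---------------------------------------------------------------------------
# Shuffle control


def shuffle_pairs(corpus: list[Session], n_shuffles: int,
                  seed: int | np.random.Generator = 0) -> list[Session]:
    """Build virtual pair sessions by combining call trains across sessions.

    Each virtual session takes one caller's train from one real session and a
    different caller's train from a *different* session, so any coordination
    between the two trains is destroyed while every marginal train statistic
    (call count, ICI distribution, call lengths) is preserved exactly.
    """
    if len(corpus) < 2:
        raise ValueError("shuffle control needs at least 2 sessions")
    rng = np.random.default_rng(seed)
    trains = [(si, cid) for si, s in enumerate(corpus) for cid in s.roster]
    legal = [(a, b) for a, b in itertools.permutations(range(len(trains)), 2)
             if trains[a][0] != trains[b][0]]
    out = []
    idx = rng.choice(len(legal), size=n_shuffles, replace=n_shuffles > len(legal))
    for k, ii in enumerate(idx):
        a, b = legal[ii]
        (sa, ca), (sb, cb) = trains[a], trains[b]
        dur = min(corpus[sa].duration, corpus[sb].duration)
        sid = f"shuffle_{k}"
        calls = []
        for src, cid, alias in ((corpus[sa], ca, "A"), (corpus[sb], cb, "B")):
            for c in src.calls_by(cid):
                if c.offset <= dur:
                    calls.append(replace(c, session_id=sid, caller_id=alias))
        out.append(Session(sid, dur, "pair", ["A", "B"], calls))
    return out
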