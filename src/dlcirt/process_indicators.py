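"""Extraction of engagement indicators from raw assessment event logs.

Turns navigation / option-selection event streams into page visits,
item response times, and the three encounter-level indicators:
answer change, text reread, and item revisit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import InvalidArgumentError

__all__ = [
    "LogEvent",
    "PageVisit",
    "IndicatorCounts",
    "ParseReport",
    "parse_event_log",
    "filter_navigation",
    "build_page_visits",
    "response_time",
    "count_answer_changes",
    "count_text_rereads",
    "count_item_revisits",
    "dichotomize",
    "extract_indicator_counts",
    "assemble_encounters",
    "item_summary",
    "EVENT_LOG_COLUMNS",
]

EVENT_LOG_COLUMNS = ("person_id", "seq", "timestamp_ms", "kind", "page_id",
                     "page_kind", "task_id", "item_id", "option_id")

EVENT_KINDS = ("navigate", "select_option")
PAGE_KINDS = ("text", "item", "other")


@dataclass(frozen=True)
class LogEvent:
    person_id: object
    seq: int
    timestamp_ms: int
    kind: str
    page_id: object
    page_kind: str = "other"
    task_id: object = None
    item_id: object = None
    option_id: object = None


@dataclass
class PageVisit:
    person_id: object
    page_id: object
    page_kind: str
    task_id: object
    item_id: object
    t_start: int
    t_end: int
    unterminated: bool = False
    selections: list = field(default_factory=list)

    @property
    def duration_ms(self) -> int:
        return self.t_end - self.t_start


@dataclass
class IndicatorCounts:
    person_id: object
    item_id: object
    rt_seconds: float | None
    n_answer_change: int
    n_text_reread: int
    n_item_revisit: int

    @property
    def visited(self) -> bool:
        return self.rt_seconds is not None


@dataclass
class ParseReport:
    n_rows: int = 0
    n_events: int = 0
    rejects: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_event_log(source, sep: str = "\t") -> tuple:
    """Read a delimited event log into per-person, time-sorted events.

    Returns ``(events, report)``; malformed rows end up in
    ``report.rejects`` as ``(row_number, reason)`` pairs.
    """
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"event log missing columns: {missing}")

    report = ParseReport(n_rows=len(df))
    events = []

    def _id(raw):
        # numeric-looking identifiers become ints so ids join cleanly
        # with scored-response tables
        if not raw:
            return None
        try:
            return int(raw)
        except ValueError:
            return raw

    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            kind = row.kind
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")
            if kind == "select_option" and not row.option_id:
                raise ValueError("select_option without option_id")
            if kind == "select_option" and not row.item_id:
                raise ValueError("select_option without item_id")
            page_kind = row.page_kind or "other"
            if page_kind not in PAGE_KINDS:
                raise ValueError(f"unknown page kind {page_kind!r}")
            events.append(LogEvent(
                person_id=_id(row.person_id),
                seq=int(row.seq),
                timestamp_ms=int(row.timestamp_ms),
                kind=kind,
                page_id=row.page_id or None,
                page_kind=page_kind,
                task_id=row.task_id or None,
                item_id=_id(row.item_id),
                option_id=row.option_id or None,
            ))
        except (TypeError, ValueError) as exc:
            report.rejects.append((row_no, str(exc)))
    events.sort(key=lambda e: (str(e.person_id), e.timestamp_ms, e.seq))
    report.n_events = len(events)
    return events, report


def _by_person(events: Iterable[LogEvent]) -> dict:
    groups: dict = {}
    for e in events:
        groups.setdefault(e.person_id, []).append(e)
    for person_events in groups.values():
        person_events.sort(key=lambda e: (e.timestamp_ms, e.seq))
    return groups


def _page_order(page_id) -> object:
    """Sort key for page ids: trailing integer when present, else the id."""
    s = str(page_id)
    digits = ""
    for ch in reversed(s):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    if digits:
        return (s[: len(s) - len(digits)], int(digits))
    return (s, -1)


# ---------------------------------------------------------------------------
# navigation filter
# ---------------------------------------------------------------------------


def filter_navigation(events: Sequence[LogEvent],
                      min_dwell_ms: int = 1000) -> list:
    """Drop pass-through navigation events.

    A navigation event is removed when the page visit it opens lasts less
    than ``min_dwell_ms`` AND the next navigation continues in the same
    direction through the page sequence.  Selection events are never
    removed.  Applied to a fixpoint, so the operation is idempotent.
    """
    if min_dwell_ms <= 0:
        return list(events)
    out = []
    for person_events in _by_person(events).values():
        current = person_events
        while True:
            filtered = _filter_pass(current, min_dwell_ms)
            if len(filtered) == len(current):
                break
            current = filtered
        out.extend(current)
    out.sort(key=lambda e: (str(e.person_id), e.timestamp_ms, e.seq))
    return out


def _filter_pass(person_events: Sequence[LogEvent], min_dwell_ms: int) -> list:
    navs = [i for i, e in enumerate(person_events) if e.kind == "navigate"]
    drop = set()
    for k, i in enumerate(navs):
        if k == 0 or k + 1 >= len(navs):
            continue
        e_prev = person_events[navs[k - 1]]
        e = person_events[i]
        e_next = person_events[navs[k + 1]]
        dwell = e_next.timestamp_ms - e.timestamp_ms
        if dwell >= min_dwell_ms:
            continue
        d_in = _direction(e_prev.page_id, e.page_id)
        d_out = _direction(e.page_id, e_next.page_id)
        if d_in != 0 and d_in == d_out:
            drop.add(i)
    return [e for i, e in enumerate(person_events) if i not in drop]


def _direction(page_a, page_b) -> int:
    ka, kb = _page_order(page_a), _page_order(page_b)
    if ka < kb:
        return 1
    if ka > kb:
        return -1
    return 0


# ---------------------------------------------------------------------------
# page visits and indicator counts
# ---------------------------------------------------------------------------


def build_page_visits(events: Sequence[LogEvent]) -> list:
    """Delimit page visits by consecutive navigation events.

    The final visit of a session has no leaving click; it is closed at the
    person's last event and flagged ``unterminated``.  Selection events are
    attached to the visit containing their timestamp.
    """
    visits = []
    for person_events in _by_person(events).values():
        person_visits = []
        navs = [e for e in person_events if e.kind == "navigate"]
        if not navs:
            continue
        last_t = person_events[-1].timestamp_ms
        for k, e in enumerate(navs):
            if k + 1 < len(navs):
                t_end, open_end = navs[k + 1].timestamp_ms, False
            else:
                t_end, open_end = max(last_t, e.timestamp_ms), True
            person_visits.append(PageVisit(
                person_id=e.person_id, page_id=e.page_id,
                page_kind=e.page_kind, task_id=e.task_id,
                item_id=e.item_id, t_start=e.timestamp_ms, t_end=t_end,
                unterminated=open_end))
        for e in person_events:
            if e.kind != "select_option":
                continue
            target = None
            for v in person_visits:
                if v.t_start <= e.timestamp_ms < v.t_end or (
                        v.unterminated and v.t_start <= e.timestamp_ms):
                    target = v
            if target is None:
                # outside any visit: attach to the nearest preceding visit
                preceding = [v for v in person_visits
                             if v.t_start <= e.timestamp_ms]
                target = preceding[-1] if preceding else None
            if target is not None:
                target.selections.append(e)
        visits.extend(person_visits)
    return visits


def response_time(visits: Sequence[PageVisit], person_id,
                  item_id) -> float | None:
    """Total seconds spent on the item's page across visits; None if never
    visited."""
    ms = [v.duration_ms for v in visits
          if v.person_id == person_id and v.item_id == item_id
          and v.page_kind == "item"]
    if not ms:
        return None
    return sum(ms) / 1000.0


def count_answer_changes(events: Sequence[LogEvent], person_id,
                         item_id) -> int:
    """Selections of a response option differing from the previously
    selected option of the same item."""
    last = None
    n = 0
    for e in sorted((e for e in events
                     if e.kind == "select_option"
                     and e.person_id == person_id and e.item_id == item_id),
                    key=lambda e: (e.timestamp_ms, e.seq)):
        if last is not None and e.option_id != last:
            n += 1
        last = e.option_id
    return n


def count_text_rereads(events: Sequence[LogEvent], person_id,
                       item_id) -> int:
    """Navigations leaving the item's page for a text page of the same task."""
    person_events = [e for e in events if e.person_id == person_id]
    person_events.sort(key=lambda e: (e.timestamp_ms, e.seq))
    navs = [e for e in person_events if e.kind == "navigate"]
    n = 0
    for prev, cur in zip(navs, navs[1:]):
        if (prev.page_kind == "item" and prev.item_id == item_id
                and cur.page_kind == "text"
                and cur.task_id == prev.task_id):
            n += 1
    return n


def count_item_revisits(visits: Sequence[PageVisit], person_id,
                        item_id) -> int:
    """Returns to the item's page with at least one *other* item's page
    visited in between (text-page returns alone do not count)."""
    person_visits = sorted(
        (v for v in visits if v.person_id == person_id),
        key=lambda v: v.t_start)
    n = 0
    seen_item_before = False
    other_item_since = False
    for v in person_visits:
        if v.page_kind == "item" and v.item_id == item_id:
            if seen_item_before and other_item_since:
                n += 1
            seen_item_before = True
            other_item_since = False
        elif v.page_kind == "item" and v.item_id is not None:
            other_item_since = True
    return n


def dichotomize(count):
    """1 if the behavior occurred at least once, 0 otherwise; None passes
    through."""
    if count is None:
        return None
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise InvalidArgumentError("counts must be non-negative")
    out = (arr >= 1).astype(int)
    return int(out) if out.ndim == 0 else out


def extract_indicator_counts(events: Sequence[LogEvent],
                             min_dwell_ms: int = 1000) -> list:
    """Full pipeline: filter navigation, build visits, count indicators for
    every person x item page encountered."""
    filtered = filter_navigation(events, min_dwell_ms)
    visits = build_page_visits(filtered)
    pairs = sorted({(v.person_id, v.item_id) for v in visits
                    if v.page_kind == "item" and v.item_id is not None},
                   key=lambda t: (str(t[0]), str(t[1])))
    out = []
    for person_id, item_id in pairs:
        out.append(IndicatorCounts(
            person_id=person_id, item_id=item_id,
            rt_seconds=response_time(visits, person_id, item_id),
            n_answer_change=count_answer_changes(filtered, person_id, item_id),
            n_text_reread=count_text_rereads(filtered, person_id, item_id),
            n_item_revisit=count_item_revisits(visits, person_id, item_id),
        ))
    return out


# ---------------------------------------------------------------------------
# encounter assembly
# ---------------------------------------------------------------------------


def assemble_encounters(counts: Sequence[IndicatorCounts],
                        responses: pd.DataFrame,
                        item_bank=None) -> pd.DataFrame:
    """Join indicator counts with scored responses into an encounter table.

    ``responses`` needs columns person_id, item_id, y.  Encounters with a
    non-positive or missing response time get all four indicators set to
    missing.  Output columns follow the model-core encounter format.
    """
    cdf = pd.DataFrame([{
        "person_id": c.person_id, "item_id": c.item_id,
        "rt_seconds": c.rt_seconds,
        "ac_count": c.n_answer_change,
        "tr_count": c.n_text_reread,
        "iv_count": c.n_item_revisit,
    } for c in counts])
    if not cdf.empty and cdf.duplicated(["person_id", "item_id"]).any():
        raise InvalidArgumentError("duplicate person x item indicator rows")
    if responses.duplicated(["person_id", "item_id"]).any():
        raise InvalidArgumentError("duplicate person x item response rows")
    cols = ["person_id", "item_id", "y", "rt_seconds",
            "ac_count", "tr_count", "iv_count"]
    if cdf.empty and responses.empty:
        return pd.DataFrame(columns=cols)
    if cdf.empty:
        merged = responses[["person_id", "item_id", "y"]].copy()
        for c in cols[3:]:
            merged[c] = np.nan
    else:
        merged = responses[["person_id", "item_id", "y"]].merge(
            cdf, on=["person_id", "item_id"], how="outer")
    bad_rt = merged["rt_seconds"].isna() | (merged["rt_seconds"] <= 0)
    merged.loc[bad_rt, ["rt_seconds", "ac_count", "tr_count", "iv_count"]] = np.nan
    return merged.sort_values(["person_id", "item_id"]).reset_index(drop=True)


def item_summary(encounters: pd.DataFrame) -> pd.DataFrame:
    """Per-item descriptives: N, response-time mean/SD, percent correct,
    percent with each indicator occurring at least once."""
    rows = []
    for item_id, g in encounters.groupby("item_id", sort=True):
        with_y = g[g["y"].isin([0, 1])]
        rt = g["rt_seconds"].dropna()
        def _pct_once(col):
            c = g[col].dropna()
            return float((c >= 1).mean() * 100.0) if len(c) else np.nan
        rows.append({
            "item_id": item_id,
            "n_encounters": int(len(with_y)),
            "rt_mean": float(rt.mean()) if len(rt) else np.nan,
            "rt_sd": float(rt.std(ddof=1)) if len(rt) > 1 else np.nan,
            "pct_correct": (float(with_y["y"].mean() * 100.0)
                            if len(with_y) else np.nan),
            "pct_answer_change": _pct_once("ac_count"),
            "pct_text_reread": _pct_once("tr_count"),
            "pct_item_revisit": _pct_once("iv_count"),
        })
    return pd.DataFrame(rows)
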