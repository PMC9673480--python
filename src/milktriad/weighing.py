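"""24-hour test-weighing: milk intake from pre/post-feed infant weights.

A mother weighs the infant immediately before and after every feed over a
24-h window starting at 08:00; the weight difference of each feed, in grams,
is the milk intake of that feed, reported as mL (density 1 g/mL). Quality
control marks single feeds above 400 g as unrealistically high (missing),
discards logs with more than 3 missing feeds, and hot-deck imputes the rest
from neighbouring feeds of the same log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeedEvent",
    "FeedLog",
    "IntakeSummary",
    "SPIKE_LIMIT_G",
    "MAX_MISSING_FEEDS",
    "feed_volume",
    "qc_feed_log",
    "hot_deck_impute",
    "summarize_intake",
    "process_feed_log",
    "feed_logs_from_frame",
    "feed_logs_to_frame",
]

#: single feeds above this weight difference are marked missing
SPIKE_LIMIT_G: float = 400.0
#: logs with more than this many missing feeds are discarded
MAX_MISSING_FEEDS: int = 3


@dataclass(frozen=True)
class FeedEvent:
    """One breastfeed: time and infant weight before/after (grams)."""

    start_time: pd.Timestamp
    pre_weight_g: float | None
    post_weight_g: float | None
    breast: str = "unknown"

    def __post_init__(self) -> None:
        for w in (self.pre_weight_g, self.post_weight_g):
            if w is not None and not math.isnan(w) and w <= 0:
                raise ValueError("weights must be positive when present")


@dataclass
class FeedLog:
    """An ordered 24-h protocol of feed events for one dyad-visit."""

    dyad_id: int
    visit: str
    events: list[FeedEvent]
    window_start: pd.Timestamp | None = None
    volume_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.start_time for e in self.events]
        if times != sorted(times):
            raise ValueError("feed events must be sorted by start time")
        if self.window_start is not None and times:
            span = times[-1] - self.window_start
            if times[0] < self.window_start or span >= pd.Timedelta(hours=24):
                raise ValueError("all feeds must fall within the 24-h window")


@dataclass(frozen=True)
class IntakeSummary:
    """Daily intake summary for one log; volumes in mL."""

    dyad_id: int
    visit: str
    total_24h_ml: float | None
    per_feed_ml: float | None
    per_kg_ml: float | None
    n_feeds: int
    n_missing: int
    n_imputed: int
    n_spike_excluded: int
    status: str  # 'ok' | 'discarded'


def feed_volume(event: FeedEvent, accuracy_g: float = 5.0) -> float | None:
    """Milk volume of a single feed, or None when it cannot be estimated.

    The volume is the post-pre weight difference in grams, reported as mL
    (density 1 g/mL). A feed with either weight absent, or with a negative
    difference (physically impossible intake), yields None — missingness is
    a value here, not an error. ``accuracy_g`` documents the scale precision
    and is retained for rounding-aware consumers; it does not alter the
    difference.
    """
    pre, post = event.pre_weight_g, event.post_weight_g
    if pre is None or post is None:
        return None
    if isinstance(pre, float) and math.isnan(pre):
        return None
    if isinstance(post, float) and math.isnan(post):
        return None
    diff = post - pre
    if diff < 0:
        return None
    return float(diff)


def _volumes(log: FeedLog) -> list[float | None]:
    return [feed_volume(e) for e in log.events]


def qc_feed_log(log: FeedLog) -> tuple[FeedLog, bool]:
    """Apply quality control; returns the flagged log and a discard verdict.

    Feeds above 400 g are unrealistically high and marked missing BEFORE the
    missing count is taken (spike exclusion precedes the >3-missing rule).
    A log with more than 3 missing feeds after spike exclusion is discarded.
    """
    if not log.events:
        raise ValueError("feed log has no events")
    flags: list[str] = []
    for v in _volumes(log):
        if v is None:
            flags.append("missing")
        elif v > SPIKE_LIMIT_G:
            flags.append("spike")
        else:
            flags.append("ok")
    flagged = replace(log, volume_flags=flags)
    n_missing = sum(f != "ok" for f in flags)
    return flagged, n_missing > MAX_MISSING_FEEDS


def hot_deck_impute(log: FeedLog) -> tuple[FeedLog, list[float]]:
    """Fill missing feed volumes from neighbouring feeds of the same log.

    Donor rule (deterministic, no RNG): the nearest feed with an observed
    volume by event index, preferring the preceding feed; when there is no
    preceding donor, or on a distance tie, the nearest following feed is
    used. Requires the log to have passed QC (``qc_feed_log`` discard
    verdict False). Returns the log and the complete per-feed volume list.
    """
    if not log.volume_flags:
        log, discard = qc_feed_log(log)
        if discard:
            raise ValueError("log was discarded by QC; imputation undefined")
    vols = _volumes(log)
    observed = [
        (i, v)
        for i, (v, f) in enumerate(zip(vols, log.volume_flags))
        if f == "ok" and v is not None
    ]
    if not observed:
        raise ValueError("all feeds missing; no hot-deck donor available")
    filled: list[float] = []
    for i, flag in enumerate(log.volume_flags):
        if flag == "ok":
            filled.append(float(vols[i]))
            continue
        # nearest observed index; preceding wins ties
        best = min(observed, key=lambda iv: (abs(iv[0] - i), iv[0] > i))
        filled.append(float(best[1]))
    return log, filled


def summarize_intake(
    log: FeedLog, infant_weight_kg: float | None = None
) -> IntakeSummary:
    """Daily total, per-feed and per-kg milk intake for a QC'd log.

    Imputation is applied if needed; the per-feed denominator counts every
    feed with a (possibly imputed) volume. Discarded logs have no summary.
    """
    flagged, discard = qc_feed_log(log)
    n_spikes = sum(f == "spike" for f in flagged.volume_flags)
    n_missing = sum(f != "ok" for f in flagged.volume_flags)
    if discard:
        return IntakeSummary(
            dyad_id=log.dyad_id, visit=log.visit,
            total_24h_ml=None, per_feed_ml=None, per_kg_ml=None,
            n_feeds=len(log.events), n_missing=n_missing,
            n_imputed=0, n_spike_excluded=n_spikes, status="discarded",
        )
    _, vols = hot_deck_impute(flagged)
    total = float(sum(vols))
    n_feeds = len(vols)
    per_kg = None
    if infant_weight_kg is not None:
        if infant_weight_kg <= 0:
            raise ValueError("infant weight must be positive")
        per_kg = total / infant_weight_kg
    return IntakeSummary(
        dyad_id=log.dyad_id, visit=log.visit,
        total_24h_ml=total, per_feed_ml=total / n_feeds, per_kg_ml=per_kg,
        n_feeds=n_feeds, n_missing=n_missing, n_imputed=n_missing,
        n_spike_excluded=n_spikes, status="ok",
    )


def process_feed_log(
    log: FeedLog, infant_weight_kg: float | None = None
) -> IntakeSummary:
    """QC + imputation + summary in one call (summary for discarded logs
    carries ``status='discarded'`` and None volumes)."""
    return summarize_intake(log, infant_weight_kg)


def feed_logs_from_frame(frame: pd.DataFrame) -> list[FeedLog]:
    """Build FeedLog objects from a tidy events table.

    Expected columns: dyad_id, visit, event_index, start_time (ISO-8601),
    pre_weight_g, post_weight_g, breast. Empty cells are missing weights.
    """
    logs = []
    for (dyad, visit), grp in frame.groupby(["dyad_id", "visit"], sort=True):
        grp = grp.sort_values("event_index")
        events = [
            FeedEvent(
                start_time=pd.Timestamp(r.start_time),
                pre_weight_g=None if pd.isna(r.pre_weight_g) else float(r.pre_weight_g),
                post_weight_g=None if pd.isna(r.post_weight_g) else float(r.post_weight_g),
                breast=getattr(r, "breast", "unknown"),
            )
            for r in grp.itertuples()
        ]
        logs.append(FeedLog(dyad_id=int(dyad), visit=str(visit), events=events))
    return logs


def feed_logs_to_frame(logs: list[FeedLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for i, e in enumerate(log.events):
            rows.append(
                dict(
                    dyad_id=log.dyad_id, visit=log.visit, event_index=i,
                    start_time=e.start_time.isoformat(),
                    pre_weight_g=e.pre_weight_g, post_weight_g=e.post_weight_g,
                    breast=e.breast,
                )
            )
    return pd.DataFrame(rows)


def summarize_all(
    logs: list[FeedLog], weights: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Intake summaries for a collection of logs as a tidy table.

    ``weights`` optionally maps (dyad_id, visit) to infant_weight_kg so the
    per-kg intake can be filled in.
    """
    wmap = {}
    if weights is not None:
        wmap = {
            (int(r.dyad_id), str(r.visit)): float(r.infant_weight_kg)
            for r in weights.itertuples()
            if not np.isnan(r.infant_weight_kg)
        }
    rows = []
    for log in logs:
        s = summarize_intake(log, wmap.get((log.dyad_id, log.visit)))
        rows.append(s.__dict__)
    return pd.DataFrame(rows)
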