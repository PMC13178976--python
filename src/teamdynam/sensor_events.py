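"""Parsing and aggregation of proximity-badge infrared detections.

Raw badge logs register up to ~50 infrared detections per minute while two
participants face each other, so raw detection counts track scan frequency
rather than distinct social exchanges.  Detections of the same dyad falling
into the same tumbling 75-second window are therefore collapsed into a single
undirected relational event, provided the window holds at least two
detections (a lone detection is treated as an aleatory passing-by).

Windows are anchored at the team-study origin (time 0); because 86400 is an
integer multiple of 75 the anchoring is equivalently per civil day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import DAY_S, MIN_DETECTIONS, WINDOW_S

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input row; message carries the 1-based line number."""


class RosterError(ValueError):
    """Badge id that does not resolve to a known actor."""


class ScheduleError(ValueError):
    """Invalid on/off state machine in a presence log."""


@dataclass(frozen=True)
class DetectionLog:
    """Time-sorted raw infrared detections.

    ``records`` has columns ``time`` (seconds since team-study start,
    float), ``badge_a`` and ``badge_b`` (actor ids, ``badge_a != badge_b``).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.records["time"].to_numpy()
        if len(t) and (np.any(t < 0) or np.any(np.diff(t) < 0)):
            raise ParseError("detection times must be non-negative and sorted")
        if len(self.records) and (
            self.records["badge_a"] == self.records["badge_b"]
        ).any():
            raise ParseError("self-detections (badge_a == badge_b) are impossible")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class PresenceSchedule:
    """Half-open on-intervals ``[on, off)`` per actor, in seconds."""

    intervals: dict[str, list[tuple[float, float]]]

    def is_present(self, actor: str, t: float) -> bool:
        return any(on <= t < off for on, off in self.intervals.get(actor, ()))

    def available(self, actors: list[str], t: float) -> np.ndarray:
        """Boolean availability mask over ``actors`` at time ``t``."""
        return np.array([self.is_present(a, t) for a in actors], dtype=bool)

    def total_on_time(self, actor: str) -> float:
        return sum(off - on for on, off in self.intervals.get(actor, ()))


@dataclass
class EventSequence:
    """Ordered undirected relational events for one team.

    ``events`` has columns ``time_s``, ``i``, ``j`` with ``i < j``
    lexicographically; row order (time, i, j) is the authoritative event
    order, simultaneous timestamps included.
    """

    events: pd.DataFrame
    team: str
    context: str
    dropped_detections: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)


def _normalize_times(raw: pd.Series, origin: float | None) -> pd.Series:
    """Accept epoch/relative seconds or ISO-8601 strings; return seconds.

    String timestamps are converted to epoch seconds; ``origin`` (epoch
    seconds) is subtracted, defaulting to midnight of the earliest day so
    that day boundaries stay aligned at multiples of 86400.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        times = numeric.astype(float)
        if origin is not None:
            times = times - origin
        return times
    if numeric.notna().any():  # mixed numeric / non-numeric: bad row
        raise ParseError(
            f"malformed time at line {int(numeric.isna().idxmax()) + 2}"
        )
    stamps = pd.to_datetime(raw, errors="raise", utc=True, format="ISO8601")
    epoch = stamps.astype("int64") / 1e9
    if origin is None:
        origin = float(np.floor(epoch.min() / DAY_S) * DAY_S)
    return epoch - origin


def parse_detection_log(
    path, roster_ids, origin: float | None = None
) -> DetectionLog:
    """Read a ``time,badge_a,badge_b`` CSV and return a sorted DetectionLog.

    Parameters
    ----------
    path
        CSV/TSV file with header ``time,badge_a,badge_b``.
    roster_ids
        Iterable of known actor ids; unknown badges raise :class:`RosterError`.
    origin
        Optional epoch origin subtracted from the timestamps.
    """
    known = set(roster_ids)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read detection log {path}: {exc}") from exc
    expected = ["time", "badge_a", "badge_b"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"expected header {expected}, got {list(df.columns)}")
    if df.empty:
        return DetectionLog(pd.DataFrame(columns=["time", "badge_a", "badge_b"]))
    bad = df[expected].isna().any(axis=1)
    if bad.any():
        raise ParseError(f"malformed row at line {int(bad.idxmax()) + 2}")
    try:
        times = _normalize_times(df["time"], origin)
    except Exception as exc:
        raise ParseError(f"unparseable timestamps: {exc}") from exc
    if times.isna().any():
        raise ParseError(
            f"malformed time at line {int(times.isna().idxmax()) + 2}"
        )
    same = df["badge_a"] == df["badge_b"]
    if same.any():
        raise ParseError(
            f"self-detection at line {int(same.idxmax()) + 2}"
        )
    for col in ("badge_a", "badge_b"):
        unknown = ~df[col].isin(known)
        if unknown.any():
            raise RosterError(
                f"unknown badge {df[col][unknown].iloc[0]!r} "
                f"at line {int(unknown.idxmax()) + 2}"
            )
    out = pd.DataFrame(
        {"time": times.astype(float), "badge_a": df["badge_a"], "badge_b": df["badge_b"]}
    )
    out = out.sort_values("time", kind="stable").reset_index(drop=True)
    return DetectionLog(out)


def build_presence_schedule(on_off_log: pd.DataFrame) -> PresenceSchedule:
    """Convert a ``badge,state,time`` log into half-open presence intervals.

    States must alternate on/off per badge; an ``off`` with no prior ``on``
    raises :class:`ScheduleError`; a dangling ``on`` is closed at the end of
    its civil day (next multiple of 86400 s).
    """
    required = {"badge", "state", "time"}
    if not required.issubset(on_off_log.columns):
        raise ScheduleError(f"presence log needs columns {sorted(required)}")
    intervals: dict[str, list[tuple[float, float]]] = {}
    df = on_off_log.copy()
    df["time"] = pd.to_numeric(df["time"])
    df = df.sort_values("time", kind="stable")
    open_at: dict[str, float] = {}
    for _, row in df.iterrows():
        badge, state, t = str(row["badge"]), str(row["state"]), float(row["time"])
        if state not in ("on", "off"):
            raise ScheduleError(f"unknown state {state!r} for badge {badge}")
        if state == "on":
            if badge in open_at:
                raise ScheduleError(f"badge {badge}: 'on' at {t} while already on")
            open_at[badge] = t
        else:
            if badge not in open_at:
                raise ScheduleError(f"badge {badge}: 'off' at {t} with no prior 'on'")
            on = open_at.pop(badge)
            if t <= on:
                raise ScheduleError(f"badge {badge}: off {t} <= on {on}")
            intervals.setdefault(badge, []).append((on, t))
    for badge, on in open_at.items():  # dangling on: close at end-of-day
        end = (np.floor(on / DAY_S) + 1) * DAY_S
        intervals.setdefault(badge, []).append((on, float(end)))
    for badge, ivs in intervals.items():
        ivs.sort()
        for (a0, a1), (b0, _) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ScheduleError(f"badge {badge}: overlapping intervals")
    return PresenceSchedule(intervals)


def aggregate_detections(
    log: DetectionLog,
    presence: PresenceSchedule,
    team: str = "team",
    context: str = "uni",
    window_s: float = WINDOW_S,
    min_detections: int = MIN_DETECTIONS,
    tie_shuffle_seed: int | None = None,
) -> EventSequence:
    """Collapse raw detections into undirected relational events.

    For every dyad and every tumbling window of ``window_s`` seconds that
    contains at least ``min_detections`` detections of that dyad, exactly one
    event is emitted, timestamped at the first detection in the window.
    Consecutive qualifying windows are deliberately not merged: a long
    interaction yields a run of events, which is what the model's recency and
    inertia statistics feed on.  Qualifying windows at which either actor is
    outside their presence schedule are dropped with a warning (the schedule
    is authoritative).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if min_detections < 1:
        raise ValueError("min_detections must be >= 1")
    if len(log) == 0:
        empty = pd.DataFrame(columns=["time_s", "i", "j"])
        return EventSequence(empty, team=team, context=context)
    df = log.records.copy()
    a = df["badge_a"].to_numpy()
    b = df["badge_b"].to_numpy()
    df["i"] = np.minimum(a, b)
    df["j"] = np.maximum(a, b)
    df["window"] = np.floor(df["time"].to_numpy() / window_s).astype(np.int64)
    rows = []
    dropped = 0
    grouped = df.groupby(["i", "j", "window"], sort=False)
    for (i, j, _w), grp in grouped:
        if len(grp) < min_detections:
            dropped += len(grp)
            continue
        t0 = float(grp["time"].min())
        if not (presence.is_present(i, t0) and presence.is_present(j, t0)):
            dropped += len(grp)
            logger.warning(
                "dropping event (%s,%s) at t=%.1f: actor absent per schedule",
                i, j, t0,
            )
            continue
        rows.append((t0, i, j))
    events = pd.DataFrame(rows, columns=["time_s", "i", "j"])
    if tie_shuffle_seed is not None:
        # optional: randomise the order of simultaneous events (the
        # default deterministic (time, i, j) order is a convention)
        rng = np.random.default_rng(tie_shuffle_seed)
        events["_tie"] = rng.permutation(len(events))
        events = events.sort_values(
            ["time_s", "_tie"], kind="stable"
        ).drop(columns="_tie").reset_index(drop=True)
    else:
        events = events.sort_values(
            ["time_s", "i", "j"], kind="stable"
        ).reset_index(drop=True)
    return EventSequence(
        events, team=team, context=context, dropped_detections=dropped
    )


def write_events_csv(sequences: list[EventSequence], path) -> None:
    """Write ``team,time_s,actor_i,actor_j`` sorted by (team, time, i, j)."""
    frames = []
    for seq in sequences:
        f = seq.events.rename(columns={"i": "actor_i", "j": "actor_j"})
        f.insert(0, "team", seq.team)
        frames.append(f)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["team", "time_s", "actor_i", "actor_j"])
    )
    out = out.sort_values(["team", "time_s", "actor_i", "actor_j"], kind="stable")
    out.to_csv(path, index=False)
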