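"""Scoring of online triggers against reference SWR events.

Online FIRED triggers are matched one-to-one to reference events
(offline-detected or ground-truth): a trigger matches an event when its
trigger time falls within ``[onset, offset + tolerance]`` (the trigger
fires after event onset plus processing latency, so it may land just
past the reference offset), assignment is greedy nearest-onset with
ties broken toward the earlier event. Unmatched triggers are false
positive detections (FPD), unmatched events missed detections (MD),
matched pairs positive detections (PD). Rates are percentages of the
union partition PD + FPD + MD, which sums to 100 by construction.
Trigger latency is trigger time minus matched-event onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError
from .offline import RippleEvent
from .online import TriggerLog
from .synth import StateSequence


@dataclass
class MatchTable:
    """One-to-one trigger↔event assignment at a given tolerance."""

    trigger_times_s: np.ndarray            # FIRED trigger times
    event_onsets_s: np.ndarray
    event_offsets_s: np.ndarray
    trigger_to_event: np.ndarray           # index or -1
    event_to_trigger: np.ndarray           # index or -1
    match_tolerance_s: float

    @property
    def n_pd(self) -> int:
        return int(np.sum(self.trigger_to_event >= 0))

    @property
    def n_fpd(self) -> int:
        return int(np.sum(self.trigger_to_event < 0))

    @property
    def n_md(self) -> int:
        return int(np.sum(self.event_to_trigger < 0))


@dataclass(frozen=True)
class DetectionRates:
    pd_pct: float
    fpd_pct: float
    md_pct: float
    n_pd: int
    n_fpd: int
    n_md: int


@dataclass
class LatencySummary:
    """Latencies of PD triggers with a 1 ms histogram.

    Bins are 1 ms wide covering at least [0, 50] ms, extended as needed
    so every latency — including flagged negative ones — is counted.
    """

    latencies_s: np.ndarray
    bin_edges_s: np.ndarray
    counts: np.ndarray
    n_negative: int
    empty: bool = False

    @property
    def min_s(self) -> float:
        return float(self.latencies_s.min()) if self.latencies_s.size else np.nan

    @property
    def max_s(self) -> float:
        return float(self.latencies_s.max()) if self.latencies_s.size else np.nan

    @property
    def modal_bin_s(self) -> tuple[float, float]:
        """(left, right) edges of the most populated 1 ms bin."""
        if self.empty:
            return (np.nan, np.nan)
        i = int(np.argmax(self.counts))
        return (float(self.bin_edges_s[i]), float(self.bin_edges_s[i + 1]))


def _check_sorted(arr: np.ndarray, name: str) -> None:
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise InvalidConfigError(f"{name} must be time-sorted")


def match_triggers(trigger_log: TriggerLog | np.ndarray,
                   reference_events: list[RippleEvent],
                   tolerance_s: float = 0.050) -> MatchTable:
    """Greedy one-to-one nearest-onset assignment of triggers to events."""
    if tolerance_s < 0:
        raise InvalidConfigError("tolerance must be >= 0")
    if isinstance(trigger_log, TriggerLog):
        trig = trigger_log.fired_times()
    else:
        trig = np.asarray(trigger_log, dtype=float)
    onsets = np.array([e.onset_s for e in reference_events])
    offsets = np.array([e.offset_s for e in reference_events])
    _check_sorted(trig, "trigger log")
    _check_sorted(onsets, "reference events")

    t2e = np.full(trig.size, -1, dtype=int)
    e2t = np.full(onsets.size, -1, dtype=int)
    for i, t in enumerate(trig):
        candidates = np.flatnonzero((onsets <= t) & (t <= offsets + tolerance_s)
                                    & (e2t < 0))
        if candidates.size == 0:
            continue
        dist = np.abs(onsets[candidates] - t)
        best = candidates[int(np.argmin(dist))]  # argmin: first (earlier) on ties
        t2e[i] = best
        e2t[best] = i
    return MatchTable(trigger_times_s=trig, event_onsets_s=onsets,
                      event_offsets_s=offsets, trigger_to_event=t2e,
                      event_to_trigger=e2t, match_tolerance_s=tolerance_s)


def detection_rates(match_table: MatchTable) -> DetectionRates:
    """PD/FPD/MD as percentages of the union partition (sums to 100)."""
    n_pd, n_fpd, n_md = (match_table.n_pd, match_table.n_fpd,
                         match_table.n_md)
    total = n_pd + n_fpd + n_md
    if total == 0:
        raise InvalidConfigError(
            "no triggers and no events: detection rates undefined")
    return DetectionRates(pd_pct=100.0 * n_pd / total,
                          fpd_pct=100.0 * n_fpd / total,
                          md_pct=100.0 * n_md / total,
                          n_pd=n_pd, n_fpd=n_fpd, n_md=n_md)


def trigger_latencies(match_table: MatchTable,
                      bin_width_s: float = 0.001,
                      min_range_s: float = 0.050) -> LatencySummary:
    """Latency (trigger time − matched event onset) per PD pair."""
    matched = np.flatnonzero(match_table.trigger_to_event >= 0)
    if matched.size == 0:
        edges = np.arange(0.0, min_range_s + bin_width_s / 2, bin_width_s)
        return LatencySummary(latencies_s=np.empty(0), bin_edges_s=edges,
                              counts=np.zeros(edges.size - 1, dtype=int),
                              n_negative=0, empty=True)
    lats = (match_table.trigger_times_s[matched]
            - match_table.event_onsets_s[match_table.trigger_to_event[matched]])
    lo = min(0.0, np.floor(lats.min() / bin_width_s) * bin_width_s)
    hi = max(min_range_s, np.ceil(lats.max() / bin_width_s) * bin_width_s)
    edges = np.arange(lo, hi + bin_width_s / 2, bin_width_s)
    counts, _ = np.histogram(lats, bins=edges)
    return LatencySummary(latencies_s=lats, bin_edges_s=edges, counts=counts,
                          n_negative=int(np.sum(lats < 0)))


def sleep_architecture(state_sequence: StateSequence) -> dict[str, float]:
    """Fraction of total time per state label (sums to 1)."""
    if not state_sequence.epochs:
        raise InvalidConfigError("empty state sequence")
    totals: dict[str, float] = {}
    for start, end, label in state_sequence.epochs:
        totals[label] = totals.get(label, 0.0) + (end - start)
    duration = sum(totals.values())
    return {label: t / duration for label, t in totals.items()}
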