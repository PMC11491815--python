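"""Per-bird flight activity and effort metrics.

Activity is summarised by the flight proportion R_flight (total flight
time over total recording time) and the mean flight duration T_flight
(total flight time over the number of bouts).  Effort is the per-flight
mean VeDBA (VeDBA_mean) averaged over a bird's flights with every flight
counted once (VeDBA_mean,bird); a duration-weighted variant is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classify import WindowLabels
from .segments import FlightSegment, segment_flights
from .signal import AccelTrace, VedbaSeries, segment_mean_vedba, vedba

#: Recordings shorter than this are flagged (not excluded).
MIN_RECORDING_S = 600.0


@dataclass(frozen=True)
class BirdSummary:
    """Activity/effort metrics for one individual plus its metadata.

    ``t_flight`` and ``vedba_mean_bird`` are None when the bird has no
    flights (the mean of zero bouts is undefined, not zero); such birds
    carry the ``"no_flights"`` flag.
    """

    bird_id: str
    sex: str | None
    brood_size: int | None
    tag_hour: float | None
    recording_duration: float
    r_flight: float
    t_flight: float | None
    n_flights: int
    flights_per_hour: float
    vedba_mean_bird: float | None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.r_flight <= 1:
            raise ValueError(f"r_flight must lie in [0, 1], got {self.r_flight}")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be > 0")


def flight_proportion(segments: list[FlightSegment], recording_duration: float) -> float:
    """R_flight: summed segment durations over the recording duration."""
    if recording_duration <= 0:
        raise ValueError("recording_duration must be > 0")
    total = 0.0
    for seg in segments:
        if seg.end > recording_duration + 1e-9:
            raise ValueError(f"segment ending at {seg.end} s exceeds the recording")
        total += seg.duration
    return total / recording_duration


def mean_flight_duration(segments: list[FlightSegment]) -> float:
    """T_flight: total flight time over the number of bouts (>= 1 bout)."""
    if not segments:
        raise ValueError("mean flight duration is undefined without flights")
    return sum(seg.duration for seg in segments) / len(segments)


def bird_effort(segments: list[FlightSegment], duration_weighted: bool = False) -> float:
    """VeDBA_mean,bird: average of per-flight mean VeDBA values.

    Each flight counts once by default; ``duration_weighted`` weights
    flights by their duration instead.
    """
    if not segments:
        raise ValueError("bird effort is undefined without flights")
    if any(seg.vedba_mean is None for seg in segments):
        raise ValueError("all segments need vedba_mean set")
    values = np.array([seg.vedba_mean for seg in segments])
    if duration_weighted:
        weights = np.array([seg.duration for seg in segments])
        return float((values * weights).sum() / weights.sum())
    return float(values.mean())


def attach_vedba(segments: list[FlightSegment], series: VedbaSeries) -> list[FlightSegment]:
    """Fill each segment's per-bout mean VeDBA from the sample series."""
    return [
        replace(seg, vedba_mean=segment_mean_vedba(series, seg.start, seg.duration))
        for seg in segments
    ]


def short_flight_fraction(segments: list[FlightSegment], threshold_s: float = 10.0) -> float:
    """Fraction of bouts shorter than ``threshold_s`` (10 s by default)."""
    if not segments:
        raise ValueError("undefined without flights")
    return sum(seg.duration < threshold_s for seg in segments) / len(segments)


def summarize_bird(
    trace: AccelTrace,
    labels: WindowLabels,
    bird_id: str = "bird",
    sex: str | None = None,
    brood_size: int | None = None,
    recording_start_hour: float | None = None,
    vedba_window: int = 5,
    fill_gaps: bool = True,
) -> tuple[BirdSummary, list[FlightSegment]]:
    """Run the full per-bird chain and summarise it.

    binarize -> fill single gaps -> segment -> per-segment mean VeDBA ->
    activity/effort metrics.  The tagging time is the midpoint of the
    recording (start plus half the span) when the start hour is known.
    """
    segs = segment_flights(labels, fill_gaps=fill_gaps)
    if segs:
        segs = attach_vedba(segs, vedba(trace, vedba_window))
    duration = trace.duration
    flags = []
    if duration < MIN_RECORDING_S:
        flags.append("short_recording")
    if not segs:
        flags.append("no_flights")
    tag_hour = None
    if recording_start_hour is not None:
        tag_hour = recording_start_hour + duration / 3600.0 / 2.0
    summary = BirdSummary(
        bird_id=bird_id,
        sex=sex,
        brood_size=brood_size,
        tag_hour=tag_hour,
        recording_duration=duration,
        r_flight=flight_proportion(segs, duration),
        t_flight=mean_flight_duration(segs) if segs else None,
        n_flights=len(segs),
        flights_per_hour=len(segs) / (duration / 3600.0),
        vedba_mean_bird=bird_effort(segs) if segs else None,
        flags=tuple(flags),
    )
    return summary, segs
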