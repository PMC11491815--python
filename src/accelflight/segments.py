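"""Flight-bout segmentation from window-level behaviour labels.

The six-class window sequence is collapsed to flying / non-flying, every
single non-flying window flanked by two flying ones is re-labelled as
flying (a sub-second pause inside a bout is still the same flight), and
maximal flying runs become flight segments with a start time and a
duration.

The gap rule is a single left-to-right pass evaluated on the *original*
sequence: in ``F,N,F,N,F`` both isolated N's are flanked by original F's
and both flip.  Runs of two or more N's never change, and a leading or
trailing N has no second flank, so it is never filled.  The rule is
idempotent and can only increase the number of flying windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classify import WindowLabels

FLYING = "flying"
KNOWN_CLASSES = frozenset(
    {"flying", "inactive", "food_shaking", "preening", "swallowing", "bill_wiping"}
)


@dataclass(frozen=True)
class FlightSegment:
    """One flight bout: start (s from trace start), duration (s), and the
    per-bout mean VeDBA (g) once the metrics layer fills it in."""

    start: float
    duration: float
    vedba_mean: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration <= 0:
            raise ValueError(f"invalid segment start={self.start} duration={self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration


def binarize(labels: WindowLabels | np.ndarray, known: frozenset = KNOWN_CLASSES) -> np.ndarray:
    """Collapse behaviour classes to a boolean flying sequence."""
    arr = np.asarray(labels.labels if isinstance(labels, WindowLabels) else labels, dtype=object)
    if arr.size == 0:
        raise ValueError("empty label sequence")
    unknown = {str(x) for x in arr} - set(known)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    return np.fromiter((str(x) == FLYING for x in arr), dtype=bool, count=arr.size)


def fill_single_gaps(flying: np.ndarray) -> np.ndarray:
    """Flip every isolated non-flying window between two flying ones."""
    b = np.asarray(flying, dtype=bool)
    out = b.copy()
    if b.size >= 3:
        isolated = ~b[1:-1] & b[:-2] & b[2:]
        out[1:-1][isolated] = True
    return out


def segment(flying: np.ndarray, window_duration: float) -> list[FlightSegment]:
    """Maximal flying runs as segments on the window time grid."""
    if window_duration <= 0:
        raise ValueError(f"window_duration must be > 0, got {window_duration}")
    b = np.asarray(flying, dtype=bool)
    padded = np.concatenate([[0], b.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [
        FlightSegment(start=float(s * window_duration), duration=float((e - s) * window_duration))
        for s, e in zip(starts, ends)
    ]


def segments_to_binary(segments: list[FlightSegment], window_duration: float, n_windows: int) -> np.ndarray:
    """Inverse of :func:`segment`: rebuild the boolean window sequence."""
    out = np.zeros(n_windows, dtype=bool)
    for seg in segments:
        i0 = int(round(seg.start / window_duration))
        i1 = int(round(seg.end / window_duration))
        if i1 > n_windows:
            raise ValueError("segment extends past the sequence")
        out[i0:i1] = True
    return out


def segment_flights(labels: WindowLabels, fill_gaps: bool = True) -> list[FlightSegment]:
    """binarize -> (fill single gaps) -> segment, on one window sequence."""
    b = binarize(labels)
    if fill_gaps:
        b = fill_single_gaps(b)
    return segment(b, labels.window_duration)
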