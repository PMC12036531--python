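"""Speech/pause interval sequences.

A :class:`SegmentSequence` is the common currency of the package: the voice
activity detector produces one per recording, the synthetic-data generator
produces one per fragment, and the fluency metrics consume them.  Intervals
are contiguous, non-overlapping, label-alternating and expressed in seconds
on a 0-based, half-open ``[start, end)`` timeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

SPEECH = "speech"
PAUSE = "pause"
_LABELS = (SPEECH, PAUSE)

# times equal when within this many seconds (0.1 ms)
_TIME_EPS = 1e-4


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    label: str

    @property
    def duration(self) -> float:
        return self.end - self.start


class SegmentSequence:
    """Ordered, contiguous speech/pause intervals covering a narration.

    Parameters
    ----------
    intervals
        Iterable of ``(start_s, end_s, label)`` tuples or :class:`Interval`
        objects.  Adjacent intervals sharing a label are merged.
    offset_s
        Offset of this sequence relative to its parent recording (set by
        :func:`pausekit.vad.split_fragments`); interval times always start
        at zero.
    is_partial
        True for a trailing fragment shorter than the nominal fragment
        length.
    """

    def __init__(
        self,
        intervals: Iterable,
        *,
        offset_s: float = 0.0,
        is_partial: bool = False,
    ) -> None:
        items: list[Interval] = []
        for iv in intervals:
            if not isinstance(iv, Interval):
                iv = Interval(float(iv[0]), float(iv[1]), str(iv[2]))
            if iv.label not in _LABELS:
                raise ValueError(f"unknown interval label {iv.label!r}")
            if not iv.end > iv.start:
                raise ValueError(
                    f"interval [{iv.start}, {iv.end}) has non-positive duration"
                )
            if items and items[-1].label == iv.label:
                items[-1] = Interval(items[-1].start, iv.end, iv.label)
                continue
            items.append(iv)
        if not items:
            raise ValueError("a SegmentSequence needs at least one interval")
        if abs(items[0].start) > _TIME_EPS:
            raise ValueError("first interval must start at 0")
        for prev, cur in zip(items, items[1:]):
            if abs(prev.end - cur.start) > _TIME_EPS:
                raise ValueError(
                    f"intervals not contiguous at t={prev.end:.4f}/{cur.start:.4f}"
                )
        # snap to exact contiguity so downstream sums are clean
        snapped = [items[0] if items[0].start == 0.0 else Interval(0.0, items[0].end, items[0].label)]
        for cur in items[1:]:
            snapped.append(Interval(snapped[-1].end, snapped[-1].end + cur.duration, cur.label))
        self._intervals: tuple[Interval, ...] = tuple(snapped)
        self.offset_s = float(offset_s)
        self.is_partial = bool(is_partial)

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Interval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i: int) -> Interval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentSequence):
            return NotImplemented
        return self.as_tuples() == other.as_tuples()

    def __repr__(self) -> str:
        return (
            f"SegmentSequence({len(self)} intervals, {self.duration:.2f} s, "
            f"{self.pause_time:.2f} s pause)"
        )

    # -- views --------------------------------------------------------------
    @property
    def intervals(self) -> tuple[Interval, ...]:
        return self._intervals

    @property
    def duration(self) -> float:
        return self._intervals[-1].end

    @property
    def speech_time(self) -> float:
        return float(sum(iv.duration for iv in self._intervals if iv.label == SPEECH))

    @property
    def pause_time(self) -> float:
        return float(sum(iv.duration for iv in self._intervals if iv.label == PAUSE))

    @property
    def pauses(self) -> tuple[Interval, ...]:
        return tuple(iv for iv in self._intervals if iv.label == PAUSE)

    @property
    def n_pauses(self) -> int:
        return sum(1 for iv in self._intervals if iv.label == PAUSE)

    def pause_durations_ms(self) -> np.ndarray:
        return np.array([iv.duration * 1000.0 for iv in self.pauses])

    def as_tuples(self) -> tuple[tuple[float, float, str], ...]:
        return tuple((iv.start, iv.end, iv.label) for iv in self._intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.as_tuples(), columns=["start_s", "end_s", "label"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "SegmentSequence":
        cols = ["start_s", "end_s", "label"]
        return cls(frame[cols].itertuples(index=False, name=None), **kwargs)

    @classmethod
    def from_durations(
        cls, durations_s: Sequence[float], labels: Sequence[str], **kwargs
    ) -> "SegmentSequence":
        """Build a sequence from consecutive interval durations."""
        t = 0.0
        ivs = []
        for d, lab in zip(durations_s, labels, strict=True):
            ivs.append((t, t + float(d), lab))
            t += float(d)
        return cls(ivs, **kwargs)
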