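"""Energy-based voice activity detection and pause extraction.

The detector computes frame log-energies over sliding windows, thresholds
them, optionally applies a hangover, and converts the frame labels into a
:class:`~pausekit.segments.SegmentSequence`.  Pauses are non-speech runs of
at least 50 ms, the conventional floor below which silent gaps are treated
as articulatory rather than genuine pauses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import MIN_PAUSE_MS
from .segments import PAUSE, SPEECH, SegmentSequence


@dataclass(frozen=True)
class FrameLabels:
    """Per-frame binary speech labels at a fixed hop."""

    labels: np.ndarray  # bool, True = speech
    hop_ms: float
    frame_ms: float

    def __post_init__(self) -> None:
        if not self.hop_ms > 0:
            raise ValueError("hop_ms must be > 0")
        if self.frame_ms < self.hop_ms:
            raise ValueError("frame_ms must be >= hop_ms")

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.hop_ms / 1000.0


@dataclass(frozen=True)
class PauseRecord:
    """One detected pause with its provenance metadata."""

    duration_ms: float
    fragment_id: int | None = None
    speaker_id: str | None = None
    group: str | None = None
    moment: int | None = None

    def __post_init__(self) -> None:
        if self.duration_ms < MIN_PAUSE_MS:
            raise ValueError(f"pauses shorter than {MIN_PAUSE_MS} ms are not records")


def detect_speech(
    waveform: np.ndarray,
    sample_rate: int,
    frame_ms: float = 25.0,
    hop_ms: float = 10.0,
    threshold_quantile: float | None = None,
    hangover_ms: float = 0.0,
    *,
    floor_dbfs: float = -60.0,
    margin_db: float = 3.0,
) -> FrameLabels:
    """Label each ``hop_ms`` slot of the waveform as speech or non-speech.

    The log-energy of a ``frame_ms`` window centred on each slot is compared
    against a threshold.  With ``threshold_quantile`` set, the threshold is
    that quantile of the frame log-energy distribution.  By default the
    threshold is ``max(Q95(logE) - margin_db, floor_dbfs)``: a few dB below
    the speech level, which places interval boundaries where half the window
    is speech, with an absolute floor so silent-only input is never promoted
    to speech.  A hangover keeps the speech label alive ``hangover_ms``
    after the last supra-threshold frame.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim == 2:  # stereo: downmix
        x = x.mean(axis=1)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("waveform must be a non-empty 1-D (or stereo 2-D) array")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    if threshold_quantile is not None and not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    frame = int(round(frame_ms * sample_rate / 1000.0))
    hop = int(round(hop_ms * sample_rate / 1000.0))
    if frame < 1 or hop < 1:
        raise ValueError("frame_ms/hop_ms too small for this sample rate")
    if x.size < frame:
        raise ValueError("waveform shorter than one analysis frame")

    n_slots = int(np.ceil(x.size / hop))
    csum = np.concatenate([[0.0], np.cumsum(x**2)])
    centers = (np.arange(n_slots) + 0.5) * hop
    lo = np.clip((centers - frame / 2).astype(int), 0, x.size)
    hi = np.clip((centers + frame / 2).astype(int), 0, x.size)
    width = np.maximum(hi - lo, 1)
    energy = (csum[hi] - csum[lo]) / width
    log_e = 10.0 * np.log10(energy + 1e-30)  # dBFS power

    if threshold_quantile is not None:
        thr = float(np.quantile(log_e, threshold_quantile))
    else:
        thr = max(float(np.quantile(log_e, 0.95)) - margin_db, floor_dbfs)
    labels = log_e > thr

    if hangover_ms > 0:
        k = int(round(hangover_ms / hop_ms))
        if k > 0:
            idx = np.flatnonzero(labels)
            for i in idx:
                labels[i : i + k + 1] = True
    return FrameLabels(labels=labels, hop_ms=hop_ms, frame_ms=frame_ms)


def _runs(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    """(start, stop, value) runs over a boolean array; stop exclusive."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, bool(labels[start])))
            start = i
    return out


def segments_from_labels(
    labels: FrameLabels,
    min_pause_ms: float = MIN_PAUSE_MS,
    min_speech_ms: float = 50.0,
) -> SegmentSequence:
    """Merge frame labels into a speech/pause interval sequence.

    Non-speech runs shorter than ``min_pause_ms`` are absorbed into the
    surrounding speech first; speech runs shorter than ``min_speech_ms``
    are then absorbed into the surrounding non-speech.  The output tiles
    exactly ``n_frames * hop_ms`` of time.
    """
    lab = np.asarray(labels.labels, dtype=bool)
    if lab.size == 0:
        raise ValueError("labels must be non-empty")
    hop = labels.hop_ms

    def absorb(arr: np.ndarray, value: bool, min_ms: float) -> np.ndarray:
        # flip runs of `value` shorter than min_ms, unless the whole array is `value`
        arr = arr.copy()
        runs = _runs(arr)
        if all(v == value for *_, v in runs):
            return arr
        for a, b, v in runs:
            if v == value and (b - a) * hop < min_ms:
                arr[a:b] = not value
        return arr

    lab = absorb(lab, False, min_pause_ms)   # short pauses first (tie-break)
    lab = absorb(lab, True, min_speech_ms)
    ivs = [
        (a * hop / 1000.0, b * hop / 1000.0, SPEECH if v else PAUSE)
        for a, b, v in _runs(lab)
    ]
    return SegmentSequence(ivs)


def extract_pauses(
    segments: SegmentSequence,
    metadata: dict | None = None,
    min_pause_ms: float = MIN_PAUSE_MS,
) -> list[PauseRecord]:
    """One :class:`PauseRecord` per pause interval of at least the floor."""
    meta = metadata or {}
    out = []
    for iv in segments.pauses:
        dur = iv.duration * 1000.0
        if dur >= min_pause_ms - 1e-9:
            out.append(PauseRecord(duration_ms=dur, **meta))
    return out


def pause_records_to_frame(records: list[PauseRecord]) -> pd.DataFrame:
    cols = ["speaker_id", "group", "moment", "fragment_id", "duration_ms"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def split_fragments(
    segments: SegmentSequence, fragment_s: float = 20.0
) -> list[SegmentSequence]:
    """Cut a sequence at multiples of ``fragment_s``.

    Intervals straddling a cut are split; each fragment is re-based to start
    at zero and carries ``offset_s``; a trailing short fragment is flagged
    ``is_partial``.  Concatenating the fragments reproduces the input.
    """
    if not fragment_s > 0:
        raise ValueError("fragment_s must be > 0")
    total = segments.duration
    out = []
    t0 = 0.0
    eps = 1e-9
    while t0 < total - eps:
        t1 = min(t0 + fragment_s, total)
        ivs = []
        for iv in segments:
            a, b = max(iv.start, t0), min(iv.end, t1)
            if b - a > eps:
                ivs.append((a - t0, b - t0, iv.label))
        out.append(
            SegmentSequence(ivs, offset_s=t0, is_partial=(t1 - t0) < fragment_s - eps)
        )
        t0 = t1
    return out
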